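"""Simulate pooled paired-end reads as post-alignment records.

Rather than running an external aligner, the simulator emits the alignment a
local aligner would produce, derived analytically from each haplotype's
coordinate map: a read lying wholly inside an unedited segment aligns
full-length; a read crossing an edit junction is anchored on its longest
reference-consistent end and soft-clipped thereafter, with the clipped bases
kept in the record; a small deletion (<= ``max_small_gap``) inside a read is
expressed as a CIGAR ``D`` operation instead of a clip, as local aligners do.
Reads derived from a TE payload align to the TE-library contig, so mates of
reads flanking a TE insertion appear on another contig (one-end-anchored
pairs).  Pairs spanning a deletion acquire an enlarged apparent insert and
pairs straddling a tandem head-to-tail junction acquire the everted
orientation signature, both emerging directly from the coordinate map.

Sequencing errors are substitutions only, applied after the alignment
coordinates are fixed (emulating an error-tolerant aligner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .._seq import mutate, revcomp
from .edits import EditValidationError, Haplotype, HaplotypePool
from .reference import TE_CONTIG, ReferenceSet

# pysam CIGAR operation codes
_OP = {"M": 0, "I": 1, "D": 2, "S": 4}


@dataclass
class SimAlignment:
    """Emulated local alignment of one read, in genome orientation."""

    contig: str
    pos: int  # 0-based leftmost aligned reference position
    cigar: list[tuple[str, int]]  # ops 'S', 'M', 'D' in genome orientation

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def ref_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def aligned_read_len(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")


@dataclass
class SimRead:
    """One simulated read; ``seq`` is stored in genome (haplotype) orientation."""

    seq: str
    is_reverse: bool
    hap_start: int  # 0-based start on the haplotype
    aln: SimAlignment | None  # None = unmapped
    crosses_breakpoint: bool

    @property
    def fastq_seq(self) -> str:
        return revcomp(self.seq) if self.is_reverse else self.seq


@dataclass
class SimReadPair:
    """A simulated fragment: two reads plus truth annotation."""

    name: str
    hap_index: int
    frag_start: int
    frag_len: int
    read1: SimRead
    read2: SimRead
    crosses_breakpoint: bool


def _runs(
    hap: Haplotype, a: int, b: int
) -> list[tuple[int, int, str | None, int]]:
    """Decompose haplotype interval [a, b) into per-segment runs.

    Each run is ``(offset_in_read, length, target_contig, target_start0)``.
    """
    out = []
    for seg in hap.segments:
        lo = max(a, seg.hap_start)
        hi = min(b, seg.hap_end)
        if hi > lo:
            out.append((lo - a, hi - lo, seg.target_contig, seg.target_start + (lo - seg.hap_start)))
    return out


def _anchor(
    runs: list[tuple[int, int, str | None, int]],
    read_len: int,
    from_start: bool,
    max_small_gap: int,
) -> SimAlignment | None:
    """Build the maximal alignment anchored at one end of the read."""
    seq_runs = runs if from_start else runs[::-1]
    first = seq_runs[0]
    if first[2] is None:
        return None
    contig = first[2]
    items: list[tuple[str, int]] = [("M", first[1])]
    ref_lo, ref_hi = first[3], first[3] + first[1]
    aligned = first[1]
    for off, length, tgt, tstart in seq_runs[1:]:
        if tgt != contig:
            break
        gap = (tstart - ref_hi) if from_start else (ref_lo - (tstart + length))
        if gap == 0:
            items.append(("M", length))
        elif 0 < gap <= max_small_gap:
            items.append(("D", gap))
            items.append(("M", length))
        else:
            break
        aligned += length
        if from_start:
            ref_hi = tstart + length
        else:
            ref_lo = tstart
    clip = read_len - aligned
    if not from_start:
        items = items[::-1]
    if clip:
        items = items + [("S", clip)] if from_start else [("S", clip)] + items
    # merge adjacent same-op items
    merged: list[tuple[str, int]] = []
    for op, n in items:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return SimAlignment(contig, ref_lo, merged)


def _align_read(
    hap: Haplotype,
    a: int,
    read_len: int,
    min_anchor: int,
    max_small_gap: int,
) -> SimAlignment | None:
    runs = _runs(hap, a, a + read_len)
    pre = _anchor(runs, read_len, True, max_small_gap)
    suf = _anchor(runs, read_len, False, max_small_gap)
    best = None
    for cand in (pre, suf):
        if cand is None:
            continue
        if best is None or cand.aligned_read_len > best.aligned_read_len:
            best = cand
    if best is None or best.aligned_read_len < min_anchor:
        return None
    return best


def simulate_pool_reads(
    pool: HaplotypePool,
    coverage: float,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    read_len: int = 125,
    error_rate: float = 0.0,
    seed: int = 0,
    min_anchor: int = 20,
    max_small_gap: int = 20,
) -> list[SimReadPair]:
    """Simulate read pairs from a haplotype pool at the given mean coverage.

    The number of fragments is set so the expected per-base depth over the
    first haplotype's length is ``coverage``; fragment lengths are drawn from
    Normal(``insert_mean``, ``insert_sd``) truncated to [read_len, haplotype
    length]; haplotypes are drawn per fragment at their pool frequencies.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    if not pool.haplotypes:
        raise EditValidationError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    mean_len = float(np.mean([len(h) for h in pool.haplotypes]))
    n_pairs = int(round(coverage * mean_len / (2 * read_len)))
    hap_idx = rng.choice(len(pool.haplotypes), size=n_pairs, p=pool.frequencies)
    pairs: list[SimReadPair] = []
    for i in range(n_pairs):
        hap = pool.haplotypes[hap_idx[i]]
        L = len(hap)
        frag = int(np.clip(round(rng.normal(insert_mean, insert_sd)), read_len, L))
        start = int(rng.integers(0, L - frag + 1))
        junctions = [j for j in hap.junction_positions() if start < j < start + frag]
        reads = []
        for a, is_rev in ((start, False), (start + frag - read_len, True)):
            aln = _align_read(hap, a, read_len, min_anchor, max_small_gap)
            seq = mutate(hap.seq[a : a + read_len], error_rate, rng)
            crosses = any(a < j < a + read_len for j in junctions)
            reads.append(SimRead(seq, is_rev, a, aln, crosses))
        pairs.append(
            SimReadPair(
                f"sim{i:07d}",
                int(hap_idx[i]),
                start,
                frag,
                reads[0],
                reads[1],
                bool(junctions),
            )
        )
    return pairs


def _sam_header(ref: ReferenceSet) -> pysam.AlignmentHeader:
    names = [ref.main_contig(), TE_CONTIG] if TE_CONTIG in ref.contigs else list(ref.contigs)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(ref.contigs[n])} for n in names],
        }
    )


def write_sam(pairs: list[SimReadPair], ref: ReferenceSet, path: str) -> None:
    """Write simulated pairs as coordinate-sorted SAM text."""
    header = _sam_header(ref)
    segs: list[pysam.AlignedSegment] = []
    for pair in pairs:
        mates = (pair.read1, pair.read2)
        built = []
        for k, read in enumerate(mates):
            a = pysam.AlignedSegment(header)
            a.query_name = pair.name
            a.query_sequence = read.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            a.is_paired = True
            a.is_read1 = k == 0
            a.is_read2 = k == 1
            a.is_reverse = read.is_reverse
            if read.aln is None:
                a.is_unmapped = True
                a.mapping_quality = 0
            else:
                a.reference_name = read.aln.contig
                a.reference_start = read.aln.pos
                a.mapping_quality = 60
                a.cigartuples = [(_OP[op], n) for op, n in read.aln.cigar]
            a.set_tag("XH", pair.hap_index)
            a.set_tag("XB", int(read.crosses_breakpoint))
            built.append(a)
        r1, r2 = built
        for a, b, mate in ((r1, r2, pair.read2), (r2, r1, pair.read1)):
            a.mate_is_reverse = mate.is_reverse
            if b.is_unmapped:
                a.mate_is_unmapped = True
                if not a.is_unmapped:
                    b.reference_name = a.reference_name
                    b.reference_start = a.reference_start
            else:
                a.next_reference_name = b.reference_name
                a.next_reference_start = b.reference_start
        if not r1.is_unmapped and not r2.is_unmapped and r1.reference_id == r2.reference_id:
            lo = min(r1.reference_start, r2.reference_start)
            hi = max(r1.reference_end, r2.reference_end)
            tlen = hi - lo
            left_first = r1.reference_start <= r2.reference_start
            r1.template_length = tlen if left_first else -tlen
            r2.template_length = -tlen if left_first else tlen
            proper = (
                r1.is_reverse != r2.is_reverse
                and tlen <= insert_upper_bound()
            )
            r1.is_proper_pair = proper
            r2.is_proper_pair = proper
        segs.extend(built)
    segs.sort(key=lambda s: (s.reference_id if s.reference_id >= 0 else 1 << 30, s.reference_start))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for s in segs:
            out.write(s)


def insert_upper_bound(insert_mean: float = 350.0, insert_sd: float = 50.0, k: float = 4.0) -> float:
    """Upper insert-size bound used for the proper-pair flag."""
    return insert_mean + k * insert_sd


def write_fastq(pairs: list[SimReadPair], path1: str, path2: str) -> None:
    """Write the pairs as two FASTQ files (sequencing orientation)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            for read, fh, tag in ((pair.read1, f1, "/1"), (pair.read2, f2, "/2")):
                fh.write(
                    f"@{pair.name}{tag}\n{read.fastq_seq}\n+\n{'I' * len(read.seq)}\n"
                )


def write_reference_fasta(ref: ReferenceSet, path: str, width: int = 80) -> None:
    """Write all contigs (main + TE library) as FASTA."""
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
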