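"""Structural-variant detection from pooled paired-end alignments.

Copy-number and structural variants are inferred from three linked lines of
evidence, then reconciled into records with exact breakpoints:

1. **Coverage depth** relative to the genome-wide median: runs of elevated
   (gain) or depressed (loss) smoothed relative depth mark candidate
   copy-number regions.
2. **Anomalous read pairs**: correctly oriented pairs with a too-large
   apparent insert indicate a deletion in the sequenced sample; pairs in
   everted (swapped) orientation indicate a head-to-tail tandem junction;
   pairs whose mates align to another contig feed the transposon scan.
3. **Chimeric (clipped) reads**: reads soft-clipped at a breakpoint whose
   clipped sequence matches reference sequence at the partner breakpoint
   define both breakpoints exactly and the variant's orientation class.

A variant is called when at least two evidence lines agree; breakpoints come
from chimeric matches when available (exact), else from depth-run edges
(approximate).  Breakpoint labels use ``contig:left–right`` with left = last
unaffected base and right = last affected base (1-based), and the reported
length is (right - left)/1000 kb truncated to 0.1 kb.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.ndimage import gaussian_filter1d

from ._seq import encode


@dataclass
class AlignmentRecord:
    """The slice of a SAM record the SV/TE scans need."""

    qname: str
    contig: str
    pos: int  # 1-based leftmost aligned position
    is_reverse: bool
    mapq: int
    ref_len: int  # reference span of the alignment (M/D)
    left_clip: int
    right_clip: int
    left_clip_seq: str
    right_clip_seq: str
    cigar: tuple[tuple[int, int], ...]
    mate_contig: str | None
    mate_pos: int  # 1-based; 0 if unavailable
    mate_is_reverse: bool
    tlen: int
    seq: str = field(repr=False, default="")

    @property
    def end(self) -> int:
        """1-based position of the last aligned base."""
        return self.pos + self.ref_len - 1

    def ref_positions(self) -> dict[int, str]:
        """Map of 1-based aligned reference positions to read bases (M only)."""
        out: dict[int, str] = {}
        rpos, qpos = self.pos, 0
        for op, n in self.cigar:
            if op == 0:  # M
                for k in range(n):
                    out[rpos + k] = self.seq[qpos + k]
                rpos += n
                qpos += n
            elif op == 2:  # D
                rpos += n
            elif op in (1, 4):  # I, S
                qpos += n
        return out


class UnsortedInputError(ValueError):
    """Raised when alignments are not coordinate-sorted."""


def read_alignments(path: str) -> list[AlignmentRecord]:
    """Read SAM text into :class:`AlignmentRecord` objects (mapped reads)."""
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            ct = tuple((op, n) for op, n in a.cigartuples)
            lclip = ct[0][1] if ct[0][0] == 4 else 0
            rclip = ct[-1][1] if ct[-1][0] == 4 else 0
            seq = a.query_sequence or ""
            records.append(
                AlignmentRecord(
                    qname=a.query_name,
                    contig=a.reference_name,
                    pos=a.reference_start + 1,
                    is_reverse=a.is_reverse,
                    mapq=a.mapping_quality,
                    ref_len=a.reference_length or 0,
                    left_clip=lclip,
                    right_clip=rclip,
                    left_clip_seq=seq[:lclip] if lclip else "",
                    right_clip_seq=seq[len(seq) - rclip :] if rclip else "",
                    cigar=ct,
                    mate_contig=a.next_reference_name if not a.mate_is_unmapped else None,
                    mate_pos=(a.next_reference_start + 1) if not a.mate_is_unmapped else 0,
                    mate_is_reverse=a.mate_is_reverse,
                    tlen=a.template_length,
                    seq=seq,
                )
            )
    return records


def preprocess(records: list[AlignmentRecord], min_mapq: int = 10) -> list[AlignmentRecord]:
    """Filter on mapping quality and collapse duplicates.

    Records with mapq below ``min_mapq`` are removed.  Duplicates — identical
    (contig, position, strand, CIGAR, mate position) — are collapsed to one;
    including the CIGAR in the key avoids merging distinct clipped reads at
    breakpoints.  Raises :class:`UnsortedInputError` on unsorted input.
    """
    last: dict[str, int] = {}
    for r in records:
        if r.contig in last and r.pos < last[r.contig]:
            raise UnsortedInputError("input alignments must be coordinate-sorted")
        last[r.contig] = r.pos
    seen: set[tuple] = set()
    out = []
    for r in records:
        if r.mapq < min_mapq:
            continue
        key = (r.contig, r.pos, r.is_reverse, r.cigar, r.mate_pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Evidence line 1: coverage depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Per-position aligned depth, genome-wide median and smoothed relative depth."""

    depth: dict[str, np.ndarray]
    median: float
    relative: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    bandwidth: float


def depth_profile(
    records: list[AlignmentRecord],
    contig_lengths: dict[str, int],
    bandwidth: float = 250.0,
) -> DepthProfile:
    """Depth of aligned (non-clipped) bases per position, relative to the
    genome-wide median over covered positions, kernel-smoothed."""
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in contig_lengths.items()}
    for r in records:
        if r.contig not in depth:
            continue
        arr = depth[r.contig]
        rpos = r.pos - 1
        for op, n in r.cigar:
            if op == 0:  # M adds depth
                arr[rpos : rpos + n] += 1
                rpos += n
            elif op == 2:  # D advances without depth
                rpos += n
    covered = np.concatenate([a[a > 0] for a in depth.values() if (a > 0).any()] or [np.array([])])
    if covered.size == 0:
        raise ValueError("no aligned coverage")
    med = float(np.median(covered))
    relative = {c: a / med for c, a in depth.items()}
    smoothed = {c: gaussian_filter1d(rel.astype(float), bandwidth) for c, rel in relative.items()}
    return DepthProfile(depth, med, relative, smoothed, bandwidth)


@dataclass(frozen=True)
class CNVInterval:
    contig: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    kind: str  # "gain" | "loss"
    mean_relative_depth: float


def cnv_candidate_regions(
    profile: DepthProfile,
    up_thresh: float = 1.4,
    down_thresh: float = 0.6,
    min_len: int = 500,
) -> list[CNVInterval]:
    """Maximal runs of smoothed relative depth beyond the gain/loss thresholds."""
    out = []
    for contig, sm in profile.smoothed.items():
        if not (profile.depth[contig] > 0).any():
            continue  # uncovered contig (e.g. an unused TE-library contig)
        for kind, mask in (("gain", sm >= up_thresh), ("loss", sm <= down_thresh)):
            if not mask.any():
                continue
            edges = np.diff(mask.astype(np.int8))
            starts = list(np.nonzero(edges == 1)[0] + 1)
            ends = list(np.nonzero(edges == -1)[0] + 1)
            if mask[0]:
                starts.insert(0, 0)
            if mask[-1]:
                ends.append(len(mask))
            for s, e in zip(starts, ends):
                if e - s >= min_len:
                    rel = float(profile.relative[contig][s:e].mean())
                    out.append(CNVInterval(contig, s + 1, e, kind, rel))
    return sorted(out, key=lambda iv: (iv.contig, iv.start))


# ---------------------------------------------------------------------------
# Evidence line 2: read-pair classes
# ---------------------------------------------------------------------------

@dataclass
class PairClasses:
    concordant: list[AlignmentRecord]
    deletion_type: list[AlignmentRecord]
    tandem_type: list[AlignmentRecord]
    interchromosomal: list[AlignmentRecord]


def classify_read_pairs(
    records: list[AlignmentRecord],
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    k: float = 4.0,
) -> PairClasses:
    """Classify pairs by orientation and apparent insert size.

    Each pair is represented once, by its leftmost mapped record.
    Deletion-type: forward-reverse orientation with insert > mean + k*sd.
    Tandem-type: everted orientation (leftmost read reverse, mate forward),
    the signature of reads spanning a head-to-tail duplication junction.
    """
    classes = PairClasses([], [], [], [])
    upper = insert_mean + k * insert_sd
    for r in records:
        if r.mate_contig is None:
            continue
        if r.mate_contig != r.contig:
            classes.interchromosomal.append(r)
            continue
        if r.pos > r.mate_pos or (r.pos == r.mate_pos and r.is_reverse):
            continue  # count each pair once, via its leftmost record
        if r.is_reverse and not r.mate_is_reverse:
            classes.tandem_type.append(r)
        elif not r.is_reverse and r.mate_is_reverse:
            if abs(r.tlen) > upper:
                classes.deletion_type.append(r)
            else:
                classes.concordant.append(r)
        # same-strand pairs (inversion-like) are ignored: not called here
    return classes


# ---------------------------------------------------------------------------
# Evidence line 3: clipped-read clusters and chimeric matches
# ---------------------------------------------------------------------------

@dataclass
class ClipCluster:
    """A cluster of reads clipped at a common boundary.

    ``side`` is where the clip falls on the alignment: ``"right"`` means
    reads align up to ``boundary`` (1-based last aligned base) and are
    clipped after it; ``"left"`` means reads are clipped before ``boundary``
    (1-based first aligned base).  The consensus is the majority vote of the
    clipped sequences, anchored at the junction.
    """

    contig: str
    boundary: int
    side: str
    support: int
    consensus: str


def _consensus(strings: list[str], anchored_right: bool) -> str:
    """Majority-vote consensus of variable-length strings.

    For right-anchored strings (left-side clips, which end at the junction)
    the vote is taken per column counting from the junction end.
    """
    if anchored_right:
        strings = [s[::-1] for s in strings]
    length = max(len(s) for s in strings)
    cols = []
    for i in range(length):
        votes: dict[str, int] = defaultdict(int)
        for s in strings:
            if i < len(s):
                votes[s[i]] += 1
        cols.append(max(votes, key=votes.get))
    out = "".join(cols)
    return out[::-1] if anchored_right else out


def clip_clusters(
    records: list[AlignmentRecord],
    min_support: int = 3,
    tolerance: int = 2,
    min_clip: int = 5,
) -> list[ClipCluster]:
    """Cluster soft-clip boundaries within ``tolerance`` bp, by clip side."""
    raw: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    for r in records:
        if r.right_clip >= min_clip:
            raw[(r.contig, "right")].append((r.end, r.right_clip_seq))
        if r.left_clip >= min_clip:
            raw[(r.contig, "left")].append((r.pos, r.left_clip_seq))
    clusters = []
    for (contig, side), items in raw.items():
        items.sort()
        group: list[tuple[int, str]] = []
        for pos, seq in items + [(10**15, "")]:
            if group and pos - group[-1][0] > tolerance:
                if len(group) >= min_support:
                    boundary = int(np.median([p for p, _ in group]))
                    cons = _consensus([s for _, s in group], anchored_right=(side == "left"))
                    if len(cons) >= 5:
                        clusters.append(
                            ClipCluster(contig, boundary, side, len(group), cons)
                        )
                group = []
            if seq:
                group.append((pos, seq))
    return sorted(clusters, key=lambda c: (c.contig, c.boundary))


@dataclass
class ChimericMatch:
    """A clipped-consensus match to reference sequence at a partner breakpoint."""

    cluster: ClipCluster
    contig: str
    match_start: int  # 1-based
    match_end: int  # 1-based inclusive
    identity: float
    kind: str  # implied SV kind: "deletion" | "tandem_duplication"
    left: int
    right: int


def _best_match(consensus: str, ref_codes: np.ndarray) -> tuple[int, float] | None:
    """Best gapless placement of ``consensus`` on the reference.

    Returns (0-based start, identity) of the best full-length placement.
    """
    m = len(consensus)
    if m > len(ref_codes) or m == 0:
        return None
    cons = encode(consensus)
    windows = np.lib.stride_tricks.sliding_window_view(ref_codes, m)
    matches = (windows == cons).sum(axis=1)
    best = int(np.argmax(matches))
    return best, matches[best] / m


def match_chimeric(
    cluster: ClipCluster,
    ref: dict[str, str],
    min_identity: float = 0.9,
    min_len: int = 15,
    max_consensus: int = 80,
    search_radius: int = 200_000,
) -> ChimericMatch | None:
    """Locate a clip cluster's consensus in the reference and infer the SV.

    Geometry: a right-side clip at boundary L whose clipped sequence matches
    reference *downstream* implies a deletion (the clipped part is the
    sequence beyond the deleted segment); a match *upstream* implies a
    head-to-tail tandem junction.  Mirrored logic applies to left-side
    clips.  Returns ``None`` when no adequate match exists (the cluster is
    retained for the TE scan).
    """
    cons = cluster.consensus
    if len(cons) < min_len:
        return None
    if cluster.side == "left" and len(cons) > max_consensus:
        cons = cons[-max_consensus:]  # keep the junction-adjacent part
    elif len(cons) > max_consensus:
        cons = cons[:max_consensus]
    seq = ref[cluster.contig]
    lo = max(0, cluster.boundary - 1 - search_radius)
    hi = min(len(seq), cluster.boundary - 1 + search_radius)
    codes = encode(seq[lo:hi])
    hit = _best_match(cons, codes)
    if hit is None or hit[1] < min_identity:
        return None
    start0 = lo + hit[0]
    match_start = start0 + 1
    match_end = start0 + len(cons)
    if cluster.side == "right":
        b = cluster.boundary
        if match_start > b:
            kind, left, right = "deletion", b, match_start - 1
        else:
            kind, left, right = "tandem_duplication", match_start - 1, b
    else:
        b = cluster.boundary  # first aligned base after the junction
        if match_end < b:
            kind, left, right = "deletion", match_end, b - 1
        else:
            kind, left, right = "tandem_duplication", b - 1, match_end
    if left >= right:
        return None
    return ChimericMatch(
        cluster, cluster.contig, match_start, match_end, hit[1], kind, left, right
    )


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def length_kb(left: int, right: int) -> float:
    """SV length in kb, truncated (floor) to 0.1 kb: floor((right-left)/100)/10."""
    return math.floor((right - left) / 100) / 10


@dataclass
class SVRecord:
    """A called structural variant."""

    kind: str  # tandem_duplication | deletion | insertion_polymorphism
    contig: str
    left: int
    right: int
    exact: bool = True
    frequency: float = float("nan")
    copy_estimate: tuple[int, int] | None = None
    nested_in: str | None = None
    conflict: bool = False
    evidence: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.contig}:{self.left}–{self.right}"

    @property
    def length_kb(self) -> float:
        return length_kb(self.left, self.right)


def _merge_candidates(
    matches: list[ChimericMatch], tolerance: int = 2
) -> list[tuple[str, str, int, int, int]]:
    """Group chimeric matches into (kind, contig, left, right, n_clusters)."""
    groups: list[list[ChimericMatch]] = []
    for m in sorted(matches, key=lambda m: (m.contig, m.kind, m.left, m.right)):
        placed = False
        for g in groups:
            h = g[0]
            if (
                h.kind == m.kind
                and h.contig == m.contig
                and abs(h.left - m.left) <= tolerance
                and abs(h.right - m.right) <= tolerance
            ):
                g.append(m)
                placed = True
                break
        if not placed:
            groups.append([m])
    out = []
    for g in groups:
        # prefer breakpoints seen by both clip sides; else majority
        lefts = sorted(m.left for m in g)
        rights = sorted(m.right for m in g)
        out.append((g[0].kind, g[0].contig, lefts[len(lefts) // 2], rights[len(rights) // 2], len(g)))
    return out


def call_svs(
    cnv_regions: list[CNVInterval],
    pairs: PairClasses,
    matches: list[ChimericMatch],
    insert_mean: float = 350.0,
    min_pair_support: int = 2,
    tolerance: int = 2,
) -> list[SVRecord]:
    """Reconcile the three evidence lines into SV records.

    A record is emitted when at least two lines agree.  Chimeric matches give
    exact breakpoints; candidates with only depth + pair support are emitted
    with approximate (depth-edge) breakpoints.  A deletion lying inside a
    called duplication is flagged as nested (duplication-with-deletion
    haplotypes); records of conflicting kind at the same locus are both
    reported with a conflict flag.
    """
    records: list[SVRecord] = []
    for kind, contig, left, right, n_clusters in _merge_candidates(matches, tolerance):
        if kind == "deletion":
            support_pairs = [
                p
                for p in pairs.deletion_type
                if p.contig == contig and p.end <= left + insert_mean and p.mate_pos + 1 >= right - insert_mean
                and p.end <= right and p.mate_pos >= left
            ]
            depth_hit = any(
                iv.kind == "loss" and iv.contig == contig and _overlap(iv, left, right) > 0.5
                for iv in cnv_regions
            )
        else:
            support_pairs = [
                p
                for p in pairs.tandem_type
                if p.contig == contig
                and left - insert_mean <= p.pos
                and p.mate_pos <= right + insert_mean
            ]
            depth_hit = any(
                iv.kind == "gain" and iv.contig == contig and _overlap(iv, left, right) > 0.5
                for iv in cnv_regions
            )
        lines = 1 + (len(support_pairs) >= min_pair_support) + depth_hit
        if lines >= 2:
            records.append(
                SVRecord(
                    kind,
                    contig,
                    left,
                    right,
                    exact=True,
                    evidence={
                        "n_clip_clusters": n_clusters,
                        "n_discordant_pairs": len(support_pairs),
                        "depth_support": bool(depth_hit),
                    },
                )
            )

    # depth+pair candidates lacking chimeric confirmation: approximate records
    for iv in cnv_regions:
        kind = "tandem_duplication" if iv.kind == "gain" else "deletion"
        iv_len = iv.end - iv.start + 1
        if any(
            r.kind == kind
            and r.contig == iv.contig
            and (min(iv.end, r.right) - max(iv.start, r.left + 1) + 1) / iv_len > 0.5
            for r in records
        ):
            continue
        pool = pairs.tandem_type if iv.kind == "gain" else pairs.deletion_type
        support_pairs = [
            p
            for p in pool
            if p.contig == iv.contig
            and iv.start - insert_mean <= p.pos
            and p.mate_pos <= iv.end + insert_mean
        ]
        if len(support_pairs) >= min_pair_support:
            records.append(
                SVRecord(
                    kind,
                    iv.contig,
                    iv.start,
                    iv.end,
                    exact=False,
                    evidence={
                        "n_clip_clusters": 0,
                        "n_discordant_pairs": len(support_pairs),
                        "depth_support": True,
                        "mean_relative_depth": iv.mean_relative_depth,
                    },
                )
            )

    # nesting and conflicts
    for r in records:
        if r.kind != "deletion":
            continue
        for d in records:
            if (
                d.kind == "tandem_duplication"
                and d.contig == r.contig
                and d.left <= r.left
                and r.right <= d.right
            ):
                r.nested_in = d.label
    for r in records:
        for s in records:
            if (
                r is not s
                and r.kind != s.kind
                and r.contig == s.contig
                and s.nested_in is None
                and r.nested_in is None
                and min(r.right, s.right) - max(r.left, s.left) > 0
            ):
                r.conflict = True
    return sorted(records, key=lambda r: (r.contig, r.left, r.right))


def _overlap(iv: CNVInterval, left: int, right: int) -> float:
    """Overlap of a CNV interval with (left, right], as a fraction of the span."""
    inter = min(iv.end, right) - max(iv.start, left + 1) + 1
    return max(inter, 0) / (right - left)


def sv_frequency(
    sv: SVRecord,
    records: list[AlignmentRecord],
    tolerance: int = 2,
    margin: int = 5,
) -> float:
    """Variant frequency from chimeric vs. read-through reads at the breakpoints.

    Junction support is the number of reads clipped at either breakpoint
    boundary; read-through support is the number of reads aligned
    continuously across a boundary.  Each junction-crossing read is clipped
    at exactly one of the two boundaries (whichever end anchors), while
    read-through flux is counted at both, so the unbiased carrier-frequency
    estimate is C / (C + T/2) with C and T summed over both breakpoints.
    NaN when no informative reads.

    Deletion chimeras clip after the left breakpoint and before the right
    one; tandem-duplication chimeras clip at the far end of each copy, i.e.
    after ``right`` and before ``left + 1``.  For duplications the junction
    estimate f equals q(c-1)/(q(c-1)+1) for carrier frequency q and copy
    number c; the returned value inverts this under the 2-copy assumption
    (q = f/(1-f), capped at 1).
    """
    if sv.kind == "tandem_duplication":
        boundaries = ((sv.right, "right"), (sv.left + 1, "left"))
    else:
        boundaries = ((sv.left, "right"), (sv.right + 1, "left"))
    chim_total = thr_total = 0
    informative = False
    for boundary, side in boundaries:
        chimeric = through = 0
        for r in records:
            if r.contig != sv.contig:
                continue
            if side == "right":
                if r.right_clip >= 5 and abs(r.end - boundary) <= tolerance:
                    chimeric += 1
                elif r.pos + margin - 1 <= boundary and r.end - margin + 1 >= boundary + 1 and r.right_clip < 5 and r.left_clip < 5:
                    through += 1
            else:
                if r.left_clip >= 5 and abs(r.pos - boundary) <= tolerance:
                    chimeric += 1
                elif r.pos + margin - 1 <= boundary - 1 and r.end - margin + 1 >= boundary and r.left_clip < 5 and r.right_clip < 5:
                    through += 1
        chim_total += chimeric
        thr_total += through
        informative = informative or (chimeric + through) > 0
    if not informative:
        return float("nan")
    f = chim_total / (chim_total + thr_total / 2.0)
    if sv.kind == "tandem_duplication":
        return min(f / (1.0 - f), 1.0) if f < 1.0 else 1.0
    return f


def copy_number_estimate(
    sv: SVRecord, profile: DepthProfile, band: float = 0.25
) -> tuple[int, int] | None:
    """Tandem copy number from relative depth adjusted for variant frequency.

    With relative depth ``rel`` over the duplicated span and variant
    frequency ``q``, the carried haplotypes have ``(rel - (1 - q)) / q``
    copies.  Reported as a single integer when within ``band`` of an
    integer, else as the bracketing integer range (e.g. relative depth 3.5
    at q = 1 gives 3–4 copies).
    """
    q = sv.frequency
    if not q or math.isnan(q) or q <= 0:
        return None
    rel = float(profile.relative[sv.contig][sv.left : sv.right].mean())
    x = (rel - (1.0 - q)) / q
    nearest = round(x)
    if abs(x - nearest) <= band and nearest >= 1:
        return (int(nearest), int(nearest))
    return (max(int(math.floor(x)), 1), int(math.ceil(x)))


# ---------------------------------------------------------------------------
# End-to-end convenience + output
# ---------------------------------------------------------------------------

def scan(
    sam_path: str,
    ref: dict[str, str],
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    min_mapq: int = 10,
    min_support: int = 3,
    insert_sd_k: float = 4.0,
) -> tuple[list[SVRecord], DepthProfile]:
    """Run the full SV scan on a SAM file against reference sequences."""
    records = preprocess(read_alignments(sam_path), min_mapq=min_mapq)
    profile = depth_profile(records, {c: len(s) for c, s in ref.items()})
    cnv = cnv_candidate_regions(profile)
    pairs = classify_read_pairs(records, insert_mean, insert_sd, insert_sd_k)
    clusters = clip_clusters(records, min_support=min_support)
    matches = [m for c in clusters if (m := match_chimeric(c, ref)) is not None]
    svs = call_svs(cnv, pairs, matches, insert_mean)
    for sv in svs:
        if sv.exact:
            sv.frequency = sv_frequency(sv, records)
        if sv.kind == "tandem_duplication":
            sv.copy_estimate = copy_number_estimate(sv, profile)
    return svs, profile


def classify_polymorphic(records: list[SVRecord], lo: float = 0.05, hi: float = 0.95) -> None:
    """Re-label deletions segregating at intermediate frequency.

    A deletion at frequency strictly between ``lo`` and ``hi`` is a
    segregating insertion/deletion polymorphism rather than a fixed variant;
    its kind becomes ``insertion_polymorphism`` (the record keeps the
    deletion-frequency value: the insertion allele frequency is its
    complement).  Deletions nested inside a duplication are exempt: their
    read-through support comes from the intact copy on the same haplotype,
    so an intermediate junction fraction reflects the copy configuration,
    not a segregating allele.
    """
    for r in records:
        if (
            r.kind == "deletion"
            and r.nested_in is None
            and not math.isnan(r.frequency)
            and lo < r.frequency < hi
        ):
            r.kind = "insertion_polymorphism"


def write_sv_tsv(records: list[SVRecord], path: str) -> None:
    import pandas as pd

    rows = []
    for r in records:
        cp = r.copy_estimate
        rows.append(
            {
                "kind": r.kind,
                "contig": r.contig,
                "left": r.left,
                "right": r.right,
                "label": r.label,
                "length_kb": r.length_kb,
                "exact": r.exact,
                "frequency": r.frequency,
                "copies": "" if cp is None else (str(cp[0]) if cp[0] == cp[1] else f"{cp[0]}–{cp[1]}"),
                "nested_in": r.nested_in or "",
                "conflict": r.conflict,
                "n_clip_clusters": r.evidence.get("n_clip_clusters", 0),
                "n_discordant_pairs": r.evidence.get("n_discordant_pairs", 0),
                "depth_support": r.evidence.get("depth_support", False),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sv_bed(records: list[SVRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.left}\t{r.right}\t{r.label}\t{r.kind}\n")
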