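"""Structural edits applied to a reference to build haplotypes.

Coordinate convention (used throughout the package): breakpoints are 1-based;
``left`` is the last unaffected base before the edited segment and ``right``
is the last affected base, so the affected slice in 0-based half-open
coordinates is ``[left, right)`` and the span length is ``right - left``.
A tandem duplication of ``left=100, right=200`` therefore duplicates the
0-based slice ``seq[100:200]`` head-to-tail, and its junction sequence is
``seq[190:200] + seq[100:110]``.

A transposon insertion at position ``left`` with target-site duplication
length ``d`` inserts the payload after base ``left`` and then repeats the
``d`` reference bases immediately preceding the insertion point, so the TSD
appears on both flanks of the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import TE_CONTIG, ReferenceSet

EDIT_KINDS = ("tandem_duplication", "deletion", "insertion", "te_insertion")
SPAN_KINDS = ("tandem_duplication", "deletion")


class EditValidationError(ValueError):
    """Raised for invalid or overlapping structural edits."""


@dataclass(frozen=True)
class StructuralEdit:
    """One structural change relative to the reference.

    ``payload`` is the inserted sequence (``insertion``) or the TE name
    (``te_insertion``).  ``right`` is unused for insertions; ``copies`` only
    applies to tandem duplications; ``tsd_len`` only to TE insertions.
    """

    kind: str
    contig: str
    left: int
    right: int = 0
    payload: str | None = None
    tsd_len: int = 0
    copies: int = 2

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise EditValidationError(f"unknown edit kind {self.kind!r}")
        if self.kind in SPAN_KINDS and not self.left < self.right:
            raise EditValidationError(f"{self.kind} requires left < right")
        if self.kind == "tandem_duplication" and self.copies < 2:
            raise EditValidationError("tandem_duplication requires copies >= 2")
        if self.kind == "te_insertion" and not 0 <= self.tsd_len <= 20:
            raise EditValidationError("tsd_len must be in [0, 20]")
        if self.kind in ("insertion", "te_insertion") and not self.payload:
            raise EditValidationError(f"{self.kind} requires a payload")

    @property
    def span(self) -> int:
        """Length of the affected reference segment (0 for insertions)."""
        return self.right - self.left if self.kind in SPAN_KINDS else 0

    @property
    def label(self) -> str:
        """Breakpoint label, e.g. ``rp1:37410–43954``."""
        return f"{self.contig}:{self.left}–{self.right}"

    def interval0(self) -> tuple[int, int]:
        """Affected 0-based half-open reference interval (point for insertions)."""
        if self.kind in SPAN_KINDS:
            return (self.left, self.right)
        return (self.left, self.left)


@dataclass(frozen=True)
class Segment:
    """Maps a haplotype slice ``[hap_start, hap_start+length)`` to its origin.

    ``target_contig`` is a reference contig (possibly the TE-library contig)
    with ``target_start`` the 0-based start there, or ``None`` for novel
    inserted sequence.
    """

    hap_start: int
    length: int
    target_contig: str | None
    target_start: int

    @property
    def hap_end(self) -> int:
        return self.hap_start + self.length


@dataclass
class Haplotype:
    """An edited sequence plus its piecewise-affine coordinate map."""

    name: str
    seq: str
    segments: list[Segment]
    edits: list[StructuralEdit]
    source_contig: str

    def __len__(self) -> int:
        return len(self.seq)

    def hap_to_ref(self, pos: int) -> tuple[str, int] | None:
        """Map a 0-based haplotype position to ``(contig, 0-based ref pos)``.

        Returns ``None`` for novel inserted sequence.
        """
        seg = self._segment_at(pos)
        if seg.target_contig is None:
            return None
        return seg.target_contig, seg.target_start + (pos - seg.hap_start)

    def ref_to_hap(self, pos: int, contig: str | None = None) -> list[int]:
        """Map a 0-based reference position to all haplotype positions.

        Duplicated reference bases map to multiple haplotype positions;
        deleted bases map to none.
        """
        contig = contig or self.source_contig
        out = []
        for seg in self.segments:
            if seg.target_contig == contig and seg.target_start <= pos < seg.target_start + seg.length:
                out.append(seg.hap_start + (pos - seg.target_start))
        return out

    def _segment_at(self, pos: int) -> Segment:
        if not 0 <= pos < len(self.seq):
            raise IndexError(pos)
        lo, hi = 0, len(self.segments)
        while lo < hi - 1:
            mid = (lo + hi) // 2
            if self.segments[mid].hap_start <= pos:
                lo = mid
            else:
                hi = mid
        return self.segments[lo]

    def junction_positions(self) -> list[int]:
        """Haplotype positions of segment boundaries interior to the sequence."""
        return [s.hap_start for s in self.segments[1:]]


def _check_overlaps(
    edits: list[StructuralEdit],
) -> tuple[dict[int, list[StructuralEdit]], set[int]]:
    """Validate edits; return (nested deletions keyed by enclosing-dup index,
    indices of those nested deletions).

    Edits must not overlap, except a deletion strictly nested inside a
    tandem duplication (duplication-with-internal-deletion haplotypes).
    """
    nested: dict[int, list[StructuralEdit]] = {}
    skip: set[int] = set()
    for j, e in enumerate(edits):
        if e.kind != "deletion":
            continue
        for i, d in enumerate(edits):
            if d.kind == "tandem_duplication" and d.left <= e.left and e.right <= d.right:
                nested.setdefault(i, []).append(e)
                skip.add(j)
                break
    top = [(i, e) for i, e in enumerate(edits) if i not in skip]
    intervals = sorted((e.interval0(), i) for i, e in top)
    for ((_, a_end), ia), ((b_start, _), ib) in zip(intervals, intervals[1:]):
        if b_start < a_end:
            raise EditValidationError(
                f"overlapping non-nested edits: {edits[ia].label} and {edits[ib].label}"
            )
    return nested, skip


def apply_edits(
    ref: ReferenceSet,
    edits: list[StructuralEdit],
    contig: str | None = None,
    name: str = "hap",
) -> Haplotype:
    """Apply structural edits to one reference contig, producing a haplotype.

    Tandem duplications insert ``copies`` head-to-tail copies of the affected
    segment; a deletion nested inside a duplication is applied to every copy
    after the first, so the haplotype carries both the head-to-tail junction
    and the deletion junction.  TE insertions duplicate ``tsd_len`` flanking
    reference bases around the payload.
    """
    contig = contig or ref.main_contig()
    seq0 = ref.contigs[contig]
    for e in edits:
        if e.contig != contig:
            raise EditValidationError(f"edit {e.label} is not on contig {contig}")
        lo, hi = e.interval0()
        if not 0 <= lo <= hi <= len(seq0):
            raise EditValidationError(f"edit {e.label} outside contig bounds")
    nested, skip_idx = _check_overlaps(edits)
    top_level = sorted(
        ((i, e) for i, e in enumerate(edits) if i not in skip_idx),
        key=lambda ie: ie[1].interval0(),
    )

    pieces: list[tuple[str, str | None, int]] = []  # (seq, target_contig, target_start0)

    def emit_ref(a: int, b: int) -> None:
        if b > a:
            pieces.append((seq0[a:b], contig, a))

    cursor = 0
    for idx, e in top_level:
        lo, hi = e.interval0()
        emit_ref(cursor, lo)
        if e.kind == "deletion":
            cursor = hi
        elif e.kind == "tandem_duplication":
            dels = sorted(nested.get(idx, []), key=lambda d: d.left)
            emit_ref(lo, hi)  # first copy intact
            for _ in range(e.copies - 1):
                pos = lo
                for d in dels:
                    emit_ref(pos, d.left)
                    pos = d.right
                emit_ref(pos, hi)
            cursor = hi
        elif e.kind == "insertion":
            pieces.append((e.payload, None, 0))
            cursor = lo
        elif e.kind == "te_insertion":
            te_seq = ref.te_library.get(e.payload)
            if te_seq is None:
                raise EditValidationError(f"unknown TE {e.payload!r}")
            te_start = ref.te_offsets.get(e.payload, 0)
            pieces.append((te_seq, TE_CONTIG, te_start))
            if e.tsd_len:
                if lo - e.tsd_len < 0:
                    raise EditValidationError("tsd extends past contig start")
                emit_ref(lo - e.tsd_len, lo)
            cursor = lo
    emit_ref(cursor, len(seq0))

    segments: list[Segment] = []
    hap_pos = 0
    parts: list[str] = []
    for part, tgt, tstart in pieces:
        segments.append(Segment(hap_pos, len(part), tgt, tstart))
        parts.append(part)
        hap_pos += len(part)
    return Haplotype(name, "".join(parts), segments, list(edits), contig)


@dataclass
class HaplotypePool:
    """A pool of haplotypes with population frequencies.

    ``pool_size`` is the number of genomes contributing to the pool
    (default 40, a pool of 40 field-collected individuals).
    """

    haplotypes: list[Haplotype]
    frequencies: list[float]
    pool_size: int = 40

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise EditValidationError("empty haplotype pool")
        if len(self.haplotypes) != len(self.frequencies):
            raise EditValidationError("haplotypes and frequencies differ in length")
        f = np.asarray(self.frequencies, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise EditValidationError("frequencies must be >= 0 and sum to 1")
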