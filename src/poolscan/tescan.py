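"""Transposable-element insertion detection with TSD and TIR inference.

A TE present in the sequenced pool but absent from the reference leaves a
characteristic signature at the insertion point: one-end-anchored read pairs
facing the site from both directions (mates aligned to TE sequence on
another contig), reads clipped at the two insertion boundaries, a short
reference motif — the target-site duplication (TSD) — present unclipped in
reads from both directions and covered twice (a small depth micro-peak), and
clipped sequences whose junction-proximal ends are reverse complements of
one another: the element's terminal inverted repeats (TIRs).

Boundary geometry: because the TSD is duplicated, reads approaching from the
left align *through* the TSD before being clipped, and reads approaching
from the right begin aligning at the TSD start; the right-side clip boundary
therefore sits to the *left* of the left-side clip boundary, and the TSD is
the reference substring between them (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .svscan import AlignmentRecord, ClipCluster, clip_clusters


@dataclass
class AnchorCluster:
    """One-end-anchored pairs facing a common insertion point.

    ``direction`` is the side the anchored reads approach from: ``"left"``
    reads are forward-strand with mates elsewhere (facing right, toward the
    insertion); ``"right"`` reads are reverse-strand (facing left).
    """

    contig: str
    position: int  # 1-based innermost read edge
    direction: str
    support: int
    mate_contigs: dict[str, int] = field(default_factory=dict)


def anchor_clusters(
    records: list[AlignmentRecord],
    min_support: int = 3,
    span: int = 500,
) -> list[tuple[AnchorCluster, AnchorCluster | None]]:
    """Cluster one-end-anchored pairs; pair up left- and right-facing clusters.

    Returns (left_facing, right_facing) tuples for bidirectional clusters
    within ``span`` bp; unidirectional clusters are returned with ``None``
    as the partner (low-confidence).
    """
    by_dir: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for r in records:
        if r.mate_contig is None or r.mate_contig == r.contig:
            continue
        if not r.is_reverse:
            by_dir.setdefault((r.contig, "left"), []).append((r.end, r.mate_contig))
        else:
            by_dir.setdefault((r.contig, "right"), []).append((r.pos, r.mate_contig))

    def cluster(items: list[tuple[int, str]], contig: str, direction: str, tol: int = 50):
        items.sort()
        out, group = [], []
        for pos, mc in items + [(10**15, "")]:
            if group and pos - group[-1][0] > tol:
                if len(group) >= min_support:
                    mates: dict[str, int] = {}
                    for _, m in group:
                        mates[m] = mates.get(m, 0) + 1
                    edge = max(p for p, _ in group) if direction == "left" else min(p for p, _ in group)
                    out.append(AnchorCluster(contig, edge, direction, len(group), mates))
                group = []
            if mc:
                group.append((pos, mc))
        return out

    lefts, rights = [], []
    for (contig, direction), items in by_dir.items():
        found = cluster(items, contig, direction)
        (lefts if direction == "left" else rights).extend(found)

    pairs: list[tuple[AnchorCluster, AnchorCluster | None]] = []
    used: set[int] = set()
    for lc in lefts:
        partner = None
        for i, rc in enumerate(rights):
            if i in used or rc.contig != lc.contig:
                continue
            if -span <= rc.position - lc.position <= span:
                partner = rc
                used.add(i)
                break
        pairs.append((lc, partner))
    for i, rc in enumerate(rights):
        if i not in used:
            pairs.append((rc, None))
    return pairs


def find_tsd(
    left_clip: ClipCluster,
    right_clip: ClipCluster,
    ref: dict[str, str],
    max_tsd: int = 20,
) -> str | None:
    """Target-site duplication between the two clip boundaries.

    ``left_clip`` is the right-side clip cluster of left-approaching reads
    (its boundary is the last aligned base, the TSD end); ``right_clip`` is
    the left-side clip cluster of right-approaching reads (its boundary is
    the first aligned base, the TSD start).  Returns the reference substring
    between the boundaries, the empty string for a 0 bp target site, or
    ``None`` when the boundaries are more than ``max_tsd`` apart.
    """
    if left_clip.contig != right_clip.contig:
        return None
    tsd_end = left_clip.boundary
    tsd_start = right_clip.boundary
    length = tsd_end - tsd_start + 1
    if length < 0 or length > max_tsd:
        return None if length > max_tsd else ""
    return ref[left_clip.contig][tsd_start - 1 : tsd_end]


def find_tir(
    left_consensus: str,
    right_consensus: str,
    min_len: int = 10,
    min_identity: float = 0.9,
) -> tuple[str, str] | None:
    """Terminal inverted repeats from the two clipped consensi.

    The left consensus reads into the element from its left end; the right
    consensus ends at the junction, so its junction-proximal suffix is the
    element's right end.  A TIR pair is the longest prefix of the left
    consensus whose reverse complement matches the corresponding suffix of
    the right consensus at >= ``min_identity``; identical (non-reverse-
    complementary) repeats do not qualify.
    """
    if len(left_consensus) < min_len or len(right_consensus) < min_len:
        return None
    kmax = min(len(left_consensus), len(right_consensus))
    a = encode(left_consensus)
    for k in range(kmax, min_len - 1, -1):
        b = encode(revcomp(right_consensus[-k:]))
        if (a[:k] == b).mean() >= min_identity:
            return left_consensus[:k], right_consensus[-k:]
    return None


def match_te_identity(
    consensus: str,
    te_library: dict[str, str],
    min_identity: float = 0.9,
    min_len: int = 20,
) -> str:
    """Best TE-library match of a clipped consensus (both orientations)."""
    best_name, best_score = "unknown", min_identity
    for name, te in te_library.items():
        for cand in (consensus, revcomp(consensus)):
            if len(cand) < min_len or len(cand) > len(te):
                continue
            probe = cand[: max(min_len, min(len(cand), 60))]
            codes = encode(te)
            win = np.lib.stride_tricks.sliding_window_view(codes, len(probe))
            score = float((win == encode(probe)).sum(axis=1).max() / len(probe))
            if score >= best_score:
                best_name, best_score = name, score
    return best_name


@dataclass
class TEInsertionCall:
    """A transposon insertion absent from the reference."""

    contig: str
    left_boundary: int  # TSD start (1-based) — right-approaching clip boundary
    right_boundary: int  # TSD end (1-based) — left-approaching clip boundary
    tsd: str | None
    tir: tuple[str, str] | None
    te_name: str
    n_anchor_pairs: int
    n_clipped: int
    depth_micro_peak: bool
    frequency: float = float("nan")
    bidirectional: bool = True

    @property
    def label(self) -> str:
        return f"{self.contig}:{self.left_boundary}–{self.right_boundary}"


def _junction_frequency(
    records: list[AlignmentRecord],
    contig: str,
    boundary: int,
    side: str,
    tolerance: int = 2,
    margin: int = 5,
) -> tuple[int, int]:
    """(junction reads, read-through reads) at one insertion boundary."""
    chim = through = 0
    for r in records:
        if r.contig != contig:
            continue
        if side == "right":
            if r.right_clip >= 5 and abs(r.end - boundary) <= tolerance:
                chim += 1
            elif r.left_clip < 5 and r.right_clip < 5 and r.pos + margin - 1 <= boundary and r.end - margin + 1 >= boundary + 1:
                through += 1
        else:
            if r.left_clip >= 5 and abs(r.pos - boundary) <= tolerance:
                chim += 1
            elif r.left_clip < 5 and r.right_clip < 5 and r.pos + margin - 1 <= boundary - 1 and r.end - margin + 1 >= boundary:
                through += 1
    return chim, through


def call_te_insertions(
    records: list[AlignmentRecord],
    ref: dict[str, str],
    te_library: dict[str, str],
    min_support: int = 3,
    max_tsd: int = 20,
    pair_span: int = 60,
) -> list[TEInsertionCall]:
    """Assemble anchor, clip, TSD and TIR evidence into TE insertion calls.

    A call requires bidirectional support (anchored pairs or clip clusters
    on both sides).  TE identity is the best clipped-consensus match to the
    TE library; a micro-peak of depth over the TSD (covered from both
    directions) is recorded as corroborating evidence.
    """
    clips = clip_clusters(records, min_support=min_support)
    anchors = anchor_clusters(records, min_support=min_support)
    calls: list[TEInsertionCall] = []
    right_side = [c for c in clips if c.side == "right"]  # left-approaching reads
    left_side = [c for c in clips if c.side == "left"]  # right-approaching reads
    used: set[int] = set()
    for rc in right_side:
        for i, lc in enumerate(left_side):
            if i in used or lc.contig != rc.contig:
                continue
            # TSD geometry: TSD start (left-side boundary) at most max_tsd-1
            # before the TSD end (right-side boundary); gap -1 means a clean
            # 0 bp target site
            gap = rc.boundary - lc.boundary
            if not -1 <= gap <= max_tsd - 1:
                continue
            tsd = find_tsd(rc, lc, ref, max_tsd)
            tir = find_tir(rc.consensus, lc.consensus)
            te_name = match_te_identity(rc.consensus, te_library)
            if te_name == "unknown":
                te_name = match_te_identity(lc.consensus, te_library)
            anchor_n = 0
            bidirectional_anchor = False
            for a, b in anchors:
                if a.contig == rc.contig and abs(a.position - rc.boundary) <= 500:
                    anchor_n += a.support + (b.support if b else 0)
                    bidirectional_anchor = b is not None
            depth_peak = _tsd_micro_peak(records, rc.contig, lc.boundary, rc.boundary)
            # each junction read is clipped at one boundary only, while
            # read-through flux is counted at both: freq = C / (C + T/2)
            chim_l, thr_l = _junction_frequency(records, rc.contig, rc.boundary, "right")
            chim_r, thr_r = _junction_frequency(records, rc.contig, lc.boundary, "left")
            C, T = chim_l + chim_r, thr_l + thr_r
            freq = C / (C + T / 2.0) if C + T > 0 else float("nan")
            calls.append(
                TEInsertionCall(
                    contig=rc.contig,
                    left_boundary=lc.boundary,
                    right_boundary=rc.boundary,
                    tsd=tsd,
                    tir=tir,
                    te_name=te_name,
                    n_anchor_pairs=anchor_n,
                    n_clipped=rc.support + lc.support,
                    depth_micro_peak=depth_peak,
                    frequency=freq,
                    bidirectional=bidirectional_anchor or (rc.support >= 1 and lc.support >= 1),
                )
            )
            used.add(i)
            break
    return calls


def _tsd_micro_peak(
    records: list[AlignmentRecord], contig: str, start: int, end: int, flank: int = 200
) -> bool:
    """True when mean depth over [start, end] exceeds the flanking mean.

    The duplicated target site is sequenced from both flanks of the element,
    so its local depth rises above the surrounding coverage.
    """
    if end < start:
        return False
    inner = flank_sum = 0
    inner_n = flank_n = 0
    for r in records:
        if r.contig != contig:
            continue
        lo, hi = r.pos, r.end
        inner += max(0, min(hi, end) - max(lo, start) + 1)
        flank_sum += max(0, min(hi, start - 1) - max(lo, start - flank) + 1)
        flank_sum += max(0, min(hi, end + flank) - max(lo, end + 1) + 1)
    inner_n = end - start + 1
    flank_n = 2 * flank
    if inner_n <= 0:
        return False
    return inner / inner_n > flank_sum / flank_n


def write_te_tsv(calls: list[TEInsertionCall], path: str) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "contig": c.contig,
                "left_boundary": c.left_boundary,
                "right_boundary": c.right_boundary,
                "label": c.label,
                "tsd": c.tsd if c.tsd is not None else "",
                "tir_left": c.tir[0] if c.tir else "",
                "tir_right": c.tir[1] if c.tir else "",
                "te_name": c.te_name,
                "n_anchor_pairs": c.n_anchor_pairs,
                "n_clipped": c.n_clipped,
                "depth_micro_peak": c.depth_micro_peak,
                "frequency": c.frequency,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
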