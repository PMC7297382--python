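"""Paralog gene-conversion detection by distance-based phylogenetics.

Gene conversion — non-reciprocal transfer of sequence between paralogs —
makes a converted copy of one paralog resemble the other.  Given a set of
aligned, paralog-labelled gene sequences, conversion shows up as sequences
whose phylogenetic placement contradicts their label: a b-labelled sequence
sitting inside the a clade.  The module implements the standard distance
pipeline: uncorrected p-distances for multidimensional scaling, Kimura
2-parameter (K2P) distances for Neighbour-Joining, column-resampling
bootstrap for clade support, and a clade-purity rule for calling converted
sequences.  A complementary read-level signal is the coverage-depth ratio
across the paralog pair: conversion re-assigns reads from the converted
paralog to its template, raising one paralog's depth while lowering the
other's with the total conserved.

Distances use pairwise (not listwise) deletion of gapped columns, which
preserves 3'-truncated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode

GAP_CODE = 4


# ---------------------------------------------------------------------------
# Alignment container and trimming
# ---------------------------------------------------------------------------

@dataclass
class SeqAlignment:
    """Labelled aligned sequences with optional column annotations.

    ``matrix`` holds uint8 codes (A=0, C=1, G=2, T=3, gap=4), one row per
    sequence.  ``labels`` is the paralog tag per row, ``populations`` the
    geographic tag.  ``col_annotations`` marks columns as ``upstream``,
    ``coding`` or ``intron``.
    """

    ids: list[str]
    labels: list[str]
    populations: list[str]
    matrix: np.ndarray
    col_annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match number of sequences")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_fasta(cls, path: str, col_annotations: np.ndarray | None = None) -> "SeqAlignment":
        """Read aligned FASTA with ``name|paralog|population`` headers."""
        from Bio import SeqIO

        ids, labels, pops, rows = [], [], [], []
        for rec in SeqIO.parse(path, "fasta"):
            parts = rec.id.split("|")
            ids.append(parts[0])
            labels.append(parts[1] if len(parts) > 1 else "")
            pops.append(parts[2] if len(parts) > 2 else "")
            rows.append(encode(str(rec.seq)))
        matrix = np.vstack(rows)
        return cls(ids, labels, pops, matrix, col_annotations)


def trim_alignment(aln: SeqAlignment, coding_length: int = 1464) -> SeqAlignment:
    """Trim to the first ``coding_length`` coding columns.

    Upstream (pre-start-codon) and intron columns are removed using the
    column annotations; rows lacking 3' sequence are already gap-padded by
    the alignment.  Raises when the alignment is unannotated or has no
    coding columns.
    """
    if aln.col_annotations is None:
        raise ValueError("alignment has no column annotations; cannot trim")
    coding = np.asarray(aln.col_annotations) == "coding"
    if not coding.any():
        raise ValueError("alignment has no coding columns")
    idx = np.nonzero(coding)[0][:coding_length]
    matrix = aln.matrix[:, idx]
    return SeqAlignment(
        list(aln.ids),
        list(aln.labels),
        list(aln.populations),
        matrix,
        np.array(["coding"] * matrix.shape[1]),
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise distances with the transition/transversion components."""

    ids: list[str]
    d: np.ndarray
    metric: str  # "p" | "k2p"
    P: np.ndarray | None = None  # transition proportions (K2P)
    Q: np.ndarray | None = None  # transversion proportions (K2P)

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")


def p_distance(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """Uncorrected distance: mismatches / shared non-gap columns (NaN if none)."""
    ok = (row_i != GAP_CODE) & (row_j != GAP_CODE)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((row_i[ok] != row_j[ok]).sum() / n)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance: -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    ``P`` and ``Q`` are the transition and transversion proportions.
    Returns +inf (saturation) outside the domain of the logarithms.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("inf")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


class _EncodedAlignment:
    """One-hot encoding of an alignment, cached across bootstrap replicates."""

    def __init__(self, matrix: np.ndarray):
        self.onehot = [np.asarray(matrix == b, dtype=np.float32) for b in range(4)]
        self.valid_mask = np.asarray(matrix != GAP_CODE, dtype=np.float32)

    def pair_counts(
        self, weights: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(valid columns, mismatches, transitions) for all sequence pairs.

        Implemented as one-hot matrix products so bootstrap replicates can
        reweight columns (integer multinomial weights) without re-encoding.
        """
        n = self.valid_mask.shape[0]
        w = None if weights is None else np.asarray(weights, dtype=np.float32)

        def product(M: np.ndarray, N: np.ndarray) -> np.ndarray:
            return ((M * w) if w is not None else M) @ N.T

        valid = product(self.valid_mask, self.valid_mask)
        match = np.zeros((n, n), dtype=np.float32)
        for M in self.onehot:
            match += product(M, M)
        # transitions: A<->G and C<->T (purine/purine, pyrimidine/pyrimidine)
        A, C, G, T = self.onehot
        transitions = product(A, G) + product(G, A) + product(C, T) + product(T, C)
        mismatch = valid - match
        return (
            valid.astype(np.float64),
            mismatch.astype(np.float64),
            transitions.astype(np.float64),
        )


def pairwise_distances(
    aln: SeqAlignment | _EncodedAlignment,
    metric: str = "p",
    weights: np.ndarray | None = None,
    ids: list[str] | None = None,
) -> DistanceMatrix:
    """All-pairs p or K2P distances with pairwise gap deletion."""
    if isinstance(aln, _EncodedAlignment):
        enc = aln
        ids = ids or [f"t{i}" for i in range(enc.valid_mask.shape[0])]
    else:
        enc = _EncodedAlignment(aln.matrix)
        ids = ids or list(aln.ids)
    valid, mismatch, transitions = enc.pair_counts(weights)
    with np.errstate(invalid="ignore", divide="ignore"):
        if metric == "p":
            d = mismatch / valid
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(ids, d, "p")
        if metric == "k2p":
            P = transitions / valid
            Q = (mismatch - transitions) / valid
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.maximum(w1, 1e-300)) - 0.25 * np.log(np.maximum(w2, 1e-300)),
                np.inf,
            )
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(ids, d, "k2p", P, Q)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Classical (Torgerson) MDS
# ---------------------------------------------------------------------------

def classical_mds(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical MDS by double-centering eigendecomposition.

    Returns an (n, k) coordinate matrix whose pairwise Euclidean distances
    reproduce the input for Euclidean-realizable matrices.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("input must be a symmetric square matrix")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


# ---------------------------------------------------------------------------
# Neighbour-Joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted (stored rooted at the final join) phylogeny."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._newick()}:{bl:.6g}" for c, bl in self.children)
        sup = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){sup}"

    def bipartitions(self) -> dict[frozenset[str], "TreeNode"]:
        """Map of leaf-set bipartition (one side) to the subtending node."""
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                out[below] = node
            return below

        walk(self)
        return out


def nj_tree(dist: DistanceMatrix | np.ndarray, labels: list[str] | None = None) -> TreeNode:
    """Saitou–Nei Neighbour-Joining on the Q criterion.

    Negative branch lengths are clamped to zero.  Exact for additive
    distance matrices.  Requires >= 3 taxa.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.d.copy()
        labels = labels or dist.ids
    else:
        d = np.asarray(dist, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("Neighbour-Joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=0)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new node to the remaining taxa
        dn = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d[ai, :] = dn
        d[:, ai] = dn
        d[ai, ai] = 0.0
        nodes[ai] = new
        active.remove(aj)
    # final three-way join (unrooted)
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )


def bootstrap_support(
    aln: SeqAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    metric: str = "k2p",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with column-resampling bootstrap supports (percent).

    Builds the tree from the full alignment, then resamples alignment
    columns with replacement ``n_reps`` times, rebuilding distances and the
    NJ tree each time and counting the recurrence of each bipartition of
    the full tree.  Supports are attached to the tree's internal nodes.
    """
    if aln.length < 10:
        raise ValueError("bootstrap requires >= 10 alignment columns")
    rng = np.random.default_rng(seed)
    enc = _EncodedAlignment(aln.matrix)
    tree = nj_tree(pairwise_distances(enc, metric, ids=list(aln.ids)))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    L = aln.length
    p = np.full(L, 1.0 / L)
    for _ in range(n_reps):
        w = rng.multinomial(L, p)
        rep = nj_tree(pairwise_distances(enc, metric, weights=w, ids=list(aln.ids)))
        all_leaves = frozenset(rep.leaves())
        seen = set()
        for bp in rep.bipartitions():
            seen.add(bp)
            seen.add(all_leaves - bp)
        for bp in counts:
            if bp in seen:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    for bp, node in target.items():
        node.support = support[bp]
    return tree, support


# ---------------------------------------------------------------------------
# Conversion classification
# ---------------------------------------------------------------------------

@dataclass
class ConversionCall:
    """Placement-based classification of one labelled sequence."""

    seq_id: str
    label: str
    placement: str | None  # clade the sequence falls in, or None = unplaced
    converted: bool
    clade_support: float | None = None


def _label_clades(
    bipartitions: dict[frozenset[str], TreeNode],
    labels: dict[str, str],
    purity: float,
) -> dict[str, frozenset[str]]:
    """Pick, per label, the bipartition side that best captures that label.

    Candidates must be at least ``purity`` pure for the label; among them
    the side maximising (own-label count) - (contaminant count) wins, with
    larger size breaking ties.  Pure maximal-size selection is not used
    because the complement of a deep subclade of the *other* label can sit
    exactly at the purity threshold and absorb foreign sequences.
    """
    all_ids = set(labels)
    clades: dict[str, frozenset[str]] = {}
    for lab in sorted(set(labels.values())):
        best: frozenset[str] | None = None
        best_key: tuple[int, int] | None = None
        for bp in bipartitions:
            for side in (bp, frozenset(all_ids) - bp):
                own = sum(1 for s in side if labels[s] == lab)
                if own / len(side) < purity:
                    continue
                key = (own - (len(side) - own), len(side))
                if best_key is None or key > best_key:
                    best, best_key = side, key
        if best is not None:
            clades[lab] = best
    return clades


def classify_conversion(
    tree: TreeNode | None,
    labels: dict[str, str],
    embedding: np.ndarray | None = None,
    ids: list[str] | None = None,
    purity: float = 0.9,
    support: dict[frozenset[str], float] | None = None,
) -> list[ConversionCall]:
    """Call converted sequences from phylogenetic (or MDS) placement.

    Each paralog's clade is the largest bipartition side composed of at
    least ``purity`` sequences of that label.  A sequence whose label
    differs from its placement clade is converted; sequences in neither
    clade are unplaced (flagged, not converted).

    With ``tree=None`` an MDS ``embedding`` (with matching ``ids``) is used
    instead: placement is by the nearer label centroid, with points near the
    midline left unplaced.
    """
    if len(set(labels.values())) < 2:
        raise ValueError("need two labelled groups to classify conversion")
    calls: list[ConversionCall] = []
    if tree is not None:
        clades = _label_clades(tree.bipartitions(), labels, purity)
        for seq_id, lab in labels.items():
            placement = None
            for clade_label, members in clades.items():
                if seq_id in members:
                    placement = clade_label
                    break
            sup = None
            if support is not None and placement is not None:
                members = clades[placement]
                sup = support.get(members) or support.get(
                    frozenset(labels) - members
                )
            calls.append(
                ConversionCall(
                    seq_id,
                    lab,
                    placement,
                    placement is not None and placement != lab,
                    sup,
                )
            )
        return calls
    if embedding is None or ids is None:
        raise ValueError("provide a tree, or an embedding with ids")
    groups = sorted(set(labels.values()))
    pts = {i: embedding[k] for k, i in enumerate(ids)}
    centroids = {
        g: np.mean([pts[i] for i in ids if labels[i] == g], axis=0) for g in groups
    }
    scale = float(np.linalg.norm(centroids[groups[0]] - centroids[groups[1]]))
    for seq_id in ids:
        dists = {g: float(np.linalg.norm(pts[seq_id] - c)) for g, c in centroids.items()}
        ranked = sorted(dists, key=dists.get)
        margin = (dists[ranked[1]] - dists[ranked[0]]) / scale if scale else 0.0
        placement = ranked[0] if margin > 0.1 else None
        calls.append(
            ConversionCall(
                seq_id,
                labels[seq_id],
                placement,
                placement is not None and placement != labels[seq_id],
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Coverage-ratio corroboration
# ---------------------------------------------------------------------------

@dataclass
class ParalogDepthRatio:
    """Windowed depth ratio across a paralog pair."""

    window_starts: np.ndarray
    ratio: np.ndarray
    total_relative: np.ndarray
    flagged: bool
    flagged_span: tuple[int, int] | None


def paralog_depth_ratio(
    depth_a: np.ndarray,
    depth_b: np.ndarray,
    window: int = 100,
    flag_ratio: float = 1.5,
    min_span: int = 200,
    total_tolerance: float = 0.35,
) -> ParalogDepthRatio:
    """Windowed a/b depth ratio over homologous paralog intervals.

    Depths should already be normalised (e.g. relative to the genome-wide
    median).  The conversion-corroboration flag fires when the ratio stays
    at or above ``flag_ratio`` over at least ``min_span`` bp while the
    total a+b depth stays within ``total_tolerance`` of its own mean —
    reads re-assigned between paralogs, not gained.  Windows with zero b
    depth get a capped ratio and are flagged as informative.
    """
    a = np.asarray(depth_a, dtype=float)
    b = np.asarray(depth_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paralog depth arrays must have equal length")
    n_win = len(a) // window
    starts = np.arange(n_win) * window
    am = np.array([a[s : s + window].mean() for s in starts])
    bm = np.array([b[s : s + window].mean() for s in starts])
    cap = 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bm > 0, am / np.maximum(bm, 1e-12), cap)
    total = am + bm
    total_ok = np.abs(total - total.mean()) <= total_tolerance * max(total.mean(), 1e-12)
    hot = (ratio >= flag_ratio) & total_ok
    flagged = False
    span = None
    run = 0
    for i, h in enumerate(hot):
        run = run + 1 if h else 0
        if run * window >= min_span:
            flagged = True
            span = (int(starts[i - run + 1] + 1), int(starts[i] + window))
    return ParalogDepthRatio(starts + 1, ratio, total, flagged, span)


def write_conversion_tsv(calls: list[ConversionCall], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "label": c.label,
                "placement": c.placement or "unplaced",
                "converted": c.converted,
                "clade_support": "" if c.clade_support is None else c.clade_support,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_embedding_tsv(ids: list[str], embedding: np.ndarray, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(embedding, columns=[f"axis{i + 1}" for i in range(embedding.shape[1])])
    df.insert(0, "seq_id", ids)
    df.to_csv(path, sep="\t", index=False)
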