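"""Coalescent-derived haplotype windows and pooled site counts.

The neutral mode is the standard n-coalescent: while k lineages remain the
waiting time to the next coalescence is exponential with rate k(k-1)/2 (time
in units of 2N generations) and mutations fall on branches as a Poisson
process with rate theta/2 per unit branch length under the infinite-sites
model, giving E[pairwise diversity] = theta and E[S] = theta * a1.

The sweep mode replaces the genealogy with a star tree whose branch length is
the neutral expected TMRCA scaled by a factor ``f`` in (0, 1]: a minimal
stand-in for the immediate post-sweep genealogy, in which every variant is a
recent private mutation.  Small ``f`` yields few, rare variants — the reduced
diversity and excess of rare alleles (strongly negative Tajima's D) that a
selection scan must detect.

Pooled counts are then drawn per site: sequencing depth ~ Poisson(lambda),
allele sampling binomial in the pool frequency, and errors flipping each
sampled base to a uniformly chosen other base at rate e.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._seq import BASES


@dataclass
class CoalescentWindowParams:
    """Parameters for one simulated window of pooled data."""

    n_haplotypes: int = 20
    theta: float = 10.0  # per-window population mutation rate (all chunks)
    mode: str = "neutral"  # "neutral" | "star_sweep"
    sweep_scaling: float = 1.0  # f in (0, 1]; star-tree height = f * E[TMRCA]
    coverage: float = 40.0  # pool depth lambda
    error_rate: float = 0.0
    seed: int = 0
    window_length: int = 50_000
    n_chunks: int = 1  # independent genealogies per window (recombination between, not within)

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")
        if self.mode not in ("neutral", "star_sweep"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.sweep_scaling <= 1:
            raise ValueError("sweep_scaling must be in (0, 1]")


@dataclass
class WindowSim:
    """Truth and pooled observation for one window."""

    matrix: np.ndarray  # S x n derived-allele indicator matrix
    positions: np.ndarray  # 1-based site positions within the window
    counts: pd.DataFrame  # pooled site counts (contig, pos, ref, A, C, G, T)
    params: CoalescentWindowParams = field(repr=False, default=None)


def simulate_window_matrix(
    params: CoalescentWindowParams, rng: np.random.Generator
) -> np.ndarray:
    """S x n haplotype matrix for one window: ``n_chunks`` independent
    genealogies, each carrying theta/n_chunks of the mutation rate.

    A 50 kb window of real data spans many partially independent
    genealogies; modelling a window as several unlinked chunks reproduces
    the lighter tails of window statistics that intra-window recombination
    causes, while a sweep (star) window stays coherently extreme because
    every chunk shares the post-sweep genealogy shape.
    """
    if params.n_chunks == 1:
        return simulate_genealogy_matrix(params, rng)
    sub = replace(params, theta=params.theta / params.n_chunks, n_chunks=1)
    mats = [simulate_genealogy_matrix(sub, rng) for _ in range(params.n_chunks)]
    return np.vstack(mats)


def simulate_genealogy_matrix(
    params: CoalescentWindowParams, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the S x n haplotype matrix for one genealogy (infinite sites)."""
    n = params.n_haplotypes
    if params.mode == "star_sweep":
        height = params.sweep_scaling * 2.0 * (1.0 - 1.0 / n)
        rows = []
        for leaf in range(n):
            s = rng.poisson(height * params.theta / 2.0)
            for _ in range(s):
                row = np.zeros(n, dtype=np.int8)
                row[leaf] = 1
                rows.append(row)
        return np.array(rows, dtype=np.int8).reshape(-1, n)

    # neutral n-coalescent: merge lineages, mutations Poisson on branches
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    active_since = {ls: 0.0 for ls in lineages}
    t = 0.0
    rows = []
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for child in (a, b):
            branch = t - active_since.pop(child)
            s = rng.poisson(branch * params.theta / 2.0)
            if s:
                row = np.zeros(n, dtype=np.int8)
                row[list(child)] = 1
                rows.append((row, s))
        merged = a | b
        lineages = [ls for ls in lineages if ls not in (a, b)] + [merged]
        active_since[merged] = t
    out = []
    for row, s in rows:
        out.extend([row] * s)
    return np.array(out, dtype=np.int8).reshape(-1, n)



def _site_positions(S: int, window_length: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct, sorted 1-based site positions within the window."""
    if S > window_length:
        raise ValueError("more segregating sites than window positions")
    return np.sort(rng.choice(window_length, size=S, replace=False)) + 1


def pooled_counts_from_freqs(
    freqs: np.ndarray,
    params: CoalescentWindowParams,
    rng: np.random.Generator,
    positions: np.ndarray,
    contig: str = "sim",
    site_alleles: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw pooled A/C/G/T counts for sites with given derived-allele freqs.

    The reference (ancestral) base and the derived base are drawn per site
    (or taken from ``site_alleles`` = (ref codes, alt codes) so that several
    pools share site identities); depth ~ Poisson(lambda), derived copies ~
    Binomial(depth, freq), and each sampled base is flipped to a uniform
    other base with probability e.
    """
    S = len(freqs)
    if site_alleles is None:
        ref_idx = rng.integers(0, 4, size=S)
        alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
    else:
        ref_idx, alt_idx = site_alleles
    depth = rng.poisson(params.coverage, size=S)
    derived = rng.binomial(depth, np.clip(freqs, 0, 1))
    counts = np.zeros((S, 4), dtype=int)
    for s in range(S):
        base_draw = np.full(depth[s], ref_idx[s])
        base_draw[: derived[s]] = alt_idx[s]
        if params.error_rate > 0 and depth[s] > 0:
            err = rng.random(depth[s]) < params.error_rate
            base_draw[err] = (base_draw[err] + rng.integers(1, 4, size=err.sum())) % 4
        counts[s] = np.bincount(base_draw, minlength=4)
    df = pd.DataFrame(counts, columns=list(BASES))
    df.insert(0, "ref", [BASES[i] for i in ref_idx])
    df.insert(0, "pos", positions)
    df.insert(0, "contig", contig)
    return df


def simulate_coalescent_window(params: CoalescentWindowParams) -> WindowSim:
    """Simulate one window: haplotype matrix plus pooled site counts."""
    rng = np.random.default_rng(params.seed)
    matrix = simulate_window_matrix(params, rng)
    S = matrix.shape[0]
    positions = _site_positions(S, params.window_length, rng)
    freqs = matrix.mean(axis=1) if S else np.zeros(0)
    counts = pooled_counts_from_freqs(freqs, params, rng, positions)
    return WindowSim(matrix, positions, counts, params)


def simulate_temporal_pair(
    params: CoalescentWindowParams, swept: bool
) -> tuple[WindowSim, WindowSim]:
    """Simulate pre/post time-point pools sharing one neutral genealogy.

    The pre pool samples all n haplotypes at equal frequency.  If ``swept``,
    the post pool models a near-complete sweep: one haplotype rises to
    frequency (1 - f) while the original pool retains total frequency f
    (``f = sweep_scaling``); otherwise the post pool equals the pre pool in
    expectation.  Sharing the genealogy keeps the two time points polymorphic
    at the same sites, the configuration a temporal FST contrast measures.
    """
    rng = np.random.default_rng(params.seed)
    matrix = simulate_window_matrix(params, rng)
    S = matrix.shape[0]
    positions = _site_positions(S, params.window_length, rng)
    pre_freqs = matrix.mean(axis=1) if S else np.zeros(0)
    if swept and S:
        f = params.sweep_scaling
        chosen = int(rng.integers(params.n_haplotypes))
        post_freqs = (1 - f) * matrix[:, chosen] + f * pre_freqs
    else:
        post_freqs = pre_freqs
    ref_idx = rng.integers(0, 4, size=S)
    alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
    alleles = (ref_idx, alt_idx)
    pre = pooled_counts_from_freqs(pre_freqs, params, rng, positions, site_alleles=alleles)
    post = pooled_counts_from_freqs(post_freqs, params, rng, positions, site_alleles=alleles)
    return (
        WindowSim(matrix, positions, pre, params),
        WindowSim(matrix, positions, post, params),
    )


def simulate_window_series(
    base_params: CoalescentWindowParams,
    n_windows: int,
    sweep_windows: set[int] = frozenset(),
    contig: str = "sim",
) -> pd.DataFrame:
    """Simulate a series of adjacent windows as one concatenated count table.

    Windows in ``sweep_windows`` use star-sweep genealogies (with the base
    parameters' ``sweep_scaling``); all others are neutral.  Window ``w``
    occupies positions ``[w * window_length + 1, (w + 1) * window_length]``.
    """
    frames = []
    ss = np.random.SeedSequence(base_params.seed)
    seeds = ss.generate_state(n_windows)
    for w in range(n_windows):
        p = CoalescentWindowParams(
            n_haplotypes=base_params.n_haplotypes,
            theta=base_params.theta,
            mode="star_sweep" if w in sweep_windows else "neutral",
            sweep_scaling=base_params.sweep_scaling,
            coverage=base_params.coverage,
            error_rate=base_params.error_rate,
            seed=int(seeds[w] % (2**31)),
            window_length=base_params.window_length,
            n_chunks=base_params.n_chunks,
        )
        sim = simulate_coalescent_window(p)
        df = sim.counts.copy()
        df["pos"] = df["pos"] + w * base_params.window_length
        df["contig"] = contig
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "ref", *BASES])
    return pd.concat(frames, ignore_index=True)
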