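"""Population-genetic statistics for pooled sequencing data.

Site tables are pandas DataFrames with columns ``contig, pos, ref, A, C, G,
T`` (one table per pool; ``pos`` 1-based).  The workflow mirrors the
standard Pool-seq recipe: filter sites on depth (minimum and a per-pool 95th
centile cap), subsample counts with replacement to a uniform depth n,
treat the n subsampled reads as n sampled chromosomes, and compute windowed
diversity statistics:

* per-site pi = (n/(n-1)) * (1 - sum_b p_b^2), summed over window sites;
* Watterson's theta_W = S / a1 with S the number of polymorphic subsampled
  sites and a1 = sum_{i=1}^{n-1} 1/i;
* Tajima's D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the constants of
  Tajima (1989), undefined when S = 0;
* pairwise FST per window as a ratio of sums of (H_T - H_S) over H_T, with
  H = 2p(1-p) heterozygosities from the two pools' major-allele frequencies.

Windows default to 50 kb moving in 25 kb steps (scan mode); fine-scale
re-analysis uses 10 kb / 5 kb.  Sweep outliers are windows in the lowest
0.1% (or 1%) tail of the empirical Tajima's D distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

BASES = ("A", "C", "G", "T")

#: default scan windows (bp)
WINDOW, STEP = 50_000, 25_000
#: fine-scale windows for locus-level plots
FINE_WINDOW, FINE_STEP = 10_000, 5_000


@dataclass(frozen=True)
class SiteCount:
    """Per-site allele counts for one pool."""

    contig: str
    pos: int
    ref: str
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.counts)

    @property
    def major_allele(self) -> str:
        return BASES[int(np.argmax(self.counts))]

    @property
    def minor_allele_frequency(self) -> float:
        d = self.depth
        return 1.0 - max(self.counts) / d if d else 0.0


@dataclass(frozen=True)
class TajimaConstants:
    """The constants of Tajima's D for subsample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise ValueError("Tajima's D requires n >= 4")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class SmoothedTrack:
    """A kernel-smoothed positional statistic."""

    positions: np.ndarray
    values: np.ndarray
    bandwidth: float


# ---------------------------------------------------------------------------
# I/O: sync-like tab-separated site count tables
# ---------------------------------------------------------------------------

def write_site_counts(pools: dict[str, pd.DataFrame], path: str) -> None:
    """Write pools as a sync-like TSV: contig, pos, ref, then one ``A:C:G:T``
    column per pool (shared sites only)."""
    names = list(pools)
    merged: pd.DataFrame | None = None
    for name in names:
        df = pools[name].copy()
        df[name] = (
            df["A"].astype(str) + ":" + df["C"].astype(str) + ":"
            + df["G"].astype(str) + ":" + df["T"].astype(str)
        )
        df = df[["contig", "pos", "ref", name]]
        merged = df if merged is None else merged.merge(df, on=["contig", "pos", "ref"])
    merged.to_csv(path, sep="\t", index=False)


def read_site_counts(path: str) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_site_counts`."""
    raw = pd.read_csv(path, sep="\t")
    out: dict[str, pd.DataFrame] = {}
    for name in raw.columns[3:]:
        counts = raw[name].str.split(":", expand=True).astype(int)
        counts.columns = list(BASES)
        df = pd.concat([raw[["contig", "pos", "ref"]], counts], axis=1)
        out[name] = df
    return out


def depth(df: pd.DataFrame) -> pd.Series:
    return df[list(BASES)].sum(axis=1)


def major_allele_freq(df: pd.DataFrame) -> pd.Series:
    d = depth(df)
    return df[list(BASES)].max(axis=1) / d.where(d > 0)


def minor_allele_freq(df: pd.DataFrame) -> pd.Series:
    return 1.0 - major_allele_freq(df)


# ---------------------------------------------------------------------------
# Filtering and subsampling
# ---------------------------------------------------------------------------

def filter_sites(
    df: pd.DataFrame, min_depth: int = 20, max_depth_centile: float = 95.0
) -> pd.DataFrame:
    """Remove sites with depth below ``min_depth`` or above the pool-wide
    depth centile (the centile is computed over all covered sites passed in,
    i.e. per pool across the whole table)."""
    if df.empty:
        return df.copy()
    d = depth(df)
    covered = d[d > 0]
    if covered.empty:
        return df.iloc[0:0].copy()
    cap = float(np.percentile(covered, max_depth_centile))
    return df[(d >= min_depth) & (d <= cap)].reset_index(drop=True)


def subsample_counts(
    counts: np.ndarray, target_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample one site's A/C/G/T counts with replacement to depth target_n."""
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot subsample a zero-depth site")
    return rng.multinomial(target_n, counts / total)


def subsample_table(df: pd.DataFrame, target_n: int = 20, seed: int = 0) -> pd.DataFrame:
    """Subsample every site to uniform depth ``target_n`` (with replacement).

    Sites with depth below ``target_n`` are dropped (they are excluded
    upstream by the depth filter in the standard workflow).  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    d = depth(df)
    kept = df[d >= target_n].reset_index(drop=True)
    if kept.empty:
        return kept
    raw = kept[list(BASES)].to_numpy()
    probs = raw / raw.sum(axis=1, keepdims=True)
    out = np.empty_like(raw[:, :4])
    for i in range(len(kept)):
        out[i] = rng.multinomial(target_n, probs[i])
    kept.loc[:, list(BASES)] = out
    return kept


# ---------------------------------------------------------------------------
# Windowed diversity statistics
# ---------------------------------------------------------------------------

def site_pi(counts: np.ndarray, n: int) -> np.ndarray:
    """Per-site pi for an array of subsampled count rows (depth n)."""
    p = counts / n
    return (n / (n - 1.0)) * (1.0 - (p**2).sum(axis=1))


def window_pi_theta(
    window_counts: np.ndarray, n: int, constants: TajimaConstants | None = None
) -> tuple[float, float, int]:
    """(pi, theta_W, S) for the subsampled sites of one window."""
    constants = constants or TajimaConstants.for_n(n)
    if len(window_counts) == 0:
        return 0.0, 0.0, 0
    poly = (window_counts > 0).sum(axis=1) > 1
    S = int(poly.sum())
    pi = float(site_pi(window_counts[poly], n).sum()) if S else 0.0
    theta_w = S / constants.a1
    return pi, theta_w, S


def tajimas_d(pi: float, S: int, constants: TajimaConstants) -> float:
    """Tajima's D from window pi and S; NaN when S = 0."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return float("nan")
    var = constants.e1 * S + constants.e2 * S * (S - 1)
    return (pi - S / constants.a1) / np.sqrt(var)


def _windows(positions: np.ndarray, window: int, step: int):
    """Yield (start, end, mask) for sliding windows covering the positions."""
    if len(positions) == 0:
        return
    last = int(positions.max())
    start = 0
    while start < last:
        end = start + window
        mask = (positions > start) & (positions <= end)
        yield start + 1, end, mask
        start += step


def window_stats(
    df: pd.DataFrame,
    n: int = 20,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Windowed pi, theta_W, Tajima's D and mean MAF for one (subsampled) pool.

    ``df`` must already be subsampled to uniform depth ``n``.  Returns one
    row per window with columns contig, start, end, n_sites, S, pi, theta_w,
    tajimas_d, maf_mean.
    """
    constants = TajimaConstants.for_n(n)
    rows = []
    for contig, sub in df.groupby("contig", sort=False):
        positions = sub["pos"].to_numpy()
        counts = sub[list(BASES)].to_numpy()
        maf = minor_allele_freq(sub).to_numpy()
        for start, end, mask in _windows(positions, window, step):
            wc = counts[mask]
            pi, theta_w, S = window_pi_theta(wc, n, constants)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_sites": int(mask.sum()),
                    "S": S,
                    "pi": pi,
                    "theta_w": theta_w,
                    "tajimas_d": tajimas_d(pi, S, constants),
                    "maf_mean": float(maf[mask].mean()) if mask.any() else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "n_sites", "S",
            "pi", "theta_w", "tajimas_d", "maf_mean",
        ],
    )


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------

def _shared_sites(df1: pd.DataFrame, df2: pd.DataFrame) -> pd.DataFrame:
    return df1.merge(df2, on=["contig", "pos", "ref"], suffixes=("_1", "_2"))


def fst_site_components(merged: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (H_T - H_S, H_T) from a merged two-pool table.

    ``p`` is the frequency of the combined major allele in each pool;
    H = 2p(1-p); H_S is the mean of the two pools and H_T uses the mean
    frequency.
    """
    c1 = merged[[b + "_1" for b in BASES]].to_numpy(dtype=float)
    c2 = merged[[b + "_2" for b in BASES]].to_numpy(dtype=float)
    major = (c1 + c2).argmax(axis=1)
    idx = np.arange(len(merged))
    p1 = c1[idx, major] / c1.sum(axis=1)
    p2 = c2[idx, major] / c2.sum(axis=1)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    return ht - hs, ht


def window_fst(
    df1: pd.DataFrame,
    df2: pd.DataFrame,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Windowed pairwise FST (ratio of sums) over shared subsampled sites."""
    merged = _shared_sites(df1, df2)
    rows = []
    for contig, sub in merged.groupby("contig", sort=False):
        positions = sub["pos"].to_numpy()
        num, den = fst_site_components(sub)
        for start, end, mask in _windows(positions, window, step):
            d = den[mask].sum()
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_sites": int(mask.sum()),
                    "fst": num[mask].sum() / d if d > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_sites", "fst"])


def allele_freq_diff(df1: pd.DataFrame, df2: pd.DataFrame) -> pd.DataFrame:
    """Per-site major-allele frequency differences with exact-test p-values.

    The 2x2 table per site is (combined-major allele count, all other
    counts) in each pool, tested with Fisher's exact test (two-sided).
    Zero-depth sites are skipped.
    """
    merged = _shared_sites(df1, df2)
    c1 = merged[[b + "_1" for b in BASES]].to_numpy()
    c2 = merged[[b + "_2" for b in BASES]].to_numpy()
    d1, d2 = c1.sum(axis=1), c2.sum(axis=1)
    ok = (d1 > 0) & (d2 > 0)
    merged, c1, c2, d1, d2 = merged[ok], c1[ok], c2[ok], d1[ok], d2[ok]
    major = (c1 + c2).argmax(axis=1)
    idx = np.arange(len(merged))
    m1, m2 = c1[idx, major], c2[idx, major]
    pvals = np.ones(len(merged))
    diffs = m1 / d1 - m2 / d2
    for i in range(len(merged)):
        if m1[i] * (d2[i] - m2[i]) != m2[i] * (d1[i] - m1[i]):  # not identical freqs
            _, pvals[i] = _stats.fisher_exact(
                [[m1[i], d1[i] - m1[i]], [m2[i], d2[i] - m2[i]]]
            )
    out = merged[["contig", "pos", "ref"]].copy()
    out["freq_diff"] = diffs
    out["p_value"] = pvals
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Smoothing and outlier calling
# ---------------------------------------------------------------------------

def kernel_smooth(
    positions: np.ndarray, values: np.ndarray, bandwidth: float
) -> SmoothedTrack:
    """Gaussian-kernel weighted mean evaluated at the input positions.

    Missing (NaN) values contribute no weight.  Positions must be sorted.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.size == 0:
        return SmoothedTrack(positions, values.copy(), bandwidth)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    ok = ~np.isnan(values)
    out = np.full(positions.shape, np.nan)
    if ok.any():
        px, vx = positions[ok], values[ok]
        for i, x in enumerate(positions):
            w = np.exp(-0.5 * ((px - x) / bandwidth) ** 2)
            out[i] = np.sum(w * vx) / np.sum(w)
    return SmoothedTrack(positions, out, bandwidth)


def outlier_windows(
    stats_df: pd.DataFrame,
    tail: float = 0.001,
    side: str = "low",
    value_col: str = "tajimas_d",
    exclude_contigs: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Flag windows in the extreme empirical tail of a window statistic.

    ``tail`` must be 0.01 or 0.001.  Ties at the threshold are not flagged
    (strict exceedance), so a constant statistic flags nothing.  Missing
    values are excluded from the quantile computation.  ``exclude_contigs``
    removes contigs (e.g. the X chromosome, analysed separately) before the
    quantile is computed.
    """
    if tail not in (0.01, 0.001):
        raise ValueError("tail must be 0.01 or 0.001")
    if side not in ("low", "high", "both"):
        raise ValueError("side must be low, high or both")
    df = stats_df[~stats_df["contig"].isin(exclude_contigs)]
    vals = df[value_col].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        return df.iloc[0:0]
    flagged = np.zeros(len(df), dtype=bool)
    if side in ("low", "both"):
        lo = np.quantile(vals[ok], tail)
        flagged |= vals < lo
    if side in ("high", "both"):
        hi = np.quantile(vals[ok], 1.0 - tail)
        flagged |= vals > hi
    return df[flagged & ok].reset_index(drop=True)
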