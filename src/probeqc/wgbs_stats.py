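"""Array-vs-WGBS concordance and noise statistics.

Whole-genome bisulfite sequencing gives a per-base methylation fraction
(methylated reads / total reads) that serves as the gold standard against
which array beta values are judged. This module pairs array betas with WGBS
betas at the interrogated C position (coverage-filtered), and computes the
noise statistics used to decide which probe categories are "noisy": per
category median |delta beta|, Pearson correlation, Wilcoxon rank-sum tests
against the high-quality background, the 2-D beta density matrix (window
0.02), the unknown-factor flag (|delta beta| > 0.3), per-probe standard
deviations across samples, and keep/discard SD comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .manifest_io import ProbeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WgbsSite",
    "PairedBeta",
    "CategoryStats",
    "load_wgbs_sites",
    "pair_probe_wgbs",
    "pearson_r",
    "wilcoxon_rank_sum",
    "category_stats",
    "density_matrix",
    "flag_unknown_factors",
    "per_probe_sd",
    "sd_comparison",
    "category_beta_distribution",
]

DEFAULT_MIN_COVERAGE = 5
UNKNOWN_FACTOR_THRESHOLD = 0.3


@dataclass(frozen=True)
class WgbsSite:
    """One cytosine's WGBS methylation call."""

    chrom: str
    pos: int  # 1-based
    beta: float  # score / 100
    coverage: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"{self.chrom}:{self.pos}: beta {self.beta} outside [0, 1]")
        if self.coverage < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative coverage")


@dataclass(frozen=True)
class PairedBeta:
    """One probe's array beta matched to its WGBS beta.

    ``signed_diff`` is array minus sequencing, so a positive value means the
    array overestimates methylation relative to WGBS.
    """

    probe_id: str
    beta_array: float
    beta_wgbs: float

    @property
    def abs_diff(self) -> float:
        return abs(self.beta_array - self.beta_wgbs)

    @property
    def signed_diff(self) -> float:
        return self.beta_array - self.beta_wgbs


@dataclass
class CategoryStats:
    """Noise summary of one probe category against the high-quality background."""

    category: str
    n: int
    median_abs_diff: float
    pearson_r: float
    wilcoxon_p: float


def load_wgbs_sites(
    path: str | Path,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> dict[tuple[str, int], WgbsSite]:
    """Read per-base methylation (bedGraph-like TSV) keyed by (chrom, 1-based pos).

    Accepts 5 columns (chrom, start, end, score, coverage; BED-style 0-based
    start) or 4 columns (chrom, pos 1-based, score, coverage). Scores are on
    the 0-100 scale and divided by 100; sites with coverage < ``min_coverage``
    are excluded. Duplicate rows for one position keep the higher-coverage row.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] >= 5:
        chroms, pos, score, cov = df[0], df[1].astype(int) + 1, df[3], df[4]
    elif df.shape[1] == 4:
        chroms, pos, score, cov = df[0], df[1].astype(int), df[2], df[3]
    else:
        raise ValueError(f"{path}: expected 4 or 5 columns, got {df.shape[1]}")
    bad = (score < 0) | (score > 100)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} row(s) with score outside [0, 100]")
    sites: dict[tuple[str, int], WgbsSite] = {}
    for c, p, s, v in zip(chroms, pos, score, cov):
        v = int(v)
        if v < min_coverage:
            continue
        key = (str(c), int(p))
        site = WgbsSite(str(c), int(p), float(s) / 100.0, v)
        if key in sites:
            logger.warning("duplicate WGBS rows at %s:%d; keeping higher coverage", *key)
            if v <= sites[key].coverage:
                continue
        sites[key] = site
    return sites


def pair_probe_wgbs(
    probes: Sequence[ProbeRecord],
    sites: Mapping[tuple[str, int], WgbsSite],
    array_betas: Mapping[str, float],
) -> tuple[list[PairedBeta], list[str]]:
    """Match each probe's interrogated C position to a surviving WGBS site.

    Returns (pairs, unmatched probe ids). A probe pairs iff its forward C
    position has a WGBS site and the probe has an array beta.
    """
    pairs: list[PairedBeta] = []
    unmatched: list[str] = []
    for probe in probes:
        site = sites.get((probe.chrom, probe.cpg_pos))
        beta = array_betas.get(probe.probe_id)
        if site is None or beta is None or (isinstance(beta, float) and np.isnan(beta)):
            unmatched.append(probe.probe_id)
            continue
        pairs.append(PairedBeta(probe.probe_id, float(beta), site.beta))
    return pairs, unmatched


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> float:
    """Two-sided (by default) Mann-Whitney/Wilcoxon rank-sum p-value.

    ``mode='exact'`` enumerates the exact null distribution (valid without
    ties); ``'normal'`` uses the tie- and continuity-corrected normal
    approximation; ``'auto'`` is exact when both samples have n <= 8 and no
    ties are present, normal otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode == "auto":
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        mode = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "normal"
    method = {"exact": "exact", "normal": "asymptotic"}[mode]
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def category_stats(
    paired: Sequence[PairedBeta],
    category_ids: Iterable[str],
    background_ids: Iterable[str],
    category: str = "category",
    wilcoxon_mode: str = "auto",
) -> CategoryStats:
    """Noise statistics of one category vs the high-quality background.

    n counts unique category probes that have a pairing. An empty category
    yields n=0 with NaN statistics.
    """
    category_ids = set(category_ids)
    background_ids = set(background_ids)
    cat = [p for p in paired if p.probe_id in category_ids]
    bg = [p for p in paired if p.probe_id in background_ids]
    if not cat:
        return CategoryStats(category, 0, float("nan"), float("nan"), float("nan"))
    diffs = np.array([p.abs_diff for p in cat])
    median = float(np.median(diffs))
    try:
        r = pearson_r([p.beta_wgbs for p in cat], [p.beta_array for p in cat])
    except ValueError:  # degenerate category (n < 3 or zero variance): r undefined
        r = float("nan")
    p = wilcoxon_rank_sum(diffs, [q.abs_diff for q in bg], mode=wilcoxon_mode) if bg else float("nan")
    return CategoryStats(category, len({p.probe_id for p in cat}), median, r, p)


def density_matrix(paired: Sequence[PairedBeta], window: float = 0.02) -> np.ndarray:
    """2-D beta-density count grid ("2DMM").

    Cell (i, j) counts pairs with beta_wgbs in [i*w, (i+1)*w) and beta_array
    likewise; the last bin is closed so beta = 1.0 is countable. Total count
    is conserved.
    """
    nbins = int(round(1.0 / window))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    x = np.array([p.beta_wgbs for p in paired], dtype=float)
    y = np.array([p.beta_array for p in paired], dtype=float)
    grid, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    return grid.astype(np.int64)


def flag_unknown_factors(
    paired: Sequence[PairedBeta],
    threshold: float = UNKNOWN_FACTOR_THRESHOLD,
) -> set[str]:
    """Probes whose |array - WGBS| beta difference strictly exceeds the threshold."""
    return {p.probe_id for p in paired if p.abs_diff > threshold}


def per_probe_sd(matrix: pd.DataFrame) -> pd.Series:
    """Sample standard deviation (n-1 denominator) per probe row.

    Rows with fewer than two non-missing values are skipped (SD undefined).
    """
    counts = matrix.notna().sum(axis=1)
    skipped = int((counts < 2).sum())
    if skipped:
        logger.info("per_probe_sd: skipped %d probe(s) with < 2 values", skipped)
    return matrix.loc[counts >= 2].std(axis=1, ddof=1)


def sd_comparison(
    sds: pd.Series,
    keep_ids: Iterable[str],
    discard_ids: Iterable[str],
    min_sd: float = 0.10,
) -> dict:
    """Compare keep vs discard SD distributions.

    The Wilcoxon rank-sum p is computed on the full SD distributions; the
    reported per-group density summaries are restricted to SD >= ``min_sd``.
    """
    keep_ids, discard_ids = set(keep_ids), set(discard_ids)
    if keep_ids & discard_ids:
        raise ValueError("keep and discard sets must be disjoint")
    keep = sds.loc[sds.index.intersection(keep_ids)]
    discard = sds.loc[sds.index.intersection(discard_ids)]
    if keep.empty or discard.empty:
        raise ValueError("both groups must be nonempty")
    p = wilcoxon_rank_sum(keep.to_numpy(), discard.to_numpy(), mode="normal")

    def _summary(s: pd.Series) -> dict:
        high = s[s >= min_sd]
        return {
            "n": int(s.size),
            "median_sd": float(s.median()),
            "n_ge_min": int(high.size),
            "median_sd_ge_min": float(high.median()) if high.size else float("nan"),
        }

    return {"p_value": p, "keep": _summary(keep), "discard": _summary(discard), "min_sd": min_sd}


def category_beta_distribution(
    matrix: pd.DataFrame,
    category_ids: Iterable[str],
    n_bins: int = 20,
) -> pd.Series:
    """Pooled beta histogram over all samples for probes in one category.

    20 bins of width 0.05 by default, last bin closed; the histogram mass
    equals n_probes * n_samples minus missing values.
    """
    ids = matrix.index.intersection(set(category_ids))
    values = matrix.loc[ids].to_numpy(dtype=float).ravel()
    values = values[~np.isnan(values)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    labels = [f"[{a:.2f},{b:.2f})" for a, b in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    return pd.Series(counts, index=labels, name="count")
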