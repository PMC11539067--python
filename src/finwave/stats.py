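"""Statistics layer: permutation testing, FDR correction, rank tests,
bootstrap confidence bands.

Group comparisons use Fisher's permutation test: group labels are
permuted (by default 200,000 times) and the two-sided p-value is the
add-one-corrected fraction of resamples whose statistic magnitude
reaches the observed one, so p is never exactly zero and never below
1/(n_resamples + 1). Families of p-values are corrected with the
Benjamini-Hochberg step-up false-discovery-rate procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permutation_test",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "bootstrap_median_band",
]

DEFAULT_N_RESAMPLES = 200_000


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    p_value: float
    n_resamples: int
    seed: int | None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")
        if self.p_value < 1.0 / (self.n_resamples + 1) - 1e-15:
            raise ValueError("p_value below the add-one floor")


_STATISTICS = {
    "median_diff": lambda x, y: np.median(x) - np.median(y),
    "mean_diff": lambda x, y: np.mean(x) - np.mean(y),
}


def permutation_test(
    x,
    y,
    statistic: str = "median_diff",
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | np.random.Generator | None = 0,
    with_replacement: bool = False,
    batch: int = 2000,
) -> PermutationResult:
    """Two-sided Fisher permutation test for a two-group difference.

    Labels are permuted without replacement (the permutation null); a
    resampling-with-replacement variant is available behind
    ``with_replacement``. ``statistic`` is ``median_diff`` (default —
    group summaries here are medians throughout) or ``mean_diff``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_resamples < 1000:
        warnings.warn(f"n_resamples={n_resamples} < 1000: p-value resolution is coarse",
                      RuntimeWarning)
    stat_fn = _STATISTICS[statistic]
    obs = float(stat_fn(x, y))
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    rng = np.random.default_rng(seed)
    use_median = statistic == "median_diff"
    count = 0
    done = 0
    while done < n_resamples:
        b = min(batch, n_resamples - done)
        if with_replacement:
            mat = pooled[rng.integers(0, n, size=(b, n))]
        else:
            mat = rng.permuted(np.broadcast_to(pooled, (b, n)).copy(), axis=1)
        gx, gy = mat[:, :nx], mat[:, nx:]
        if use_median:
            stats_b = np.median(gx, axis=1) - np.median(gy, axis=1)
        else:
            stats_b = gx.mean(axis=1) - gy.mean(axis=1)
        count += int(np.sum(np.abs(stats_b) >= abs(obs) - 1e-12))
        done += b
    p = (1 + count) / (1 + n_resamples)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationResult(statistic_observed=obs, p_value=float(p),
                             n_resamples=n_resamples, seed=seed_val)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for small untied samples (min group size
    <= 10, no ties); otherwise the normal approximation with tie
    correction. Completely tied data returns p = 1 with a warning flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; rank-sum test is uninformative",
                      RuntimeWarning)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bootstrap_median_band(
    series: np.ndarray,
    level: float = 95.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile-bootstrap confidence band for the cross-individual median.

    ``series`` is (individuals, time). Individuals are resampled with
    replacement; per time point the ``level``% percentile interval of the
    bootstrap medians is returned together with the sample median.
    Returns ``(median, lower, upper)``.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_ind = series.shape[0]
    rng = np.random.default_rng(seed)
    med = np.median(series, axis=0)
    if n_ind == 1:
        return med, med.copy(), med.copy()
    idx = rng.integers(0, n_ind, size=(n_boot, n_ind))
    boots = np.median(series[idx], axis=1)  # (n_boot, time)
    alpha = (100.0 - level) / 2.0
    lo = np.percentile(boots, alpha, axis=0)
    hi = np.percentile(boots, 100.0 - alpha, axis=0)
    # a percentile band of medians always embraces the sample median
    lo = np.minimum(lo, med)
    hi = np.maximum(hi, med)
    return med, lo, hi
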