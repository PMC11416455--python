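"""Low-expression filtering and TMM/CPM normalization.

Small-RNA libraries are dominated by a handful of very abundant miRNAs, so
column totals are a poor scale estimate: a composition shift in a few
high-abundance species drags every other miRNA's CPM with it.  The
trimmed-mean-of-M-values (TMM) estimator corrects for this by assuming most
miRNAs are not differentially expressed and estimating, per sample, the
log-ratio of proportions against a reference sample after trimming the most
extreme log-ratios (M) and the abundance extremes (A).  The normalization is
implemented here directly rather than delegated, since it is one of the
computations this package exists to make transparent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizationResult
from .errors import AnalysisError

__all__ = ["filter_low_expression", "tmm_factors", "log_cpm", "normalize"]


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep miRNAs with unnormalized CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    The default (CPM >= 1 in at least 3 samples, the smallest condition-cell
    size) is the conventional reading of the small-RNA-seq filtering step;
    both thresholds are configurable.  Row order is preserved and the
    operation is idempotent.
    """
    if min_samples > counts.counts.shape[1]:
        raise AnalysisError(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({counts.counts.shape[1]})"
        )
    lib = counts.library_sizes.to_numpy(float)
    cpm = counts.counts.to_numpy(float) / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("expression filter removed every miRNA", stacklevel=2)
    return CountMatrix(counts.counts.loc[keep], counts.samples)


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    # Sample whose 75th-percentile count fraction is closest to the mean of
    # those quantities across samples (the standard TMM reference rule).
    q75 = np.quantile(counts / lib, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale)."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method (binomial) variance of M, used as precision weights
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = m.size
    if n == 0:
        warnings.warn("no miRNA positive in both samples; TMM factor set to 1", stacklevel=3)
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 miRNAs left after TMM trimming; factor set to 1", stacklevel=3)
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 0.0
    return float(f)


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    For each sample versus the reference, per-miRNA M (log2 ratio of
    library-size-scaled proportions) and A (average log2 proportion) values
    are computed over miRNAs positive in both samples, doubly trimmed by M
    (default 30%) and A (default 5%), and combined as a precision-weighted
    mean with inverse asymptotic (binomial delta-method) variances as
    weights.  The factor is 2 to that mean.
    """
    y = counts.counts.to_numpy(float)
    if y.shape[1] < 2:
        raise AnalysisError("TMM requires at least 2 samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise AnalysisError(f"samples with all-zero counts: {bad}")
    if ref_sample is None:
        ref_idx = _choose_reference(y, lib)
    else:
        ref_idx = counts.sample_ids.get_loc(ref_sample)
    logf = np.array(
        [
            _tmm_pair(y[:, j], y[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(y.shape[1])
        ]
    )
    factors = 2.0 ** (logf - logf.mean())  # geometric mean 1
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 2.0,
) -> NormalizationResult:
    """log2 counts-per-million on TMM-effective library sizes with a prior count.

    The prior is scaled proportionally to each sample's effective library
    size, ``prior_j = prior_count * lib_eff_j / 1e6`` (i.e. the prior is a
    pseudo-CPM: a sample at depth 1e6 gets exactly ``prior_count`` pseudo-
    counts), so that ``logcpm = log2((y + prior_j) / (lib_eff_j +
    2 * prior_j) * 1e6)`` is exactly invariant to rescaling all counts and
    library sizes together.  With ``prior_count=0`` the exponentiated CPM of
    each column sums to 1e6 exactly.  The ubiquitous-expression rule
    downstream (log2 CPM >= 12 in all IC samples) reads this matrix, so the
    prior convention matters and is documented here: default 2.
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.sample_ids)
    factors = factors.reindex(counts.sample_ids)
    if (factors <= 0).any() or factors.isna().any():
        raise AnalysisError("TMM factors must be positive for every sample")
    lib_eff = counts.library_sizes.to_numpy(float) * factors.to_numpy(float)
    prior = prior_count * lib_eff / 1e6
    y = counts.counts.to_numpy(float)
    logcpm = np.log2((y + prior) / (lib_eff + 2.0 * prior) * 1e6)
    return NormalizationResult(
        tmm_factor=factors,
        effective_library_size=pd.Series(lib_eff, index=counts.sample_ids, name="effective_library_size"),
        logcpm=pd.DataFrame(logcpm, index=counts.mirna_ids, columns=counts.sample_ids),
        prior_count=prior_count,
    )


def normalize(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    prior_count: float = 2.0,
) -> tuple[CountMatrix, NormalizationResult]:
    """Filter, estimate TMM factors and compute log2 CPM in one call."""
    filtered = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    return filtered, log_cpm(filtered, factors, prior_count=prior_count)
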