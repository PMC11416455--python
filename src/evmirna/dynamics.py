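"""Temporal dynamics: dynamic miRNA calling, profile clustering, ubiquity.

A miRNA is *dynamic* when it is significantly differentially expressed
(BH q < 0.05) between at least two timepoints in the IC samples of the
ventral and/or dorsal organoids — the union over the six pairwise timepoint
contrasts per region.  Dynamic miRNAs are clustered on their standardized
(zero-mean, unit-variance) log2 CPM profiles across all IC samples with
Euclidean distance and Ward's minimum-variance linkage.  Separately, miRNAs
with log2 CPM >= 12 in *every* IC sample are called ubiquitously expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .containers import CountMatrix, NormalizationResult, TIMEPOINTS
from .errors import AnalysisError
from .glm import NBQLModel, design_matrix, pairwise_contrast

__all__ = [
    "TEMPORAL_CONTRASTS",
    "temporal_de",
    "DynamicSet",
    "dynamic_mirnas",
    "dynamic_mirnas_joint",
    "scale_profiles",
    "ProfileClustering",
    "ward_cluster",
    "ubiquitous_mirnas",
]

#: the six pairwise timepoint comparisons, in the study's order
TEMPORAL_CONTRASTS = (
    "D13_vs_D0",
    "D40_vs_D0",
    "D75_vs_D0",
    "D40_vs_D13",
    "D75_vs_D13",
    "D75_vs_D40",
)


def temporal_de(
    counts: CountMatrix,
    norm: NormalizationResult,
    region: str,
    genotype: str = "IC",
    dispersion=None,
) -> dict[str, pd.DataFrame]:
    """Six pairwise timepoint DE tables for one region's IC samples.

    The model pools the shared iPSC day-0 samples with the region's D13/D40/
    D75 samples (4 timepoint coefficients, one per cell); dispersion is
    estimated within this sample subset.
    """
    s = counts.samples
    keep = (s["genotype"] == genotype) & s["region"].isin([region, "iPSC"])
    sub = counts.subset_samples(s.index[keep])
    present = set(sub.samples["timepoint"])
    if present != set(TIMEPOINTS):
        raise AnalysisError(
            f"region {region!r} ({genotype}) lacks timepoints: {set(TIMEPOINTS) - present}"
        )
    X = design_matrix(sub.samples, by="timepoint")
    offset = np.log(norm.effective_library_size.loc[sub.sample_ids].to_numpy(float))
    fit = NBQLModel(sub, X, offset=offset).fit(dispersion=dispersion)
    tables = {}
    for name in TEMPORAL_CONTRASTS:
        a, b = name.split("_vs_")
        tables[name] = fit.test(pairwise_contrast(X, a, b), name=name)
    return tables


@dataclass
class DynamicSet:
    """Union of temporally significant miRNAs with per-(region, contrast) flags."""

    mirnas: list[str]
    flags: pd.DataFrame  # bool, index = union miRNAs, columns = "region:contrast"
    alpha: float

    def regions_of(self, mirna: str) -> set[str]:
        hit = self.flags.loc[mirna]
        return {c.split(":", 1)[0] for c in hit.index[hit]}


def dynamic_mirnas(
    de_tables: dict[str, dict[str, pd.DataFrame]], alpha: float = 0.05
) -> DynamicSet:
    """Union over regions and the six contrasts of miRNAs with q < alpha.

    ``de_tables`` maps region -> contrast name -> DE table; each region must
    provide exactly the six pairwise timepoint contrasts.
    """
    for region, tabs in de_tables.items():
        missing = set(TEMPORAL_CONTRASTS) - set(tabs)
        if missing:
            raise AnalysisError(f"region {region!r} is missing contrasts: {sorted(missing)}")
    cols = {}
    for region, tabs in de_tables.items():
        for name in TEMPORAL_CONTRASTS:
            cols[f"{region}:{name}"] = tabs[name]["q_value"] < alpha
    flags = pd.DataFrame(cols)
    union = flags.index[flags.any(axis=1)]
    return DynamicSet(mirnas=list(union), flags=flags.loc[union], alpha=alpha)


def dynamic_mirnas_joint(
    counts: CountMatrix,
    norm: NormalizationResult,
    alpha: float = 0.05,
    genotype: str = "IC",
    dispersion=None,
) -> DynamicSet:
    """Dynamic miRNAs via one joint QL F-test per region.

    Testing all timepoint differences simultaneously (a rank-3 contrast of
    the four timepoint coefficients, the count-model analogue of one-way
    ANOVA) identifies miRNAs changed between *at least two* timepoints with
    a single BH adjustment per region, so the dynamic set's false-discovery
    rate stays at the nominal level; the six-pairwise-contrast union
    (:func:`dynamic_mirnas`) gives the same kind of set but compounds the
    adjustment across contrasts.  Flags record the triggering region(s).
    """
    s = counts.samples
    cols = {}
    for region in ("dorsal", "ventral"):
        keep = (s["genotype"] == genotype) & s["region"].isin([region, "iPSC"])
        sub = counts.subset_samples(s.index[keep])
        X = design_matrix(sub.samples, by="timepoint")
        offset = np.log(norm.effective_library_size.loc[sub.sample_ids].to_numpy(float))
        fit = NBQLModel(sub, X, offset=offset).fit(dispersion=dispersion)
        names = list(X.columns)
        C = np.zeros((3, X.shape[1]))
        for i, tp in enumerate(("D13", "D40", "D75")):
            C[i, names.index(tp)] = 1.0
            C[i, names.index("D0")] = -1.0
        tab = fit.test(C)
        cols[f"{region}:joint"] = tab["q_value"] < alpha
    flags = pd.DataFrame(cols)
    union = flags.index[flags.any(axis=1)]
    return DynamicSet(mirnas=list(union), flags=flags.loc[union], alpha=alpha)


def scale_profiles(logcpm: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Zero-center and unit-variance scale each row (sample sd by default).

    Constant rows cannot be scaled and are mapped to all-zeros with a
    warning.
    """
    if logcpm.shape[1] < 2:
        raise AnalysisError("profile scaling needs at least 2 samples")
    vals = logcpm.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profile(s) scaled to all-zeros", stacklevel=2
        )
    sd[const] = 1.0
    out = (vals - mean) / sd
    out[const] = 0.0
    return pd.DataFrame(out, index=logcpm.index, columns=logcpm.columns)


@dataclass
class ProfileClustering:
    """Ward clustering of standardized temporal profiles."""

    standardized: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series                  # cluster label (1..k) per miRNA
    monotonicity: dict[int, str]       # cluster -> increasing | decreasing | mixed

    @property
    def k(self) -> int:
        return int(self.labels.nunique())


def _cluster_monotonicity(
    profile: pd.Series, samples: pd.DataFrame
) -> str:
    """Call a mean profile monotone if its timepoint means rise (or fall)
    strictly within both regions, with the shared iPSC D0 as each region's
    first point."""
    by_cond = profile.groupby(
        [samples.loc[profile.index, "region"], samples.loc[profile.index, "timepoint"]]
    ).mean()
    directions = set()
    for region in ("dorsal", "ventral"):
        seq = [by_cond.get(("iPSC", "D0"), np.nan)]
        for tp in ("D13", "D40", "D75"):
            seq.append(by_cond.get((region, tp), np.nan))
        seq = [v for v in seq if not np.isnan(v)]
        d = np.diff(seq)
        if len(d) == 0:
            continue
        if (d > 0).all():
            directions.add("increasing")
        elif (d < 0).all():
            directions.add("decreasing")
        else:
            directions.add("mixed")
    if directions == {"increasing"}:
        return "increasing"
    if directions == {"decreasing"}:
        return "decreasing"
    return "mixed"


def ward_cluster(
    standardized: pd.DataFrame, samples: pd.DataFrame, k: int = 3
) -> ProfileClustering:
    """Agglomerative Ward clustering (Euclidean) cut into ``k`` groups.

    ``k=3`` mirrors the three temporal profile groups of the study
    (increasing / decreasing / remainder); per-cluster monotonicity is read
    off the sign pattern of the cluster-mean profile across ordered
    timepoints within each region.
    """
    n = standardized.shape[0]
    if not 1 <= k <= n:
        raise AnalysisError(f"k={k} outside [1, {n}]")
    Z = hierarchy.linkage(standardized.to_numpy(float), method="ward")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=k, criterion="maxclust"),
        index=standardized.index,
        name="cluster",
    )
    mono = {}
    for lab in sorted(labels.unique()):
        mean_profile = standardized.loc[labels[labels == lab].index].mean(axis=0)
        mono[int(lab)] = _cluster_monotonicity(mean_profile, samples)
    return ProfileClustering(standardized, Z, labels, mono)


def ubiquitous_mirnas(
    logcpm: pd.DataFrame, samples: pd.DataFrame, threshold: float = 12.0
) -> list[str]:
    """miRNAs with log2 CPM >= ``threshold`` in every IC sample.

    Only IC columns are read; adding or removing RTT samples cannot change
    the result.
    """
    ic = samples.index[samples["genotype"] == "IC"]
    ic = [s for s in ic if s in logcpm.columns]
    if not ic:
        raise AnalysisError("no IC samples available for the ubiquitous-expression rule")
    sub = logcpm[ic]
    return list(sub.index[(sub >= threshold).all(axis=1)])
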