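"""Genotype contrasts (RTT vs IC) per timepoint and genomic-cluster summaries.

The mutant and control lines are compared at each of the seven condition
cells (iPSC:D0, ventral:D13/D40/D75, dorsal:D13/D40/D75); fold changes are
signed RTT minus IC and BH adjustment is applied within each comparison
separately.  The union of significant miRNAs across comparisons feeds the
fold-change heatmap and the pathway analysis; genomic miRNA clusters (such
as C14MC at chr14q32) are summarized by ordering members along the genome
and reporting per-condition mean expression, the member fraction reaching
significance and the mean member fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CONDITION_CELLS, CountMatrix, MiRNAAnnotation, NormalizationResult
from .errors import AnalysisError
from .glm import NBQLModel, bh_adjust, design_matrix, pairwise_contrast

__all__ = [
    "GENOTYPE_COMPARISONS",
    "per_timepoint_de",
    "DifferentialUnion",
    "differential_union",
    "ClusterSummary",
    "cluster_summary",
]

#: comparison keys, "region_timepoint", in the study's order
GENOTYPE_COMPARISONS = tuple(f"{r}_{t}" for r, t in CONDITION_CELLS)


def _fit_region_model(counts, norm, region, dispersion):
    s = counts.samples
    keep = s["region"].isin([region, "iPSC"]) if region != "iPSC" else s["region"] == "iPSC"
    sub = counts.subset_samples(s.index[keep])
    X = design_matrix(sub.samples, by="genotype_timepoint")
    offset = np.log(norm.effective_library_size.loc[sub.sample_ids].to_numpy(float))
    fit = NBQLModel(sub, X, offset=offset).fit(dispersion=dispersion)
    return sub, X, fit


def per_timepoint_de(
    counts: CountMatrix,
    norm: NormalizationResult,
    alpha: float = 0.05,
    dispersion=None,
    global_adjust: bool = False,
) -> dict[str, pd.DataFrame]:
    """Seven RTT-vs-IC DE tables, one per region/timepoint cell.

    Dispersions are estimated per regional model (the shared iPSC day-0
    cells plus one region's three timepoints, both genotypes); the iPSC:D0
    comparison comes from its own iPSC-only model.  Cells missing a genotype
    or with fewer than 2 replicates per genotype are skipped with a warning.
    With ``global_adjust=True`` the BH adjustment is recomputed across all
    seven comparisons jointly instead of within each one.
    """
    s = counts.samples
    tables: dict[str, pd.DataFrame] = {}
    for region in ("iPSC", "dorsal", "ventral"):
        cells = [(r, t) for r, t in CONDITION_CELLS if r == region]
        reps = s.groupby(["genotype", "region", "timepoint"]).size()
        ok_cells = []
        for r, t in cells:
            n_ic = reps.get(("IC", r, t), 0)
            n_rtt = reps.get(("RTT", r, t), 0)
            if n_ic >= 2 and n_rtt >= 2:
                ok_cells.append((r, t))
            else:
                warnings.warn(
                    f"comparison {r}:{t} skipped (IC n={n_ic}, RTT n={n_rtt})",
                    stacklevel=2,
                )
        if not ok_cells:
            continue
        _, X, fit = _fit_region_model(counts, norm, region, dispersion)
        for r, t in ok_cells:
            c = pairwise_contrast(X, f"RTT.{t}", f"IC.{t}")  # RTT minus IC
            tables[f"{r}_{t}"] = fit.test(c, name=f"{r}_{t}")
    if global_adjust and tables:
        allp = pd.concat([tab["p_value"] for tab in tables.values()])
        allq = pd.Series(bh_adjust(allp.to_numpy()), index=allp.index)
        start = 0
        for tab in tables.values():
            tab["q_value"] = allq.iloc[start : start + len(tab)].to_numpy()
            start += len(tab)
    return tables


@dataclass
class DifferentialUnion:
    """Union of RTT-vs-IC significant miRNAs with the fold-change matrix."""

    mirnas: list[str]
    log2fc: pd.DataFrame       # union miRNAs x comparisons
    significant: pd.DataFrame  # bool, same shape
    alpha: float


def differential_union(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> DifferentialUnion:
    """miRNAs with q < alpha in >= 1 comparison, plus the heatmap-style
    log2FC matrix (rows = union miRNAs, columns = comparisons) with
    per-comparison significance flags."""
    if not tables:
        raise AnalysisError("no DE tables supplied")
    lfc = pd.DataFrame({name: tab["log2fc"] for name, tab in tables.items()})
    sig = pd.DataFrame({name: tab["q_value"] < alpha for name, tab in tables.items()})
    union = sig.index[sig.any(axis=1)]
    return DifferentialUnion(
        mirnas=list(union),
        log2fc=lfc.loc[union],
        significant=sig.loc[union],
        alpha=alpha,
    )


@dataclass
class ClusterSummary:
    """Summary of one genomic miRNA cluster across conditions and contrasts."""

    cluster_id: str
    members: list[str]                   # ordered by genomic start
    n_members: int
    n_tested: int
    n_significant: int
    fraction_significant: float
    condition_mean_logcpm: pd.DataFrame  # tested members (genomic order) x condition
    mean_log2fc: pd.Series               # per comparison, mean over tested members
    significant_members: list[str]


def cluster_summary(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame],
    annotation: MiRNAAnnotation,
    cluster_id: str,
    alpha: float = 0.05,
) -> ClusterSummary:
    """Per-condition expression and significance summary of a named cluster.

    Members are ordered by genomic start (0-based, GRCh38-style intervals);
    ``n_tested`` counts members surviving the expression filter (present in
    the DE tables), and a member is significant when q < alpha in >= 1 of
    the seven genotype comparisons.
    """
    members_tab = annotation.cluster_members(cluster_id)
    if members_tab.empty:
        raise AnalysisError(f"unknown cluster id {cluster_id!r}")
    members = list(members_tab.index)
    tested_universe = next(iter(de_tables.values())).index if de_tables else logcpm.index
    tested = [m for m in members if m in tested_universe]

    sig = pd.DataFrame(
        {name: tab["q_value"].reindex(tested) < alpha for name, tab in de_tables.items()}
    )
    sig_members = list(sig.index[sig.any(axis=1)]) if not sig.empty else []

    cond = (
        samples["genotype"].astype(str)
        + "."
        + samples["region"].astype(str)
        + "."
        + samples["timepoint"].astype(str)
    )
    present = [m for m in tested if m in logcpm.index]
    cond_mean = logcpm.loc[present].T.groupby(cond).mean().T

    mean_lfc = pd.Series(
        {name: float(tab["log2fc"].reindex(tested).mean()) for name, tab in de_tables.items()},
        name="mean_log2fc",
    )
    return ClusterSummary(
        cluster_id=cluster_id,
        members=members,
        n_members=len(members),
        n_tested=len(tested),
        n_significant=len(sig_members),
        fraction_significant=(len(sig_members) / len(tested)) if tested else float("nan"),
        condition_mean_logcpm=cond_mean,
        mean_log2fc=mean_lfc,
        significant_members=sig_members,
    )
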