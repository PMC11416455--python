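"""Synthetic data with the statistical structure of the organoid EV study.

The real sequencing data are not publicly deposited, so the pipeline is
exercised on generated data that emulate the study design: 14 condition
cells (iPSC day 0 plus dorsal/ventral organoids at days 13/40/75, each for
the isogenic control IC and the MeCP2:R255X mutant RTT line) with 3
replicates, negative-binomial counts on a log-normal abundance backbone,
log-normal library-size variation, and planted signal classes:

* ``increasing`` / ``decreasing`` — monotone temporal log2 trends (the
  pink/yellow profile groups),
* ``genotype_elevated`` — a genomically contiguous cluster with higher
  expression in RTT (a C14MC-like cluster),
* ``ubiquitous`` — constitutively high miRNAs (true log2 CPM 14 in every
  condition, two log2 units above the >= 12 calling rule so biological
  noise rarely drops a replicate below it),
* ``null`` — no planted effect; a fraction of these receive per-sample
  composition noise to exercise TMM normalization.

Every generator takes one integer seed; sub-streams are derived with
``numpy.random.SeedSequence`` so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONDITION_CELLS,
    GENOTYPES,
    CountMatrix,
    MiRNAAnnotation,
    PathwayCollection,
    TargetMap,
    condition_label,
)
from .errors import SpecificationError

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "TruthLabels",
    "simulate_counts",
    "simulate_annotation",
    "simulate_target_map",
    "simulate_pathways",
    "gene_universe",
    "DEFAULT_CLUSTER_LOCUS",
]

_TP_INDEX = {"D0": 0, "D13": 1, "D40": 2, "D75": 3}

#: chr14q32-like host locus for the planted genotype-elevated cluster.
DEFAULT_CLUSTER_LOCUS = ("chr14", 100_800_000, 101_000_000)
DEFAULT_CLUSTER_ID = "C14MC_sim"


@dataclass
class DesignSpec:
    """Sampling design: condition cells x replicates, depth and dispersion."""

    replicates_per_condition: int = 3
    n_mirnas: int = 600
    mean_library_size: float = 1e6
    library_size_cv: float = 0.2
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise SpecificationError("replicates_per_condition must be >= 1")
        if self.n_mirnas < 1:
            raise SpecificationError("n_mirnas must be >= 1")
        if self.mean_library_size <= 0:
            raise SpecificationError("mean_library_size must be positive")
        if self.library_size_cv < 0 or self.nb_dispersion < 0:
            raise SpecificationError("library_size_cv and nb_dispersion must be >= 0")

    @property
    def conditions(self) -> list[tuple[str, str, str]]:
        """All 14 (genotype, region, timepoint) cells in canonical order."""
        return [(g, r, t) for g in GENOTYPES for r, t in CONDITION_CELLS]

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.replicates_per_condition


@dataclass
class EffectSpec:
    """Planted effect classes and their sizes.

    Class counts mirror the study's findings (a ~50-member elevated genomic
    cluster, ~10 ubiquitous miRNAs, a few dozen temporally dynamic ones);
    effect sizes are log2 units.  ``composition_bias_fraction`` of the null
    miRNAs get sample-class-specific abundance (by default elevated
    2**``composition_bias_log2``-fold in RTT libraries; ``"noise"`` mode
    draws independent per-sample log2-uniform noise instead), which perturbs
    library composition the way asymmetric regulation does in real
    small-RNA libraries — the distortion TMM exists to undo.
    """

    n_increasing: int = 15
    n_decreasing: int = 15
    n_genotype_cluster: int = 50
    n_ubiquitous: int = 10
    temporal_log2_step: float = 1.0
    genotype_log2fc: float = 1.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    ubiquitous_log2_cpm: float = 14.0
    composition_bias_fraction: float = 0.10
    composition_bias_log2: float = 1.0
    composition_bias_mode: str = "genotype"  # "genotype" or "noise"
    #: optional abundance floor (log2 CPM) for the planted temporal and
    #: genotype classes, so power experiments test detectable effects rather
    #: than the abundance lottery of the log-normal baseline
    planted_floor_log2cpm: float | None = None
    #: when True, temporal miRNAs alternate between dorsal-only and
    #: ventral-only dynamics (region-specific profiles, as part of the real
    #: dynamic set shows); default is the same trend in both regions
    temporal_region_split: bool = False

    def validate(self, n_mirnas: int) -> None:
        counts = (
            self.n_increasing,
            self.n_decreasing,
            self.n_genotype_cluster,
            self.n_ubiquitous,
        )
        if any(c < 0 for c in counts):
            raise SpecificationError("effect class counts must be nonnegative")
        if sum(counts) > n_mirnas:
            raise SpecificationError(
                f"effect class counts sum to {sum(counts)} > n_mirnas={n_mirnas}"
            )
        if not 0 <= self.composition_bias_fraction <= 1:
            raise SpecificationError("composition_bias_fraction must be in [0, 1]")
        if self.composition_bias_mode not in ("genotype", "noise"):
            raise SpecificationError(
                f"unknown composition_bias_mode {self.composition_bias_mode!r}"
            )


@dataclass
class TruthLabels:
    """Ground truth: per-miRNA class, true per-condition log2 relative mean,
    per-sample true TMM-style scaling factor, and the composition-noise flag."""

    classes: pd.Series                 # mirna -> class name
    true_log2_mean: pd.DataFrame       # mirna x condition label, log2 relative abundance
    true_factor: pd.Series             # sample -> true normalization factor (geomean 1)
    composition_biased: pd.Series      # mirna -> bool

    def of_class(self, name: str) -> list[str]:
        return list(self.classes.index[self.classes == name])


def _mirna_ids(n: int) -> list[str]:
    return [f"sim-mir-{i:04d}" for i in range(n)]


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene ids shared by target-map and pathway sims."""
    return [f"g{i:06d}" for i in range(n_genes)]


def _assign_classes(design: DesignSpec, effects: EffectSpec) -> pd.Series:
    ids = _mirna_ids(design.n_mirnas)
    classes = np.array(["null"] * design.n_mirnas, dtype=object)
    i = 0
    for name, k in (
        ("ubiquitous", effects.n_ubiquitous),
        ("increasing", effects.n_increasing),
        ("decreasing", effects.n_decreasing),
        ("genotype_elevated", effects.n_genotype_cluster),
    ):
        classes[i : i + k] = name
        i += k
    return pd.Series(classes, index=ids, name="class")


def _condition_abundance(
    design: DesignSpec, effects: EffectSpec, classes: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Relative abundance per (miRNA, condition); columns sum to 1."""
    G = design.n_mirnas
    conds = design.conditions
    labels = [condition_label(*c) for c in conds]
    base = 2.0 ** rng.normal(effects.baseline_log2_mean, effects.baseline_log2_sd, G)
    cls = classes.to_numpy()
    if effects.planted_floor_log2cpm is not None:
        planted = np.isin(cls, ("increasing", "decreasing", "genotype_elevated"))
        floor = 2.0**effects.planted_floor_log2cpm / 1e6 * base.sum()
        base[planted] = np.maximum(base[planted], floor)
    A = np.tile(base[:, None], (1, len(conds)))
    # per-miRNA region restriction for temporal effects (None = both regions)
    temporal_region = np.full(G, None, dtype=object)
    if effects.temporal_region_split:
        for name in ("increasing", "decreasing"):
            idx = np.flatnonzero(cls == name)
            temporal_region[idx[0::2]] = "dorsal"
            temporal_region[idx[1::2]] = "ventral"
    for j, (g, r, t) in enumerate(conds):
        k = _TP_INDEX[t]
        for name, sign in (("increasing", 1.0), ("decreasing", -1.0)):
            sel = cls == name
            if effects.temporal_region_split and r != "iPSC":
                sel = sel & ((temporal_region == r) | (temporal_region == None))  # noqa: E711
            A[sel, j] *= 2.0 ** (sign * k * effects.temporal_log2_step)
        if g == "RTT":
            A[cls == "genotype_elevated", j] *= 2.0**effects.genotype_log2fc
    # pin the ubiquitous class at an exact relative abundance per condition so
    # its true log2 CPM equals ubiquitous_log2_cpm everywhere
    ub = cls == "ubiquitous"
    n_ub = int(ub.sum())
    if n_ub:
        target_p = 2.0**effects.ubiquitous_log2_cpm / 1e6
        if n_ub * target_p >= 1.0:
            raise SpecificationError("ubiquitous class cannot exceed the whole library")
        other_sum = A[~ub].sum(axis=0)
        A[ub] = target_p / (1.0 - n_ub * target_p) * other_sum
    total = A.sum(axis=0)
    P = A / total
    return (
        pd.DataFrame(P, index=classes.index, columns=labels),
        pd.Series(total, index=labels),
    )


def simulate_counts(
    design: DesignSpec, effects: EffectSpec, seed: int
) -> tuple[CountMatrix, TruthLabels]:
    """Draw an NB count matrix for the full design plus its ground truth.

    Counts are NB with mean = true library scale x relative abundance (times
    per-sample composition noise for flagged null miRNAs) and the design's
    common dispersion; ``nb_dispersion=0`` degenerates to Poisson.  The same
    seed and specs reproduce the output bit for bit.
    """
    effects.validate(design.n_mirnas)
    ss = np.random.SeedSequence(seed)
    r_classes, r_lib, r_bias, r_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    classes = _assign_classes(design, effects)
    P, cond_total = _condition_abundance(design, effects, classes, r_classes)

    rows = []
    for g, r, t in design.conditions:
        for k in range(1, design.replicates_per_condition + 1):
            rows.append(
                {
                    "sample_id": f"{g}_{r}_{t}_r{k}",
                    "genotype": g,
                    "region": r,
                    "timepoint": t,
                    "replicate": k,
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samp = len(samples)

    cv = design.library_size_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        lib = design.mean_library_size * np.exp(
            r_lib.normal(-0.5 * sigma**2, sigma, n_samp)
        )
    else:
        lib = np.full(n_samp, float(design.mean_library_size))

    cls = classes.to_numpy()
    null_idx = np.flatnonzero(cls == "null")
    n_biased = int(round(effects.composition_bias_fraction * design.n_mirnas))
    n_biased = min(n_biased, null_idx.size)
    biased_idx = null_idx[:n_biased]
    biased = np.zeros(design.n_mirnas, bool)
    biased[biased_idx] = True

    cond_of_sample = [
        condition_label(g, r, t)
        for g, r, t in zip(samples["genotype"], samples["region"], samples["timepoint"])
    ]
    mean = P[cond_of_sample].to_numpy() * lib[None, :]
    if n_biased:
        if effects.composition_bias_mode == "genotype":
            # sample-class-specific abundance: half of the biased miRNAs are
            # elevated in RTT libraries, half in IC, shifting each genotype's
            # library composition (what TMM must undo to keep the unbiased
            # majority comparable)
            rtt = (samples["genotype"] == "RTT").to_numpy()
            up_in_rtt = np.arange(n_biased) % 2 == 0
            boost = 2.0**effects.composition_bias_log2
            mean[biased_idx[up_in_rtt]] *= np.where(rtt, boost, 1.0)[None, :]
            mean[biased_idx[~up_in_rtt]] *= np.where(rtt, 1.0, boost)[None, :]
        else:  # independent per-sample composition noise
            noise = 2.0 ** r_bias.uniform(
                -effects.composition_bias_log2, effects.composition_bias_log2,
                (n_biased, n_samp),
            )
            mean[biased_idx] = mean[biased_idx] * noise

    phi = design.nb_dispersion
    if phi == 0:
        counts = r_counts.poisson(mean)
    else:
        n_param = 1.0 / phi
        counts = r_counts.negative_binomial(n_param, n_param / (n_param + mean))

    counts_df = pd.DataFrame(counts, index=classes.index, columns=samples.index)

    # true factor: the rescaling that makes the unbiased majority's CPM
    # comparable.  Sequencing renormalizes proportions per condition (fixed
    # depth), so an unbiased miRNA's expected count is lib * a_i / S_c with
    # S_c the condition's total unnormalized abundance; the factor TMM
    # should recover is lib / (realized column total * S_c), geomean 1.
    s_c = cond_total[cond_of_sample].to_numpy()
    f = lib / (counts.sum(axis=0) * s_c)
    f = f / np.exp(np.mean(np.log(f)))
    truth = TruthLabels(
        classes=classes,
        true_log2_mean=np.log2(P),
        true_factor=pd.Series(f, index=samples.index, name="true_factor"),
        composition_biased=pd.Series(biased, index=classes.index, name="composition_biased"),
    )
    return CountMatrix(counts_df, samples), truth


def simulate_annotation(
    truth: TruthLabels,
    cluster_locus: tuple[str, int, int] = DEFAULT_CLUSTER_LOCUS,
    seed: int = 0,
    cluster_id: str = DEFAULT_CLUSTER_ID,
    member_length: int = 80,
) -> MiRNAAnnotation:
    """Place miRNAs on the genome; the genotype-elevated class becomes one
    contiguous cluster of adjacent, non-overlapping intervals inside
    ``cluster_locus`` (0-based half-open coordinates), mimicking C14MC.
    """
    chrom, lo, hi = cluster_locus
    members = truth.of_class("genotype_elevated")
    n = len(members)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = {}
    if n:
        step = (hi - lo) // n
        if step < 2:
            raise SpecificationError(
                f"cluster locus of length {hi - lo} cannot host {n} miRNAs"
            )
        length = min(member_length, step - 1)
        for i, mid in enumerate(members):
            start = lo + i * step
            rows[mid] = (chrom, start, start + length, "+", cluster_id)
    other_chroms = [f"chr{c}" for c in list(range(1, 14)) + list(range(15, 23))]
    for mid in truth.classes.index:
        if mid in rows:
            continue
        c = other_chroms[rng.integers(len(other_chroms))]
        start = int(rng.integers(1_000_000, 200_000_000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows[mid] = (c, start, start + member_length, strand, None)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "start", "end", "strand", "cluster_id"]
    ).loc[truth.classes.index]
    table.index.name = "mirna_id"
    return MiRNAAnnotation(table)


def simulate_target_map(
    truth: TruthLabels,
    n_genes: int = 2000,
    targets_per_mirna: int = 30,
    enriched_pathway_fraction: float = 0.6,
    seed: int = 0,
    enriched_class: str = "genotype_elevated",
    enriched_block_size: int = 100,
    distribution: str = "poisson",
) -> TargetMap:
    """miRNA -> target-gene sets over a synthetic gene universe.

    miRNAs of ``enriched_class`` draw ``enriched_pathway_fraction`` of their
    targets from the designated gene block (the first ``enriched_block_size``
    universe genes, which :func:`simulate_pathways` exposes as its designated
    pathway), so pathway-enrichment recovery is testable.  ``distribution``
    is ``"poisson"`` (mean ``targets_per_mirna``) or ``"constant"``.
    """
    if n_genes <= targets_per_mirna:
        raise SpecificationError("n_genes must exceed targets_per_mirna")
    if not 0 <= enriched_pathway_fraction <= 1:
        raise SpecificationError("enriched_pathway_fraction must be in [0, 1]")
    genes = np.array(gene_universe(n_genes))
    block = genes[:enriched_block_size]
    rest = genes[enriched_block_size:]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    targets: dict[str, frozenset[str]] = {}
    for mid, cls in truth.classes.items():
        if distribution == "constant":
            k = targets_per_mirna
        elif distribution == "poisson":
            k = int(rng.poisson(targets_per_mirna))
        else:
            raise SpecificationError(f"unknown targets distribution {distribution!r}")
        k = min(k, n_genes)
        if k == 0:
            targets[mid] = frozenset()
            continue
        if cls == enriched_class:
            k_in = min(int(round(enriched_pathway_fraction * k)), block.size)
            chosen = list(rng.choice(block, size=k_in, replace=False))
            k_out = min(k - k_in, rest.size)
            if k_out:
                chosen += list(rng.choice(rest, size=k_out, replace=False))
        else:
            chosen = list(rng.choice(genes, size=k, replace=False))
        targets[mid] = frozenset(chosen)
    return TargetMap(targets, pool=tuple(truth.classes.index))


def simulate_pathways(
    n_pathways: int = 50,
    genes_per_pathway: int = 80,
    n_genes: int = 2000,
    seed: int = 0,
    enriched_block_size: int = 100,
) -> PathwayCollection:
    """Named random gene sets; pathway ``P0000`` is the designated enriched
    block shared with :func:`simulate_target_map` (synthetic stand-in for a
    curated pathway collection)."""
    if n_genes < genes_per_pathway:
        raise SpecificationError("n_genes must be >= genes_per_pathway")
    genes = np.array(gene_universe(n_genes))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    block = min(n_genes, max(enriched_block_size, genes_per_pathway))
    pathways["P0000"] = frozenset(genes[:block])
    descriptions["P0000"] = "designated enriched pathway (synthetic)"
    for i in range(1, n_pathways):
        name = f"P{i:04d}"
        pathways[name] = frozenset(rng.choice(genes, size=genes_per_pathway, replace=False))
        descriptions[name] = "random pathway (synthetic)"
    return PathwayCollection(pathways, descriptions)
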