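"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular formats are TSV (UTF-8, "." for missing); annotations are BED6
plus a two-column cluster-membership TSV; pathway collections are GMT.
`run_pipeline` chains simulate/load -> normalize -> temporal DE -> dynamics
-> genotype contrasts -> cluster summary -> enrichment and writes a
machine-readable manifest, deterministically for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, MiRNAAnnotation, PathwayCollection, TargetMap
from .contrasts import cluster_summary, differential_union, per_timepoint_de
from .dynamics import (
    dynamic_mirnas,
    dynamic_mirnas_joint,
    scale_profiles,
    temporal_de,
    ubiquitous_mirnas,
    ward_cluster,
)
from .enrichment import permutation_pvalues
from .errors import ConfigurationError, DataFormatError
from .preprocessing import normalize
from .simulate import (
    DEFAULT_CLUSTER_ID,
    DesignSpec,
    EffectSpec,
    simulate_annotation,
    simulate_counts,
    simulate_pathways,
    simulate_target_map,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_targets",
    "write_targets",
    "read_gmt",
    "write_gmt",
    "RunConfig",
    "run_pipeline",
]

MISSING = "."


# ---------------------------------------------------------------------------
# counts + sample sheet

def read_counts(counts_path, sample_sheet_path) -> CountMatrix:
    """Parse a counts TSV (first column miRNA ids) and its sample sheet."""
    counts_path = Path(counts_path)
    lines = counts_path.read_text().splitlines()
    if not lines:
        raise DataFormatError("empty counts file", counts_path)
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise DataFormatError("counts header has no sample columns", counts_path, 1)
    ids, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataFormatError(
                f"expected {len(header)} fields, got {len(parts)}", counts_path, ln
            )
        try:
            vals = [int(v) for v in parts[1:]]
        except ValueError as exc:
            raise DataFormatError(f"non-integer count: {exc}", counts_path, ln) from None
        if any(v < 0 for v in vals):
            raise DataFormatError("negative count", counts_path, ln)
        ids.append(parts[0])
        rows.append(vals)
    if not ids:
        raise DataFormatError("counts file has no data rows", counts_path)
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="mirna_id"), columns=sample_ids)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"replicate": int})
    if "sample_id" not in sheet.columns:
        raise DataFormatError("sample sheet must have a sample_id column", sample_sheet_path)
    sheet = sheet.set_index("sample_id")
    return CountMatrix(counts, sheet)


def write_counts(cm: CountMatrix, counts_path, sample_sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
    cm.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# annotation (BED6 + cluster TSV)

def read_annotation(bed_path, cluster_path=None) -> MiRNAAnnotation:
    """BED6 intervals (0-based half-open) plus optional cluster membership."""
    bed_path = Path(bed_path)
    rows = {}
    for ln, line in enumerate(bed_path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise DataFormatError(f"BED6 needs 6 fields, got {len(parts)}", bed_path, ln)
        chrom, start, end, name, _score, strand = parts[:6]
        if strand not in {"+", "-"}:
            raise DataFormatError(f"invalid strand {strand!r}", bed_path, ln)
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise DataFormatError("non-integer coordinates", bed_path, ln) from None
        if name in rows:
            raise DataFormatError(f"duplicate miRNA id {name!r}", bed_path, ln)
        rows[name] = (chrom, start_i, end_i, strand, None)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "start", "end", "strand", "cluster_id"]
    )
    table.index.name = "mirna_id"
    if cluster_path is not None:
        memb = pd.read_csv(cluster_path, sep="\t")
        if list(memb.columns[:2]) != ["mirna_id", "cluster_id"]:
            memb.columns = ["mirna_id", "cluster_id"] + list(memb.columns[2:])
        unknown = set(memb["mirna_id"]) - set(table.index)
        if unknown:
            warnings.warn(
                f"{len(unknown)} cluster-file miRNA(s) absent from BED, ignored",
                stacklevel=2,
            )
        memb = memb[memb["mirna_id"].isin(table.index)]
        table.loc[memb["mirna_id"].to_numpy(), "cluster_id"] = memb["cluster_id"].to_numpy()
    return MiRNAAnnotation(table)


def write_annotation(ann: MiRNAAnnotation, bed_path, cluster_path=None) -> None:
    with open(bed_path, "w") as fh:
        for mid, row in ann.table.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{mid}\t0\t{row['strand']}\n"
            )
    if cluster_path is not None:
        memb = ann.table.dropna(subset=["cluster_id"])
        with open(cluster_path, "w") as fh:
            fh.write("mirna_id\tcluster_id\n")
            for mid, row in memb.iterrows():
                fh.write(f"{mid}\t{row['cluster_id']}\n")


# ---------------------------------------------------------------------------
# targets + GMT

def read_targets(path, pool=None) -> TargetMap:
    """Two-column miRNA-to-gene TSV (header optional); repeated pairs collapse."""
    path = Path(path)
    targets: dict[str, set[str]] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataFormatError(f"expected 2 fields, got {len(parts)}", path, ln)
        if ln == 1 and parts == ["mirna_id", "gene_id"]:
            continue
        targets.setdefault(parts[0], set()).add(parts[1])
    frozen = {m: frozenset(g) for m, g in targets.items()}
    if pool is None:
        pool = tuple(sorted(frozen))
    return TargetMap(frozen, pool=tuple(pool))


def write_targets(tm: TargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m in sorted(tm.targets):
            for g in sorted(tm.targets[m]):
                fh.write(f"{m}\t{g}\n")


def read_gmt(path) -> PathwayCollection:
    """GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ... per line."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataFormatError("GMT line needs >= 3 fields", path, ln)
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in pathways:
            raise DataFormatError(f"duplicate pathway id {name!r}", path, ln)
        if len(set(genes)) != len(genes):
            warnings.warn(f"duplicate genes in pathway {name!r} deduplicated", stacklevel=2)
        pathways[name] = frozenset(genes)
        descriptions[name] = desc
    return PathwayCollection(pathways, descriptions)


def write_gmt(pc: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in pc.pathways:
            desc = pc.descriptions.get(name, MISSING)
            genes = "\t".join(sorted(pc.pathways[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# run configuration + pipeline

@dataclass
class RunConfig:
    """Everything one end-to-end run needs; loadable from a YAML file."""

    out_dir: str = "evmirna_run"
    seed: int = 0
    # input paths (unused when simulate=True)
    counts: str | None = None
    sample_sheet: str | None = None
    annotation_bed: str | None = None
    annotation_clusters: str | None = None
    targets: str | None = None
    gmt: str | None = None
    # thresholds
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 3
    prior_count: float = 2.0
    ubiquitous_threshold: float = 12.0
    k_clusters: int = 3
    n_perm: int = 10_000
    paper_parity: bool = False
    cluster_id: str | None = None
    skip_enrich: bool = False
    # synthetic-data mode
    simulate: bool = False
    design: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")
        if not self.simulate:
            for key in ("counts", "sample_sheet"):
                p = getattr(self, key)
                if p is None:
                    raise ConfigurationError(f"config requires {key!r} unless simulate=true")
                if not Path(p).exists():
                    raise ConfigurationError(f"{key} path does not exist: {p}")
            if not self.skip_enrich:
                for key in ("targets", "gmt"):
                    p = getattr(self, key)
                    if p is None:
                        raise ConfigurationError(
                            f"enrichment enabled but {key!r} not set (use skip_enrich)"
                        )
                    if not Path(p).exists():
                        raise ConfigurationError(f"{key} path does not exist: {p}")
            for key in ("annotation_bed", "annotation_clusters"):
                p = getattr(self, key)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{key} path does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, index_label="mirna_id") -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING, index_label=index_label)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written as
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "evmirna",
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "outputs": [],
    }

    def emit(df, name, index_label="mirna_id"):
        path = out / name
        _write_tsv(df, path, index_label=index_label)
        manifest["outputs"].append(name)

    # ---- stage 1: inputs -------------------------------------------------
    annotation = target_map = pathway_collection = None
    cluster_id = config.cluster_id
    if config.simulate:
        design = DesignSpec(**config.design)
        effects = EffectSpec(**config.effects)
        cm, truth = simulate_counts(design, effects, config.seed)
        annotation = simulate_annotation(truth, seed=config.seed + 1)
        target_map = simulate_target_map(truth, seed=config.seed + 2)
        pathway_collection = simulate_pathways(seed=config.seed + 3)
        cluster_id = cluster_id or DEFAULT_CLUSTER_ID
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        write_counts(cm, inputs / "counts.tsv", inputs / "samples.tsv")
        write_annotation(annotation, inputs / "annotation.bed", inputs / "clusters.tsv")
        write_targets(target_map, inputs / "targets.tsv")
        write_gmt(pathway_collection, inputs / "pathways.gmt")
        truth_df = pd.DataFrame(
            {"class": truth.classes, "composition_biased": truth.composition_biased}
        )
        _write_tsv(truth_df, inputs / "truth.tsv")
    else:
        cm = read_counts(config.counts, config.sample_sheet)
        if config.annotation_bed:
            annotation = read_annotation(config.annotation_bed, config.annotation_clusters)
        if config.targets:
            target_map = read_targets(config.targets)
        if config.gmt:
            pathway_collection = read_gmt(config.gmt)
    manifest["stages"]["input"] = {"mirnas": int(cm.counts.shape[0]), "samples": int(cm.counts.shape[1])}

    # ---- stage 2: normalization -----------------------------------------
    filtered, norm = normalize(
        cm, min_cpm=config.min_cpm, min_samples=config.min_samples,
        prior_count=config.prior_count,
    )
    emit(norm.tmm_factor.to_frame().join(norm.effective_library_size), "normalization.tsv",
         index_label="sample_id")
    emit(norm.logcpm, "logcpm.tsv")
    manifest["stages"]["normalize"] = {"mirnas_kept": int(filtered.counts.shape[0])}

    # ---- stage 3: temporal DE + dynamics --------------------------------
    de_temporal = {
        region: temporal_de(filtered, norm, region) for region in ("dorsal", "ventral")
    }
    for region, tabs in de_temporal.items():
        for name, tab in tabs.items():
            emit(tab, f"de_temporal_{region}_{name}.tsv")
    # the dynamic set itself comes from one joint F-test per region (single
    # BH adjustment); the six-contrast union is written alongside for
    # per-contrast reporting
    dyn = dynamic_mirnas_joint(filtered, norm, alpha=config.alpha)
    emit(dyn.flags.astype(int), "dynamic_set.tsv")
    dyn_pairwise = dynamic_mirnas(de_temporal, alpha=config.alpha)
    emit(dyn_pairwise.flags.astype(int), "dynamic_set_pairwise.tsv")
    manifest["stages"]["dynamics"] = {
        "n_dynamic": len(dyn.mirnas),
        "n_dynamic_pairwise_union": len(dyn_pairwise.mirnas),
    }

    ic_samples = filtered.samples.index[filtered.samples["genotype"] == "IC"]
    if len(dyn.mirnas) >= max(2, config.k_clusters):
        Zs = scale_profiles(norm.logcpm.loc[dyn.mirnas, ic_samples])
        clustering = ward_cluster(Zs, filtered.samples, k=config.k_clusters)
        emit(Zs, "profiles_standardized.tsv")
        labels = clustering.labels.to_frame()
        labels["monotonicity"] = labels["cluster"].map(clustering.monotonicity)
        emit(labels, "profile_clusters.tsv")
        manifest["stages"]["clustering"] = {
            "k": clustering.k,
            "monotonicity": clustering.monotonicity,
        }
    ubiq = ubiquitous_mirnas(norm.logcpm, filtered.samples, config.ubiquitous_threshold)
    emit(pd.DataFrame(index=pd.Index(ubiq, name="mirna_id")), "ubiquitous_set.tsv")
    manifest["stages"]["ubiquitous"] = {"n_ubiquitous": len(ubiq)}

    # ---- stage 4: genotype contrasts ------------------------------------
    de_genotype = per_timepoint_de(filtered, norm, alpha=config.alpha)
    for name, tab in de_genotype.items():
        emit(tab, f"de_genotype_{name}.tsv")
    union = differential_union(de_genotype, alpha=config.alpha)
    emit(union.log2fc, "genotype_log2fc_matrix.tsv")
    emit(union.significant.astype(int), "genotype_significance.tsv")
    manifest["stages"]["genotype"] = {"n_union": len(union.mirnas)}

    if annotation is not None and cluster_id is not None:
        cs = cluster_summary(
            norm.logcpm, filtered.samples, de_genotype, annotation, cluster_id,
            alpha=config.alpha,
        )
        emit(cs.condition_mean_logcpm, "cluster_condition_means.tsv")
        summary = pd.DataFrame(
            {
                "value": {
                    "cluster_id": cs.cluster_id,
                    "n_members": cs.n_members,
                    "n_tested": cs.n_tested,
                    "n_significant": cs.n_significant,
                    "fraction_significant": cs.fraction_significant,
                }
            }
        )
        emit(summary, "cluster_summary.tsv", index_label="field")
        emit(cs.mean_log2fc.to_frame(), "cluster_mean_log2fc.tsv", index_label="comparison")
        manifest["stages"]["cluster_summary"] = {
            "cluster_id": cs.cluster_id,
            "fraction_significant": cs.fraction_significant,
        }

    # ---- stage 5: enrichment --------------------------------------------
    if not config.skip_enrich and target_map is not None and pathway_collection is not None:
        measured = [m for m in filtered.counts.index]
        tm = TargetMap(
            {m: target_map.targets.get(m, frozenset()) for m in measured},
            pool=tuple(measured),
        )
        queries = {
            "dynamic": dyn.mirnas,
            "genotype_union": union.mirnas,
            "ubiquitous": ubiq,
        }
        for qname, mirnas in queries.items():
            mirnas = [m for m in mirnas if m in tm.pool]
            table = permutation_pvalues(
                mirnas, tm, pathway_collection,
                n_perm=config.n_perm, seed=config.seed + 4,
                paper_parity=config.paper_parity,
            )
            emit(table, f"enrichment_{qname}.tsv", index_label="pathway_id")
            manifest["stages"][f"enrichment_{qname}"] = {
                "n_query_mirnas": len(mirnas),
                "top_pathway": str(table["p_perm"].idxmin()),
                "top_p_perm": float(table["p_perm"].min()),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
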