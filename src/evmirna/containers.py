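"""Core in-memory containers shared across the pipeline.

The study design is fixed by the experiment: two genotypes (IC, the isogenic
control line, and RTT, the MeCP2:R255X mutant), three regional states (iPSC
at day 0, dorsally and ventrally patterned forebrain organoids afterwards)
and four sampling days (D0, D13, D40, D75). Day 0 exists only in the iPSC
state; the later days only in the two patterned regions, giving 7 condition
cells per genotype and 14 overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

GENOTYPES = ("IC", "RTT")
REGIONS = ("iPSC", "dorsal", "ventral")
TIMEPOINTS = ("D0", "D13", "D40", "D75")

#: (region, timepoint) condition cells, in the study's canonical order.
CONDITION_CELLS = (
    ("iPSC", "D0"),
    ("dorsal", "D13"),
    ("dorsal", "D40"),
    ("dorsal", "D75"),
    ("ventral", "D13"),
    ("ventral", "D40"),
    ("ventral", "D75"),
)

SAMPLE_SHEET_COLUMNS = ("genotype", "region", "timepoint", "replicate")


def condition_label(genotype: str, region: str, timepoint: str) -> str:
    """Canonical label for a genotype x region x timepoint cell."""
    return f"{genotype}.{region}.{timepoint}"


@dataclass
class CountMatrix:
    """A miRNA-by-sample matrix of raw read counts plus the sample sheet.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers; index = miRNA ids (unique),
        columns = sample ids (unique).
    samples
        DataFrame indexed by sample id with columns ``genotype``, ``region``,
        ``timepoint`` and ``replicate``, aligned with ``counts.columns``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c, s = self.counts, self.samples
        if c.index.has_duplicates:
            raise DataFormatError("duplicate miRNA ids in count matrix")
        if c.columns.has_duplicates or s.index.has_duplicates:
            raise DataFormatError("duplicate sample ids")
        if list(c.columns) != list(s.index):
            raise DataFormatError("sample sheet does not match count-matrix columns")
        missing = [col for col in SAMPLE_SHEET_COLUMNS if col not in s.columns]
        if missing:
            raise DataFormatError(f"sample sheet missing columns: {missing}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataFormatError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataFormatError("counts must be nonnegative")
        bad_gt = set(s["genotype"]) - set(GENOTYPES)
        bad_rg = set(s["region"]) - set(REGIONS)
        bad_tp = set(s["timepoint"]) - set(TIMEPOINTS)
        if bad_gt or bad_rg or bad_tp:
            raise DataFormatError(
                f"unknown sample-sheet levels: {bad_gt | bad_rg | bad_tp}"
            )
        d0 = s["timepoint"] == "D0"
        ipsc = s["region"] == "iPSC"
        if not (d0 == ipsc).all():
            raise DataFormatError("timepoint D0 must coincide exactly with region iPSC")

    @property
    def mirna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.samples.loc[sample_ids])

    def subset_mirnas(self, mirna_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirna_ids)], self.samples)

    def condition_of(self) -> pd.Series:
        """Per-sample ``genotype.region.timepoint`` condition label."""
        s = self.samples
        return (
            s["genotype"].astype(str)
            + "."
            + s["region"].astype(str)
            + "."
            + s["timepoint"].astype(str)
        )


@dataclass
class NormalizationResult:
    """TMM factors, effective library sizes and the derived log2 CPM matrix."""

    tmm_factor: pd.Series
    effective_library_size: pd.Series
    logcpm: pd.DataFrame
    prior_count: float = 2.0

    def __post_init__(self) -> None:
        gm = float(np.exp(np.mean(np.log(self.tmm_factor.to_numpy(float)))))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")


@dataclass
class MiRNAAnnotation:
    """Genomic intervals (0-based half-open, GRCh38 convention) per miRNA.

    ``table`` columns: chrom, start, end, strand, cluster_id (``None``/NaN for
    miRNAs outside any genomic cluster such as C14MC or miR-302/367).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise DataFormatError("duplicate miRNA ids in annotation")
        if (t["start"] >= t["end"]).any():
            raise DataFormatError("annotation intervals must satisfy start < end")
        if not set(t["strand"]) <= {"+", "-"}:
            raise DataFormatError("strand must be '+' or '-'")
        for cid, members in t.dropna(subset=["cluster_id"]).groupby("cluster_id"):
            if members["chrom"].nunique() != 1:
                raise DataFormatError(f"cluster {cid} spans multiple chromosomes")

    def cluster_members(self, cluster_id: str) -> pd.DataFrame:
        """Members of a named genomic cluster, ordered by genomic start."""
        m = self.table[self.table["cluster_id"] == cluster_id]
        return m.sort_values("start")


@dataclass
class TargetMap:
    """miRNA -> target-gene sets plus the miRNA sampling pool.

    The pool is the set of measured miRNAs the permutation null draws from;
    it includes miRNAs with empty target sets.
    """

    targets: dict[str, frozenset[str]]
    pool: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.pool:
            self.pool = tuple(sorted(self.targets))
        missing = set(self.targets) - set(self.pool)
        if missing:
            raise ValueError(f"target map has miRNAs outside the pool: {sorted(missing)[:5]}")

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.targets.values():
            out |= s
        return frozenset(out)


@dataclass
class PathwayCollection:
    """Named gene sets over a gene universe (GMT-style)."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.pathways.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)
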