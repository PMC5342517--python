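"""Mutation and expression feature preparation.

Mutation records are filtered to coding, non-silent variant classes,
binarized per (sample, gene), optionally patched with a germline override
list, recurrence-filtered, and partitioned into collinear groups (genes
mutated in exactly the same samples).  Groups whose mutant samples are all
hypermutants, and large groups, carry flags since their signal is harder to
attribute to a driver.

Expression matrices (genes x samples) are gene-mean-centered and reduced to
high-variance genes either by an SD threshold or by a top fraction.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_CLASSES",
    "RETAINED_CLASSES",
    "VARIANT_CLASS_ALIASES",
    "MutationRecord",
    "BinaryFeatureMatrix",
    "CollinearGroup",
    "normalize_variant_class",
    "filter_and_binarize",
    "apply_overrides",
    "recurrence_filter",
    "group_collinear",
    "subset_genes",
    "mean_center",
    "variance_filter",
]

VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice",
        "silent",
        "intron",
        "intergenic",
        "noncoding",
        "utr",
        "flank",
        "other",
    }
)

#: coding, non-silent classes kept for binarization
RETAINED_CLASSES = frozenset({"missense", "nonsense", "frameshift", "splice", "other"})

#: normalization of common annotation spellings to the canonical classes;
#: anything that does not resolve raises rather than passing silently
VARIANT_CLASS_ALIASES: dict[str, str] = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "in_frame_del": "other",
    "in_frame_ins": "other",
    "translation_start_site": "other",
    "splice_site": "splice",
    "splice_region": "splice",
    "silent": "silent",
    "synonymous": "silent",
    "intron": "intron",
    "igr": "intergenic",
    "intergenic_region": "intergenic",
    "rna": "noncoding",
    "lincrna": "noncoding",
    "3'utr": "utr",
    "5'utr": "utr",
    "3utr": "utr",
    "5utr": "utr",
    "3'flank": "flank",
    "5'flank": "flank",
}


def normalize_variant_class(klass: str) -> str:
    """Map an annotation spelling to a canonical variant class or raise."""
    key = klass.strip().lower()
    if key in VARIANT_CLASSES:
        return key
    if key in VARIANT_CLASS_ALIASES:
        return VARIANT_CLASS_ALIASES[key]
    raise ValueError(f"unknown variant class: {klass!r}")


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    sample: str
    gene: str
    variant_class: str
    variant_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_class", normalize_variant_class(self.variant_class))


@dataclasses.dataclass
class BinaryFeatureMatrix:
    """Samples x genes 0/1 matrix plus the per-sample hypermutant flag."""

    values: pd.DataFrame  # index: samples, columns: genes, dtype int8 in {0,1}
    hypermutant: pd.Series  # bool per sample, aligned to values.index

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix must be strictly binary")
        self.hypermutant = self.hypermutant.reindex(self.values.index).fillna(False).astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclasses.dataclass(frozen=True)
class CollinearGroup:
    """Genes sharing one exact mutation pattern across samples."""

    group_id: str
    samples: tuple[str, ...]
    pattern: tuple[int, ...]
    genes: tuple[str, ...]
    hypermutant_only: bool
    large_group: bool
    n_mutant_samples: int

    @property
    def feature_id(self) -> str:
        return "/".join(self.genes)

    @property
    def mutant_samples(self) -> tuple[str, ...]:
        return tuple(s for s, bit in zip(self.samples, self.pattern) if bit)


def _records_frame(records: Iterable[MutationRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns={"class": "variant_class"}).copy()
        df["variant_class"] = df["variant_class"].map(normalize_variant_class)
        return df[["sample", "gene", "variant_class"]]
    rows = [(r.sample, r.gene, r.variant_class) for r in records]
    return pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])


def filter_and_binarize(
    records: Iterable[MutationRecord] | pd.DataFrame,
    samples: Sequence[str],
    hypermutants: Sequence[str] = (),
) -> BinaryFeatureMatrix:
    """Retain coding, non-silent records; 1 per (sample, gene) with >= 1 hit.

    No distinction is made between multiple or different mutation types in the
    same gene and sample.
    """
    df = _records_frame(records)
    unknown = set(df["sample"]) - set(samples)
    if unknown:
        raise ValueError(f"records reference samples not in the cohort: {sorted(unknown)}")
    kept = df[df["variant_class"].isin(RETAINED_CLASSES)]
    genes = sorted(kept["gene"].unique())
    matrix = pd.DataFrame(
        0, index=pd.Index(list(samples), name="sample"), columns=genes, dtype=np.int8
    )
    for sample, gene in zip(kept["sample"], kept["gene"]):
        matrix.at[sample, gene] = 1
    hyper = pd.Series(
        [s in set(hypermutants) for s in samples], index=matrix.index, dtype=bool
    )
    return BinaryFeatureMatrix(values=matrix, hypermutant=hyper)


def apply_overrides(
    matrix: BinaryFeatureMatrix, overrides: Sequence[tuple[str, str]]
) -> BinaryFeatureMatrix:
    """Force the named (sample, gene) cells to mutant; e.g. for curated
    germline variants that the somatic filter would otherwise miss."""
    values = matrix.values.copy()
    for sample, gene in overrides:
        if sample not in values.index:
            raise ValueError(f"override references unknown sample: {sample!r}")
        if gene not in values.columns:
            values[gene] = np.int8(0)
        values.at[sample, gene] = 1
    return BinaryFeatureMatrix(values=values, hypermutant=matrix.hypermutant)


def recurrence_filter(matrix: BinaryFeatureMatrix, min_samples: int = 2) -> BinaryFeatureMatrix:
    """Drop genes mutated in fewer than ``min_samples`` samples (inclusive keep)."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    keep = matrix.values.columns[matrix.values.sum(axis=0) >= min_samples]
    return BinaryFeatureMatrix(values=matrix.values[keep], hypermutant=matrix.hypermutant)


def group_collinear(
    matrix: BinaryFeatureMatrix, large_threshold: int = 5
) -> list[CollinearGroup]:
    """Partition genes by identical mutation pattern across samples.

    ``hypermutant_only`` flags groups whose every mutant sample is a
    hypermutant; ``large_group`` flags groups with >= ``large_threshold``
    member genes.  Group order follows first gene appearance in the matrix.
    """
    hyper = set(matrix.values.index[matrix.hypermutant])
    by_pattern: dict[tuple[int, ...], list[str]] = {}
    for gene in matrix.values.columns:
        pattern = tuple(int(x) for x in matrix.values[gene])
        by_pattern.setdefault(pattern, []).append(gene)
    groups = []
    for i, (pattern, genes) in enumerate(by_pattern.items(), start=1):
        mutants = {s for s, bit in zip(matrix.values.index, pattern) if bit}
        groups.append(
            CollinearGroup(
                group_id=f"MG{i:03d}",
                samples=tuple(matrix.values.index),
                pattern=pattern,
                genes=tuple(genes),
                hypermutant_only=bool(mutants) and mutants <= hyper,
                large_group=len(genes) >= large_threshold,
                n_mutant_samples=len(mutants),
            )
        )
    return groups


def subset_genes(matrix: BinaryFeatureMatrix, gene_list: Sequence[str]) -> BinaryFeatureMatrix:
    """Keep only columns named in ``gene_list`` (exact match, matrix order)."""
    if len(gene_list) == 0:
        raise ValueError("gene_list must be nonempty")
    wanted = set(gene_list)
    keep = [g for g in matrix.values.columns if g in wanted]
    if not keep:
        warnings.warn("gene list shares no genes with the matrix; returning empty matrix")
    return BinaryFeatureMatrix(values=matrix.values[keep], hypermutant=matrix.hypermutant)


def mean_center(expression: pd.DataFrame) -> pd.DataFrame:
    """Center every gene row to mean 0 (idempotent)."""
    return expression.sub(expression.mean(axis=1), axis=0)


def variance_filter(expression: pd.DataFrame, mode: str, value: float) -> pd.DataFrame:
    """Reduce to high-variance genes.

    ``sd_threshold`` keeps genes with sample SD (n−1 denominator) strictly
    above ``value``; ``top_fraction`` keeps the ceil(value·n_genes) highest-SD
    genes with ties broken by gene id.
    """
    if value <= 0:
        raise ValueError(f"value must be > 0, got {value}")
    sds = expression.std(axis=1, ddof=1)
    if mode == "sd_threshold":
        return expression.loc[sds > value]
    if mode == "top_fraction":
        if value > 1:
            raise ValueError(f"top_fraction value must be <= 1, got {value}")
        k = math.ceil(value * len(expression))
        order = sorted(expression.index, key=lambda g: (-sds[g], g))
        keep = set(order[:k])
        return expression.loc[[g for g in expression.index if g in keep]]
    raise ValueError(f"unknown variance filter mode: {mode!r}")
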