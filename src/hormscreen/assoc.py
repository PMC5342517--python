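"""Feature-response association with a multi-measure robustness rule.

Mutation groups are tested against each of the four viability measures with
two-sided Welch t-tests (mutant vs wild type), Benjamini-Hochberg adjusted
per measure and called significant at adjusted p < 0.25.  Expression genes
use Pearson correlation with an inclusive |r| >= 0.5 cutoff.  A feature is
reported as robust only when significant for at least two of the four
measures; flags from collinear groups (hypermutant-only, large group)
propagate to the report.  Sample-level annotations are tested with a Welch
t-test (two groups) or one-way ANOVA (subtypes), and a multi-drug AUC panel
is screened by pairwise-complete Pearson correlation against the focal drug.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hormscreen.doseresponse import ViabilityMeasures
from hormscreen.features import CollinearGroup

__all__ = [
    "MEASURES",
    "AssociationRecord",
    "RobustFeature",
    "benjamini_hochberg",
    "mutation_association",
    "expression_association",
    "robustness_filter",
    "group_scalar_test",
    "subtype_association",
    "drug_correlations",
]

MEASURES = ViabilityMeasures.MEASURE_NAMES

P_ADJ_CUTOFF = 0.25
R_CUTOFF = 0.5
MIN_MEASURES = 2


@dataclasses.dataclass(frozen=True)
class AssociationRecord:
    feature_id: str
    feature_kind: str  # mutation_group | expression_gene | subtype | hypermutant | drug
    measure: str
    direction: str  # sensitizing | resistance | n/a
    statistic: float
    p: float
    p_adj: float
    significant: bool
    hypermutant_only: bool = False
    large_group: bool = False


@dataclasses.dataclass(frozen=True)
class RobustFeature:
    feature_id: str
    feature_kind: str
    n_significant_measures: int
    hypermutant_only: bool = False
    large_group: bool = False


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values: min over j >= i of m·p(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _welch(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> tuple[float, float]:
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # zero variance in both groups with equal means etc.
        return 0.0, 1.0
    return t, p


def mutation_association(
    measures: pd.DataFrame,
    groups: Sequence[CollinearGroup],
    alpha: float = P_ADJ_CUTOFF,
    min_group: int = 2,
    equal_var: bool = False,
) -> tuple[list[AssociationRecord], list[str]]:
    """Welch t-test of every collinear mutation group against every measure.

    ``measures`` is indexed by sample with the four measure columns.  Returns
    (records, skipped group feature ids); groups need >= ``min_group`` samples
    on both sides to be tested.  BH adjustment is per measure across tested
    groups; direction is sensitizing when mutant means are lower (more
    response) than wild type.
    """
    missing = [m for m in MEASURES if m not in measures.columns]
    if missing:
        raise ValueError(f"measures table lacks columns: {missing}")
    censored_cols = [c for c in ("ic50_trap_censored", "ic50_fit_censored") if c in measures]
    for col in censored_cols:
        if measures[col].any():
            warnings.warn(
                f"{int(measures[col].sum())} samples have censored {col.replace('_censored', '')}"
                "; censored values enter tests at c_max"
            )
    samples = measures.index
    tested, skipped = [], []
    for group in groups:
        mutants = set(group.mutant_samples)
        mask = np.array([s in mutants for s in samples])
        n_mut = int(mask.sum())
        if n_mut < min_group or len(samples) - n_mut < min_group:
            skipped.append(group.feature_id)
            continue
        tested.append((group, mask))
    records: list[AssociationRecord] = []
    for measure in MEASURES:
        vals = measures[measure].to_numpy(dtype=float)
        stats_p = []
        for group, mask in tested:
            t, p = _welch(vals[mask], vals[~mask], equal_var=equal_var)
            direction = "sensitizing" if vals[mask].mean() < vals[~mask].mean() else "resistance"
            stats_p.append((group, t, p, direction))
        p_adj = benjamini_hochberg([p for _, _, p, _ in stats_p])
        for (group, t, p, direction), pa in zip(stats_p, p_adj):
            records.append(
                AssociationRecord(
                    feature_id=group.feature_id,
                    feature_kind="mutation_group",
                    measure=measure,
                    direction=direction,
                    statistic=t,
                    p=p,
                    p_adj=float(pa),
                    significant=bool(pa < alpha),
                    hypermutant_only=group.hypermutant_only,
                    large_group=group.large_group,
                )
            )
    return records, skipped


def expression_association(
    measures: pd.DataFrame,
    expression: pd.DataFrame,
    r_cutoff: float = R_CUTOFF,
) -> tuple[list[AssociationRecord], list[str]]:
    """Pearson correlation of every expression gene with every measure.

    Significance is |r| >= ``r_cutoff`` (inclusive).  Genes constant across
    samples are skipped (second return value), not errors.
    """
    missing = [m for m in MEASURES if m not in measures.columns]
    if missing:
        raise ValueError(f"measures table lacks columns: {missing}")
    common = [s for s in expression.columns if s in measures.index]
    if len(common) < 3:
        raise ValueError(f"need >= 3 overlapping samples, got {len(common)}")
    expr = expression[common]
    sub = measures.loc[common]
    constant = expr.std(axis=1, ddof=1) == 0
    skipped = list(expr.index[constant])
    expr = expr.loc[~constant]
    records: list[AssociationRecord] = []
    for measure in MEASURES:
        vals = sub[measure].to_numpy(dtype=float)
        raw_p: list[float] = []
        raw: list[tuple[str, float, float, str]] = []
        for gene in expr.index:
            r, p = stats.pearsonr(expr.loc[gene].to_numpy(dtype=float), vals)
            direction = "sensitizing" if r > 0 else "resistance"
            raw.append((gene, float(r), float(p), direction))
            raw_p.append(float(p))
        p_adj = benjamini_hochberg(raw_p)
        for (gene, r, p, direction), pa in zip(raw, p_adj):
            records.append(
                AssociationRecord(
                    feature_id=gene,
                    feature_kind="expression_gene",
                    measure=measure,
                    direction=direction,
                    statistic=r,
                    p=p,
                    p_adj=float(pa),
                    significant=bool(abs(r) >= r_cutoff),
                )
            )
    return records, skipped


def robustness_filter(
    records: Iterable[AssociationRecord], min_measures: int = MIN_MEASURES
) -> list[RobustFeature]:
    """Keep features significant for at least ``min_measures`` of the four
    measures; flags are propagated from the underlying records."""
    by_feature: dict[tuple[str, str], list[AssociationRecord]] = {}
    for rec in records:
        by_feature.setdefault((rec.feature_id, rec.feature_kind), []).append(rec)
    robust = []
    for (feature_id, kind), recs in by_feature.items():
        n_sig = sum(1 for r in recs if r.significant)
        if n_sig >= min_measures:
            robust.append(
                RobustFeature(
                    feature_id=feature_id,
                    feature_kind=kind,
                    n_significant_measures=n_sig,
                    hypermutant_only=any(r.hypermutant_only for r in recs),
                    large_group=any(r.large_group for r in recs),
                )
            )
    return robust


def group_scalar_test(
    values: Sequence[float], labels: Sequence, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided t-test (Welch by default) of a measure between two groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    x = values[labels == levels[0]]
    y = values[labels == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"each group needs >= 2 samples, got {len(x)} and {len(y)}")
    return _welch(x, y, equal_var=equal_var)


def subtype_association(
    values: Sequence[float], labels: Sequence, min_per_level: int = 2
) -> tuple[float, float]:
    """One-way ANOVA of a measure across subtype levels.

    Levels with fewer than ``min_per_level`` samples are merged into "other"
    with a warning; fewer than two usable levels is an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(pd.Series(labels).astype(str))
    counts = pd.Series(labels).value_counts()
    small = set(counts.index[counts < min_per_level])
    if small:
        warnings.warn(f"merging small subtype levels into 'other': {sorted(small)}")
        labels = np.where(np.isin(labels, list(small)), "other", labels)
    groups = [
        values[labels == lev]
        for lev in sorted(np.unique(labels))
        if np.sum(labels == lev) >= min_per_level
    ]
    if len(groups) < 2:
        raise ValueError("need >= 2 usable subtype levels")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def drug_correlations(
    drugs: pd.DataFrame, focal: str, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise-complete Pearson correlation across a samples x drugs panel.

    Pairs with fewer than ``min_pairs`` complete observations get NA.  Returns
    the full symmetric matrix (unit diagonal) and the ranked correlations of
    all other drugs with ``focal``, descending.
    """
    if focal not in drugs.columns:
        raise ValueError(f"focal drug {focal!r} not in the panel")
    corr = drugs.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    ranked = corr[focal].drop(index=focal).sort_values(ascending=False, kind="stable")
    return corr, ranked
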