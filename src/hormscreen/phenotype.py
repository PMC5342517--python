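"""Monotonous vs non-monotonous responder comparison.

A sample is non-monotonous when its fitted curve shows a growth response of
at least 1.5x the untreated control at the lowest nonzero concentration
(inclusive threshold).  The two groups are compared on the binary mutation
matrix with per-gene chi-square tests and on expression with empirical-Bayes
moderated two-group t-statistics, which stabilize per-gene variances at the
tiny group sizes typical of organoid panels.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import chi2
from scipy.stats import t as t_dist

from hormscreen.assoc import benjamini_hochberg
from hormscreen.doseresponse import DoseGrid, HormeticFit, hormetic_model
from hormscreen.features import BinaryFeatureMatrix

__all__ = [
    "MONOTONICITY_THRESHOLD",
    "MonotonicityCall",
    "classify_monotonicity",
    "chisq_per_mutation",
    "moderated_de",
]

MONOTONICITY_THRESHOLD = 1.5


@dataclasses.dataclass(frozen=True)
class MonotonicityCall:
    sample: str
    viability_at_lowest_dose: float
    label: str  # "monotonous" | "non_monotonous"


def classify_monotonicity(
    fit: HormeticFit,
    grid: DoseGrid,
    sample: str = "?",
    threshold: float = MONOTONICITY_THRESHOLD,
) -> MonotonicityCall:
    """Label a sample by its fitted viability at the lowest nonzero dose."""
    value = float(hormetic_model(grid.lowest_nonzero, fit.params))
    label = "non_monotonous" if value >= threshold else "monotonous"
    return MonotonicityCall(sample=sample, viability_at_lowest_dose=value, label=label)


def chisq_per_mutation(matrix: BinaryFeatureMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-gene 2x2 chi-square (no continuity correction, df=1) of mutation
    status against a two-group sample label.

    Genes with a zero marginal (never/always mutated, or versus an empty
    group) are flagged degenerate with statistic 0 and p 1.
    """
    labels = labels.reindex(matrix.values.index)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    in_a = (labels == levels[0]).to_numpy()
    rows = []
    small_expected = False
    for gene in matrix.values.columns:
        mut = matrix.values[gene].to_numpy().astype(bool)
        a = int(np.sum(mut & in_a))
        b = int(np.sum(mut & ~in_a))
        c = int(np.sum(~mut & in_a))
        d = int(np.sum(~mut & ~in_a))
        n = a + b + c + d
        marginals = [a + b, c + d, a + c, b + d]
        if 0 in marginals:
            rows.append((gene, 0.0, 1.0, True))
            continue
        stat = n * (a * d - b * c) ** 2 / (marginals[0] * marginals[1] * marginals[2] * marginals[3])
        expected_min = min(marginals[0], marginals[1]) * min(marginals[2], marginals[3]) / n
        small_expected = small_expected or expected_min < 5
        rows.append((gene, float(stat), float(chi2.sf(stat, df=1)), False))
    if small_expected:
        warnings.warn("chi-square: some 2x2 tables have expected cell counts < 5")
    return pd.DataFrame(rows, columns=["gene", "statistic", "p", "degenerate"]).set_index("gene")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (df0, s0^2) to the
    observed distribution of per-gene sample variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid_var = e_var - special.polygamma(1, df / 2.0)
    if resid_var <= 0:
        return np.inf, float(np.exp(e_mean))
    df0 = 2.0 * _trigamma_inverse(resid_var)
    s0_sq = float(np.exp(e_mean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0)))
    return df0, s0_sq


def moderated_de(
    expression: pd.DataFrame, labels: pd.Series, prior_df: float | None = None
) -> pd.DataFrame:
    """Two-group moderated t-test per gene (genes x samples input).

    Per-gene pooled variances are shrunk toward a common prior estimated by
    empirical Bayes from the variance distribution across genes; the moderated
    t uses the shrunken variance with prior-augmented degrees of freedom.
    ``prior_df`` overrides the estimated prior df (0 recovers the ordinary
    pooled t).  P-values are Benjamini-Hochberg adjusted across genes.
    """
    labels = labels.reindex(expression.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    group_a = expression.loc[:, (labels == levels[0]).to_numpy()]
    group_b = expression.loc[:, (labels == levels[1]).to_numpy()]
    n1, n2 = group_a.shape[1], group_b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples, got {n1} and {n2}")
    diff = group_b.mean(axis=1) - group_a.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * group_a.var(axis=1, ddof=1) + (n2 - 1) * group_b.var(axis=1, ddof=1)) / df_resid
    s2 = s2.to_numpy()
    df0, s0_sq = _fit_variance_prior(s2, df_resid) if prior_df is None else (prior_df, 1.0)
    if prior_df is not None and prior_df > 0:
        _, s0_sq = _fit_variance_prior(s2, df_resid)
    if np.isinf(df0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e9
    elif df0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (df0 * s0_sq + df_resid * s2) / (df0 + df_resid)
        df_total = df_resid + df0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff.to_numpy() / se, 0.0)
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    return pd.DataFrame(
        {
            "log_diff": diff.to_numpy(),
            "t": t,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "s2": s2,
            "s2_post": s2_post,
            "df_prior": df0,
            "s2_prior": s0_sq,
        },
        index=expression.index,
    )
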