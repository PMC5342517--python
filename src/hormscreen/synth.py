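"""Seeded synthetic cohorts with planted, recorded ground truth.

Generates everything the downstream stages consume — replicate count tables,
somatic-mutation records, an expression matrix, a multi-drug AUC panel and
sample annotations — from true per-sample dose-response curves, so every
stage of the pipeline can be validated offline against known truth.

Planting strategy
-----------------
* Each sample gets a true five-parameter curve; a configured fraction carries
  a low-dose growth peak reaching at least 1.5x control at the lowest nonzero
  dose (the non-monotonous phenotype).
* A mutation gene is planted whose mutant samples have their true AUC mean
  shifted down by ``planted_mut_effect`` (µM·viability units); the sigmoid
  midpoint of every sample is solved numerically so the true model AUC hits
  its target exactly, giving exact group means.
* One expression gene and one panel drug are constructed with an exact
  empirical correlation (``planted_expr_corr`` / ``planted_drug_corr``)
  against the true AUC vector / focal-drug column.
* Collinear mutation groups are planted by copying one pattern column to k
  genes; hypermutant samples mutate at 5x the background rate.

Counts are ``seed_count x true viability x lognormal(0, noise_sd)``, rounded
to nonnegative integers.  Identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from hormscreen import io as hio
from hormscreen.doseresponse import DoseGrid, HormeticParams, hormetic_model

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "FOCAL_DRUG",
]

FOCAL_DRUG = "FOCAL"

_CODING_CLASSES = ("missense", "nonsense", "frameshift", "splice", "other")
_CODING_PROBS = (0.70, 0.10, 0.10, 0.05, 0.05)
_EXCLUDED_CLASSES = ("silent", "intron", "intergenic", "noncoding", "utr", "flank")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror a 20-line panel."""

    n_samples: int = 20
    dose_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    n_replicates: int = 3
    seed_count: int = 2000
    noise_sd: float = 0.05
    frac_hormetic: float = 0.15
    n_genes_mutation: int = 40
    n_collinear_groups: int = 3
    collinear_size_range: tuple[int, int] = (2, 8)
    n_hypermutants: int = 3
    planted_mut_effect: float = 1.6
    auc_sd: float = 0.8
    n_genes_expression: int = 300
    frac_high_var: float = 0.11
    sd_high: float = 1.5
    sd_low: float = 0.3
    planted_expr_corr: float = -0.7
    n_drugs: int = 30
    planted_drug_corr: float = 0.8
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 6:
            raise ValueError(f"n_samples must be >= 6, got {self.n_samples}")
        try:
            DoseGrid(self.dose_grid)
        except ValueError as exc:
            raise ValueError(f"dose_grid: {exc}") from exc
        if not 3 <= self.n_replicates <= 4:
            raise ValueError(f"n_replicates must be 3 or 4, got {self.n_replicates}")
        if self.seed_count <= 0:
            raise ValueError(f"seed_count must be positive, got {self.seed_count}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("frac_hormetic", "frac_high_var"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0 <= self.n_hypermutants <= self.n_samples:
            raise ValueError(
                f"n_hypermutants must be in [0, n_samples], got {self.n_hypermutants}"
            )
        lo, hi = self.collinear_size_range
        if not 2 <= lo <= hi:
            raise ValueError(f"collinear_size_range invalid: {self.collinear_size_range}")
        reserved = 1 + self.n_collinear_groups * hi
        if self.n_genes_mutation < reserved + 5:
            raise ValueError(
                f"n_genes_mutation too small for planted structure: need >= {reserved + 5}"
            )
        if self.n_genes_expression < 10:
            raise ValueError(f"n_genes_expression must be >= 10, got {self.n_genes_expression}")
        if self.sd_high <= 0:
            raise ValueError(f"sd_high must be > 0, got {self.sd_high}")
        if self.sd_low <= 0:
            raise ValueError(f"sd_low must be > 0, got {self.sd_low}")
        if self.auc_sd <= 0:
            raise ValueError(f"auc_sd must be > 0, got {self.auc_sd}")
        for name in ("planted_expr_corr", "planted_drug_corr"):
            value = getattr(self, name)
            if not -1.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {value}")
        if self.n_drugs < 3:
            raise ValueError(f"n_drugs must be >= 3, got {self.n_drugs}")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort."""

    params: dict[str, HormeticParams]
    true_auc: dict[str, float]
    hormetic_samples: list[str]
    hypermutant_samples: list[str]
    planted_mutation_gene: str
    planted_mutant_samples: list[str]
    planted_expression_gene: str
    planted_drug: str
    collinear_groups: dict[str, list[str]]  # group id -> member genes

    def to_jsonable(self) -> dict:
        return {
            "params": {s: dataclasses.asdict(p) for s, p in self.params.items()},
            "true_auc": self.true_auc,
            "hormetic_samples": self.hormetic_samples,
            "hypermutant_samples": self.hypermutant_samples,
            "planted_mutation_gene": self.planted_mutation_gene,
            "planted_mutant_samples": self.planted_mutant_samples,
            "planted_expression_gene": self.planted_expression_gene,
            "planted_drug": self.planted_drug,
            "collinear_groups": self.collinear_groups,
        }


@dataclasses.dataclass
class SyntheticCohort:
    counts: pd.DataFrame  # long format: sample, replicate, dose_uM, count
    mutations: pd.DataFrame  # sample, gene, class, variant_id
    expression: pd.DataFrame  # genes x samples
    drugs: pd.DataFrame  # samples x drugs (AUC panel)
    annotations: pd.DataFrame  # sample, subtype, hypermutant
    truth: SyntheticTruth


def _sigmoid_auc(shift: float, slope: float, c_max: float) -> float:
    # closed-form integral of the decreasing logistic on [0, c_max]
    return (np.logaddexp(0.0, slope * shift) - np.logaddexp(0.0, -slope * (c_max - shift))) / slope


def _model_auc(mu, sigma, shift, slope, amp, c_max) -> float:
    peak = amp * (norm.cdf(c_max, mu, sigma) - norm.cdf(0.0, mu, sigma))
    return float(_sigmoid_auc(shift, slope, c_max) + peak)


def _solve_params_for_auc(
    target_auc: float,
    slope: float,
    sigma_base: float,
    peak_value: float | None,
    c1: float,
    c_max: float,
) -> HormeticParams:
    """Choose shift, amp (and sigma for hormetic samples) so the true model
    AUC hits ``target_auc`` exactly while v(0) = 1 exactly.

    The two-parameter sigmoid alone never passes through 1 at zero
    concentration; every planted curve therefore carries a normal-density
    term whose value at c = 0 exactly compensates the sigmoid deficit
    ``expit(-slope*shift)``.  For monotonous samples the peak sits at mu = 0
    (the resulting curve is strictly decreasing on c > 0); for hormetic
    samples it sits at mu = c1 with sigma chosen so the curve value at the
    lowest nonzero dose equals ``peak_value`` exactly.
    """
    hormetic = peak_value is not None
    mu = c1 if hormetic else 0.0

    def peak_params(shift: float) -> tuple[float, float]:
        deficit = float(expit(-slope * shift))  # 1 - sigmoid(0)
        if not hormetic:
            return sigma_base, deficit / norm.pdf(0.0, mu, sigma_base)
        sig_at_c1 = float(expit(-slope * (c1 - shift)))
        ratio = max((peak_value - sig_at_c1) / max(deficit, 1e-12), 1.5)
        sigma = c1 / math.sqrt(2.0 * math.log(ratio))
        return sigma, deficit / norm.pdf(0.0, mu, sigma)

    def f(shift: float) -> float:
        sigma, amp = peak_params(shift)
        return _model_auc(mu, sigma, shift, slope, amp, c_max) - target_auc

    lo, hi = -2.0 * c_max, 3.0 * c_max
    scan = np.linspace(lo, hi, 121)
    vals = np.array([f(s) for s in scan])
    idx = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if idx.size == 0:  # target unattainable: take best effort
        shift = float(scan[np.argmin(np.abs(vals))])
    else:
        i = int(idx[0])
        shift = float(brentq(f, scan[i], scan[i + 1], xtol=1e-10))
    sigma, amp = peak_params(shift)
    return HormeticParams(mu=mu, sigma=sigma, shift=shift, slope=slope, amp=amp)


def _exact_correlate(z: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector whose empirical Pearson r with ``z`` is exactly ``r``."""
    z = np.asarray(z, dtype=float)
    zs = (z - z.mean()) / z.std()
    e = rng.standard_normal(z.size)
    e -= e.mean()
    e -= zs * (e @ zs) / (zs @ zs)
    e /= e.std()
    return r * zs + math.sqrt(1.0 - r * r) * e


def _random_pattern(
    rng: np.random.Generator, samples: Sequence[str], allowed: Sequence[str]
) -> np.ndarray:
    """Binary column over samples with support of >= 2 inside ``allowed``."""
    k = int(rng.integers(2, max(3, min(len(allowed), 6) + 1)))
    chosen = rng.choice(np.asarray(allowed), size=min(k, len(allowed)), replace=False)
    pattern = np.zeros(len(samples), dtype=np.int8)
    lookup = {s: i for i, s in enumerate(samples)}
    for s in chosen:
        pattern[lookup[s]] = 1
    return pattern


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete cohort plus its :class:`SyntheticTruth`."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    grid = DoseGrid(config.dose_grid)
    c_max, c1 = grid.c_max, grid.lowest_nonzero
    n = config.n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]

    # --- sample roles -----------------------------------------------------
    n_horm = int(round(config.frac_hormetic * n))
    hormetic = sorted(rng.choice(samples, size=n_horm, replace=False).tolist())
    hypermutants = sorted(rng.choice(samples, size=config.n_hypermutants, replace=False).tolist())

    n_mut = max(2, int(round(0.4 * n)))
    if n - n_mut < 2:
        n_mut = n - 2
    mutant_samples = sorted(rng.choice(samples, size=n_mut, replace=False).tolist())

    # --- true AUC targets with exact group means --------------------------
    wt_mean = 0.55 * c_max
    mut_mean = wt_mean - config.planted_mut_effect
    deviations = rng.normal(0.0, config.auc_sd, n)
    deviations = np.clip(deviations, -2.2 * config.auc_sd, 2.2 * config.auc_sd)
    is_mut = np.array([s in mutant_samples for s in samples])
    deviations[is_mut] -= deviations[is_mut].mean()
    deviations[~is_mut] -= deviations[~is_mut].mean()
    targets = np.where(is_mut, mut_mean, wt_mean) + deviations
    targets = np.clip(targets, 0.06 * c_max, 0.94 * c_max)

    # --- true curves ------------------------------------------------------
    params: dict[str, HormeticParams] = {}
    true_auc: dict[str, float] = {}
    for i, s in enumerate(samples):
        slope = float(rng.uniform(1.0, 2.5))
        sigma_base = float(rng.uniform(0.6, 1.0))
        peak = float(rng.uniform(1.6, 2.0)) if s in hormetic else None
        p = _solve_params_for_auc(float(targets[i]), slope, sigma_base, peak, c1, c_max)
        params[s] = p
        true_auc[s] = _model_auc(p.mu, p.sigma, p.shift, p.slope, p.amp, c_max)

    # --- replicate count tables -------------------------------------------
    conc = grid.as_array()
    rows = []
    for s in samples:
        v_true = hormetic_model(conc, params[s])
        for r in range(1, config.n_replicates + 1):
            noise = (
                rng.lognormal(0.0, config.noise_sd, conc.size)
                if config.noise_sd > 0
                else np.ones(conc.size)
            )
            counts = np.rint(config.seed_count * v_true * noise).astype(int)
            counts = np.maximum(counts, 0)
            counts[0] = max(counts[0], 1)  # control well must stay positive
            for c, k in zip(conc, counts):
                rows.append((s, f"R{r}", c, int(k)))
    counts_df = pd.DataFrame(rows, columns=["sample", "replicate", "dose_uM", "count"])

    # --- mutation matrix --------------------------------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes_mutation)]
    base_rate = 0.12
    hyper_rate = min(5.0 * base_rate, 0.9)
    is_hyper = np.array([s in hypermutants for s in samples])
    rates = np.where(is_hyper, hyper_rate, base_rate)
    matrix = (rng.random((n, config.n_genes_mutation)) < rates[:, None]).astype(np.int8)

    planted_gene = genes[0]
    matrix[:, 0] = is_mut.astype(np.int8)

    collinear_groups: dict[str, list[str]] = {}
    next_col = 1
    lo, hi = config.collinear_size_range
    for g in range(config.n_collinear_groups):
        size = int(rng.integers(lo, hi + 1))
        if g == 0 and len(hypermutants) >= 2:
            pattern = _random_pattern(rng, samples, hypermutants)
        else:
            pattern = _random_pattern(rng, samples, samples)
        members = genes[next_col : next_col + size]
        for j in range(next_col, next_col + size):
            matrix[:, j] = pattern
        collinear_groups[f"planted_group_{g + 1}"] = members
        next_col += size

    # --- mutation records (plus excluded-class decoys) --------------------
    rec_rows = []
    vid = 1
    for i, s in enumerate(samples):
        for j, g in enumerate(genes):
            if matrix[i, j]:
                klass = str(rng.choice(_CODING_CLASSES, p=_CODING_PROBS))
                rec_rows.append((s, g, klass, f"v{vid:05d}"))
                vid += 1
    for _ in range(2 * n):
        s = str(rng.choice(samples))
        g = str(rng.choice(genes))
        klass = str(rng.choice(_EXCLUDED_CLASSES))
        rec_rows.append((s, g, klass, f"v{vid:05d}"))
        vid += 1
    mutations_df = pd.DataFrame(rec_rows, columns=["sample", "gene", "class", "variant_id"])

    # --- expression matrix ------------------------------------------------
    egenes = [f"E{i + 1:04d}" for i in range(config.n_genes_expression)]
    n_high = max(1, int(round(config.frac_high_var * config.n_genes_expression)))
    auc_vec = np.array([true_auc[s] for s in samples])
    expr = np.empty((config.n_genes_expression, n))
    sds = np.full(config.n_genes_expression, config.sd_low)
    sds[:n_high] = config.sd_high
    for i in range(config.n_genes_expression):
        expr[i] = rng.normal(0.0, sds[i], n)
    planted_egene = egenes[0]
    if abs(config.planted_expr_corr) > 0:
        expr[0] = _exact_correlate(auc_vec, config.planted_expr_corr, rng) * config.sd_high
    expression_df = pd.DataFrame(expr, index=pd.Index(egenes, name="gene"), columns=samples)

    # --- drug panel -------------------------------------------------------
    drug_names = [FOCAL_DRUG] + [f"D{i + 1:03d}" for i in range(config.n_drugs - 1)]
    drugs = np.empty((n, config.n_drugs))
    drugs[:, 0] = auc_vec + rng.normal(0.0, 0.05, n)
    for j in range(1, config.n_drugs):
        drugs[:, j] = rng.normal(0.55 * c_max, 1.0, n)
    planted_drug = drug_names[1]
    if abs(config.planted_drug_corr) > 0:
        drugs[:, 1] = _exact_correlate(drugs[:, 0], config.planted_drug_corr, rng) + 0.55 * c_max
    drugs_df = pd.DataFrame(drugs, index=pd.Index(samples, name="sample"), columns=drug_names)

    # --- annotations ------------------------------------------------------
    subtypes = rng.choice(["CMS1", "CMS2", "CMS3", "CMS4"], size=n)
    annotations_df = pd.DataFrame(
        {
            "sample": samples,
            "subtype": subtypes,
            "hypermutant": is_hyper.astype(int),
        }
    )

    truth = SyntheticTruth(
        params=params,
        true_auc={s: float(a) for s, a in true_auc.items()},
        hormetic_samples=hormetic,
        hypermutant_samples=hypermutants,
        planted_mutation_gene=planted_gene,
        planted_mutant_samples=mutant_samples,
        planted_expression_gene=planted_egene,
        planted_drug=planted_drug,
        collinear_groups=collinear_groups,
    )
    return SyntheticCohort(
        counts=counts_df,
        mutations=mutations_df,
        expression=expression_df,
        drugs=drugs_df,
        annotations=annotations_df,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, meta: dict | None = None) -> None:
    """Emit the cohort as TSV matrices plus truth.json."""
    outdir = Path(outdir)
    hio.write_tsv(cohort.counts, outdir / "counts.tsv", meta=meta)
    hio.write_tsv(cohort.mutations, outdir / "mutations.tsv", meta=meta)
    hio.write_tsv(cohort.expression.reset_index(), outdir / "expression.tsv", meta=meta)
    hio.write_tsv(
        cohort.drugs.T.rename_axis("drug").reset_index(), outdir / "drugs.tsv", meta=meta
    )
    hio.write_tsv(cohort.annotations, outdir / "annotations.tsv", meta=meta)
    hio.write_json(cohort.truth.to_jsonable(), outdir / "truth.json")
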