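"""Shared fixtures.

The 50-seed cohort sweeps and the fixed-seed quantified cohorts are
session-scoped because several test modules (and the acceptance suite)
assert against the same computations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hormscreen.doseresponse import DoseGrid
from hormscreen.pipeline import PipelineConfig, analyze_cohort, quantify_counts
from hormscreen.synth import CohortConfig, generate_cohort

N_SWEEP_SEEDS = 50


@pytest.fixture(scope="session")
def default_grid() -> DoseGrid:
    return DoseGrid((0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0))


def _quantified(noise_sd: float, seed: int = 42):
    cohort = generate_cohort(CohortConfig(rng_seed=seed, noise_sd=noise_sd))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        measures, fits = quantify_counts(cohort.counts, seed=1, n_restarts=150)
    return cohort, measures, fits


@pytest.fixture(scope="session")
def noiseless_quantified():
    """Noiseless default cohort (seed 42) with measures and fits."""
    return _quantified(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_quantified():
    """Default-noise cohort (seed 42) with measures and fits."""
    return _quantified(noise_sd=0.05)


def _run_seed(cohort_cfg: CohortConfig, pipeline_seed: int) -> dict:
    cohort = generate_cohort(cohort_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = analyze_cohort(
            cohort.counts,
            cohort.mutations,
            cohort.expression,
            cohort.drugs,
            cohort.annotations,
            cfg=PipelineConfig(rng_seed=pipeline_seed, n_restarts=150),
        )
    truth = cohort.truth
    robust = res["robust_features"]
    mut_features = {}
    for rec in res["mutation_records"]:
        mut_features.setdefault(rec.feature_id, []).append(rec.significant)
    return {
        "truth": truth,
        "hit_mutation": any(
            truth.planted_mutation_gene in r.feature_id.split("/")
            for r in robust
            if r.feature_kind == "mutation_group"
        ),
        "hit_expression": any(
            r.feature_id == truth.planted_expression_gene
            for r in robust
            if r.feature_kind == "expression_gene"
        ),
        "drug_first": res["drug_ranking"].index[0] == truth.planted_drug,
        "frac_single": (
            sum(1 for flags in mut_features.values() if any(flags)) / len(mut_features)
        ),
        "frac_robust": (
            sum(1 for flags in mut_features.values() if sum(flags) >= 2) / len(mut_features)
        ),
    }


@pytest.fixture(scope="session")
def effect_sweep():
    """50 seeded cohorts with the default planted effects, fully analyzed."""
    return [
        _run_seed(CohortConfig(rng_seed=1000 + s), pipeline_seed=s)
        for s in range(N_SWEEP_SEEDS)
    ]


@pytest.fixture(scope="session")
def null_sweep():
    """50 seeded cohorts with every planted effect zeroed."""
    cfg = dict(planted_mut_effect=0.0, planted_expr_corr=0.0, planted_drug_corr=0.0)
    return [
        _run_seed(CohortConfig(rng_seed=2000 + s, **cfg), pipeline_seed=s)
        for s in range(N_SWEEP_SEEDS)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
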