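"""End-to-end orchestration: simulate -> quantify -> features -> phenotype -> associate.

A single global seed fans out to per-stage seeds via ``numpy`` seed
sequences, so stages are independently reproducible.  Every output file
carries a ``#`` metadata header with the config hash and seed; identical
config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hormscreen import assoc, features, io as hio, phenotype, synth
from hormscreen.doseresponse import (
    DoseGrid,
    HormeticFit,
    HormeticParams,
    ViabilityMeasures,
    normalize_counts,
    quantify_sample,
)

__all__ = ["PipelineConfig", "quantify_counts", "analyze_cohort", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Every numeric threshold of the analysis, plus seeding and options."""

    p_adj_cutoff: float = 0.25
    r_cutoff: float = 0.5
    min_measures: int = 2
    sd_cutoff: float = 0.7
    recurrence_min: int = 2
    large_threshold: int = 5
    monotonicity_threshold: float = 1.5
    n_restarts: int = 500
    focal_drug: str = synth.FOCAL_DRUG
    gene_list: tuple[str, ...] | None = None
    overrides: tuple[tuple[str, str], ...] = ()
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_adj_cutoff",
            "r_cutoff",
            "min_measures",
            "sd_cutoff",
            "recurrence_min",
            "large_threshold",
            "monotonicity_threshold",
            "n_restarts",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_list"] = list(self.gene_list) if self.gene_list is not None else None
        d["overrides"] = [list(o) for o in self.overrides]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("gene_list") is not None:
            d["gene_list"] = tuple(d["gene_list"])
        if d.get("overrides"):
            d["overrides"] = tuple((s, g) for s, g in d["overrides"])
        else:
            d["overrides"] = ()
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "quantify", "phenotype", "features", "associate")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(child.generate_state(1)[0]) for name, child in zip(names, children)}


def quantify_counts(
    counts: pd.DataFrame,
    grid: DoseGrid | None = None,
    n_restarts: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, HormeticFit]]:
    """Counts (long format: sample, replicate, dose_uM, count) -> per-sample
    measures table plus the hormetic fits."""
    required = {"sample", "replicate", "dose_uM", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    if grid is None:
        grid = DoseGrid(tuple(sorted(counts["dose_uM"].unique())))
    rows = []
    fits: dict[str, HormeticFit] = {}
    for i, (sample, sdf) in enumerate(counts.groupby("sample", sort=True)):
        curves = []
        for replicate, rdf in sdf.groupby("replicate", sort=True):
            rdf = rdf.sort_values("dose_uM")
            if not np.allclose(rdf["dose_uM"].to_numpy(), grid.as_array()):
                raise ValueError(f"{sample}/{replicate}: doses do not match the grid")
            curves.append(
                normalize_counts(
                    rdf["count"].to_numpy(), grid, sample=str(sample), replicate=str(replicate)
                )
            )
        measures, fit = quantify_sample(curves, n_restarts=n_restarts, seed=seed + i)
        fits[str(sample)] = fit
        p = fit.params
        rows.append(
            {
                "sample": sample,
                "auc_trap": measures.auc_trap,
                "ic50_trap": measures.ic50_trap,
                "auc_fit": measures.auc_fit,
                "ic50_fit": measures.ic50_fit,
                "ic50_trap_censored": measures.ic50_trap_censored,
                "ic50_fit_censored": measures.ic50_fit_censored,
                "mu": p.mu,
                "sigma": p.sigma,
                "shift": p.shift,
                "slope": p.slope,
                "amp": p.amp,
                "rss": fit.rss,
                "converged": fit.converged,
                "method": fit.method,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows).set_index("sample"), fits


def fits_from_measures(measures: pd.DataFrame) -> dict[str, HormeticFit]:
    """Rebuild fit objects from a measures table that carries the params."""
    fits = {}
    for sample, row in measures.iterrows():
        fits[str(sample)] = HormeticFit(
            params=HormeticParams(
                mu=row["mu"],
                sigma=row["sigma"],
                shift=row["shift"],
                slope=row["slope"],
                amp=row["amp"],
            ),
            rss=row["rss"],
            converged=bool(row["converged"]),
            method=str(row["method"]),
            n_points=int(row["n_points"]),
        )
    return fits


def prepare_features(
    mutations: pd.DataFrame,
    annotations: pd.DataFrame,
    expression: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[features.BinaryFeatureMatrix, list[features.CollinearGroup], pd.DataFrame]:
    """Mutation records + annotations + raw expression -> grouped binary
    matrix and filtered, centered expression."""
    samples = list(annotations["sample"])
    hypermutants = list(annotations.loc[annotations["hypermutant"].astype(bool), "sample"])
    matrix = features.filter_and_binarize(mutations, samples, hypermutants=hypermutants)
    if cfg.overrides:
        matrix = features.apply_overrides(matrix, cfg.overrides)
    matrix = features.recurrence_filter(matrix, min_samples=cfg.recurrence_min)
    if cfg.gene_list is not None:
        matrix = features.subset_genes(matrix, cfg.gene_list)
    groups = features.group_collinear(matrix, large_threshold=cfg.large_threshold)
    expr = features.mean_center(expression)
    expr = features.variance_filter(expr, mode="sd_threshold", value=cfg.sd_cutoff)
    return matrix, groups, expr


def analyze_cohort(
    counts: pd.DataFrame,
    mutations: pd.DataFrame,
    expression: pd.DataFrame,
    drugs: pd.DataFrame,
    annotations: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    grid: DoseGrid | None = None,
) -> dict:
    """Run every analysis stage in memory; returns a dict of results."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    seeds = _stage_seeds(cfg.rng_seed)

    measures, fits = quantify_counts(
        counts, grid=grid, n_restarts=cfg.n_restarts, seed=seeds["quantify"]
    )
    if grid is None:
        grid = DoseGrid(tuple(sorted(counts["dose_uM"].unique())))

    matrix, groups, expr = prepare_features(mutations, annotations, expression, cfg)

    calls = [
        phenotype.classify_monotonicity(
            fits[s], grid, sample=s, threshold=cfg.monotonicity_threshold
        )
        for s in measures.index
    ]
    mono_labels = pd.Series(
        {c.sample: c.label for c in calls}, name="label"
    ).reindex(measures.index)
    mono_df = pd.DataFrame(
        {
            "viability_at_lowest_dose": [c.viability_at_lowest_dose for c in calls],
            "label": [c.label for c in calls],
        },
        index=measures.index,
    )
    pheno: dict[str, pd.DataFrame | None] = {"chisq": None, "de": None}
    if mono_labels.nunique() == 2 and mono_labels.value_counts().min() >= 2:
        pheno["chisq"] = phenotype.chisq_per_mutation(matrix, mono_labels)
        pheno["de"] = phenotype.moderated_de(expr, mono_labels)
    elif mono_labels.nunique() == 2:
        pheno["chisq"] = phenotype.chisq_per_mutation(matrix, mono_labels)

    mut_records, skipped_groups = assoc.mutation_association(
        measures, groups, alpha=cfg.p_adj_cutoff
    )
    expr_records, skipped_genes = assoc.expression_association(
        measures, expr, r_cutoff=cfg.r_cutoff
    )
    robust = assoc.robustness_filter(
        list(mut_records) + list(expr_records), min_measures=cfg.min_measures
    )

    ann = annotations.set_index("sample").reindex(measures.index)
    scalar_tests = {}
    hyper = ann["hypermutant"].astype(bool)
    if hyper.nunique() == 2 and hyper.value_counts().min() >= 2:
        for measure in assoc.MEASURES:
            t, p = assoc.group_scalar_test(measures[measure].to_numpy(), hyper.to_numpy())
            scalar_tests[f"hypermutant:{measure}"] = {"statistic": t, "p": p}
    try:
        for measure in assoc.MEASURES:
            f, p = assoc.subtype_association(measures[measure].to_numpy(), ann["subtype"])
            scalar_tests[f"subtype:{measure}"] = {"statistic": f, "p": p}
    except ValueError:
        pass  # degenerate subtype composition on tiny cohorts

    corr, ranked = assoc.drug_correlations(drugs, focal=cfg.focal_drug)

    return {
        "config": cfg,
        "grid": grid,
        "measures": measures,
        "fits": fits,
        "matrix": matrix,
        "groups": groups,
        "expression_filtered": expr,
        "monotonicity": mono_df,
        "phenotype": pheno,
        "mutation_records": mut_records,
        "expression_records": expr_records,
        "skipped_groups": skipped_groups,
        "skipped_genes": skipped_genes,
        "robust_features": robust,
        "scalar_tests": scalar_tests,
        "drug_correlation_matrix": corr,
        "drug_ranking": ranked,
    }


def records_frame(records: Sequence[assoc.AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def robust_frame(robust: Sequence[assoc.RobustFeature]) -> pd.DataFrame:
    cols = [
        "feature_id",
        "feature_kind",
        "n_significant_measures",
        "hypermutant_only",
        "large_group",
    ]
    return pd.DataFrame([dataclasses.asdict(r) for r in robust], columns=cols)


def groups_frame(groups: Sequence[features.CollinearGroup]) -> pd.DataFrame:
    rows = [
        {
            "group_id": g.group_id,
            "feature_id": g.feature_id,
            "genes": ",".join(g.genes),
            "mutant_samples": ",".join(g.mutant_samples),
            "n_genes": len(g.genes),
            "n_mutant_samples": g.n_mutant_samples,
            "hypermutant_only": g.hypermutant_only,
            "large_group": g.large_group,
        }
        for g in groups
    ]
    cols = [
        "group_id",
        "feature_id",
        "genes",
        "mutant_samples",
        "n_genes",
        "n_mutant_samples",
        "hypermutant_only",
        "large_group",
    ]
    return pd.DataFrame(rows, columns=cols)


def groups_from_frame(df: pd.DataFrame, samples: Sequence[str]) -> list[features.CollinearGroup]:
    """Inverse of :func:`groups_frame` against a known sample ordering."""
    groups = []
    for _, row in df.iterrows():
        mutants = set(str(row["mutant_samples"]).split(",")) if pd.notna(row["mutant_samples"]) else set()
        pattern = tuple(1 if s in mutants else 0 for s in samples)
        groups.append(
            features.CollinearGroup(
                group_id=str(row["group_id"]),
                samples=tuple(samples),
                pattern=pattern,
                genes=tuple(str(row["genes"]).split(",")),
                hypermutant_only=bool(row["hypermutant_only"]),
                large_group=bool(row["large_group"]),
                n_mutant_samples=int(row["n_mutant_samples"]),
            )
        )
    return groups


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    cohort_config: synth.CohortConfig | None = None,
    inputs: dict[str, pd.DataFrame] | None = None,
) -> dict:
    """Simulate (or load) a cohort, run every stage, write the report directory.

    Either ``cohort_config`` (simulate) or ``inputs`` (pre-loaded tables with
    keys counts/mutations/expression/drugs/annotations) must be given.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash, "seed": cfg.rng_seed}
    seeds = _stage_seeds(cfg.rng_seed)

    if inputs is None:
        if cohort_config is None:
            raise ValueError("either cohort_config or inputs is required")
        cohort_config = dataclasses.replace(cohort_config, rng_seed=seeds["simulate"])
        cohort = synth.generate_cohort(cohort_config)
        synth.write_cohort(cohort, outdir / "cohort", meta=meta)
        inputs = {
            "counts": cohort.counts,
            "mutations": cohort.mutations,
            "expression": cohort.expression,
            "drugs": cohort.drugs,
            "annotations": cohort.annotations,
        }

    results = analyze_cohort(
        inputs["counts"],
        inputs["mutations"],
        inputs["expression"],
        inputs["drugs"],
        inputs["annotations"],
        cfg=cfg,
    )

    hio.write_tsv(results["measures"].reset_index(), outdir / "measures.tsv", meta=meta)
    hio.write_tsv(groups_frame(results["groups"]), outdir / "groups.tsv", meta=meta)
    hio.write_tsv(
        results["matrix"].values.reset_index(), outdir / "mutation_matrix.tsv", meta=meta
    )
    hio.write_tsv(
        results["expression_filtered"].reset_index(), outdir / "expression_filtered.tsv", meta=meta
    )
    hio.write_tsv(
        results["monotonicity"].reset_index(), outdir / "monotonicity.tsv", meta=meta
    )
    if results["phenotype"]["chisq"] is not None:
        hio.write_tsv(
            results["phenotype"]["chisq"].reset_index(), outdir / "phenotype_chisq.tsv", meta=meta
        )
    if results["phenotype"]["de"] is not None:
        hio.write_tsv(
            results["phenotype"]["de"].reset_index(), outdir / "phenotype_de.tsv", meta=meta
        )
    all_records = records_frame(
        list(results["mutation_records"]) + list(results["expression_records"])
    )
    hio.write_tsv(all_records, outdir / "associations.tsv", meta=meta)
    hio.write_tsv(robust_frame(results["robust_features"]), outdir / "robust_features.tsv", meta=meta)
    hio.write_tsv(
        results["drug_correlation_matrix"].rename_axis("drug").reset_index(),
        outdir / "drug_correlation_matrix.tsv",
        meta=meta,
    )

    summary = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.rng_seed,
        "n_samples": int(len(results["measures"])),
        "monotonicity": results["monotonicity"]["label"].to_dict(),
        "robust_features": [dataclasses.asdict(r) for r in results["robust_features"]],
        "skipped_groups": results["skipped_groups"],
        "scalar_tests": results["scalar_tests"],
        "top_drug_correlations": {
            k: (None if pd.isna(v) else float(v))
            for k, v in results["drug_ranking"].head(5).items()
        },
    }
    hio.write_json(summary, outdir / "summary.json")
    results["summary"] = summary
    return results
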