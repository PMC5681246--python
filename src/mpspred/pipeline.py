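"""End-to-end orchestration: simulate (or ingest) -> harmonize -> score ->
fit single-score and multi-score models -> evaluate on the hold-out set.

Every random stage derives its seed deterministically from the global seed, so
a rerun with the same :class:`RunConfig` reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, models, scoring, sumstats as ss
from .simulate import (
    GenotypePanel,
    SimulationConfig,
    simulate_all,
    stage_seed,
    write_manifest,
    write_phenotypes,
    write_sumstats,
    write_vcf,
)

__all__ = ["RunConfig", "EvaluationReport", "run_pipeline", "build_scores"]


@dataclass
class QCConfig:
    maf_min: float = 0.01
    info_min: float = 0.70
    drop_ambiguous: bool = True


@dataclass
class ScoringConfig:
    fractions: tuple[float, ...] = models.DEFAULT_FRACTIONS
    h2: float | None = None          # None: take each trait's true h2 from simulation
    window_size: int | None = None   # None: simulation block size
    n_pcs: int = 5                   # real-cohort convention is 30; desk scale smaller
    gibbs_iters: int = 500
    gibbs_burn_in: int = 100


@dataclass
class ModelConfig:
    alpha_grid: tuple[float, ...] = models.DEFAULT_ALPHA_GRID
    n_lambda: int = 100
    k: int = 10
    repeats: int = 5                 # full-scale analyses use 100


@dataclass
class EvalConfig:
    train_fraction: float = 0.6
    n_perm: int = 100_000
    n_quantiles: int = 10


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializes to/from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed drives the simulation unless one was set explicitly
        if self.simulation.seed == 0 and self.seed != 0:
            self.simulation.seed = stage_seed(self.seed, "simulation")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["simulation"] = self.simulation.to_dict()
        for key in ("scoring", "model"):
            for k, v in doc[key].items():
                if isinstance(v, tuple):
                    doc[key][k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            simulation=SimulationConfig.from_dict(doc.get("simulation", {})),
            qc=QCConfig(**doc.get("qc", {})),
            scoring=ScoringConfig(**{k: tuple(v) if k == "fractions" else v
                                     for k, v in doc.get("scoring", {}).items()}),
            model=ModelConfig(**{k: tuple(v) if k == "alpha_grid" else v
                                 for k, v in doc.get("model", {}).items()}),
            evaluation=EvalConfig(**doc.get("evaluation", {})),
            seed=doc.get("seed", 0),
        )


@dataclass
class EvaluationReport:
    """Final numbers of one pipeline run."""

    r2_test_mps: float
    r2_test_single: float
    delta_r2: float
    p_value: float
    n_perm: int
    mean_cv_r2_mps: float
    mean_cv_r2_single: float
    best_single: str
    best_single_fraction: float
    alpha: float
    lam: float
    n_retained: int
    retained: list[str]
    decile: evaluation.DecileReport
    n_train: int
    n_test: int
    seed: int
    qc_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r2_test_mps": self.r2_test_mps,
            "r2_test_single": self.r2_test_single,
            "delta_r2": self.delta_r2,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "mean_cv_r2_mps": self.mean_cv_r2_mps,
            "mean_cv_r2_single": self.mean_cv_r2_single,
            "best_single": self.best_single,
            "best_single_fraction": self.best_single_fraction,
            "alpha": self.alpha,
            "lambda": self.lam,
            "n_retained": self.n_retained,
            "retained": self.retained,
            "cohens_d": self.decile.d,
            "d_ci": list(self.decile.d_ci),
            "u3": self.decile.u3,
            "common_language": self.decile.cl,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def build_scores(
    panel: GenotypePanel,
    harmonized: dict[str, ss.HarmonizedSumStats],
    gwas_n: dict[str, int],
    h2: dict[str, float],
    fractions=models.DEFAULT_FRACTIONS,
    window_size: int = 50,
    n_pcs: int = 5,
    gibbs_iters: int = 500,
    gibbs_burn_in: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized, PC-adjusted polygenic scores for every (GWAS, fraction).

    Returns a DataFrame indexed by sample id with one column per GWAS and
    causal fraction, named ``{gwas}|p={fraction}``.  The p = 1 variant uses
    the closed-form infinitesimal shrinkage; sparser priors use the Gibbs
    sampler.  LD is estimated from the target panel itself.
    """
    ld = scoring.estimate_ld(panel, window_size)
    xstd = panel.standardized()
    pcs = scoring.compute_pcs(xstd, n_pcs) if n_pcs > 0 else None
    cols: dict[str, np.ndarray] = {}
    for name, harm in harmonized.items():
        beta = harm.weights_for_panel(panel)
        for p in fractions:
            if p >= 1.0:
                shrunk = scoring.shrink_infinitesimal(beta, ld, gwas_n[name], h2[name])
            else:
                shrunk = scoring.shrink_gibbs(
                    beta, ld, gwas_n[name], h2[name], fraction_p=p,
                    iters=gibbs_iters, burn_in=gibbs_burn_in,
                    seed=stage_seed(seed, f"gibbs:{name}:{p}"),
                )
            raw = scoring.compute_scores(xstd, shrunk.weights)
            cols[f"{name}|p={p:g}"] = raw
    raw_mat = np.column_stack(list(cols.values()))
    adjusted = scoring.adjust_scores(raw_mat, pcs)
    return pd.DataFrame(adjusted, index=panel.sample_ids, columns=list(cols))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> EvaluationReport:
    """Execute the full analysis on a simulated study and evaluate it.

    Stages: simulate -> harmonize each GWAS against the panel -> construct
    scores (per GWAS x causal fraction) -> 60/40 split -> select each GWAS's
    best fraction and the best single-score model by repeated cross-validated
    R^2 on the training set -> tune the elastic-net multi-score model ->
    evaluate both on the test set with a permutation comparison and decile
    stratification.  Writes all artifacts when ``out_dir`` is given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim = config.simulation
    ld, panel, effects, sumstat_tables, phenotypes = simulate_all(sim)
    gwas_names = [f"gwas{t}" for t in range(sim.n_traits)]

    harmonized: dict[str, ss.HarmonizedSumStats] = {}
    qc_counts: dict[str, dict[str, int]] = {}
    for name, tab in zip(gwas_names, sumstat_tables):
        harm = ss.harmonize(tab, panel, maf_min=config.qc.maf_min,
                            info_min=config.qc.info_min,
                            drop_ambiguous=config.qc.drop_ambiguous)
        harmonized[name] = harm
        qc_counts[name] = ss.qc_report(harm)

    window = config.scoring.window_size or max(sim.n_snps // sim.n_blocks, 1)
    h2_map = {name: (config.scoring.h2 if config.scoring.h2 is not None else float(sim.h2[t]))
              for t, name in enumerate(gwas_names)}
    n_map = {name: int(sim.gwas_n[t]) for t, name in enumerate(gwas_names)}
    scores = build_scores(
        panel, harmonized, n_map, h2_map,
        fractions=config.scoring.fractions, window_size=window,
        n_pcs=config.scoring.n_pcs, gibbs_iters=config.scoring.gibbs_iters,
        gibbs_burn_in=config.scoring.gibbs_burn_in,
        seed=stage_seed(config.seed, "scoring"),
    )

    y = phenotypes["outcome"].to_numpy()
    split = evaluation.train_test_split(
        np.arange(len(y)), fraction=config.evaluation.train_fraction,
        seed=stage_seed(config.seed, "split"),
    )
    ytr = y[split.train]
    plan = models.make_fold_plan(len(split.train), k=config.model.k,
                                 repeats=config.model.repeats,
                                 seed=stage_seed(config.seed, "folds"))

    # single-score models: best fraction per GWAS, then best GWAS
    best_cols: dict[str, str] = {}
    single_results: dict[str, models.SingleScoreResult] = {}
    for name in gwas_names:
        variants = {p: scores[f"{name}|p={p:g}"].to_numpy()[split.train]
                    for p in config.scoring.fractions}
        res = models.select_best_fraction(variants, ytr, plan)
        single_results[name] = res
        best_cols[name] = f"{name}|p={res.chosen_fraction:g}"
    best_single = max(gwas_names, key=lambda g: single_results[g].cv_r2)
    best_res = single_results[best_single]
    single_col = scores[best_cols[best_single]].to_numpy()
    pred_single_test = best_res.predict(single_col[split.test])
    r2_single = evaluation.r2_test(y[split.test], pred_single_test)

    # multi-score elastic net on each GWAS's best fraction variant
    x_cols = [best_cols[name] for name in gwas_names]
    x = scores[x_cols].to_numpy()
    fit = models.enet_tune(x[split.train], ytr, plan,
                           alpha_grid=config.model.alpha_grid,
                           n_lambda=config.model.n_lambda)
    pred_mps_test = fit.predict(x[split.test])
    r2_mps = evaluation.r2_test(y[split.test], pred_mps_test)

    perm = evaluation.permutation_model_comparison(
        y[split.test], pred_mps_test, pred_single_test,
        n_perm=config.evaluation.n_perm, seed=stage_seed(config.seed, "permutation"),
    )
    decile = evaluation.decile_stratify(y[split.test], pred_mps_test,
                                        n_quantiles=config.evaluation.n_quantiles)

    retained = [x_cols[j] for j in fit.retained]
    report = EvaluationReport(
        r2_test_mps=float(r2_mps), r2_test_single=float(r2_single),
        delta_r2=float(r2_mps - r2_single), p_value=perm.p_value, n_perm=perm.n_perm,
        mean_cv_r2_mps=float(fit.cv_r2_mean), mean_cv_r2_single=float(best_res.cv_r2),
        best_single=best_single, best_single_fraction=best_res.chosen_fraction,
        alpha=fit.alpha, lam=fit.lam, n_retained=len(retained), retained=retained,
        decile=decile, n_train=len(split.train), n_test=len(split.test),
        seed=config.seed, qc_counts=qc_counts,
    )

    if out is not None:
        _write_artifacts(out, config, panel, sumstat_tables, gwas_names, phenotypes,
                         qc_counts, scores, fit, x_cols, report)
    return report


def _write_artifacts(out, config, panel, sumstat_tables, gwas_names, phenotypes,
                     qc_counts, scores, fit, x_cols, report) -> None:
    config.to_yaml(out / "config.yaml")
    write_manifest(config.simulation, out / "manifest.yaml",
                   extra={"global_seed": config.seed})
    write_vcf(panel, out / "genotypes.vcf")
    write_phenotypes(phenotypes, out / "phenotypes.tsv")
    for name, tab in zip(gwas_names, sumstat_tables):
        write_sumstats(tab, out / f"sumstats_{name}.tsv")
    pd.DataFrame(qc_counts).T.to_csv(out / "qc_report.tsv", sep="\t")
    scores.round(10).to_csv(out / "scores.tsv", sep="\t", index_label="iid")
    with open(out / "model.txt", "w") as fh:
        fh.write(f"alpha\t{fit.alpha}\nlambda\t{fit.lam}\nintercept\t{float(fit.intercept)!r}\n")
        for name, c in zip(x_cols, fit.coef):
            fh.write(f"coef\t{name}\t{float(c)!r}\n")
    report.decile.table.to_csv(out / "deciles.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_file(path: str | Path) -> models.ElasticNetFit:
    """Re-load an exported model; predictions on the same score table are
    bit-identical because coefficients are written with full repr precision."""
    alpha = lam = intercept = None
    names, coefs = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "alpha":
                alpha = float(parts[1])
            elif parts[0] == "lambda":
                lam = float(parts[1])
            elif parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "coef":
                names.append(parts[1])
                coefs.append(float(parts[2]))
    fit = models.ElasticNetFit(alpha=alpha, lam=lam, coef=np.array(coefs),
                               intercept=intercept)
    fit.predictor_names = names
    return fit
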