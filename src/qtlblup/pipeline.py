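"""Experiment orchestration: replicates, seeding, model fitting, summaries.

``run_experiment`` loops over independent replicates.  Each replicate
simulates a study population, ranks QTL, builds the inclusion scenarios, fits
the requested prediction models, and scores accuracy and dispersion bias in
every test generation.  All randomness flows from a master seed through
``numpy.random.SeedSequence`` spawning, so a rerun with the same
configuration reproduces the results bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blup import GenomicMixedModel
from .grm import vanraden_g, weighted_g
from .mlmodels import MLConfig, fit_predict_rf, fit_predict_svr
from .popsim import SimulationConfig, PopulationSchedule, StudyData, simulate_study
from .scenarios import (
    accuracy,
    assemble_features,
    build_scenario,
    dispersion_bias,
    importance_compare,
    rank_qtl,
)

__all__ = [
    "ExperimentConfig",
    "run_replicate",
    "run_experiment",
    "summarize",
    "plot_accuracy",
    "importance_analysis",
]

FULL_THRESHOLDS = (
    0.0, 0.05, 0.10, 0.15, 0.20, 0.40, 0.60, 0.70,
    0.80, 0.85, 0.90, 0.95, 0.99, 1.0,
)
ALL_MODELS = ("GBLUP", "2GBLUP", "w2GBLUP", "RF", "SVR")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    sim: SimulationConfig = field(default_factory=SimulationConfig.full_scale)
    thresholds: tuple = FULL_THRESHOLDS
    models: tuple = ALL_MODELS
    n_replicates: int = 20
    seed: int = 1
    rf: MLConfig = field(default_factory=MLConfig.default_rf)
    svr: MLConfig = field(default_factory=MLConfig.default_svr)

    @classmethod
    def full_scale(cls, seed: int = 1) -> "ExperimentConfig":
        return cls(seed=seed)

    @classmethod
    def mini_ci(
        cls,
        seed: int = 1,
        n_replicates: int = 2,
        thresholds: tuple = (0.0, 0.8, 1.0),
        models: tuple = ALL_MODELS,
    ) -> "ExperimentConfig":
        """Scaled-down preset: small genome and herd, lighter forest."""
        return cls(
            sim=SimulationConfig.mini_ci(),
            thresholds=thresholds,
            models=models,
            n_replicates=n_replicates,
            seed=seed,
            rf=MLConfig(model="rf", n_estimators=300, max_features=100),
        )

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = json.loads(json.dumps(self.to_dict()))  # tuples -> lists
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d:
            sim = dict(d["sim"])
            if "schedule" in sim:
                sched = dict(sim["schedule"])
                sched["historic_anchors"] = tuple(
                    tuple(a) for a in sched["historic_anchors"]
                )
                sim["schedule"] = PopulationSchedule(**sched)
            for key in ("train_generations", "test_generations"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimulationConfig(**sim)
        for key in ("thresholds", "models"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("rf", "svr"):
            if key in d and isinstance(d[key], dict):
                d[key] = MLConfig(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(replicate,))


def _segregating_cols(X: np.ndarray) -> np.ndarray:
    """Columns still segregating in the genotyped sample.

    Loci are pre-filtered on generation-0 frequencies, but drift and selection
    can fix a locus by the analysis generations; a fixed column carries no
    information and would break the GRM scale.
    """
    p = X.mean(axis=0) / 2.0
    return (p > 0.0) & (p < 1.0)


def _reml_record(res, test_sets, train_pred, y_train):
    """Metric rows per test generation plus fit-level diagnostics."""
    rows = []
    base = dict(
        sigma_g=res.sigma_g2,
        sigma_e=res.sigma_e,
        h2_hat=res.h2,
        converged=res.converged,
        train_corr=float(np.corrcoef(train_pred, y_train)[0, 1]),
    )
    if len(res.model.names) == 2:
        base["sigma_qtl"], base["sigma_snp"] = res.sigma_u
    for g, (pred, tbv) in test_sets.items():
        rows.append(
            dict(generation=g, accuracy=accuracy(pred, tbv),
                 dispersion_bias=dispersion_bias(pred, tbv), **base)
        )
    return rows


def run_replicate(cfg: ExperimentConfig, replicate: int) -> pd.DataFrame:
    """Simulate one replicate and evaluate every model x scenario x generation."""
    ss = _replicate_seed(cfg.seed, replicate)
    sim_ss, ml_ss = ss.spawn(2)
    study = simulate_study(cfg.sim, sim_ss)
    ml_seed = int(ml_ss.generate_state(1)[0] % (2**31))
    ds = study.datasets
    test_gens = sorted(ds.tests)
    X_all = np.concatenate([ds.train.X] + [ds.tests[g].X for g in test_gens])
    n_train = ds.train.n
    train_idx = np.arange(n_train)
    slices, start = {}, n_train
    for g in test_gens:
        slices[g] = slice(start, start + ds.tests[g].n)
        start += ds.tests[g].n
    y = ds.train.y
    ranking = rank_qtl(study.arch, study.p0)
    records = []

    def add(rows, scenario, model):
        for r in rows:
            r.update(replicate=replicate, scenario=scenario.label,
                     threshold=scenario.threshold, n_qtl=scenario.n_qtl, model=model)
        records.extend(rows)

    for threshold in cfg.thresholds:
        scenario = build_scenario(ranking, threshold)
        pooled = assemble_features(X_all, study.seg_snp, scenario, "pooled").pooled
        pooled = pooled[:, _segregating_cols(pooled)]
        # QTL still segregating in the genotyped sample; an empty set reduces
        # the two-component models to plain GBLUP
        fs_all = assemble_features(X_all, study.seg_snp, scenario, "split-weighted")
        qtl_keep = (
            _segregating_cols(fs_all.qtl) if scenario.n_qtl else np.zeros(0, bool)
        )
        n_qtl_eff = int(qtl_keep.sum())
        needs_gblup = "GBLUP" in cfg.models or (
            n_qtl_eff == 0 and {"2GBLUP", "w2GBLUP"} & set(cfg.models)
        )
        gblup_rows = None
        if needs_gblup:
            G = vanraden_g(pooled)
            res = GenomicMixedModel(y, {"genomic": G}, train_idx).fit()
            pred = res.gebv
            tests = {g: (pred[slices[g]], ds.tests[g].tbv) for g in test_gens}
            gblup_rows = _reml_record(res, tests, pred[train_idx], y)
        if "GBLUP" in cfg.models:
            add([dict(r) for r in gblup_rows], scenario, "GBLUP")
        for model in ("2GBLUP", "w2GBLUP"):
            if model not in cfg.models:
                continue
            if n_qtl_eff == 0:
                # no QTL component: the two-component model reduces to GBLUP
                add([dict(r) for r in gblup_rows], scenario, model)
                continue
            Xq = fs_all.qtl[:, qtl_keep]
            if model == "w2GBLUP":
                G1 = weighted_g(Xq, fs_all.qtl_weights[qtl_keep])
            else:
                G1 = vanraden_g(Xq)
            snp_X = fs_all.snp[:, _segregating_cols(fs_all.snp)]
            G2 = vanraden_g(snp_X)
            res = GenomicMixedModel(y, {"qtl": G1, "snp": G2}, train_idx).fit()
            pred = res.gebv
            tests = {g: (pred[slices[g]], ds.tests[g].tbv) for g in test_gens}
            add(_reml_record(res, tests, pred[train_idx], y), scenario, model)
        for model, fitter, mlcfg in (
            ("RF", fit_predict_rf, cfg.rf.with_seed(ml_seed)),
            ("SVR", fit_predict_svr, cfg.svr),
        ):
            if model not in cfg.models:
                continue
            fit = fitter(pooled[train_idx], y, pooled[n_train:], mlcfg)
            rows = []
            for g in test_gens:
                sl = slice(slices[g].start - n_train, slices[g].stop - n_train)
                pred = fit.test_pred[sl]
                rows.append(
                    dict(generation=g, accuracy=accuracy(pred, ds.tests[g].tbv),
                         dispersion_bias=dispersion_bias(pred, ds.tests[g].tbv),
                         train_corr=float(np.corrcoef(fit.train_pred, y)[0, 1]),
                         converged=True)
                )
            add(rows, scenario, model)
    df = pd.DataFrame(records)
    front = ["replicate", "scenario", "threshold", "n_qtl", "model", "generation",
             "accuracy", "dispersion_bias"]
    return df[front + [c for c in df.columns if c not in front]]


def run_experiment(
    cfg: ExperimentConfig, outdir=None, resume: bool = False
) -> pd.DataFrame:
    """Run all replicates; optionally persist per-replicate results + manifest.

    With ``outdir`` set, each replicate is written to its own CSV as soon as
    it finishes; ``resume=True`` skips replicates whose file already exists.
    A failed model/scenario never aborts the experiment silently: errors
    propagate from the replicate, which is the unit of resumption.
    """
    out = None if outdir is None else Path(outdir)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    frames = []
    for rep in range(cfg.n_replicates):
        path = None if out is None else out / f"replicate_{rep:03d}.csv"
        if path is not None and resume and path.exists():
            frames.append(pd.read_csv(path))
            continue
        df = run_replicate(cfg, rep)
        if path is not None:
            df.to_csv(path, index=False)
        frames.append(df)
    results = pd.concat(frames, ignore_index=True)
    if out is not None:
        results.to_csv(out / "results.csv", index=False)
        _write_manifest(cfg, out)
    return results


def _write_manifest(cfg: ExperimentConfig, out: Path) -> None:
    import sklearn

    files = {}
    for f in sorted(out.glob("*.csv")):
        files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = dict(
        config=json.loads(json.dumps(cfg.to_dict(), default=str)),
        config_hash=cfg.config_hash(),
        replicate_seeds=[
            {"replicate": r, "entropy": int(cfg.seed), "spawn_key": [r]}
            for r in range(cfg.n_replicates)
        ],
        versions={
            "qtlblup": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        files=files,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate means and SDs by scenario, model and generation."""
    if len(results) == 0:
        raise ValueError("no results to summarize")
    grouped = (
        results.groupby(["scenario", "threshold", "model", "generation"])
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            bias_mean=("dispersion_bias", "mean"),
            bias_sd=("dispersion_bias", "std"),
            n_replicates=("replicate", "nunique"),
        )
        .reset_index()
        .sort_values(["generation", "threshold", "model"])
        .reset_index(drop=True)
    )
    return grouped


def plot_accuracy(summary: pd.DataFrame, generation: int = 16, ax=None):
    """Accuracy versus QTL-variance threshold, one line per model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    sub = summary[summary["generation"] == generation]
    for model, grp in sub.groupby("model"):
        grp = grp.sort_values("threshold")
        ax.errorbar(
            grp["threshold"] * 100, grp["accuracy_mean"], yerr=grp["accuracy_sd"],
            marker="o", capsize=3, label=model,
        )
    ax.set_xlabel("genetic variance explained by included QTL (%)")
    ax.set_ylabel("accuracy (cor(GEBV, TBV))")
    ax.set_title(f"Prediction accuracy, generation {generation}")
    ax.legend()
    return ax


def importance_analysis(
    study: StudyData, cfg: ExperimentConfig, threshold: float = 1.0
):
    """Feature-importance diagnostic: RF importances and GBLUP backsolved
    variances against the true per-locus variance shares (pooled features)."""
    ds = study.datasets
    ranking = rank_qtl(study.arch, study.p0)
    scenario = build_scenario(ranking, threshold)
    X_train = assemble_features(ds.train.X, study.seg_snp, scenario, "pooled").pooled
    g16 = min(ds.tests)
    X_test = assemble_features(ds.tests[g16].X, study.seg_snp, scenario, "pooled").pooled
    y = ds.train.y
    # truth: SNPs explain nothing, ranked QTL their 2 p q a^2
    true_var = np.concatenate([np.zeros(len(study.seg_snp)), scenario.qtl_variances])
    G = vanraden_g(np.concatenate([X_train, X_test]))
    res = GenomicMixedModel(y, {"genomic": G}, np.arange(len(y))).fit()
    back = res.backsolve("genomic", np.concatenate([X_train, X_test]))
    rf_fit = fit_predict_rf(X_train, y, X_test, cfg.rf)
    return importance_compare(rf_fit.feature_importances, back.variances, true_var)
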