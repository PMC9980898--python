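"""Experiment harness: deterministic splits, shared 5-fold CV, metric
computation, multi-run orchestration and consistency analyses.

The protocol: subjects are sorted by id, the first 15% form a held-out test
set, and the remainder is partitioned into five folds by a seeded
permutation. The same plan is reused verbatim across modalities and models
so results are directly comparable. For each fold, the deep model is
trained ``n_reps`` times from random initializations (best-validation-epoch
checkpointing) and the classical models select their regularization on the
fold's validation split from the 300-value grid. Test metrics are averaged
across folds; gradient maps are averaged across all reps x folds.

Anti-leakage rules enforced here: the proportional-threshold mask, factor
models, covariate z-scoring and regularization selection are computed from
non-test subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import attribution, dlmodel, factors, linear, preprocess
from .synth import Cohort

TASK_KINDS = {"sex": "classification", "age": "regression",
              "g": "regression", "mhq": "regression"}


# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Deterministic test split plus 5-fold partition of the remainder."""

    test_ids: list[str]
    folds: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        train = [i for fold in self.folds for i in fold]
        if set(self.test_ids) & set(train):
            raise ValueError("test and training ids overlap")

    @property
    def train_ids(self) -> list[str]:
        return [i for fold in self.folds for i in fold]

    def fold_split(self, k: int) -> tuple[list[str], list[str]]:
        """(train ids, validation ids) for CV iteration k."""
        val = self.folds[k]
        tr = [i for j, fold in enumerate(self.folds) if j != k for i in fold]
        return tr, val


def make_plan(ids, test_fraction: float = 0.15, n_folds: int = 5,
              seed: int = 0) -> CVPlan:
    """Sort ids ascending; first ``floor(test_fraction * N)`` become the
    test set; the rest are permuted (seeded) into ``n_folds`` folds."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) < 20:
        raise ValueError("need at least 20 subjects")
    ids = sorted(ids)
    n_test = int(np.floor(test_fraction * len(ids)))
    test_ids = ids[:n_test]
    rest = np.array(ids[n_test:], dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(rest))
    folds = [list(chunk) for chunk in np.array_split(rest[perm], n_folds)]
    return CVPlan(test_ids=test_ids, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(kind: str, predictions: np.ndarray, truth: np.ndarray) -> dict:
    """Classification: accuracy (%) at the 0.5 threshold and rank-based
    AUC. Regression: MAE and Pearson correlation of raw predictions."""
    predictions = np.asarray(predictions, float)
    truth = np.asarray(truth, float)
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if kind == "classification":
        if len(np.unique(truth)) < 2:
            raise ValueError("single-class truth: AUC undefined")
        acc = 100.0 * np.mean((predictions > 0.5) == (truth > 0.5))
        return {"accuracy": float(acc),
                "auc": float(roc_auc_score(truth, predictions))}
    mae = float(np.mean(np.abs(predictions - truth)))
    if np.std(predictions) < 1e-12:
        r = 0.0
    else:
        r = float(stats.pearsonr(predictions, truth)[0])
    return {"mae": mae, "r": r}


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    tasks: tuple = ("sex", "age")
    models: tuple = ("brainnetcnn", "ridge")
    modalities: tuple | None = None          # default: all in the cohort
    covariate_tasks: tuple = ()              # tasks also run with covariates
    n_reps: int = 3
    epochs: int = 200
    n_folds: int = 5
    test_fraction: float = 0.15
    n_lambda: int = 300
    seed: int = 0
    e2e_filters: int = 8
    e2n_filters: int = 16
    n2g_units: int = 30
    dropout_rate: float = 0.5
    leaky_slope: float = 0.33
    batch_size: int = 128
    learning_rate: float = 1e-3


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    consistency: dict
    maps: dict = field(default_factory=dict)      # (task, modality, with_cov) -> GradientMap
    betas: dict = field(default_factory=dict)     # (task, modality, model, with_cov) -> (n,n) matrix
    plans: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)    # task -> per-subject target values


# ---------------------------------------------------------------------------
# target construction (leakage-free)
# ---------------------------------------------------------------------------

def _task_targets(cohort: Cohort, task: str, config: ExperimentConfig):
    """Return (ids, y, plan) for one task, fitting any factor model on
    non-test subjects only."""
    pheno = cohort.phenotypes
    if task == "mhq":
        items = pheno[[c for c in pheno.columns if c.startswith("item")]]
        kept = factors.drop_incomplete(items, max_missing=3)
        ids = [cohort.subjects[i] for i in kept.index]
        plan = make_plan(ids, config.test_fraction, config.n_folds, config.seed)
        items_complete = factors.impute_missing(kept.reset_index(drop=True))
        id_pos = {sid: i for i, sid in enumerate(ids)}
        train_rows = [id_pos[s] for s in plan.train_ids]
        model = factors.fit_mhqfactor(items_complete.iloc[train_rows])
        y = factors.score_factor(model, items_complete)
        return ids, np.asarray(y), plan
    ids = list(cohort.subjects)
    plan = make_plan(ids, config.test_fraction, config.n_folds, config.seed)
    if task == "sex":
        return ids, pheno["sex"].to_numpy(float), plan
    if task == "age":
        return ids, pheno["age"].to_numpy(float), plan
    if task == "g":
        tasks_tbl = pheno[[c for c in pheno.columns if c.startswith("task")]]
        tasks_tbl = factors.impute_missing(tasks_tbl)
        id_pos = {sid: i for i, sid in enumerate(ids)}
        train_rows = [id_pos[s] for s in plan.train_ids]
        model = factors.fit_gfactor(tasks_tbl.iloc[train_rows])
        y = factors.score_factor(model, tasks_tbl)
        return ids, np.asarray(y), plan
    raise ValueError(f"unknown task {task!r}")


def _preprocess_modality(stack: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Symmetrize, threshold (mask from training subjects only), normalize."""
    sym = preprocess.symmetrize(stack)
    mask = preprocess.proportional_threshold(sym[train_idx])
    return preprocess.max_normalize(preprocess.apply_mask(sym, mask))


def _zscore_train(values: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    mu = values[train_idx].mean(axis=0)
    sd = values[train_idx].std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (values - mu) / sd


# ---------------------------------------------------------------------------
# model runners
# ---------------------------------------------------------------------------

def _run_classical(model: str, kind: str, Xv, y, cov, plan, id_pos, config):
    """Per-fold lambda selection + fit + test evaluation. Returns
    (per-fold metric dicts, mean beta matrix or None, chosen lambdas)."""
    n_cov = cov.shape[1] if cov is not None else 0
    feats = np.hstack([Xv, cov]) if cov is not None else Xv
    test_idx = np.array([id_pos[s] for s in plan.test_ids])
    grid = linear.lambda_grid(config.n_lambda)
    fold_metrics, fold_betas, lams = [], [], []
    for k in range(len(plan.folds)):
        tr_ids, va_ids = plan.fold_split(k)
        tr = np.array([id_pos[s] for s in tr_ids])
        va = np.array([id_pos[s] for s in va_ids])
        chosen, _ = linear.select_lambda(model, kind, feats, y, [(tr, va)], grid)
        lam = chosen[0]
        lams.append(lam)
        if model == "krr":
            fit = linear.fit_krr(feats[tr], y[tr], lam)
            pred = fit.predict(feats[test_idx])
        else:
            fit = linear._fit_one(model, kind, feats[tr], y[tr], lam)
            pred = fit.predict(feats[test_idx])
            full = np.concatenate([fit.betas, fit.cov_betas]) if n_cov else fit.betas
            fold_betas.append(full[:Xv.shape[1]])
        fold_metrics.append(evaluate(kind, pred, y[test_idx]))
    beta_mat = None
    if fold_betas:
        beta_mat = preprocess.matrix_from_upper(np.mean(fold_betas, axis=0))
    return fold_metrics, beta_mat, lams


def _run_brainnetcnn(kind: str, Xm, y, cov, plan, id_pos, config, task, modality):
    """n_reps x n_folds trainings; per-fold test metrics (mean over reps)
    and the averaged symmetrized gradient map over all models."""
    n_nodes = Xm.shape[1]
    with_cov = cov is not None
    spec = dlmodel.ArchitectureSpec(
        n_nodes=n_nodes, e2e_filters=config.e2e_filters,
        e2n_filters=config.e2n_filters, n2g_units=config.n2g_units,
        leaky_slope=config.leaky_slope, dropout_rate=config.dropout_rate,
        with_covariates=with_cov, n_covariates=cov.shape[1] if with_cov else 0,
        task=kind)
    loss = "cross-entropy" if kind == "classification" else "mean-squared-error"
    test_idx = np.array([id_pos[s] for s in plan.test_ids])
    fold_metrics, maps, fold_map_lists = [], [], []
    for k in range(len(plan.folds)):
        tr_ids, va_ids = plan.fold_split(k)
        tr = np.array([id_pos[s] for s in tr_ids])
        va = np.array([id_pos[s] for s in va_ids])
        if kind == "regression":
            mu, sd = y[tr].mean(), max(y[tr].std(), 1e-12)
        else:
            mu, sd = 0.0, 1.0
        ytr, yva = (y[tr] - mu) / sd, (y[va] - mu) / sd
        rep_metrics, fold_maps = [], []
        for rep in range(config.n_reps):
            run_seed = (config.seed * 9973 + k * 101 + rep) % (2 ** 31)
            net = dlmodel.build_network(spec, seed=run_seed)
            tcfg = dlmodel.TrainingConfig(
                learning_rate=config.learning_rate, batch_size=config.batch_size,
                epochs=config.epochs, loss=loss, seed=run_seed + 1)
            train = (Xm[tr], ytr, cov[tr]) if with_cov else (Xm[tr], ytr)
            val = (Xm[va], yva, cov[va]) if with_cov else (Xm[va], yva)
            dlmodel.train_network(net, train, val, tcfg)
            pred = net.predict(Xm[test_idx], cov[test_idx] if with_cov else None)
            if kind == "regression":
                pred = pred * sd + mu
            rep_metrics.append(evaluate(kind, pred, y[test_idx]))
            raw = attribution.input_gradient(
                net, Xm[test_idx], cov[test_idx] if with_cov else None)
            fold_maps.append(attribution.symmetrize_gradient(raw, task=task,
                                                             modality=modality))
        fold_metrics.append({k2: float(np.mean([m[k2] for m in rep_metrics]))
                             for k2 in rep_metrics[0]})
        maps.extend(fold_maps)
        fold_map_lists.append(attribution.average_maps(fold_maps))
    return fold_metrics, attribution.average_maps(maps), fold_map_lists


def _summarize(fold_metrics: list[dict]) -> dict:
    out = {}
    for key in fold_metrics[0]:
        vals = [m[key] for m in fold_metrics]
        out[key] = float(np.mean(vals))
        out[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[f"{key}_folds"] = ",".join(f"{v:.6g}" for v in vals)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_experiment(cohort: Cohort, config: ExperimentConfig) -> ExperimentResult:
    """Run every requested task x modality x model (with/without covariate
    variants) under one shared split plan per task; compute test metrics,
    attribution maps, beta maps and concordance summaries."""
    modalities = config.modalities or tuple(cohort.modalities)
    rows, maps, betas, plans, scores = [], {}, {}, {}, {}
    fold_maps_store: dict = {}
    pheno = cohort.phenotypes
    covariate_base = np.column_stack([pheno["age"].to_numpy(float),
                                      pheno["sex"].to_numpy(float)])

    for task in config.tasks:
        kind = TASK_KINDS[task]
        ids, y, plan = _task_targets(cohort, task, config)
        plans[task] = plan
        scores[task] = dict(zip(ids, y))
        id_pos = {sid: i for i, sid in enumerate(ids)}
        cohort_idx = [cohort.subjects.index(s) for s in ids]
        train_idx = np.array([id_pos[s] for s in plan.train_ids])
        cov_variants: list[bool] = [False]
        if task in config.covariate_tasks:
            cov_variants.append(True)
        cov_all = _zscore_train(covariate_base[cohort_idx], train_idx)
        for modality in modalities:
            stack = cohort.matrices[modality][cohort_idx]
            Xm = _preprocess_modality(stack, train_idx)
            Xv = preprocess.vectorize_upper(Xm)
            for with_cov in cov_variants:
                cov = cov_all if with_cov else None
                for model in config.models:
                    if model == "krr" and kind == "classification":
                        continue  # dual ridge on labels is not a classifier here
                    if model == "brainnetcnn":
                        fm, gmap, per_fold = _run_brainnetcnn(
                            kind, Xm, y, cov, plan, id_pos, config, task, modality)
                        maps[(task, modality, with_cov)] = gmap
                        fold_maps_store[(task, modality, with_cov)] = per_fold
                    else:
                        fm, beta_mat, lams = _run_classical(
                            model, kind, Xv, y, cov, plan, id_pos, config)
                        if beta_mat is not None:
                            betas[(task, modality, model, with_cov)] = beta_mat
                    row = {"task": task, "modality": modality, "model": model,
                           "with_covariates": with_cov}
                    row.update(_summarize(fm))
                    rows.append(row)

    metrics = pd.DataFrame(rows)
    consistency = _consistency_analyses(maps, betas, fold_maps_store, modalities)
    return ExperimentResult(metrics=metrics, consistency=consistency,
                            maps=maps, betas=betas, plans=plans, scores=scores)


def _pairwise_mean_corr(mats: list, method: str = "spearman") -> float:
    vals = []
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            vals.append(attribution.map_concordance(mats[i], mats[j], method))
    return float(np.mean(vals)) if vals else np.nan


def _consistency_analyses(maps, betas, fold_maps_store, modalities) -> dict:
    """Gradient-vs-beta concordance, top-region overlap, cross-fold
    stability, and the covariate de-confounding comparison."""
    out: dict = {"gradient_beta_spearman": {}, "top10_overlap": {},
                 "cross_fold_map_corr": {}, "covariate_effect": {}}
    for (task, modality, with_cov), gmap in maps.items():
        bkey = (task, modality, "ridge", with_cov)
        if bkey in betas:
            bmat = betas[bkey]
            key = f"{task}/{modality}" + ("/cov" if with_cov else "")
            out["gradient_beta_spearman"][key] = attribution.map_concordance(
                gmap, bmat, "spearman")
            out["top10_overlap"][key] = attribution.top_region_overlap(
                attribution.node_scores(gmap), attribution.node_scores(bmat), k=10)
    for key, per_fold in fold_maps_store.items():
        task, modality, with_cov = key
        name = f"{task}/{modality}" + ("/cov" if with_cov else "")
        out["cross_fold_map_corr"][name] = _pairwise_mean_corr(per_fold)
    for modality in modalities:
        g_plain = maps.get(("g", modality, False))
        g_cov = maps.get(("g", modality, True))
        age_map = maps.get(("age", modality, False))
        if g_plain is not None and g_cov is not None and age_map is not None:
            out["covariate_effect"][modality] = covariate_effect_analysis(
                g_cov, g_plain, age_map)
    return out


def covariate_effect_analysis(maps_with, maps_without, age_map) -> dict:
    """Correlation of the g-prediction gradient map with the age map,
    with and without covariates in the g model. With an age-mediated
    confound planted, the with-covariates correlation should shrink."""
    r_without = attribution.map_concordance(maps_without, age_map, "pearson")
    r_with = attribution.map_concordance(maps_with, age_map, "pearson")
    return {"corr_without_covariates": r_without,
            "corr_with_covariates": r_with,
            "attenuated": bool(abs(r_with) < abs(r_without))}


# ---------------------------------------------------------------------------
# reference benchmark conditions
# ---------------------------------------------------------------------------

def benchmark_cohort(seed: int = 11, n_subjects: int = 400, n_nodes: int = 16):
    """The package's reference synthetic study conditions for the model-
    comparability and attribution-concordance analyses: near-linear sparse
    sex and age edge effects (small log-scale sizes so the multiplicative
    model is well approximated by its linear expansion), a diffuse weak
    g effect, an age-mediated confound on latent g, and no global scale
    confound (that mechanism is exercised separately)."""
    from .synth import generate_cohort, make_truth
    truth = make_truth(n_nodes, seed=0, n_sex_edges=20, sex_size=0.8,
                       n_age_edges=20, age_size=0.15, g_sd=0.04, p_sd=0.0,
                       scale_confound_beta=0.0, age_g_confound=0.6)
    return generate_cohort(n_subjects, n_nodes, truth=truth, seed=seed,
                           task_noise_sd=0.5)


def benchmark_config(seed: int = 0, n_reps: int = 3,
                     epochs: int = 150) -> ExperimentConfig:
    """Experiment settings paired with :func:`benchmark_cohort`."""
    return ExperimentConfig(tasks=("sex", "age", "g"),
                            models=("brainnetcnn", "ridge"),
                            covariate_tasks=("g",), n_reps=n_reps,
                            epochs=epochs, n_lambda=300, seed=seed)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def save_report(result: ExperimentResult, out_dir) -> None:
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return float(obj)
        return obj

    (out / "consistency.json").write_text(json.dumps(_clean(result.consistency),
                                                     indent=2))
    for (task, modality, model, with_cov), bmat in result.betas.items():
        suffix = "_cov" if with_cov else ""
        np.savetxt(out / f"betas_{task}_{modality}_{model}{suffix}.txt", bmat)
        iu = np.triu_indices(bmat.shape[0], k=1)
        pd.DataFrame({
            "edge_id": np.arange(len(iu[0])), "node_i": iu[0],
            "node_j": iu[1], "beta": bmat[iu],
        }).to_csv(out / f"betas_{task}_{modality}_{model}{suffix}.tsv",
                  sep="\t", index=False)
    for (task, modality, with_cov), gmap in result.maps.items():
        suffix = "_cov" if with_cov else ""
        np.savetxt(out / f"gradmap_{task}_{modality}{suffix}.txt", gmap.grads)
        ns = attribution.node_scores(gmap)
        order = np.argsort(ns.importance)[::-1]
        pd.DataFrame({
            "node_id": order,
            "predictive_power": ns.predictive_power[order],
            "importance": ns.importance[order],
            "rank": np.arange(1, len(order) + 1),
        }).to_csv(out / f"nodes_{task}_{modality}{suffix}.tsv", sep="\t", index=False)
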