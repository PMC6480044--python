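"""Cross-validated comparison of the estimator variants.

The harness mirrors the study design: k-fold cross-validation (default 10)
split *by food* (all replicates and augmented copies of a food stay in one
fold), per-nutrient R² and SMAPE pooled over the held-out predictions of all
folds, and — for the proposed variant — selective-prediction metrics over
accepted predictions only, alongside the rejection rate.  Out-of-distribution
foods can be injected into the test folds to measure how much the rejection
mechanism protects the error metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import Calibration, calibrate_tau, predict_with_rejection
from .spectra import Dataset, FoodSample, NUTRIENTS, SpectraError
from .training import TrainConfig, fit
from .architecture import estimate

__all__ = [
    "kfold_indices",
    "r2",
    "smape",
    "UndefinedMetricError",
    "EvaluationReport",
    "evaluate_variants",
    "best_models_smape",
]


class UndefinedMetricError(SpectraError):
    """The metric is undefined for these inputs (e.g. constant truth)."""


def kfold_indices(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into k folds with sizes differing <= 1."""
    if not (2 <= k <= n):
        raise SpectraError(f"need n >= k >= 2, got n={n}, k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def r2(truth, pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (1.0 = perfect fit)."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 2:
        raise SpectraError("r2 expects two equal-length 1-D vectors (n >= 2)")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("r2 undefined for a constant truth vector")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


def smape(truth, pred) -> float:
    """Symmetric mean absolute percentage error as a fraction in [0, 2].

    ``(1/n) * sum 2|p_i - t_i| / (|t_i| + |p_i|)``; terms where both values
    are zero contribute 0 (no error on an exactly-zero pair).
    """
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise SpectraError("smape expects two equal-length 1-D vectors")
    denom = np.abs(t) + np.abs(p)
    num = 2.0 * np.abs(p - t)
    terms = np.where(denom == 0.0, 0.0, num / np.where(denom == 0.0, 1.0, denom))
    return float(np.mean(terms))


@dataclass
class EvaluationReport:
    """Cross-validated results for every variant.

    ``records[variant]`` holds one dict per evaluated food with the truth and
    predicted CPF, the OOD flag and (for the proposed variant) the
    reconstruction MAE and accept/reject verdict — enough to recompute every
    summary and to score reconstruction error as an OOD detector.
    """

    k: int
    seed: int
    contamination: float
    fold_ids: list[list[str]]
    config_echo: dict
    variants: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _pooled_metrics(records: list[dict], accepted_only: bool) -> dict:
    used = [r for r in records if (r["accepted"] if accepted_only else True)]
    out: dict = {"n_total": len(records), "n_used": len(used)}
    per = {}
    for i, nutrient in enumerate(NUTRIENTS):
        if len(used) < 2:
            per[nutrient] = {"r2": None, "smape": None, "flag": "too few predictions"}
            continue
        t = np.array([r["truth"][i] for r in used])
        p = np.array([r["pred"][i] for r in used])
        try:
            r2v = r2(t, p)
        except UndefinedMetricError:
            r2v = None
        per[nutrient] = {"r2": r2v, "smape": smape(t, p)}
    out["per_nutrient"] = per
    return out


def evaluate_variants(dataset: Dataset, configs: dict[str, TrainConfig],
                      k: int = 10, seed: int = 0, contamination: float = 0.0,
                      ood_foods: list[FoodSample] | None = None,
                      tau: float | None = None) -> EvaluationReport:
    """k-fold cross-validated comparison of the requested variants.

    ``configs`` maps variant name -> :class:`TrainConfig`.  When
    ``contamination`` is positive, OOD foods from ``ood_foods`` are added to
    each *test* fold so that they make up that fraction of it; training folds
    are never contaminated.  For the proposed variant the threshold is
    calibrated on the training folds' replicates unless ``tau`` is given.
    """
    if not configs:
        raise SpectraError("no variants requested")
    if not (0.0 <= contamination < 1.0):
        raise SpectraError("contamination must be in [0, 1)")
    if contamination > 0.0 and not ood_foods:
        raise SpectraError("contamination > 0 requires ood_foods")
    for s in dataset.samples:
        if s.composition is None:
            raise SpectraError(f"unlabeled sample {s.sample_id!r} in evaluation set")

    folds = kfold_indices(len(dataset), k, seed)
    ood_rng = np.random.default_rng([seed, 303])
    ood_pool = list(ood_foods or [])

    # pre-assign OOD foods to test folds (test-time contamination only)
    fold_ood: list[list[FoodSample]] = []
    cursor = 0
    for fold in folds:
        n_ood = int(round(contamination / (1.0 - contamination) * len(fold)))
        chosen = []
        for _ in range(n_ood):
            if cursor >= len(ood_pool):
                ood_rng.shuffle(ood_pool)
                cursor = 0
            chosen.append(ood_pool[cursor])
            cursor += 1
        fold_ood.append(chosen)

    report = EvaluationReport(
        k=k, seed=seed, contamination=contamination,
        fold_ids=[[dataset.samples[i].sample_id for i in fold] for fold in folds],
        config_echo={v: asdict(c) for v, c in configs.items()},
    )

    for variant, config in configs.items():
        if config.variant != variant:
            raise SpectraError(
                f"config for {variant!r} has variant={config.variant!r}")
        records: list[dict] = []
        final_losses = []
        for fold_idx, test_idx in enumerate(folds):
            test_set = set(int(i) for i in test_idx)
            train_samples = [s for i, s in enumerate(dataset.samples)
                             if i not in test_set]
            train_ds = Dataset(samples=train_samples, grid=dataset.grid,
                               provenance=dict(dataset.provenance))
            model = fit(train_ds, config)
            if model.train_log:
                final_losses.append(model.train_log[-1]["loss"])

            calib = None
            if variant == "proposed":
                calib = (Calibration.fixed(tau) if tau is not None
                         else calibrate_tau(train_ds))

            test_foods = ([(dataset.samples[i], False) for i in test_idx]
                          + [(f, True) for f in fold_ood[fold_idx]])
            for food, is_ood in test_foods:
                spec = food.mean_spectrum()
                rec = {"sample_id": food.sample_id, "fold": fold_idx,
                       "is_ood": is_ood,
                       "truth": food.composition.as_array().tolist()}
                if variant == "proposed":
                    res = predict_with_rejection(model, spec, calib)
                    rec.update(pred=res.composition.as_array().tolist(),
                               reconstruction_mae=res.reconstruction_mae,
                               tau=res.tau, accepted=res.accepted)
                else:
                    comp = estimate(model, spec)
                    rec.update(pred=comp.as_array().tolist(),
                               reconstruction_mae=None, tau=None, accepted=True)
                records.append(rec)

        summary = _pooled_metrics(records, accepted_only=(variant == "proposed"))
        if variant == "proposed":
            summary["rejection_rate"] = 1.0 - summary["n_used"] / summary["n_total"]
            if summary["n_used"] == 0:
                summary["flag"] = "all predictions rejected; metrics undefined"
        summary["mean_final_train_loss"] = (float(np.mean(final_losses))
                                            if final_losses else None)
        report.variants[variant] = summary
        report.records[variant] = records
    return report


def best_models_smape(reports: list[EvaluationReport], variant: str,
                      top_k: int = 5) -> dict:
    """Average per-nutrient SMAPE over the best restarts.

    ``reports`` are repeated cross-validation runs (different training
    seeds); restarts are ranked by mean final training loss and the pooled
    SMAPEs of the ``top_k`` best are averaged — the "best models" summary.
    """
    scored = []
    for rep in reports:
        v = rep.variants[variant]
        if v["mean_final_train_loss"] is None:
            raise SpectraError("restart has no training loss to rank by")
        scored.append((v["mean_final_train_loss"], v))
    scored.sort(key=lambda t: t[0])
    best = [v for _, v in scored[:top_k]]
    out = {}
    for nutrient in NUTRIENTS:
        vals = [v["per_nutrient"][nutrient]["smape"] for v in best]
        vals = [x for x in vals if x is not None]
        out[nutrient] = float(np.mean(vals)) if vals else None
    out["n_restarts"] = len(reports)
    out["top_k"] = min(top_k, len(scored))
    return out
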