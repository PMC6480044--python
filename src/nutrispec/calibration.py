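"""Bland–Altman calibration of the rejection threshold and selective prediction.

Replicate measurements of the *same* food differ slightly while carrying the
same nutrient content.  The repeatability of a food is summarized as the
average MAE between each replicate region spectrum and the replicates' mean.
Collecting this statistic over many foods, the Bland–Altman limits of
agreement give the largest discrepancy still attributable to measurement
repeatability:

    tau = mean(per-food MAEs) + 1.96 * sd(per-food MAEs)

A prediction is trusted only when the verification network reconstructs the
input to within tau (MAE); otherwise the estimate is flagged as rejected —
the input is taken to lie outside the family of signals the system was
trained on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .architecture import ModelState, estimate, reconstruct
from .spectra import (
    Dataset,
    FoodSample,
    NutrientComposition,
    SpectraError,
    Spectrum,
    mae,
    mean_spectrum,
)

__all__ = [
    "Calibration",
    "PredictionResult",
    "replicate_repeatability",
    "calibrate_tau",
    "predict_with_rejection",
]

#: Bland–Altman coverage factor for 95% limits of agreement.
BA_FACTOR = 1.96


@dataclass
class Calibration:
    """Per-food repeatability MAEs and the derived rejection threshold."""

    per_food_avg_maes: list[float]
    mean_mae: float
    sd_mae: float
    tau: float
    n_foods: int
    n_replicates: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            return cls(**json.load(fh))

    @classmethod
    def fixed(cls, tau: float) -> "Calibration":
        """A degenerate calibration pinning tau directly (diagnostics only)."""
        return cls(per_food_avg_maes=[], mean_mae=float(tau), sd_mae=0.0,
                   tau=float(tau), n_foods=0, n_replicates=0)


@dataclass
class PredictionResult:
    """A CPF estimate plus its trust verdict."""

    composition: NutrientComposition
    reconstruction_mae: float
    tau: float
    accepted: bool


def replicate_repeatability(food: FoodSample) -> float:
    """Average MAE between each replicate and the replicate mean.

    Requires at least 2 region spectra; identical replicates give 0.
    """
    if food.n_regions < 2:
        raise SpectraError(
            f"sample {food.sample_id!r}: repeatability needs >= 2 replicates")
    center = mean_spectrum(food.region_spectra)
    return float(np.mean([mae(r, center) for r in food.region_spectra]))


def calibrate_tau(dataset: Dataset) -> Calibration:
    """Bland–Altman threshold from per-food replicate repeatability.

    ``tau = mean + 1.96 * sd`` over the per-food average MAEs, with the
    sample (n-1) standard deviation.  Requires >= 2 foods, each with >= 2
    replicates.
    """
    if len(dataset) < 2:
        raise SpectraError("calibration needs at least 2 foods")
    per_food = [replicate_repeatability(s) for s in dataset.samples]
    mean = float(np.mean(per_food))
    sd = float(np.std(per_food, ddof=1))
    return Calibration(
        per_food_avg_maes=[float(v) for v in per_food],
        mean_mae=mean, sd_mae=sd, tau=mean + BA_FACTOR * sd,
        n_foods=len(per_food),
        n_replicates=min(s.n_regions for s in dataset.samples),
    )


def predict_with_rejection(model: ModelState, spectrum: Spectrum,
                           calibration: Calibration) -> PredictionResult:
    """Estimate CPF and accept iff the VN reconstruction MAE is <= tau.

    A rejected result still carries the (untrusted) composition so a caller
    can inspect what would have been reported.  Equality accepts: only a
    reconstruction error *larger* than tau triggers rejection.
    """
    comp = estimate(model, spectrum)
    recon = reconstruct(model, spectrum)
    err = mae(spectrum, recon)
    return PredictionResult(
        composition=comp, reconstruction_mae=err, tau=float(calibration.tau),
        accepted=bool(err <= calibration.tau),
    )
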