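"""Forward simulator of food hyperspectral spectra from CPF composition.

The simulator encodes the physical premise behind spectral nutrient
estimation: macronutrients leave characteristic absorption features in the
short-wave IR (sugar-related features sit below ~1100 nm), so a food's
spectrum is modelled as a composition-weighted mixture of three nutrient
basis spectra on top of a smooth category-specific baseline, measured with
per-region additive noise and multiplicative gain jitter:

    region_r = gain_r * (sum_n f_n * B_n + baseline_cat) + eps_r,   clipped at 0

with ``gain_r ~ N(1, scatter_sigma)`` and ``eps_r ~ N(0, replicate_sigma)``
i.i.d. per band.  Each basis ``B_n`` is a sum of Gaussian peaks.  The module
also produces out-of-distribution (OOD) foods — spectra from a perturbed
model — for exercising the error-avoidance scheme, and noise augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra import (
    Dataset,
    FoodSample,
    NutrientComposition,
    NUTRIENTS,
    SpectraError,
    Spectrum,
    default_grid,
)

__all__ = [
    "ForwardModel",
    "build_forward_model",
    "noiseless_mixture",
    "simulate_food",
    "simulate_dataset",
    "simulate_ood_food",
    "sample_composition",
    "augment",
    "DEFAULT_CATEGORIES",
]

DEFAULT_CATEGORIES = ("drink", "sauce", "snack", "meat", "misc")

#: Per-gram basis scale: mean basis intensity contributed per gram of nutrient.
_BASIS_SCALE = 0.4
#: Baseline magnitude range (intensity units).
_BASELINE_LO, _BASELINE_HI = 5.0, 20.0


def _gaussian_peaks(grid: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sum of Gaussian peaks; ``peaks`` rows are (center_nm, width_nm, amplitude)."""
    out = np.zeros_like(grid)
    for center, width, amp in peaks:
        out += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


@dataclass
class ForwardModel:
    """Generative model mapping (composition, category) -> region spectra.

    ``nutrient_peaks[n]`` is an array of (center, width, amplitude) rows for
    nutrient ``n`` (order: carbohydrate, protein, fat); ``baseline_coeffs``
    holds per-category quadratic coefficients evaluated on a unit-scaled
    wavelength axis.
    """

    grid: np.ndarray
    nutrient_peaks: dict[str, np.ndarray]
    baseline_coeffs: dict[str, np.ndarray]
    replicate_sigma: float = 1.0
    scatter_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for n in NUTRIENTS:
            if n not in self.nutrient_peaks:
                raise SpectraError(f"missing basis peaks for nutrient {n!r}")
        carb = np.asarray(self.nutrient_peaks["carbohydrate"])
        if not np.any((carb[:, 0] >= 887.0) & (carb[:, 0] <= 1100.0)):
            raise SpectraError(
                "carbohydrate basis must place a peak inside 887-1100 nm")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.baseline_coeffs)

    def basis(self, nutrient: str) -> np.ndarray:
        """Per-gram basis spectrum of one nutrient on the grid."""
        return _gaussian_peaks(self.grid, np.asarray(self.nutrient_peaks[nutrient]))

    def baseline(self, category: str) -> np.ndarray:
        """Smooth non-negative baseline spectrum of one category."""
        c = np.asarray(self.baseline_coeffs[category], dtype=float)
        u = (self.grid - self.grid[0]) / (self.grid[-1] - self.grid[0])
        return np.clip(c[0] + c[1] * u + c[2] * u ** 2, 0.0, None)

    def config(self) -> dict:
        """JSON-serializable record of the full model configuration."""
        d = asdict(self)
        d["grid"] = self.grid.tolist()
        d["nutrient_peaks"] = {k: np.asarray(v).tolist()
                               for k, v in self.nutrient_peaks.items()}
        d["baseline_coeffs"] = {k: np.asarray(v).tolist()
                                for k, v in self.baseline_coeffs.items()}
        return d


def build_forward_model(config: dict | None = None, seed: int = 0) -> ForwardModel:
    """Build a forward model, randomizing peaks deterministically under ``seed``.

    ``config`` may override ``n_bands``, ``wl_min``, ``wl_max``,
    ``categories``, ``n_peaks``, ``replicate_sigma`` and ``scatter_sigma``,
    or supply explicit ``nutrient_peaks`` / ``baseline_coeffs``.
    """
    cfg = dict(config or {})
    rng = np.random.default_rng(seed)
    grid = default_grid(cfg.get("n_bands", 256),
                        cfg.get("wl_min", 887.0), cfg.get("wl_max", 1722.0))
    categories = tuple(cfg.get("categories", DEFAULT_CATEGORIES))
    n_peaks = int(cfg.get("n_peaks", 4))

    if "nutrient_peaks" in cfg:
        peaks = {k: np.asarray(v, dtype=float) for k, v in cfg["nutrient_peaks"].items()}
    else:
        peaks = {}
        for i, nutrient in enumerate(NUTRIENTS):
            centers = rng.uniform(grid[0], grid[-1], size=n_peaks)
            if nutrient == "carbohydrate":
                # sugar-related features sit in the low-wavelength end
                centers[0] = rng.uniform(max(887.0, grid[0]), min(1100.0, grid[-1]))
            widths = rng.uniform(20.0, 80.0, size=n_peaks)
            amps = rng.uniform(0.5, 1.5, size=n_peaks)
            p = np.column_stack([centers, widths, amps])
            # comparable per-gram contribution across nutrients
            mean_now = _gaussian_peaks(grid, p).mean()
            p[:, 2] *= _BASIS_SCALE / mean_now
            peaks[nutrient] = p

    if "baseline_coeffs" in cfg:
        baselines = {k: np.asarray(v, dtype=float)
                     for k, v in cfg["baseline_coeffs"].items()}
    else:
        baselines = {}
        for cat in categories:
            c0 = rng.uniform(_BASELINE_LO, _BASELINE_HI)
            c1 = rng.uniform(-0.3, 0.3) * c0
            c2 = rng.uniform(-0.3, 0.3) * c0
            baselines[cat] = np.array([c0, c1, c2])

    return ForwardModel(
        grid=grid,
        nutrient_peaks=peaks,
        baseline_coeffs=baselines,
        replicate_sigma=float(cfg.get("replicate_sigma", 1.0)),
        scatter_sigma=float(cfg.get("scatter_sigma", 0.01)),
        seed=int(seed),
    )


def noiseless_mixture(model: ForwardModel, composition: NutrientComposition,
                      category: str) -> Spectrum:
    """The noise-free spectrum for a composition/category pair."""
    mix = model.baseline(category).copy()
    for nutrient, grams in zip(NUTRIENTS, composition.as_array()):
        mix += grams * model.basis(nutrient)
    return Spectrum(model.grid, np.clip(mix, 0.0, None))


def simulate_food(model: ForwardModel, composition: NutrientComposition,
                  category: str, n_regions: int = 5,
                  rng: np.random.Generator | None = None,
                  sample_id: str = "food") -> FoodSample:
    """Simulate one food: ``n_regions`` noisy replicate spectra."""
    if n_regions < 1:
        raise SpectraError("n_regions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    clean = noiseless_mixture(model, composition, category).intensities
    regions = []
    for _ in range(n_regions):
        gain = rng.normal(1.0, model.scatter_sigma) if model.scatter_sigma > 0 else 1.0
        eps = (rng.normal(0.0, model.replicate_sigma, size=clean.size)
               if model.replicate_sigma > 0 else 0.0)
        regions.append(Spectrum(model.grid, np.clip(gain * clean + eps, 0.0, None)))
    return FoodSample(sample_id, category, regions, composition)


def sample_composition(rng: np.random.Generator,
                       total_range: tuple[float, float] = (30.0, 90.0),
                       alpha: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       ) -> NutrientComposition:
    """Draw a CPF triple: Dirichlet fractions scaled to a random total <= 100 g."""
    total = rng.uniform(*total_range)
    frac = rng.dirichlet(alpha)
    return NutrientComposition.from_array(np.minimum(total, 100.0) * frac)


def simulate_dataset(model: ForwardModel, n_foods: int, n_regions: int = 5,
                     composition_sampler=None, seed: int = 0) -> Dataset:
    """Simulate a labeled dataset of ``n_foods`` foods, reproducible under seed."""
    if n_foods < 1:
        raise SpectraError("n_foods must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = composition_sampler or sample_composition
    cats = model.categories
    samples = []
    for i in range(n_foods):
        comp = sampler(rng)
        cat = cats[rng.integers(len(cats))]
        samples.append(simulate_food(model, comp, cat, n_regions, rng=rng,
                                     sample_id=f"food_{i:04d}"))
    return Dataset(samples=samples, grid=model.grid,
                   provenance={"generator": "nutrispec.simulate", "seed": seed,
                               "n_foods": n_foods, "n_regions": n_regions})


def _perturbed_mixture(model: ForwardModel, severity: float,
                       composition: NutrientComposition, category: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Noiseless OOD mixture: peaks shifted and a novel baseline term added,
    both scaled by severity.  Built directly (the perturbed bases need not
    satisfy the in-distribution invariants, e.g. the carbohydrate peak may
    leave the sugar window)."""
    mix = model.baseline(category).copy()
    for nutrient, grams in zip(NUTRIENTS, composition.as_array()):
        p = np.asarray(model.nutrient_peaks[nutrient], dtype=float).copy()
        shift = rng.choice([-1.0, 1.0], size=p.shape[0]) * rng.uniform(
            100.0, 200.0, size=p.shape[0])
        p[:, 0] = p[:, 0] + severity * shift
        mix += grams * _gaussian_peaks(model.grid, p)
    # a novel smooth structure absent from every training category
    u = (model.grid - model.grid[0]) / (model.grid[-1] - model.grid[0])
    novel = severity * (
        rng.uniform(5.0, 12.0) * np.sin(np.pi * u * rng.uniform(1.5, 3.0)
                                        + rng.uniform(0, np.pi)) ** 2
        + rng.uniform(0.0, 5.0) * u)
    return np.clip(mix, 0.0, None) + novel


def simulate_ood_food(model: ForwardModel, severity: float,
                      rng: np.random.Generator | None = None,
                      n_regions: int = 5, category: str | None = None,
                      sample_id: str = "ood") -> FoodSample:
    """Simulate an out-of-distribution food.

    The spectrum comes from a perturbed forward model: every basis peak is
    shifted by an amount proportional to ``severity`` (in (0, 1]) and a novel
    smooth baseline term of magnitude proportional to ``severity`` is added.
    At severity -> 0 the food converges to the in-distribution family.  The
    label is still the composition used to generate it, so an estimator that
    does not abstain is scored against it.
    """
    if not (0.0 < severity <= 1.0):
        raise SpectraError("severity must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    comp = sample_composition(rng)
    cat = category or model.categories[rng.integers(len(model.categories))]
    clean = _perturbed_mixture(model, severity, comp, cat, rng)
    regions = []
    for _ in range(n_regions):
        gain = rng.normal(1.0, model.scatter_sigma) if model.scatter_sigma > 0 else 1.0
        eps = (rng.normal(0.0, model.replicate_sigma, size=clean.size)
               if model.replicate_sigma > 0 else 0.0)
        regions.append(Spectrum(model.grid, np.clip(gain * clean + eps, 0.0, None)))
    return FoodSample(sample_id, cat, regions, comp)


def augment(dataset: Dataset, copies_per_spectrum: int, noise_sigma: float,
            seed: int = 0) -> Dataset:
    """Append noisy clones of every region spectrum (same labels).

    This is the anti-overfitting augmentation used at training time: each
    measured spectrum spawns ``copies_per_spectrum`` near-duplicates with
    small additive Gaussian noise.  ``copies_per_spectrum = 0`` returns an
    equivalent dataset unchanged.
    """
    if copies_per_spectrum < 0:
        raise SpectraError("copies_per_spectrum must be >= 0")
    if copies_per_spectrum == 0:
        return dataset
    rng = np.random.default_rng(seed)
    samples = []
    for s in dataset.samples:
        regions = list(s.region_spectra)
        for spec in s.region_spectra:
            for _ in range(copies_per_spectrum):
                noisy = spec.intensities + (
                    rng.normal(0.0, noise_sigma, size=spec.n_bands)
                    if noise_sigma > 0 else 0.0)
                regions.append(Spectrum(spec.wavelengths, np.clip(noisy, 0.0, None)))
        samples.append(FoodSample(s.sample_id, s.category, regions, s.composition))
    prov = dict(dataset.provenance)
    prov["augmented"] = {"copies": copies_per_spectrum, "noise_sigma": noise_sigma,
                         "seed": seed}
    return Dataset(samples=samples, grid=dataset.grid, provenance=prov)
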