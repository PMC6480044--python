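"""Core domain types for hyperspectral food measurements.

A measurement session yields, per food, several replicate *region spectra*
(intensity versus wavelength over a shared short-wave-infrared grid) plus an
optional ground-truth macronutrient composition taken from the nutrition
label.  All downstream stages — simulation, training, calibration and
evaluation — operate on the types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraError",
    "GridMismatchError",
    "ParseError",
    "Spectrum",
    "NutrientComposition",
    "FoodSample",
    "Dataset",
    "mean_spectrum",
    "mae",
    "read_dataset",
    "write_dataset",
]

#: Default sensor span in nanometres (short-wave IR).
DEFAULT_WL_MIN = 887.0
DEFAULT_WL_MAX = 1722.0
#: Default number of equally spaced wavelength bands.
DEFAULT_N_BANDS = 256

_GRID_ATOL = 1e-6


class SpectraError(ValueError):
    """Invalid spectral input."""


class GridMismatchError(SpectraError):
    """Spectra do not share a common wavelength grid."""


class ParseError(SpectraError):
    """Malformed spectral CSV."""


def default_grid(n_bands: int = DEFAULT_N_BANDS,
                 wl_min: float = DEFAULT_WL_MIN,
                 wl_max: float = DEFAULT_WL_MAX) -> np.ndarray:
    """Equally spaced wavelength grid over the sensor span (nm)."""
    if n_bands < 2:
        raise SpectraError("a wavelength grid needs at least 2 bands")
    return np.linspace(wl_min, wl_max, n_bands)


@dataclass(frozen=True)
class Spectrum:
    """One intensity trace over a wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing band positions in nm, length >= 2.
    intensities
        Non-negative reflectance intensities, same length.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1:
            raise SpectraError("wavelengths and intensities must be 1-D")
        if wl.size != it.size:
            raise SpectraError(
                f"length mismatch: {wl.size} wavelengths vs {it.size} intensities")
        if wl.size < 2:
            raise SpectraError("a spectrum needs at least 2 bands")
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if np.any(it < 0) or not np.all(np.isfinite(it)):
            raise SpectraError("intensities must be finite and non-negative")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def same_grid(self, other: "Spectrum") -> bool:
        return (self.n_bands == other.n_bands and
                np.allclose(self.wavelengths, other.wavelengths,
                            rtol=0.0, atol=_GRID_ATOL))


@dataclass(frozen=True)
class NutrientComposition:
    """Macronutrient content in grams per 100 g of food.

    The three values are non-negative and together cannot exceed 100 g
    (the remainder being water, fibre, ash, ...).
    """

    carbohydrate: float
    protein: float
    fat: float

    def __post_init__(self) -> None:
        vals = (self.carbohydrate, self.protein, self.fat)
        if any((not np.isfinite(v)) or v < 0 for v in vals):
            raise SpectraError("nutrient values must be finite and >= 0")
        if sum(vals) > 100.0 + 1e-9:
            raise SpectraError(
                f"carbohydrate+protein+fat = {sum(vals):.4f} exceeds 100 g/100 g")

    def as_array(self) -> np.ndarray:
        return np.array([self.carbohydrate, self.protein, self.fat], dtype=float)

    @staticmethod
    def from_array(values: Sequence[float]) -> "NutrientComposition":
        c, p, f = (float(v) for v in values)
        return NutrientComposition(c, p, f)


#: Order of the nutrient axes everywhere in the package.
NUTRIENTS = ("carbohydrate", "protein", "fat")


@dataclass
class FoodSample:
    """Replicate region spectra of one food plus optional ground truth."""

    sample_id: str
    category: str
    region_spectra: list[Spectrum]
    composition: NutrientComposition | None = None

    def __post_init__(self) -> None:
        if not self.region_spectra:
            raise SpectraError(f"sample {self.sample_id!r} has no region spectra")
        first = self.region_spectra[0]
        for s in self.region_spectra[1:]:
            if not first.same_grid(s):
                raise GridMismatchError(
                    f"sample {self.sample_id!r}: region spectra on different grids")

    @property
    def n_regions(self) -> int:
        return len(self.region_spectra)

    def mean_spectrum(self) -> Spectrum:
        return mean_spectrum(self.region_spectra)


@dataclass
class Dataset:
    """A collection of food samples on one shared wavelength grid."""

    samples: list[FoodSample]
    grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise SpectraError("dataset must contain at least one sample")
        self.grid = np.asarray(self.grid, dtype=float)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectraError(f"duplicate sample ids: {dup}")
        ref = Spectrum(self.grid, np.zeros_like(self.grid))
        for s in self.samples:
            if not s.region_spectra[0].same_grid(ref):
                raise GridMismatchError(
                    f"sample {s.sample_id!r} not on the dataset grid")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_bands(self) -> int:
        return int(self.grid.size)


def mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a common grid.

    Region averaging is how a stable per-food signal is produced from
    unstable pointwise measurements: several regions of the food surface are
    measured and their spectra averaged.
    """
    spectra = list(spectra)
    if not spectra:
        raise SpectraError("mean_spectrum of an empty list")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError("mean_spectrum over mismatched grids")
    stack = np.stack([s.intensities for s in spectra])
    return Spectrum(first.wavelengths, stack.mean(axis=0))


def mae(a: Spectrum, b: Spectrum) -> float:
    """Mean absolute error between two spectra on a common grid.

    This is the repeatability statistic and the rejection statistic of the
    error-avoidance scheme: the difference between two signals is quantified
    as ``(1/n) * sum |a_i - b_i|``.
    """
    if not a.same_grid(b):
        raise GridMismatchError("mae over mismatched grids")
    return float(np.mean(np.abs(a.intensities - b.intensities)))


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: header  sample_id,category,region_id,carb_g,protein_g,fat_g,wl_*
# with one row per measured region and band columns in strictly increasing
# wavelength order.  Empty CPF cells mark unlabeled samples.

_WL_RE = re.compile(r"^wl_(\d+(?:\.\d+)?)$")
_META_COLS = ["sample_id", "category", "region_id", "carb_g", "protein_g", "fat_g"]


def _wl_columns(grid: np.ndarray) -> list[str]:
    return [f"wl_{w:.6f}" for w in grid]


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as spectral CSV (one row per region)."""
    cols = _wl_columns(dataset.grid)
    rows = []
    for s in dataset.samples:
        comp = s.composition
        for ridx, spec in enumerate(s.region_spectra):
            row = {
                "sample_id": s.sample_id,
                "category": s.category,
                "region_id": ridx,
                "carb_g": comp.carbohydrate if comp else np.nan,
                "protein_g": comp.protein if comp else np.nan,
                "fat_g": comp.fat if comp else np.nan,
            }
            row.update(dict(zip(cols, spec.intensities)))
            rows.append(row)
    frame = pd.DataFrame(rows, columns=_META_COLS + cols)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path) -> Dataset:
    """Read a spectral CSV into a :class:`Dataset`.

    Raises :class:`ParseError` on missing columns, non-monotone band
    headers or negative intensities, naming the offending row/column.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    wl_cols = [c for c in frame.columns if c not in _META_COLS]
    if len(wl_cols) < 2:
        raise ParseError("fewer than 2 wavelength band columns")
    grid = []
    for c in wl_cols:
        m = _WL_RE.match(c)
        if not m:
            raise ParseError(f"unrecognized column {c!r}")
        grid.append(float(m.group(1)))
    grid = np.asarray(grid)
    if not np.all(np.diff(grid) > 0):
        bad = wl_cols[int(np.argmin(np.diff(grid)) + 1)]
        raise ParseError(f"band headers not strictly increasing at column {bad!r}")

    intens = frame[wl_cols].to_numpy(dtype=float)
    neg = np.argwhere(intens < 0)
    if neg.size:
        r, c = neg[0]
        raise ParseError(
            f"negative intensity at row {int(r)}, column {wl_cols[int(c)]!r}")

    samples: list[FoodSample] = []
    for sid, group in frame.groupby("sample_id", sort=False):
        cats = group["category"].unique()
        if len(cats) != 1:
            raise ParseError(f"sample {sid!r} spans multiple categories: {list(cats)}")
        cpf = group[["carb_g", "protein_g", "fat_g"]].iloc[0]
        if cpf.isna().all():
            comp = None
        elif cpf.isna().any():
            raise ParseError(f"sample {sid!r} has a partially empty CPF triple")
        else:
            comp = NutrientComposition(float(cpf["carb_g"]),
                                       float(cpf["protein_g"]),
                                       float(cpf["fat_g"]))
        regions = [Spectrum(grid, row) for row in group[wl_cols].to_numpy(dtype=float)]
        samples.append(FoodSample(str(sid), str(cats[0]), regions, comp))
    return Dataset(samples=samples, grid=grid, provenance={"source": str(path)})
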