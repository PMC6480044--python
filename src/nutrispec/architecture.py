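"""Network architecture: sandwich layer sizing and the CN/JL/NSN/VN model.

The estimator is a multi-task autoencoding network:

* **CN** (common network) — an encoder whose layer widths follow the
  *sandwich* schedule: each hidden layer has half the nodes of its
  predecessor, halving from the input band count down to the joint layer.
* **JL** (joint layer) — the 16-node compressed shared representation; 16 is
  the power of two closest to the ~17-node-per-layer reliability
  recommendation for small fully-connected regressors.
* **NSNs** (nutrient-specific networks) — three small regression heads (all
  hidden widths 16) reading the JL, one per macronutrient.
* **VN** (verification network) — a decoder mirroring the CN that
  reconstructs the input spectrum from the JL; its reconstruction error is
  the trust signal used for selective prediction.

The ``dnn`` baseline variant keeps the same total depth but trains three
separate single-task networks with no shared representation and no decoder.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import MLP
from .spectra import NutrientComposition, SpectraError, Spectrum
from . import __version__

__all__ = [
    "sandwich_sizes",
    "ArchitectureSpec",
    "Normalizer",
    "ModelState",
    "build_model",
    "encode",
    "reconstruct",
    "estimate",
    "save_model",
    "load_model",
]

JL_WIDTH_DEFAULT = 16


def sandwich_sizes(input_dim: int, floor: int = JL_WIDTH_DEFAULT) -> list[int]:
    """Layer-width schedule: halve (integer division) until the floor width.

    ``w0 = input_dim``; ``w_{k+1} = max(floor, w_k // 2)``; stops at the
    floor, which becomes the joint-layer width.  Strictly decreasing by
    construction.

    >>> sandwich_sizes(256)
    [256, 128, 64, 32, 16]
    """
    if floor < 1:
        raise SpectraError("floor must be >= 1")
    if input_dim < floor:
        raise SpectraError(f"input_dim {input_dim} below the floor width {floor}")
    widths = [input_dim]
    while widths[-1] > floor:
        widths.append(max(floor, widths[-1] // 2))
    return widths


@dataclass
class ArchitectureSpec:
    """Deterministic layer plan for the CN / JL / NSN / VN stack."""

    cn_widths: list[int]
    jl_width: int = JL_WIDTH_DEFAULT
    nsn_depth: int = 2
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cn_widths = [int(w) for w in self.cn_widths]
        if len(self.cn_widths) < 1:
            raise SpectraError("cn_widths must be non-empty")
        if any(b >= a for a, b in zip(self.cn_widths, self.cn_widths[1:])):
            raise SpectraError("cn_widths must be strictly decreasing")
        if self.cn_widths[-1] != self.jl_width:
            raise SpectraError(
                f"terminal CN width {self.cn_widths[-1]} != jl_width {self.jl_width}")
        if self.nsn_depth < 0:
            raise SpectraError("nsn_depth must be >= 0")
        if self.activation != "relu":
            raise SpectraError(f"unsupported activation {self.activation!r}")

    @property
    def input_dim(self) -> int:
        return self.cn_widths[0]

    @property
    def vn_widths(self) -> list[int]:
        """Decoder mirror of the encoder (output dim == input dim)."""
        return list(reversed(self.cn_widths))

    @property
    def nsn_widths(self) -> list[int]:
        return [self.jl_width] + [self.jl_width] * self.nsn_depth + [1]

    @classmethod
    def from_input_dim(cls, input_dim: int, jl_width: int = JL_WIDTH_DEFAULT,
                       nsn_depth: int = 2, seed: int = 0) -> "ArchitectureSpec":
        return cls(cn_widths=sandwich_sizes(input_dim, jl_width),
                   jl_width=jl_width, nsn_depth=nsn_depth, seed=seed)


@dataclass
class Normalizer:
    """Per-feature center/scale fitted on training data only."""

    mu: np.ndarray
    sd: np.ndarray

    @classmethod
    def identity(cls, dim: int) -> "Normalizer":
        return cls(np.zeros(dim), np.ones(dim))

    @classmethod
    def fit(cls, x: np.ndarray) -> "Normalizer":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        return cls(mu, np.where(sd < 1e-8, 1.0, sd))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sd

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.sd + self.mu


@dataclass
class ModelState:
    """Architecture spec plus learned weights, normalizers and training grid.

    For the ``multimodal`` and ``proposed`` variants the state holds one
    shared encoder, three heads and a decoder.  For the ``dnn`` baseline it
    holds three independent single-task networks in ``heads`` (``encoder``
    and ``decoder`` are ``None``).
    """

    spec: ArchitectureSpec
    variant: str
    encoder: MLP | None
    heads: list[MLP]
    decoder: MLP | None
    input_normalizer: Normalizer
    target_normalizer: Normalizer
    grid: np.ndarray | None = None
    train_log: list = field(default_factory=list)

    def networks(self) -> list[MLP]:
        nets = [] if self.encoder is None else [self.encoder]
        nets += self.heads
        if self.decoder is not None:
            nets.append(self.decoder)
        return nets

    def check_grid(self, spectrum: Spectrum) -> None:
        if spectrum.n_bands != self.spec.input_dim:
            raise SpectraError(
                f"grid mismatch: model expects {self.spec.input_dim} bands, "
                f"input has {spectrum.n_bands}")
        if self.grid is not None and not np.allclose(
                self.grid, spectrum.wavelengths, rtol=0.0, atol=1e-6):
            raise SpectraError("grid mismatch: input wavelengths differ from "
                               "the model's training grid")


def build_model(spec: ArchitectureSpec, seed: int | None = None,
                variant: str = "proposed") -> ModelState:
    """Deterministically initialize a model for the given variant."""
    if variant not in ("dnn", "multimodal", "proposed"):
        raise SpectraError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if variant == "dnn":
        widths = spec.cn_widths + [spec.jl_width] * spec.nsn_depth + [1]
        heads = [MLP(widths, rng) for _ in range(3)]
        encoder = decoder = None
    else:
        # the JL output itself is rectified: it is a hidden representation
        encoder = MLP(spec.cn_widths, rng, relu_last=True)
        heads = [MLP(spec.nsn_widths, rng) for _ in range(3)]
        decoder = MLP(spec.vn_widths, rng)
    return ModelState(
        spec=spec, variant=variant, encoder=encoder, heads=heads,
        decoder=decoder,
        input_normalizer=Normalizer.identity(spec.input_dim),
        target_normalizer=Normalizer.identity(3),
    )


def _as_row(model: ModelState, spectrum: Spectrum) -> np.ndarray:
    model.check_grid(spectrum)
    return model.input_normalizer.transform(spectrum.intensities[None, :])


def encode(model: ModelState, spectrum: Spectrum) -> np.ndarray:
    """Joint-layer representation (length ``jl_width``) of one spectrum."""
    if model.encoder is None:
        raise SpectraError("the dnn baseline has no shared joint layer")
    return model.encoder.forward(_as_row(model, spectrum), cache=False)[0]


def reconstruct(model: ModelState, spectrum: Spectrum) -> Spectrum:
    """VN reconstruction of the input, back in intensity units."""
    if model.encoder is None or model.decoder is None:
        raise SpectraError("the dnn baseline has no verification network")
    z = model.encoder.forward(_as_row(model, spectrum), cache=False)
    out = model.decoder.forward(z, cache=False)
    intens = model.input_normalizer.inverse(out)[0]
    return Spectrum(spectrum.wavelengths, np.clip(intens, 0.0, None))


def estimate(model: ModelState, spectrum: Spectrum) -> NutrientComposition:
    """CPF estimate for one spectrum, clipped to the physical range.

    Head outputs are inverse-normalized to grams/100 g and clipped at 0; if
    the three estimates together exceed 100 g they are rescaled onto the
    simplex boundary so the result is always a valid composition.
    """
    x = _as_row(model, spectrum)
    if model.variant == "dnn":
        raw = np.array([h.forward(x, cache=False)[0, 0] for h in model.heads])
    else:
        z = model.encoder.forward(x, cache=False)
        raw = np.array([h.forward(z, cache=False)[0, 0] for h in model.heads])
    grams = np.clip(model.target_normalizer.inverse(raw[None, :])[0], 0.0, None)
    total = grams.sum()
    if total > 100.0:
        grams = grams * (100.0 / total)
    return NutrientComposition.from_array(grams)


# ---------------------------------------------------------------------------
# Model artifact: <dir>/spec.json (architecture, normalizers, grid, variant)
# and <dir>/weights.npz (one array per parameter, in network order).

def save_model(model: ModelState, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    meta = {
        "format_version": 1,
        "package_version": __version__,
        "variant": model.variant,
        "spec": asdict(model.spec),
        "input_normalizer": {"mu": model.input_normalizer.mu.tolist(),
                             "sd": model.input_normalizer.sd.tolist()},
        "target_normalizer": {"mu": model.target_normalizer.mu.tolist(),
                              "sd": model.target_normalizer.sd.tolist()},
        "grid": None if model.grid is None else np.asarray(model.grid).tolist(),
    }
    tmp = os.path.join(directory, "spec.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(meta, fh, indent=1)
    os.replace(tmp, os.path.join(directory, "spec.json"))
    weights = [p for net in model.networks() for p in net.params]
    np.savez(os.path.join(directory, "weights.npz"),
             **{f"p{i:04d}": w for i, w in enumerate(weights)})


def load_model(directory) -> ModelState:
    with open(os.path.join(directory, "spec.json")) as fh:
        meta = json.load(fh)
    spec = ArchitectureSpec(**meta["spec"])
    model = build_model(spec, variant=meta["variant"])
    model.input_normalizer = Normalizer(
        np.asarray(meta["input_normalizer"]["mu"]),
        np.asarray(meta["input_normalizer"]["sd"]))
    model.target_normalizer = Normalizer(
        np.asarray(meta["target_normalizer"]["mu"]),
        np.asarray(meta["target_normalizer"]["sd"]))
    model.grid = None if meta["grid"] is None else np.asarray(meta["grid"])
    with np.load(os.path.join(directory, "weights.npz")) as npz:
        weights = [npz[k] for k in sorted(npz.files)]
    params = [p for net in model.networks() for p in net.params]
    if len(params) != len(weights):
        raise SpectraError("weight file does not match the architecture spec")
    for p, w in zip(params, weights):
        if p.shape != w.shape:
            raise SpectraError("weight shapes do not match the architecture spec")
        p[...] = w
    return model
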