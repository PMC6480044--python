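"""Training of the three estimator variants on a labeled spectral dataset.

Variants:

* ``dnn`` — three separate single-task networks, one per macronutrient.
* ``multimodal`` — shared encoder (CN) + joint layer + three heads (NSNs).
* ``proposed`` — the multimodal network plus the verification decoder (VN)
  trained jointly with a reconstruction term, enabling selective prediction.

Training minimizes, on standardized scales,

    L = w_recon * MSE(x, x_hat) + sum_n w_n * MSE(y_n, y_hat_n)

over region-mean spectra (one per food) plus noise-augmented copies.  Input
and target normalizers are fitted on the training set only, so applying
``fit`` inside cross-validation never leaks test-fold statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec, ModelState, Normalizer, build_model
from .nn import Adam
from .spectra import Dataset, SpectraError

__all__ = ["TrainConfig", "fit"]

VARIANTS = ("dnn", "multimodal", "proposed")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``loss_weights`` is ``(w_recon, w_C, w_P, w_F)``; when left ``None`` it
    resolves to ``(10, 1, 1, 1)`` for the proposed variant and
    ``(0, 1, 1, 1)`` for the baselines (which have no reconstruction term).
    The reconstruction term is a per-band average whereas each nutrient term
    is a single output, so the default up-weights reconstruction to give the
    verification decoder gradients of magnitude comparable to the heads'.
    ``augmentation`` is ``(copies, noise_sigma)`` applied to training spectra.
    """

    variant: str
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss_weights: tuple[float, float, float, float] | None = None
    augmentation: tuple[int, float] = (2, 0.5)
    nsn_depth: int = 2
    jl_width: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise SpectraError(f"unknown variant {self.variant!r}")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise SpectraError("epochs >= 0, batch_size >= 1, learning_rate > 0 required")
        if self.loss_weights is None:
            self.loss_weights = ((10.0, 1.0, 1.0, 1.0) if self.variant == "proposed"
                                 else (0.0, 1.0, 1.0, 1.0))
        w = tuple(float(x) for x in self.loss_weights)
        if len(w) != 4 or any(x < 0 for x in w):
            raise SpectraError("loss_weights must be 4 non-negative reals")
        if self.variant == "proposed" and w[0] <= 0:
            raise SpectraError("the proposed variant requires w_recon > 0")
        if self.variant in ("dnn", "multimodal") and w[0] != 0:
            raise SpectraError(f"variant {self.variant!r} requires w_recon == 0")
        self.loss_weights = w
        copies, sigma = self.augmentation
        if int(copies) < 0 or float(sigma) < 0:
            raise SpectraError("augmentation copies and noise_sigma must be >= 0")
        self.augmentation = (int(copies), float(sigma))


def _training_matrix(dataset: Dataset, config: TrainConfig):
    """Region-mean spectra + augmented noisy copies, as (X, y) arrays."""
    rows, targets = [], []
    for s in dataset.samples:
        if s.composition is None:
            raise SpectraError(f"unlabeled sample {s.sample_id!r} in training set")
        rows.append(s.mean_spectrum().intensities)
        targets.append(s.composition.as_array())
    X = np.asarray(rows)
    y = np.asarray(targets)
    copies, sigma = config.augmentation
    if copies > 0:
        rng = np.random.default_rng([config.seed, 101])
        noisy = [np.clip(X + rng.normal(0.0, sigma, size=X.shape), 0.0, None)
                 if sigma > 0 else X.copy() for _ in range(copies)]
        X = np.concatenate([X] + noisy)
        y = np.concatenate([y] * (copies + 1))
    return X, y


def fit(dataset: Dataset, config: TrainConfig) -> ModelState:
    """Fit one variant on a fully labeled dataset.

    Returns a :class:`ModelState` carrying the learned weights, the
    fold-local normalizers, the training grid and a per-epoch loss log.
    ``epochs=0`` returns the initialized, untrained model (normalizers are
    still fitted, so its outputs are on a sensible scale).
    """
    X_raw, y_raw = _training_matrix(dataset, config)
    input_norm = Normalizer.fit(X_raw)
    target_norm = Normalizer.fit(y_raw)
    X = input_norm.transform(X_raw)
    Y = target_norm.transform(y_raw)
    n, d = X.shape

    spec = ArchitectureSpec.from_input_dim(
        d, jl_width=config.jl_width, nsn_depth=config.nsn_depth, seed=config.seed)
    model = build_model(spec, seed=config.seed, variant=config.variant)
    model.input_normalizer = input_norm
    model.target_normalizer = target_norm
    model.grid = np.asarray(dataset.grid)

    if config.epochs == 0:
        return model

    params = [p for net in model.networks() for p in net.params]
    opt = Adam(params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng([config.seed, 202])
    w_recon, *w_heads = config.loss_weights

    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_recon = 0.0
        head_losses = np.zeros(3)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            b = len(idx)
            loss = 0.0

            if config.variant == "dnn":
                for i, head in enumerate(model.heads):
                    pred = head.forward(xb)[:, 0]
                    resid = pred - yb[:, i]
                    li = float(np.mean(resid ** 2))
                    head_losses[i] += li
                    loss += w_heads[i] * li
                    head.backward((2.0 * w_heads[i] / b) * resid[:, None])
            else:
                z = model.encoder.forward(xb)
                dz = np.zeros_like(z)
                for i, head in enumerate(model.heads):
                    pred = head.forward(z)[:, 0]
                    resid = pred - yb[:, i]
                    li = float(np.mean(resid ** 2))
                    head_losses[i] += li
                    loss += w_heads[i] * li
                    dz += head.backward((2.0 * w_heads[i] / b) * resid[:, None])
                xhat = model.decoder.forward(z)
                rresid = xhat - xb
                lr_ = float(np.mean(rresid ** 2))
                epoch_recon += lr_
                loss += w_recon * lr_
                dz += model.decoder.backward(
                    (2.0 * w_recon / (b * d)) * rresid)
                model.encoder.backward(dz)

            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch} "
                    f"(variant={config.variant}, lr={config.learning_rate}); "
                    "lower the learning rate or check the input scale")
            opt.step([g for net in model.networks() for g in net.grads])
            epoch_loss += loss
            n_batches += 1

        model.train_log.append({
            "epoch": epoch,
            "loss": epoch_loss / n_batches,
            "recon_mse": epoch_recon / n_batches,
            "head_mse": (head_losses / n_batches).tolist(),
        })
    return model
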