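# Methods

## Problem and model

`nutrispec` estimates the macronutrient composition of a food — carbohydrate,
protein and fat in grams per 100 g (CPF) — from its short-wave-infrared
hyperspectral reflectance, and refuses to report an estimate when the input
spectrum does not resemble anything the estimator was trained on.

A food is measured as several replicate *region spectra* (intensity over a
common wavelength grid, nominally 887–1722 nm); a pointwise measurement is
unstable because composition varies across the food surface, so the working
signal is the pointwise mean over regions (default 5).

The estimator is a single fully connected network with four parts trained
jointly:

* **CN (common network)** — an encoder over the input bands. Layer widths
  follow the *sandwich* schedule: each hidden layer has `floor(w/2)` nodes,
  halving from the band count until the width hits 16 (e.g. 256 → 128 → 64 →
  32 → 16). For non-power-of-two inputs the halving is integer division
  with a floor at 16.
* **JL (joint layer)** — the terminal 16-node encoder layer, a compressed
  representation shared by all downstream tasks. 16 nodes is the power of
  two nearest the ~17-nodes-per-layer reliability recommendation for small
  dense regressors.
* **NSNs (nutrient-specific networks)** — three regression heads reading
  the JL, one per nutrient, every hidden layer 16 wide (default depth 2).
* **VN (verification network)** — a decoder mirroring the CN
  (16 → … → band count) that reconstructs the input from the JL. CN+VN form
  an autoencoder; the reconstruction error is the trust signal.

Hidden layers (including the JL) use ReLU; outputs are linear. Inputs and
targets are standardized per band / per nutrient with statistics computed
from the training split only, so cross-validation never leaks test-fold
statistics. Estimates are inverse-standardized, clipped at 0, and rescaled
onto the simplex boundary in the rare case the three heads together exceed
100 g/100 g — the reported triple is always a physically valid composition.

Three variants are implemented for comparison: `dnn` (three separate
single-task networks, no sharing, no decoder), `multimodal` (shared CN/JL +
heads, no reconstruction term) and `proposed` (multimodal + VN + selective
prediction).

## Training

The joint loss on standardized scales is

    L = w_recon * MSE(x, x_hat) + Σ_n w_n * MSE(y_n, ŷ_n)

minimized by Adam (lr 1e-3, batch 32, 200 epochs by default) over region-mean
spectra plus noise-augmented copies (default 2 copies per spectrum,
σ = 0.5 intensity units — half the replicate noise scale). Default loss
weights are (10, 1, 1, 1) for `proposed` and (0, 1, 1, 1) for the baselines.
The reconstruction term is a *per-band mean* over ~256 bands while each
nutrient term is a single output, so its per-parameter gradients are roughly
a band-count factor smaller; w_recon = 10 brings the decoder's training rate
in line with the heads'. In practice this leaves per-nutrient accuracy
unchanged while the fraction of held-out in-distribution foods reconstructed
within the rejection threshold rises from ~78% to ~96% (500-food training).

Training is single-phase: VN gradients flow into the CN together with the
heads' gradients. With w_recon = 0 the shared-network path reduces *exactly*
to the multimodal baseline (identical weights under the same seed): a zero
reconstruction gradient leaves Adam's moments at zero, so the decoder stays
at initialization and contributes nothing to the encoder.

The networks are plain dense stacks of at most a few hundred thousand
parameters trained on CPU, implemented directly on numpy (He-normal
initialization, manual backward pass, Adam); all randomness flows from
explicit seeded generators, so runs are reproducible on a platform.

## Rejection threshold (Bland–Altman calibration)

Replicates of the same food differ while meaning the same composition. Each
food's repeatability is the average MAE between its replicates and their
mean; over a calibration set of foods, the Bland–Altman upper limit of
agreement

    τ = mean(per-food MAEs) + 1.96 · sd(per-food MAEs)      (sample sd, n−1)

is the largest spectral discrepancy still attributable to measurement
repeatability. A prediction is accepted iff `MAE(x, VN(CN(x))) ≤ τ`
(equality accepts; only a *larger* error rejects). A rejected result still
carries its (untrusted) composition, flagged.

For additive Gaussian replicate noise with standard deviation σ and r
replicates the expected repeatability has the closed form
σ·√(2/π)·√((r−1)/r) — the √((r−1)/r) factor because each replicate is
compared against a mean that includes it. This closed form anchors the
calibration tests; the multiplicative gain jitter must be switched off for
it to hold exactly.

τ calibrated from raw replicate noise and the autoencoder's residual scale
need not coincide: the residual is replicate noise *plus* model error. With
enough training foods (~500) the model error is small and the mismatch is
modest (~4–13% of in-distribution foods rejected); with few training foods
the autoencoder generalizes worse and τ over-rejects. An alternative is to
set τ from a quantile of validation reconstruction errors; the
replicate-based rule is the default because it is calibrated against the
physics of the measurement, not against the model being verified.

## Synthetic data generator

No measured food dataset is distributed, so the package ships a forward
simulator that encodes the premise making spectral CPF estimation possible:
nutrient content modulates distinct spectral features (sugar-related
features sit below ~1100 nm). A spectrum is

    region_r = gain_r · (Σ_n f_n·B_n + baseline_cat) + ε_r,   clipped at 0

* `B_n` — per-gram basis spectrum of nutrient n: 4 Gaussian peaks with
  randomized centers (the carbohydrate basis always places one peak in
  887–1100 nm), widths 20–80 nm, amplitudes normalized so each nutrient's
  per-gram mean contribution is equal (0.4 intensity units/g);
* `baseline_cat` — a smooth quadratic per category (5 categories, magnitude
  5–20 intensity units), giving signals of order tens of units;
* `f_n` — CPF grams, drawn as Dirichlet(1,1,1) fractions of a total
  uniform in [30, 90] g/100 g (the remainder is water/fibre/ash);
* `gain_r ~ N(1, 0.01)` multiplicative scatter, `ε_r ~ N(0, 1)` additive
  per-band noise. With σ = 1 the replicate-calibrated τ comes out around
  0.75–0.9 intensity units, i.e. a few percent of signal — the same regime
  a real replicate study produces relative to its signal scale.

Out-of-distribution foods come from a perturbed generator: every basis peak
center shifted by `severity × 100–200 nm` and a novel smooth baseline term
of magnitude `severity × ~5–17` units added. At severity → 0 the family
converges to in-distribution; the mean distance to the unperturbed mixture
is monotone in severity. OOD foods keep the composition label used to
generate them, so a non-abstaining estimator is scored against it.

Augmentation (`augment`) appends noisy clones of each region spectrum;
the default augmentation noise is half the replicate noise.

**What the simulator does not emulate:** real absorption band shapes and
overtone structure, instrument response and wavelength-dependent noise,
scattering physics (no SNV/MSC preprocessing is modelled), nonlinear
nutrient–spectrum interactions, and the long-tailed category imbalance of a
real pantry. The simulated mapping from composition to spectrum is linear
by construction, so recovery R² near 1 on clean synthetic data demonstrates
that the pipeline is implemented correctly — not that real-food accuracy
would match; on measured data the relationship is harder and accuracy
substantially lower.

## Evaluation harness

k-fold cross-validation (default k = 10) split **by food**: all replicates
and augmented copies of a food stay in one fold, and augmentation is applied
only to training folds (it happens inside `fit`). Metrics are pooled over
the concatenated held-out predictions of all folds (per-fold values are
recoverable from the records). Per nutrient:

* **R²** = 1 − SS_res/SS_tot about the truth mean (undefined for constant
  truth — raised as an error, reported as a flagged `null` in reports);
* **SMAPE** = mean of `2|ŷ−y| / (|y|+|ŷ|)`, a fraction in [0, 2]; a pair of
  exact zeros contributes 0. This denominator variant is pinned by oracle
  tests.

For the `proposed` variant metrics are computed over *accepted* predictions
only and the rejection rate is reported alongside. Contamination injects
OOD foods into test folds only (rejection is a test-time capability) so
that they form the requested fraction of each test fold.

A "best models" summary ranks repeated cross-validation restarts
(different training seeds) by mean final training loss and averages the
pooled SMAPE of the top 5 — the restart-selection convention used for the
headline SMAPE summaries.

## Numerical choices and degenerate inputs

* Grid equality uses an absolute tolerance of 1e-6 nm (survives CSV
  round-trips at the written precision); intensities are written at 10
  significant digits, making round-trips lossless for plotting and
  re-training purposes.
* Per-band standard deviations below 1e-8 are replaced by 1 in the
  normalizer (constant bands carry no signal; this avoids division blowups).
* Zero-noise simulation is exact (no degenerate sampling); noise clipping
  at zero intensity introduces a small positive bias only where the clean
  signal is within ~2σ of zero.
* NaN/inf training loss aborts with a diagnostic rather than continuing.
* `epochs = 0` returns the initialized model with fitted normalizers —
  useful as a shape/scale contract.
* Boundary accept: `reconstruction_mae == τ` accepts.
* All seeds are explicit; a single CLI `--seed` fans out to simulation,
  initialization, shuffling and augmentation streams via distinct derived
  streams.

## Known limitations

* The verification decoder is symmetric to the encoder by construction;
  asymmetric decoders are not supported.
* τ is global — no per-category thresholds.
* The `dnn` baseline has no joint layer or decoder, so `encode` /
  `reconstruct` raise for it by design; selective prediction applies only
  to models with a verification network.
* Training is full-precision, single-threaded CPU; problem sizes beyond a
  few thousand foods × a few thousand bands will be slow.
* Reported problem sizes in the acceptance script (500 simulated foods,
  10-fold CV, 20% contamination) were chosen as the smallest sizes at which
  the autoencoder's reconstruction quality saturates; smaller training sets
  over-reject in-distribution foods (see the τ discussion above).
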