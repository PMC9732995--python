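# scanstorm

Simulation and neural reconstruction of **confocal line-scan dSTORM** data.

Single-molecule localization microscopy (SMLM) reconstructs super-resolved
images by fitting the positions of sparse blinking fluorophores across
thousands of camera frames. On a confocal scanner (a galvanometric
one-pixel detector rastering the field line by line), a dye can switch into
or out of its fluorescent ON state *while its rows are being scanned*: the
recorded point spread function (PSF) is then chopped at its top or bottom.
Parametric Gaussian fitters, which assume a symmetric PSF, fail on such
data. scanstorm is for microscopists and methods developers working with
line-scanned (e.g. fluorescence-lifetime) SMLM who need

* a **simulator** producing line-scanned frames with truncated Airy PSFs,
  realistic blinking kinetics and noise, plus exact ground truth;
* a **trainable wavelet filter bank** that denoises frames and detects
  candidate emitters, which are cropped to 9×9×3 patches (previous /
  current / next frame);
* **compressed-sensing (CS) neural fitters** mapping each patch to an
  8-channel feature space — per pixel: emitter probability *p*, subpixel
  offsets Δx, Δy ∈ [−1, 1], intensity *N*, uncertainties σx, σy, σN, and
  background *B*;
* deterministic **post-processing** turning feature maps into a
  localization table (ThunderSTORM-compatible CSV), and
* **evaluation**: Jaccard index, RMSE, Fourier ring correlation (FRC).

## The model

The simulator works on a sub-lattice S of N×N cells, N = s_px · s_im
(1 nm cells at 100 nm pixels). Per scanned line (Δt = 6 ms) new emitters
arrive with rate λ; each draws a switch-ON countdown and an ON lifetime
from Poisson(90 ms), a position uniform in S, a brightness uniform in
[800, 1500] detector units (jittered per frame with σ = 0.2·ph), and an
Airy PSF with first zero in [525, 555] nm. Only emitters in the ON state
contribute to the currently scanned band of rows, so switching mid-scan
truncates the PSF. Frames are area-binned to camera pixels; Poisson shot
noise and Gaussian read noise (σ ∈ [175, 185]) are added. An emitter
counts as ground truth in a frame if it was rendered for at least 40 % of
its ON lines there.

Sparse recovery solves min_b ½‖Ab − y‖² + λ‖b‖₁ (b ≥ 0) with FISTA, where
A renders a super-resolved lattice spike as the binned PSF. The
soft-threshold weight λ ∈ (0, 0.025) is predicted per crop by a small CNN;
the solver is unrolled from differentiable primitives so λ is trained
end-to-end. Four fitter architectures are provided: `cs_cnn` (FISTA prior
+ convolutions), `cs_inception` (two inception blocks with CS paths at low
then high iteration counts), `cs_unet` (FISTA prior + U-Net) and
`rec_unet` (recursive U-Net that mimics unrolled CS by iteratively
decoding the feature space to image space, encoding the residual and
updating the estimate, with shared weights).

Training minimizes a composite loss adapted from the DECODE family: a
Gaussian-mixture localisation likelihood over (x, y, N) with per-pixel
weights p and spreads σ, a count term comparing Σp to the true emitter
count with variance Σp(1−p), and an L1 background term against the
noise-free frame. Localizations are extracted from p-maps with a
cross-shaped filter: a formation is accepted when its cross sum exceeds
t_re = 0.7 (the second-highest pixel as well above 2·t_re).

All trainable layers run on a small numpy reverse-mode autodiff engine
included in the package (`scanstorm.nn`); no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from scanstorm import ScanConfig, make_training_crops
from scanstorm.config import TrainConfig
from scanstorm.networks import build_model
from scanstorm.pipeline import Dataset, train
from scanstorm.evaluation import evaluate_crops

cfg = ScanConfig(seed=11)
ds = Dataset()
rng = np.random.default_rng(11)
for _ in range(4):                      # 4 noise batches x 1000 crops
    ds.train.extend(make_training_crops(
        1000, cfg, rng=rng, noise_sigma=rng.uniform(175, 185)))
ds.eval = make_training_crops(400, cfg, rng=rng, noise_sigma=180.0)

model = build_model("rec_unet", np.random.default_rng(11))
model, log = train(model, ds, TrainConfig(steps=2000, learning_rate=1e-3,
                                          batch_size=16, seed=11))
ji, rmse_nm, m = evaluate_crops(model, ds.eval)
print(f"JI {ji:.2f}  RMSE {rmse_nm:.0f} nm  (TP {m.TP} FP {m.FP} FN {m.FN})")
```

On this small budget the run prints

```
JI 0.22  RMSE 56 nm  (TP 219 FP 5 FN 750)
```

i.e. after only two thousand optimizer steps the fitter recovers about a
quarter of the (noisy, often heavily truncated) emitters, almost without
false positives, at ~0.56-pixel accuracy; the longer reference runs in
`scanstorm.pipeline` (`desk_scale_experiment`, 7500 steps, and the
noise-free `smoke_recovery_experiment`) reach Jaccard indices of ~0.5 on
noisy crops and ~0.94 on clean isolated emitters. The CLI wraps the same
pipeline:

```bash
scanstorm simulate --seed 1 --frames 200 --size 45 --out movie.tif
scanstorm detect movie.tif --out peaks.csv
scanstorm fit movie.tif --model ckpt.npz --out locs.csv
scanstorm evaluate locs.csv --truth movie.truth.csv --out report.json
```

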