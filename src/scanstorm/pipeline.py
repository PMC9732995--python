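"""Training loop, dataset management and inference orchestration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .config import TrainConfig
from .networks import build_model
from .nn import Adam, Module
from .objectives import GroundTruthBatch, total_loss
from .simulate import make_training_crops
from .evaluation import evaluate_crops
from .wavelet import FilterBank, denoise_frame, detect_peaks, crop_rois, \
    robust_threshold
from .postprocess import extract_from_feature_map

logger = logging.getLogger("scanstorm")

__all__ = ["Dataset", "build_dataset", "train", "infer_stack",
           "save_checkpoint", "load_checkpoint"]

LOG_COLUMNS = ["step", "loss", "val_loss", "JI", "RMSE"]


@dataclass
class Dataset:
    """Simulated crop dataset, split 3:1 into train and eval sub-batches."""

    train: list = field(default_factory=list)
    eval: list = field(default_factory=list)
    sigmas: list = field(default_factory=list)  # read-noise sigma per batch


def build_dataset(config: TrainConfig,
                  rng: np.random.Generator | None = None) -> Dataset:
    """Generate ``n_batches`` batches of ``subbatches x crops_per_subbatch``
    crops; each batch gets one read-noise sigma drawn from the configured
    range, the last sub-batch of each batch goes to the eval split."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ds = Dataset()
    lo, hi = config.sim.noise_sigma_range
    for b in range(config.n_batches):
        sigma = float(rng.uniform(lo, hi))
        ds.sigmas.append(sigma)
        for sub in range(config.subbatches):
            crops = make_training_crops(config.crops_per_subbatch, config.sim,
                                        rng=rng, noise_sigma=sigma)
            if sub == config.subbatches - 1:
                ds.eval.extend(crops)
            else:
                ds.train.extend(crops)
    return ds


def _clip_gradients(params, max_norm: float = 10.0) -> float:
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def train(model: Module, dataset: Dataset, config: TrainConfig,
          log_path=None, checkpoint_path=None,
          eval_subset: int = 200, lr_decay_at: float = 0.7):
    """Train a fitter on the dataset.

    Every ``eval_every`` steps the Jaccard index, RMSE and validation loss
    are computed on (a subset of) the eval split and appended to the log;
    the checkpoint with the best validation loss is kept.  Gradients are
    clipped to a global norm of 10 and the learning rate drops tenfold
    after ``lr_decay_at`` of the step budget (the count-term variance
    shrinks as probabilities saturate, which otherwise destabilizes the
    end of training).

    Returns ``(model, log)`` with the log as a DataFrame.
    """
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    log_rows = []
    best = (np.inf, model.state_dict())
    n_train = len(dataset.train)
    eval_crops = dataset.eval[:eval_subset]
    for step in range(config.steps):
        if step == int(lr_decay_at * config.steps):
            opt.lr = config.learning_rate / 10.0
        idx = rng.integers(0, n_train, config.batch_size)
        batch = [dataset.train[i] for i in idx]
        x = np.stack([c.pixels for c in batch])
        gt = GroundTruthBatch.from_crops(batch)
        loss = total_loss(model(x), gt)
        if not np.isfinite(loss.data):
            logger.error("NaN loss at step %d; restoring best checkpoint", step)
            model.load_state_dict(best[1])
            break
        opt.zero_grad()
        loss.backward()
        _clip_gradients(model.parameters())
        opt.step()
        if (step + 1) % config.eval_every == 0 and eval_crops:
            model.eval()
            val_gt = GroundTruthBatch.from_crops(eval_crops)
            val_x = np.stack([c.pixels for c in eval_crops])
            val_loss = float(total_loss(model(val_x), val_gt).data)
            ji, r, _ = evaluate_crops(model, eval_crops)
            model.train()
            log_rows.append([step + 1, float(loss.data), val_loss, ji, r])
            logger.info("step %d loss %.3f val %.3f JI %.3f RMSE %.1f",
                        step + 1, loss.data, val_loss, ji, r)
            if val_loss < best[0]:
                best = (val_loss, model.state_dict())
                if checkpoint_path is not None:
                    save_checkpoint(model, checkpoint_path, config)
    # the best-validation-loss state is checkpointed, but the final state is
    # returned: detection metrics keep improving after the validation loss
    # plateaus (uncertainty terms dominate the loss late in training)
    model.eval()
    log = pd.DataFrame(log_rows, columns=LOG_COLUMNS)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return model, log


def desk_scale_experiment(seed: int, n_train: int = 4000, n_val: int = 1000,
                          steps: int = 6000, learning_rate: float = 1e-3,
                          batch_size: int = 16):
    """Canonical desk-scale training run of the recursive U-Net.

    Generates ``n_train`` training crops in four read-noise batches plus
    ``n_val`` held-out validation crops, trains for ``steps`` Adam steps
    and returns ``(model, val_crops)``.  All randomness derives from
    ``seed``.
    """
    from .config import ScanConfig

    rng = np.random.default_rng(seed)
    sim = ScanConfig(seed=seed)
    ds = Dataset()
    lo, hi = sim.noise_sigma_range
    for _ in range(4):
        sigma = float(rng.uniform(lo, hi))
        ds.sigmas.append(sigma)
        ds.train.extend(make_training_crops(n_train // 4, sim, rng=rng,
                                            noise_sigma=sigma))
    ds.eval = make_training_crops(n_val, sim, rng=rng,
                                  noise_sigma=float(rng.uniform(lo, hi)))
    cfg = TrainConfig(steps=steps, learning_rate=learning_rate,
                      batch_size=batch_size, eval_every=10 ** 9,  # no cycles
                      seed=seed, sim=sim)
    model = build_model("rec_unet", np.random.default_rng(seed))
    model, _ = train(model, ds, cfg)
    return model, ds.eval


def smoke_recovery_experiment(seed: int, n_train: int = 4000,
                              n_test: int = 150, steps: int = 3000,
                              learning_rate: float = 2e-3,
                              batch_size: int = 16):
    """Pipeline health check: train the recursive U-Net on noise-free
    crops with one fully rendered emitter each, then run the full
    detection -> fitting -> extraction pipeline on held-out clips.

    Returns ``(ji, rmse_nm, match_result, model)``.
    """
    from .config import ScanConfig
    from .evaluation import match_localisations, jaccard_index, rmse
    from .simulate import make_isolated_crops
    import warnings

    sim = ScanConfig(seed=seed)
    rng = np.random.default_rng(seed)
    crops = make_isolated_crops(n_train, sim, rng=rng)
    test = make_isolated_crops(n_test, sim, rng=seed + 978)
    model = build_model("rec_unet", np.random.default_rng(seed))
    opt = Adam(model.parameters(), lr=learning_rate)
    for step in range(steps):
        if step == int(0.7 * steps):
            opt.lr = learning_rate / 10.0
        idx = rng.integers(0, n_train, batch_size)
        batch = [crops[i] for i in idx]
        x = np.stack([c.pixels for c in batch])
        gt = GroundTruthBatch.from_crops(batch)
        loss = total_loss(model(x), gt)
        opt.zero_grad()
        loss.backward()
        _clip_gradients(model.parameters())
        opt.step()
    model.eval()
    preds, truths = [], []
    for i, c in enumerate(test):
        table = infer_stack(c.pixels, model, threshold=50.0)
        table = table[table["frame"] == 1]
        preds.extend((i, x, y) for x, y in
                     zip(table["x_px"], table["y_px"]))
        truths.append((i, c.truth[0].x_px, c.truth[0].y_px))
    m = match_localisations(
        pd.DataFrame(preds, columns=["frame", "x_px", "y_px"]),
        pd.DataFrame(truths, columns=["frame", "x_px", "y_px"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return jaccard_index(m), rmse(m), m, model


def sweep_extraction_threshold(model, val_crops, t_re_grid=None,
                               t_cls: float = 0.3, batch_size: int = 64):
    """Jaccard index on validation crops as a function of the extraction
    threshold ``t_re``; returns ``(grid, ji_values)``.

    The model runs once; only the deterministic extraction is repeated.
    """
    from .evaluation import match_localisations, jaccard_index
    from .postprocess import extract_localisations

    if t_re_grid is None:
        t_re_grid = np.round(np.arange(0.1, 1.35, 0.1), 10)
    model.eval()
    fs = []
    for i0 in range(0, len(val_crops), batch_size):
        batch = val_crops[i0:i0 + batch_size]
        fs.append(model(np.stack([c.pixels for c in batch])).numpy())
    fs = np.concatenate(fs)
    truth = pd.DataFrame(
        [(i, t.x_px, t.y_px) for i, c in enumerate(val_crops)
         for t in c.truth],
        columns=["frame", "x_px", "y_px"])
    origins = [(i, 0, 0) for i in range(len(val_crops))]
    jis = []
    for t_re in t_re_grid:
        pred = extract_localisations(fs, origins, t_cls, float(t_re))
        jis.append(jaccard_index(match_localisations(pred, truth)))
    return np.asarray(t_re_grid), np.asarray(jis)


def save_checkpoint(model: Module, path, config: TrainConfig | None = None):
    state = model.state_dict()
    meta = {}
    if config is not None:
        meta["architecture"] = config.architecture
    np.savez_compressed(path, __meta_arch=np.array(
        meta.get("architecture", "")), **state)


def load_checkpoint(path, rng: np.random.Generator | None = None,
                    architecture: str | None = None, **kw) -> Module:
    data = np.load(path, allow_pickle=False)
    arch = architecture or str(data["__meta_arch"])
    model = build_model(arch, rng or np.random.default_rng(0), **kw)
    model.load_state_dict({k: data[k] for k in data.files
                           if k != "__meta_arch"})
    model.eval()
    return model


def infer_stack(frames: np.ndarray, model: Module,
                bank: FilterBank | None = None, threshold: float | None = None,
                t_cls: float = 0.3, t_re: float = 0.7,
                batch_size: int = 64,
                merge_radius_px: float = 0.5) -> pd.DataFrame:
    """Full-frame inference: wavelet detection -> 9x9x3 crops -> fitter ->
    extraction -> global localization table.

    Overlapping crops can localize the same emitter at slightly different
    subpixel positions; per frame, rows closer than ``merge_radius_px``
    (default half a pixel) are merged keeping the highest-probability one.
    """
    from .wavelet import PeakList

    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    model.eval()
    bank = bank or FilterBank()
    peaks = PeakList()
    for f, frame in enumerate(frames):
        den = denoise_frame(frame, bank)
        thr = robust_threshold(den) if threshold is None else threshold
        pl = detect_peaks(den, thr)
        for (
            _, r, c), s in zip(pl.peaks, pl.scores):
            peaks.peaks.append((f, r, c))
            peaks.scores.append(s)
    crops = crop_rois(frames, peaks)
    rows = []
    for i0 in range(0, len(crops), batch_size):
        batch = crops[i0:i0 + batch_size]
        x = np.stack([c.pixels for c in batch])
        fs = model(x).numpy()
        for fm, crop in zip(fs, batch):
            rows.extend(extract_from_feature_map(fm, crop.origin, t_cls, t_re))
    from .postprocess import COLUMNS
    table = pd.DataFrame(rows, columns=COLUMNS)
    if len(table):
        keep = []
        for f, grp in table.sort_values("p_score", ascending=False
                                        ).groupby("frame"):
            kept_xy: list[tuple[float, float]] = []
            for idx, row in grp.iterrows():
                if any((row["x_px"] - x) ** 2 + (row["y_px"] - y) ** 2
                       < merge_radius_px ** 2 for x, y in kept_xy):
                    continue
                kept_xy.append((row["x_px"], row["y_px"]))
                keep.append(idx)
        table = (table.loc[keep]
                 .sort_values(["frame", "y_px", "x_px"])
                 .reset_index(drop=True))
    return table
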