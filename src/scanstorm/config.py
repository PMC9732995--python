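"""Configuration objects (simulation, compressed sensing, training) with YAML I/O."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ScanConfig", "CSConfig", "TrainConfig", "load_config", "save_config"]


@dataclass
class ScanConfig:
    """Parameters of the line-scanned acquisition simulator.

    The simulator works on a sub-lattice ``S`` of size ``N x N`` with
    ``N = s_px * s_im``: ``s_px`` sub-lattice cells per camera pixel
    (default 100, i.e. 1 nm resolution at 100 nm pixels).  The scanner
    rasterizes one horizontal line of ``s_px`` sub-lattice rows per time
    step ``dt_line_ms``.
    """

    s_px: int = 100               # sub-lattice oversampling per camera pixel
    s_im: int = 9                 # image size in camera pixels
    pixel_size_nm: float = 100.0  # physical pixel size
    dt_line_ms: float = 6.0       # time per scanned line
    lambda_on: float = 0.12       # Poisson rate of new ON events per line
    mean_lifetime: float = 90.0   # Poisson mean of ON lifetime [ms]
    mean_countdown: float = 90.0  # Poisson mean of switch-ON countdown [ms]
    photon_range: tuple = (800, 1500)   # base brightness (detector units at PSF peak)
    photon_sigma_frac: float = 0.2      # per-frame brightness jitter, sigma = frac*ph
    airy_radius_range: tuple = (525, 555)  # first Airy zero [sub-lattice units = nm]
    noise_sigma_range: tuple = (175.0, 185.0)  # Gaussian read noise [detector units]
    min_on_fraction: float = 0.4  # fraction of ON lines that must be rendered
    shot_noise: bool = True       # Poisson shot noise on the noiseless signal
    read_noise: bool = True       # additive Gaussian read noise
    seed: int = 0

    def __post_init__(self):
        if self.s_px < 1:
            raise ValueError("s_px must be >= 1")
        if self.s_im < 9:
            raise ValueError("s_im must be >= 9")
        if not self.photon_range[0] < self.photon_range[1]:
            raise ValueError("photon_range must be increasing")
        if not 0 < self.min_on_fraction <= 1:
            raise ValueError("min_on_fraction must be in (0, 1]")
        for name in ("dt_line_ms", "mean_lifetime", "mean_countdown"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_on < 0:
            raise ValueError("lambda_on must be >= 0")

    @property
    def n_sub(self) -> int:
        """Sub-lattice side length N."""
        return self.s_px * self.s_im


@dataclass
class CSConfig:
    """Compressed-sensing (FISTA) settings."""

    lambda_max: float = 0.025  # upper bound of the learned threshold
    n_iter: int = 50
    tol: float = 0.0           # relative objective change for early stop (0 = off)
    upsampling: int = 8        # CS sub-lattice cells per camera pixel

    def __post_init__(self):
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.upsampling < 1:
            raise ValueError("upsampling must be >= 1")


@dataclass
class TrainConfig:
    """Training-loop settings.

    The full-scale dataset is 40 batches of 4x1000 crops, split 3:1 into
    training and evaluation sub-batches; per-batch read-noise sigma is drawn
    from the configured range.  ``n_batches``/``crops_per_subbatch`` scale
    the dataset down for desk-scale runs.
    """

    n_batches: int = 40
    crops_per_subbatch: int = 1000
    subbatches: int = 4           # 3 train : 1 eval
    eval_every: int = 150
    learning_rate: float = 1e-4
    batch_size: int = 32
    steps: int = 2000
    architecture: str = "rec_unet"
    n_recursions: int = 2
    seed: int = 0
    sim: ScanConfig = field(default_factory=ScanConfig)
    cs: CSConfig = field(default_factory=CSConfig)

    def __post_init__(self):
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    return conv(d)


def save_config(cfg, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name == "sim":
            v = _from_dict(ScanConfig, v)
        elif f.name == "cs":
            v = _from_dict(CSConfig, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path, cls=ScanConfig):
    d = yaml.safe_load(Path(path).read_text())
    return _from_dict(cls, d)
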