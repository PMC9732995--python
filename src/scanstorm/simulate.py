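"""Line-scanned SMLM frame simulator.

A galvanometric scanner rasterizes the field of view one horizontal line
per time step ``dt``.  Emitters blink stochastically: a new emitter appears
with Poisson rate ``lambda_on`` per line, waits out a Poisson switch-ON
countdown, stays ON for a Poisson lifetime and disappears.  Because an
emitter can switch ON or OFF while the scanner sweeps its rows, the
rendered PSF is truncated at its top or bottom — the defining feature of
this acquisition mode.

The simulation runs on a sub-lattice ``S`` of ``N x N`` cells with
``N = s_px * s_im`` (1 nm cells at the defaults).  Rendering adds, for each
emitter in the ON state, the slice of its Airy kernel that falls inside the
currently scanned band of ``s_px`` rows, scaled by the emitter's per-frame
brightness.  Kernels are peak-normalized at render time so brightness is
expressed in detector units at the PSF peak; frames are obtained by
area-average binning of ``S`` followed by Poisson shot noise and Gaussian
read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScanConfig
from .psf import _cached_peak_kernel

__all__ = [
    "EmitterRecord", "TruthEmitter", "FrameStack", "RoiCrop",
    "step_emitter_states", "render_line", "finalize_frame",
    "accept_ground_truth", "simulate_stack", "make_training_crops",
]


@dataclass
class EmitterRecord:
    """State of one simulated fluorophore."""

    Lx: float                 # column position on the sub-lattice [0, N)
    Ly: float                 # row position on the sub-lattice [0, N)
    photons: float            # base brightness (detector units at PSF peak)
    countdown_ms: float       # remaining switch-ON countdown
    lifetime_ms: float        # remaining ON lifetime
    radius: float = 540.0     # first Airy zero of this emitter's PSF
    lines_rendered: int = 0   # lines rendered in the current frame
    lines_on: int = 0         # lines in ON state in the current frame
    frame_index: int = -1     # frame of first rendering (-1: never rendered)
    amplitude: float = 0.0    # brightness in the current frame (jittered)
    on_current_line: bool = False


@dataclass
class TruthEmitter:
    """Accepted ground-truth emitter, camera-pixel units, 0-based."""

    x_px: float
    y_px: float
    photons: float


@dataclass
class FrameStack:
    """Simulated movie: noisy frames, pre-noise frames, per-frame truth."""

    frames: np.ndarray                      # (T, s_im, s_im)
    noiseless: np.ndarray                   # (T, s_im, s_im)
    ground_truth: list = field(default_factory=list)  # list[list[TruthEmitter]]

    def __post_init__(self):
        if self.frames.shape != self.noiseless.shape:
            raise ValueError("frames and noiseless must have identical shape")


@dataclass
class RoiCrop:
    """9x9 patch over three consecutive frames (previous, current, next)."""

    pixels: np.ndarray                      # (3, 9, 9)
    origin: tuple                           # (frame, row, col) of patch corner
    truth: list = field(default_factory=list)  # TruthEmitters, patch-local px
    noiseless: np.ndarray | None = None     # pre-noise central frame (9, 9)

    def __post_init__(self):
        if self.pixels.shape != (3, 9, 9):
            raise ValueError("crop must be 9x9 over 3 frames")
        if not 0 <= len(self.truth) <= 10:
            raise ValueError("crop truth count must be in [0, 10]")


def _spawn(config: ScanConfig, rng: np.random.Generator) -> EmitterRecord:
    n = config.n_sub
    lo, hi = config.photon_range
    rlo, rhi = config.airy_radius_range
    return EmitterRecord(
        Lx=rng.uniform(0, n),
        Ly=rng.uniform(0, n),
        photons=float(rng.integers(lo, hi + 1)),
        countdown_ms=float(rng.poisson(config.mean_countdown)),
        lifetime_ms=float(rng.poisson(config.mean_lifetime)),
        radius=float(rng.integers(rlo, rhi + 1)),
    )


def step_emitter_states(active: list[EmitterRecord], config: ScanConfig,
                        rng: np.random.Generator) -> list[EmitterRecord]:
    """Advance the emitter population by one scanned line.

    New emitters arrive with ``k ~ Poisson(lambda_on)``; emitters whose
    lifetime is exhausted are removed; countdowns > 0 are decremented by
    ``dt`` without rendering; once the countdown has run out, ``dt`` is
    subtracted from the remaining lifetime and the emitter is flagged as ON
    for the current line.
    """
    dt = config.dt_line_ms
    survivors = [e for e in active
                 if e.countdown_ms > 0 or e.lifetime_ms > 0]
    k = rng.poisson(config.lambda_on)
    for _ in range(k):
        e = _spawn(config, rng)
        if e.amplitude == 0.0:
            e.amplitude = _jitter(e.photons, config, rng)
        survivors.append(e)
    for e in survivors:
        if e.countdown_ms > 0:
            e.countdown_ms -= dt
            e.on_current_line = False
        else:
            e.on_current_line = True
            e.lifetime_ms -= dt
    return survivors


def _jitter(photons: float, config: ScanConfig, rng: np.random.Generator) -> float:
    a = rng.normal(photons, config.photon_sigma_frac * photons)
    return float(max(a, 1.0))


def render_line(line_index: int, active: list[EmitterRecord], S: np.ndarray,
                s_px: int, psf: np.ndarray | None = None,
                photons: float | None = None) -> np.ndarray:
    """Render the scanned band of ``s_px`` sub-lattice rows at ``line_index``.

    Each emitter flagged ON adds the band-clipped slice of its Airy kernel,
    centered at (Lx, Ly) and scaled by its brightness, producing truncated
    PSFs for emitters that switch while being scanned.  ``psf``/``photons``
    override the per-emitter kernel and brightness (used by the low-level
    contract tests).
    """
    n = S.shape[0]
    r0, r1 = line_index * s_px, min((line_index + 1) * s_px, n)
    for e in active:
        if not e.on_current_line:
            continue
        k = psf if psf is not None else _peak_kernel(e.radius)
        amp = photons if photons is not None else e.amplitude
        ksz = k.shape[0]
        half = ksz // 2
        iy0 = int(round(e.Ly)) - half
        ix0 = int(round(e.Lx)) - half
        # kernel rows overlapping the scanned band
        ky0 = max(r0 - iy0, 0)
        ky1 = min(r1 - iy0, ksz)
        kx0 = max(-ix0, 0)
        kx1 = min(n - ix0, ksz)
        if ky0 >= ky1 or kx0 >= kx1:
            continue
        S[iy0 + ky0:iy0 + ky1, ix0 + kx0:ix0 + kx1] += amp * k[ky0:ky1, kx0:kx1]
        e.lines_rendered += 1
    return S


def _peak_kernel(radius: float) -> np.ndarray:
    """Peak-normalized Airy kernel (max = 1) covering two first-zero rings."""
    size = 2 * int(radius) + 1
    return _cached_peak_kernel(int(round(radius)), size)


def finalize_frame(S: np.ndarray, config: ScanConfig, rng: np.random.Generator,
                   noise_sigma: float | None = None):
    """Bin the sub-lattice to camera pixels and apply the noise model.

    Area-average binning (each camera pixel is the mean of its
    ``s_px x s_px`` sub-lattice cells) yields the noiseless frame; Poisson
    shot noise on the signal plus additive Gaussian read noise of the given
    sigma yields the noisy frame.
    """
    s_px, s_im = config.s_px, config.s_im
    if S.shape != (s_px * s_im, s_px * s_im):
        raise ValueError("S must have shape (N, N) with N = s_px * s_im")
    noiseless = S.reshape(s_im, s_px, s_im, s_px).mean(axis=(1, 3))
    noisy = noiseless.copy()
    if config.shot_noise:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
    if config.read_noise:
        if noise_sigma is None:
            noise_sigma = rng.uniform(*config.noise_sigma_range)
        if noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, noise_sigma, noisy.shape)
    return noisy, noiseless


def accept_ground_truth(e: EmitterRecord, config: ScanConfig) -> bool:
    """True iff the emitter was rendered for >= ``min_on_fraction`` of its
    ON lines in the current frame; an emitter never ON is rejected."""
    if e.lines_on == 0:
        return False
    return e.lines_rendered / e.lines_on >= config.min_on_fraction


def simulate_stack(config: ScanConfig, n_frames: int,
                   rng: np.random.Generator | int | None = None,
                   noise_sigma: float | None = None,
                   warmup_frames: int = 2) -> FrameStack:
    """Simulate a movie of ``n_frames`` frames with per-frame ground truth.

    ``warmup_frames`` un-recorded frames are scanned first so the emitter
    population starts in its steady state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    s_im, s_px, n = config.s_im, config.s_px, config.n_sub
    frames = np.zeros((n_frames, s_im, s_im))
    noiseless = np.zeros_like(frames)
    truth: list[list[TruthEmitter]] = []
    active: list[EmitterRecord] = []
    S = np.zeros((n, n))
    for f in range(-warmup_frames, n_frames):
        S[...] = 0.0
        for e in active:
            e.lines_rendered = 0
            e.lines_on = 0
            e.amplitude = _jitter(e.photons, config, rng)
        seen: list[EmitterRecord] = list(active)
        seen_ids = {id(e) for e in seen}
        for line in range(s_im):
            active = step_emitter_states(active, config, rng)
            for e in active:
                if id(e) not in seen_ids:
                    seen.append(e)
                    seen_ids.add(id(e))
                if e.on_current_line:
                    e.lines_on += 1
            if f < 0:
                continue  # warmup: advance states only, skip rendering
            before = {id(e): e.lines_rendered for e in active}
            render_line(line, active, S, s_px)
            for e in active:
                if e.frame_index < 0 and e.lines_rendered > before[id(e)]:
                    e.frame_index = f
        if f < 0:
            continue
        noisy_f, clean_f = finalize_frame(S, config, rng, noise_sigma=noise_sigma)
        frames[f], noiseless[f] = noisy_f, clean_f
        accepted = [TruthEmitter(e.Lx / s_px, e.Ly / s_px, e.amplitude)
                    for e in seen if accept_ground_truth(e, config)]
        truth.append(accepted)
    return FrameStack(frames=frames, noiseless=noiseless, ground_truth=truth)


def make_isolated_crops(n_crops: int, config: ScanConfig,
                        rng: np.random.Generator | int | None = None,
                        margin_px: float = 0.5) -> list[RoiCrop]:
    """Noise-free 9x9x3 crops with exactly one fully rendered emitter.

    The emitter stays ON through all three frames, so its full Airy PSF is
    recorded (per-frame brightness jitter still applies).  This is the
    pipeline health-check distribution: partially scanned emitters whose
    recorded signal is only an off-center PSF tail are excluded by
    construction, and positions keep ``margin_px`` from the field edge.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    if config.s_im != 9:
        raise ValueError("isolated crops require s_im == 9")
    s_px, n = config.s_px, config.n_sub
    crops = []
    for _ in range(n_crops):
        e = _spawn(config, rng)
        e.Lx = rng.uniform(margin_px * s_px, n - margin_px * s_px)
        e.Ly = rng.uniform(margin_px * s_px, n - margin_px * s_px)
        e.countdown_ms = 0.0
        e.lifetime_ms = np.inf
        e.on_current_line = True
        frames = np.zeros((3, 9, 9))
        amp_mid = 0.0
        S = np.zeros((n, n))
        for f in range(3):
            S[...] = 0.0
            e.amplitude = _jitter(e.photons, config, rng)
            if f == 1:
                amp_mid = e.amplitude
            for line in range(config.s_im):
                render_line(line, [e], S, s_px)
            _, frames[f] = finalize_frame(S, config, rng)
        truth = [TruthEmitter(e.Lx / s_px, e.Ly / s_px, amp_mid)]
        crops.append(RoiCrop(pixels=frames, origin=(1, 0, 0), truth=truth,
                             noiseless=frames[1].copy()))
    return crops


def make_training_crops(n_crops: int, config: ScanConfig,
                        rng: np.random.Generator | int | None = None,
                        noise_sigma: float | None = None,
                        n_range: tuple = (0, 10)) -> list[RoiCrop]:
    """Simulate ``n_crops`` 9x9x3 training crops.

    Each crop holds three consecutive frames of a 9x9 field with
    ``n in [0, 10]`` accepted ground-truth emitters in the central frame
    (rejection-sampled into ``n_range``); the pre-noise central frame is
    kept as the background/denoising target.
    """
    if n_crops <= 0:
        raise ValueError("n_crops must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    if config.s_im != 9:
        raise ValueError("training crops require s_im == 9")
    crops: list[RoiCrop] = []
    while len(crops) < n_crops:
        stack = simulate_stack(config, 3, rng=rng, noise_sigma=noise_sigma)
        n_truth = len(stack.ground_truth[1])
        if not n_range[0] <= n_truth <= min(n_range[1], 10):
            continue
        crops.append(RoiCrop(
            pixels=stack.frames.copy(),
            origin=(1, 0, 0),
            truth=list(stack.ground_truth[1]),
            noiseless=stack.noiseless[1].copy(),
        ))
    return crops
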