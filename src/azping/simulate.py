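"""Synthetic GCaMP movie and dataset generation with ground truth.

Emulates the structure of postsynaptic quantal calcium imaging at the
Drosophila larval NMJ: a field of point-like active zones (AZs) on a dark
background, stochastic quantal fluorescence transients (instant rise,
exponential decay, Gaussian spatial spread reaching neighboring AZs),
linear photobleaching, rigid x-y drift, additive camera noise, and evoked
events time-locked within 1 s of stimuli delivered at 0.2 Hz.

Every downstream stage of the pipeline (stabilization, ROI quantification,
event detection, blob detection, survival and count statistics) is testable
against the ground truth returned alongside each synthetic artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MovieStack",
    "MarkerImage",
    "generate_movie",
    "generate_confocal",
    "generate_count_table",
    "generate_survival_dataset",
]


@dataclass
class MovieStack:
    """A time-ordered grayscale image stack.

    Parameters
    ----------
    data : ndarray, shape (n_frames, height, width)
        Pixel intensities within the bit range of ``bit_depth``.
    pixel_size : float
        Physical pixel edge length in micrometers.
    frame_interval : float
        Time between frames in seconds (50 ms at the native 20 Hz rate).
    bit_depth : int
        8 or 16.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (n_frames, height, width)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval


@dataclass
class MarkerImage:
    """A single-frame marker-channel image (synthetic anti-BRP stand-in)."""

    data: np.ndarray
    pixel_size: float


@dataclass
class SimConfig:
    """Parameters of the synthetic acquisition.

    Defaults mirror the acquisition this generator emulates: 50 ms exposure
    (20 Hz effective frame rate), live pixel edge 0.10833 um, confocal pixel
    edge 0.100 um, quantal transients with ~200 ms decay, stimulation at
    0.2 Hz.
    """

    image_height: int = 128
    image_width: int = 128
    n_frames: int = 400
    frame_interval: float = 0.05
    pixel_size: float = 0.10833
    confocal_pixel_size: float = 0.100
    n_az: int = 12
    min_az_spacing: float = 1.5  # um
    spont_rate: float = 0.01  # events per AZ per second
    evoked_prob: float = 0.05  # per AZ per stimulus
    amp_mean: float = 800.0  # a.u., 16-bit scale
    amp_sd: float = 200.0
    az_baseline: float = 2000.0  # static resting punctum peak, a.u.
    camera_offset: float = 400.0  # dark level, a.u.
    psf_sigma: float = 0.5  # um
    decay_tau: float = 0.2  # s
    bleach_slope: float = 0.0  # a.u. per frame, <= 0
    noise_sd: float = 0.0  # a.u.
    drift_path: np.ndarray | None = None  # (n_frames, 2) int (dx, dy)
    injected_events: Sequence[tuple] = field(default_factory=list)
    stim_times: Sequence[float] = field(default_factory=list)
    evoked_window: float = 1.0  # s after each stimulus
    true_transform: np.ndarray | None = None  # 3x3 confocal->live, live px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.confocal_pixel_size <= 0:
            raise ValueError("pixel sizes must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")
        if not 0.0 <= self.evoked_prob <= 1.0:
            raise ValueError("evoked_prob must be in [0, 1]")
        if self.bleach_slope > 0:
            raise ValueError("bleach_slope must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # ROI diameter of the downstream quantification is 0.650 um; AZs
        # closer than one ROI diameter cannot be told apart at all.
        if self.min_az_spacing <= 0.650:
            raise ValueError("min_az_spacing must exceed the ROI diameter (0.650 um)")
        if self.drift_path is not None:
            self.drift_path = np.asarray(self.drift_path, dtype=int)
            if self.drift_path.shape != (self.n_frames, 2):
                raise ValueError("drift_path must have shape (n_frames, 2)")
        if self.true_transform is not None:
            self.true_transform = np.asarray(self.true_transform, dtype=float)
            if self.true_transform.shape != (3, 3):
                raise ValueError("true_transform must be a 3x3 matrix")
        stim = np.asarray(list(self.stim_times), dtype=float)
        if stim.size and np.any(np.diff(stim) <= 0):
            raise ValueError("stim_times must be strictly increasing")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    events: pd.DataFrame  # az_index, onset_frame, amplitude, mode
    az_centers: np.ndarray  # (n_az, 2) float (x, y) live px, frame-0 coords
    true_drift: np.ndarray  # (n_frames, 2) int (dx, dy)
    true_bleach_slope: float
    true_transform: np.ndarray  # 3x3, confocal px -> live px


_EVENT_COLUMNS = ["az_index", "onset_frame", "amplitude", "mode"]


def _place_az_centers(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer AZ centers respecting min spacing and margins."""
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    drift = cfg.drift_path
    max_drift = int(np.abs(drift).max()) if drift is not None and len(drift) else 0
    margin = int(np.ceil(2 * sigma_px)) + max_drift + 1
    lo_x, hi_x = margin, cfg.image_width - margin
    lo_y, hi_y = margin, cfg.image_height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("image too small for PSF/drift margins")
    min_d_px = cfg.min_az_spacing / cfg.pixel_size
    centers: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 10000 * max(cfg.n_az, 1)
    while len(centers) < cfg.n_az:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_az} AZs with min spacing "
                f"{cfg.min_az_spacing} um after {max_attempts} attempts"
            )
        x = int(rng.integers(lo_x, hi_x))
        y = int(rng.integers(lo_y, hi_y))
        ok = all(np.hypot(x - cx, y - cy) >= min_d_px for cx, cy in centers)
        if ok:
            centers.append((x, y))
    return np.asarray(centers, dtype=float)


def _draw_events(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Spontaneous (homogeneous Poisson) plus evoked (Bernoulli per stimulus).

    Deterministically injected events (az_index, onset_frame, amplitude,
    mode) are appended; with zero rates they are the only events.
    """
    rows: list[tuple[int, int, float, str]] = [
        (int(az), int(f), float(a), str(mode))
        for az, f, a, mode in cfg.injected_events
    ]
    duration = cfg.n_frames * cfg.frame_interval
    window_frames = max(int(round(cfg.evoked_window / cfg.frame_interval)), 1)

    def draw_amp(n: int) -> np.ndarray:
        if cfg.amp_sd == 0:
            return np.full(n, cfg.amp_mean)
        a = -cfg.amp_mean / cfg.amp_sd  # truncate at zero
        return sps.truncnorm.rvs(
            a, np.inf, loc=cfg.amp_mean, scale=cfg.amp_sd, size=n, random_state=rng
        )

    for az in range(cfg.n_az):
        n_spont = rng.poisson(cfg.spont_rate * duration)
        if n_spont:
            onsets = rng.integers(0, cfg.n_frames, size=n_spont)
            amps = draw_amp(n_spont)
            rows += [(az, int(f), float(a), "spontaneous") for f, a in zip(onsets, amps)]
    for t_stim in cfg.stim_times:
        stim_frame = int(np.floor(t_stim / cfg.frame_interval))
        fire = rng.random(cfg.n_az) < cfg.evoked_prob
        for az in np.flatnonzero(fire):
            delay = int(rng.integers(1, window_frames + 1))
            onset = stim_frame + delay
            if onset < cfg.n_frames:
                amp = float(draw_amp(1)[0])
                rows.append((int(az), onset, amp, "evoked"))
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return df.sort_values(["onset_frame", "az_index"], ignore_index=True)


def _gaussian_kernel(sigma_px: float) -> tuple[np.ndarray, int]:
    """Isotropic Gaussian with unit peak; returns (kernel, radius)."""
    r = max(int(np.ceil(4 * sigma_px)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    return k, r


def _add_patch(frame: np.ndarray, kernel: np.ndarray, r: int, cx: int, cy: int,
               scale: float) -> None:
    h, w = frame.shape
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    ky0, kx0 = y0 - (cy - r), x0 - (cx - r)
    frame[y0:y1, x0:x1] += scale * kernel[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]


def generate_movie(cfg: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic 16-bit GCaMP movie and its ground truth.

    Each event is a separable kernel: an isotropic spatial Gaussian
    (``psf_sigma``) of unit peak centered on its AZ, multiplied by a
    temporal instant-rise/exponential-decay envelope (``decay_tau``) of peak
    ``amplitude``.  Per-pixel signal is
    ``camera_offset + static AZ field + sum(events) + bleach_slope * t +
    Gaussian noise``, clipped to the 16-bit range.  Deterministic for a
    fixed seed; independent sub-streams drive AZ placement, event drawing
    and camera noise.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_events, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    centers = _place_az_centers(cfg, rng_place)
    events = _draw_events(cfg, rng_events)
    drift = (
        cfg.drift_path
        if cfg.drift_path is not None
        else np.zeros((cfg.n_frames, 2), dtype=int)
    )
    transform = (
        cfg.true_transform if cfg.true_transform is not None else np.eye(3)
    )

    sigma_px = cfg.psf_sigma / cfg.pixel_size
    kernel, r = _gaussian_kernel(sigma_px)

    # Temporal amplitude envelope per AZ (transients only; the static
    # resting field is rendered separately once).
    amp = np.zeros((cfg.n_az, cfg.n_frames))
    decay_frames = cfg.decay_tau / cfg.frame_interval
    for row in events.itertuples(index=False):
        t0 = row.onset_frame
        tt = np.arange(t0, cfg.n_frames)
        amp[row.az_index, t0:] += row.amplitude * np.exp(-(tt - t0) / decay_frames)

    static = np.zeros((cfg.image_height, cfg.image_width))
    for cx, cy in centers:
        _add_patch(static, kernel, r, int(cx), int(cy), cfg.az_baseline)

    movie = np.empty((cfg.n_frames, cfg.image_height, cfg.image_width))
    tiny = 1e-3
    for t in range(cfg.n_frames):
        dx, dy = int(drift[t, 0]), int(drift[t, 1])
        if dx == 0 and dy == 0:
            frame = static.copy()
        else:
            frame = np.zeros_like(static)
            h, w = static.shape
            ys0, ys1 = max(-dy, 0), min(h - dy, h)
            xs0, xs1 = max(-dx, 0), min(w - dx, w)
            frame[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = static[ys0:ys1, xs0:xs1]
        active = np.flatnonzero(amp[:, t] > tiny)
        for az in active:
            cx, cy = centers[az]
            _add_patch(frame, kernel, r, int(cx) + dx, int(cy) + dy, amp[az, t])
        frame += cfg.camera_offset + cfg.bleach_slope * t
        movie[t] = frame
    if cfg.noise_sd > 0:
        movie += rng_noise.normal(0.0, cfg.noise_sd, size=movie.shape)
    movie = np.clip(np.rint(movie), 0, 65535).astype(np.uint16)

    stack = MovieStack(movie, cfg.pixel_size, cfg.frame_interval, bit_depth=16)
    truth = GroundTruth(
        events=events,
        az_centers=centers,
        true_drift=drift,
        true_bleach_slope=cfg.bleach_slope,
        true_transform=transform,
    )
    return stack, truth


def generate_confocal(cfg: SimConfig, truth: GroundTruth,
                      punctum_sigma_px: float = 2.0) -> MarkerImage:
    """Render the synthetic marker (anti-BRP stand-in) channel.

    AZ centers are mapped from live coordinates into confocal coordinates by
    the inverse of ``true_transform`` (which maps confocal -> live, in live
    pixels) followed by rescaling with the live/confocal pixel-size ratio.
    Puncta get per-AZ intensities so that maxima detection has realistic
    dynamic range; the image is 8-bit, matching the exported marker format.
    """
    ratio = cfg.pixel_size / cfg.confocal_pixel_size
    h = int(np.ceil(cfg.image_height * ratio))
    w = int(np.ceil(cfg.image_width * ratio))
    img = np.zeros((h, w))
    if len(truth.az_centers):
        inv = np.linalg.inv(truth.true_transform)
        pts = np.column_stack(
            [truth.az_centers, np.ones(len(truth.az_centers))]
        )  # (x, y, 1)
        conf = (inv @ pts.T).T
        conf = conf[:, :2] / conf[:, 2:3] * ratio
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        intensities = rng.uniform(120.0, 250.0, size=len(conf))
        kernel, r = _gaussian_kernel(punctum_sigma_px)
        for (cx, cy), a in zip(conf, intensities):
            _add_patch(img, kernel, r, int(round(cx)), int(round(cy)), a)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return MarkerImage(img, cfg.confocal_pixel_size)


def generate_count_table(
    n_animals: int,
    az_per_animal: int,
    group_means: Sequence[float],
    dispersion: float,
    animal_sd: float,
    seed: int,
    group_probs: Sequence[float] = (0.62, 0.25, 0.09, 0.04),
) -> pd.DataFrame:
    """Simulate per-AZ evoked counts under the negative-binomial mixed model.

    Per AZ the evoked count is drawn negative-binomially (NB2, size
    ``dispersion``; variance mu + mu^2/dispersion) with
    ``log mu = log(group mean) + b_animal`` and ``b_animal ~ N(0, animal_sd^2)``.
    Spontaneous-count group labels (0, 1, 2, >=3) are categorical with
    ``group_probs``.  Large ``dispersion`` approaches the Poisson limit.
    """
    group_means = np.asarray(group_means, dtype=float)
    if group_means.shape != (4,):
        raise ValueError("group_means must have length 4 (groups 0, 1, 2, >=3)")
    if np.any(group_means <= 0):
        raise ValueError("group means must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    probs = np.asarray(group_probs, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for animal in range(n_animals):
        b = rng.normal(0.0, animal_sd) if animal_sd > 0 else 0.0
        groups = rng.choice(4, size=az_per_animal, p=probs)
        mu = group_means[groups] * np.exp(b)
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p)
        for az in range(az_per_animal):
            rows.append((animal, az, int(groups[az]), int(counts[az])))
    return pd.DataFrame(rows, columns=["animal_id", "az_id", "spont_group", "n_evoked"])


def generate_survival_dataset(
    K: float,
    plateau: float,
    n_az: int,
    n_frames: int,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate per-AZ conversion (first evoked response) frames.

    A fraction ``plateau`` of spontaneously active AZs never converts
    ("immortal"); the rest convert at frames drawn from an exponential with
    per-frame rate ``K``.  Conversion frames at or beyond ``n_frames`` are
    censored (recorded as -1, like the immortals: neither converts within
    the recording).

    Returns a DataFrame (cell_id, az_id, convert_frame) with
    convert_frame == -1 for AZs that never convert within the recording.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for cell in range(n_cells):
        immortal = rng.random(n_az) < plateau
        frames = np.floor(rng.exponential(1.0 / K, size=n_az)).astype(int)
        for az in range(n_az):
            if immortal[az] or frames[az] >= n_frames:
                rows.append((cell, az, -1))
            else:
                rows.append((cell, az, int(frames[az])))
    return pd.DataFrame(rows, columns=["cell_id", "az_id", "convert_frame"])
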