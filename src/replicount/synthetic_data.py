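"""Synthetic data generators for every stage of the pipeline.

These simulators reproduce the statistical structure of the experimental
data so that trace idealization, step-size inference, focus detection,
trajectory linking and lifetime inference can all be validated against a
known ground truth:

* bleaching traces: each fluorophore bleaches independently at a fixed
  per-frame rate (default 1/41 per frame), the trace mean is the number of
  surviving fluorophores times the unitary step, and the noise standard
  deviation scales as the square root of the intensity (variance linear in
  intensity), with a one-fluorophore floor at the dark level;
* null traces: constant-mean unit-variance Gaussian series used to
  calibrate and audit false-positive rates;
* single-step traces: one downward transition (one fluorophore to zero)
  with a fixed or exponentially distributed step time;
* image stacks: diffraction-limited spots (2-D Gaussian PSF) planted on
  noisy cell interiors with known on/off schedules and optional drift;
* lifetimes: shifted-exponential disassembly times, frame-quantized and
  right-censored by the observation window;
* stoichiometry samples: draws from a two-Gaussian copy-number mixture.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import IntensityTrace, Idealization

__all__ = [
    "TraceSimConfig",
    "ImageSimConfig",
    "LifetimeSimConfig",
    "FocusSchedule",
    "simulate_bleach_trace",
    "simulate_null_trace",
    "simulate_final_step",
    "simulate_image_stack",
    "simulate_lifetimes",
    "simulate_stoichiometry_samples",
]


@dataclass
class TraceSimConfig:
    """Parameters of a simulated photobleaching trace.

    ``noise_ratio`` is the relative step size Δµ/σ at the one-fluorophore
    level (observed value ~2.5); ``bleach_rate`` is the per-frame bleaching
    probability-rate of a single fluorophore (observed 1/41 per frame).
    """

    n_fluorophores: int
    step_size: float = 1.0
    noise_ratio: float = 2.5
    bleach_rate: float = 1.0 / 41.0
    n_frames: int = 120
    variance_scaling: str = "linear"  # "linear" (in intensity) or "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fluorophores < 0:
            raise ValueError("n_fluorophores must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.noise_ratio <= 0:
            raise ValueError("noise_ratio must be > 0")
        if not 0 < self.bleach_rate < 1:
            raise ValueError("bleach_rate must be in (0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.variance_scaling not in ("linear", "constant"):
            raise ValueError("variance_scaling must be 'linear' or 'constant'")


@dataclass
class FocusSchedule:
    """One planted spot: present on frames [appear_frame, disappear_frame)."""

    cell_id: int
    appear_frame: int
    disappear_frame: int
    position: tuple[float, float]  # (row, col), frame-0 coordinates
    amplitude: float

    def __post_init__(self) -> None:
        if self.appear_frame >= self.disappear_frame:
            raise ValueError("appear_frame must precede disappear_frame")


@dataclass
class ImageSimConfig:
    """Parameters of a simulated fluorescence time-lapse with cell masks."""

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 10
    n_cells: int = 4
    psf_width: float = 1.5  # Gaussian sigma, pixels
    focus_schedule: list[FocusSchedule] = field(default_factory=list)
    background_mean: float = 100.0
    background_noise: float = 5.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 0.16  # um per pixel
    frame_interval: float = 2.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        for spot in self.focus_schedule:
            if spot.disappear_frame > self.n_frames or spot.appear_frame < 0:
                raise ValueError("focus schedule outside the frame range")


@dataclass
class LifetimeSimConfig:
    """Parameters of a censored complex-lifetime experiment."""

    k_true: float  # disassembly rate, 1/min
    n_complexes: int = 300
    window_T: float = 22.0  # minutes
    tau_min: float = 4.0  # minutes
    frame_interval: float = 2.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true <= 0:
            raise ValueError("k_true must be > 0")
        if self.tau_min >= self.window_T:
            raise ValueError("tau_min must be below window_T")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")


def _noise_std(level: int, cfg: TraceSimConfig) -> float:
    sigma1 = cfg.step_size / cfg.noise_ratio
    if cfg.variance_scaling == "constant":
        return sigma1
    # variance linear in intensity, with a one-fluorophore floor at the
    # dark level (camera/background noise never vanishes)
    return sigma1 * np.sqrt(max(level, 1))


def simulate_bleach_trace(
    config: TraceSimConfig,
) -> tuple[IntensityTrace, Idealization]:
    """Simulate one bleaching trace and its ground-truth idealization.

    Each of the ``n_fluorophores`` fluorophores survives a geometric number
    of frames with per-frame bleaching probability ``bleach_rate``; the
    true mean at frame ``t`` is ``step_size`` times the survivor count and
    the noise std at a level of ``m`` fluorophores is
    ``(step_size / noise_ratio) * sqrt(max(m, 1))`` under linear variance
    scaling.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    # number of complete frames each fluorophore survives (>= 1: present
    # in frame 0, may bleach between consecutive frames)
    lifetimes = rng.geometric(config.bleach_rate, size=config.n_fluorophores)
    survivors = (lifetimes[:, None] > np.arange(n)[None, :]).sum(axis=0) if config.n_fluorophores else np.zeros(n, dtype=int)
    means = config.step_size * survivors.astype(float)
    stds = np.array([_noise_std(int(m), config) for m in survivors])
    values = means + rng.standard_normal(n) * stds

    change = np.nonzero(np.diff(survivors))[0] + 1
    bounds = np.concatenate([[0], change, [n]])
    durations = np.diff(bounds).astype(int)
    level_counts = survivors[bounds[:-1]]
    truth = Idealization(
        change_points=change,
        level_means=config.step_size * level_counts.astype(float),
        level_variances=np.array(
            [_noise_std(int(m), config) ** 2 for m in level_counts]
        ),
        level_durations=durations,
    )
    trace = IntensityTrace(values=values, meta={"true_counts": survivors})
    return trace, truth


def simulate_state_dwell_trace(
    n_states: int,
    mean_dwell: float = 41.0,
    step_size: float = 1.0,
    noise_ratio: float = 2.5,
    seed: int = 0,
) -> tuple[IntensityTrace, Idealization]:
    """Simulate a bleaching staircase with per-state exponential dwells.

    Every occupancy state -- ``n_states`` fluorophores down through the
    dark state -- persists for an exponentially distributed number of
    frames with mean ``mean_dwell`` (rounded to whole frames, at least
    one).  This is the state-lifetime convention for stoichiometry
    sweeps: each level is equally resolvable regardless of how many
    fluorophores remain, unlike the per-fluorophore hazard of
    :func:`simulate_bleach_trace` under which high-occupancy levels are
    vanishingly short.  Noise scales as sqrt(intensity) with a
    one-fluorophore floor, as in the main generator.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = np.random.default_rng(seed)
    dwells = np.maximum(1, np.round(rng.exponential(mean_dwell, n_states + 1)).astype(int))
    counts = np.concatenate(
        [np.full(d, m) for m, d in zip(range(n_states, -1, -1), dwells)]
    )
    sigma1 = step_size / noise_ratio
    stds = sigma1 * np.sqrt(np.maximum(counts, 1))
    values = step_size * counts + rng.standard_normal(counts.size) * stds
    truth = Idealization(
        change_points=np.cumsum(dwells)[:-1],
        level_means=step_size * np.arange(n_states, -1, -1, dtype=float),
        level_variances=(sigma1 * np.sqrt(np.maximum(np.arange(n_states, -1, -1), 1))) ** 2,
        level_durations=dwells,
    )
    return IntensityTrace(values=values), truth


def simulate_null_trace(n_frames: int, seed: int = 0) -> IntensityTrace:
    """Constant-mean, unit-variance i.i.d. Gaussian trace (no transitions)."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    return IntensityTrace(values=rng.standard_normal(n_frames))


def simulate_final_step(
    lifetime_mode: str = "exponential",
    mean_lifetime: float = 41.0,
    rel_step: float = 2.5,
    n_frames: int = 120,
    seed: int = 0,
) -> tuple[IntensityTrace, int]:
    """One downward step from ``rel_step`` to 0 in unit-variance noise.

    Emulates the final bleaching transition (one fluorophore to zero).
    The step frame is either fixed at ``mean_lifetime`` or exponentially
    distributed with that mean, rounded to a whole frame and truncated to
    the observation window; a step frame equal to ``n_frames`` means the
    fluorophore outlived the window and no transition occurs.
    Returns the trace and the true step frame.
    """
    if mean_lifetime < 1:
        raise ValueError("mean_lifetime must be >= 1")
    if lifetime_mode not in ("fixed", "exponential"):
        raise ValueError("lifetime_mode must be 'fixed' or 'exponential'")
    rng = np.random.default_rng(seed)
    if lifetime_mode == "fixed":
        step = int(round(mean_lifetime))
    else:
        step = max(1, int(round(rng.exponential(mean_lifetime))))
    step = min(step, n_frames)
    means = np.where(np.arange(n_frames) < step, rel_step, 0.0)
    values = means + rng.standard_normal(n_frames)
    return IntensityTrace(values=values), step


def _make_cell_masks(config: ImageSimConfig) -> np.ndarray:
    """Lay out rod-shaped (capsule) cells on a grid; label image, 0 = background."""
    h, w = config.image_shape
    masks = np.zeros((h, w), dtype=int)
    n = config.n_cells
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ch, cw = h / rows, w / cols
    rr, cc = np.mgrid[0:h, 0:w]
    label = 0
    for i in range(rows):
        for j in range(cols):
            if label >= n:
                break
            label += 1
            cy, cx = (i + 0.5) * ch, (j + 0.5) * cw
            half_len = 0.35 * cw
            radius = min(0.2 * ch, 6.0)
            # capsule along x: distance to the segment of length 2*half_len
            dx = np.clip(np.abs(cc - cx) - half_len, 0, None)
            dy = rr - cy
            inside = dx**2 + dy**2 <= radius**2
            masks[inside] = label
    return masks


def gaussian_spot(
    shape: tuple[int, int],
    position: tuple[float, float],
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    """Render A * exp(-|x - x0|^2 / (2 sigma^2)) over a pixel grid."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - position[0]) ** 2 + (cc - position[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def simulate_image_stack(
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, "pd.DataFrame"]:
    """Simulate a fluorescence stack, labeled cell masks, and spot truth.

    Cells are bright (``background_mean``) capsules on a dim exterior;
    spots are 2-D Gaussians added at their scheduled frames; a global
    linear drift shifts both cells and spots.  The returned ground truth
    table has one row per planted spot per frame with its drifted position
    and integrated intensity ``2 * pi * amplitude * psf_width**2``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    masks0 = _make_cell_masks(config)
    for spot in config.focus_schedule:
        r, c = spot.position
        if masks0[int(round(r)), int(round(c))] != spot.cell_id:
            raise ValueError(
                f"spot at {spot.position} not inside cell {spot.cell_id}"
            )
    stack = np.empty((config.n_frames, h, w))
    masks = np.empty((config.n_frames, h, w), dtype=int)
    rows = []
    for t in range(config.n_frames):
        dr = config.drift_per_frame[0] * t
        dc = config.drift_per_frame[1] * t
        mask_t = np.roll(
            np.roll(masks0, int(round(dr)), axis=0), int(round(dc)), axis=1
        )
        frame = np.where(mask_t > 0, config.background_mean, 0.2 * config.background_mean)
        frame = frame + rng.standard_normal((h, w)) * config.background_noise
        for spot in config.focus_schedule:
            if not (spot.appear_frame <= t < spot.disappear_frame):
                continue
            pos = (spot.position[0] + dr, spot.position[1] + dc)
            frame += gaussian_spot((h, w), pos, spot.amplitude, config.psf_width)
            rows.append(
                {
                    "frame": t,
                    "cell_id": spot.cell_id,
                    "row": pos[0],
                    "col": pos[1],
                    "amplitude": spot.amplitude,
                    "integrated_intensity": 2 * np.pi * spot.amplitude * config.psf_width**2,
                }
            )
        stack[t] = frame
        masks[t] = mask_t
    truth = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "cell_id",
            "row",
            "col",
            "amplitude",
            "integrated_intensity",
        ],
    )
    return stack, masks, truth


def simulate_lifetimes(config: LifetimeSimConfig):
    """Draw censored, frame-quantized complex lifetimes.

    Lifetimes follow the shifted exponential
    ``p(tau | k) = k exp(-k (tau - tau_min))``, are floored to the imaging
    cadence (a lifetime is observable only as a whole number of frame
    intervals), and right-censored at the window ``T``.
    """
    from .lifetime import LifetimeDataset

    rng = np.random.default_rng(config.seed)
    tau = config.tau_min + rng.exponential(1.0 / config.k_true, size=config.n_complexes)
    dt = config.frame_interval
    tau = config.tau_min + np.floor((tau - config.tau_min) / dt) * dt
    censored = tau >= config.window_T
    tau = np.where(censored, config.window_T, tau)
    return LifetimeDataset(
        lifetimes=tau,
        censored=censored,
        window_T=config.window_T,
        tau_min=config.tau_min,
    )


def simulate_stoichiometry_samples(
    mu1: float,
    mu2: float,
    sigma1: float,
    sigma2: float,
    frac_low: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. draws from the two-Gaussian copy-number mixture."""
    if mu1 >= mu2:
        raise ValueError("mu1 must be below mu2")
    if not 0 <= frac_low <= 1:
        raise ValueError("frac_low must be in [0, 1]")
    rng = np.random.default_rng(seed)
    low = rng.random(n) < frac_low
    out = np.where(
        low,
        rng.normal(mu1, sigma1, size=n),
        rng.normal(mu2, sigma2, size=n),
    )
    return out
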