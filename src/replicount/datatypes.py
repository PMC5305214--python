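"""Shared containers for intensity traces and their piecewise-constant idealizations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntensityTrace:
    """A background-subtracted focus intensity time series.

    Parameters
    ----------
    values
        Per-frame focus intensity ``I_F(t)`` (arbitrary camera units).
    frame_interval
        Time between frames. Units are up to the caller (seconds for
        bleaching stacks, minutes for lifetime stacks).
    position
        Optional (row, col) sub-pixel position the trace was extracted at.
    cell_id
        Label of the owning cell in the segmentation mask.
    raw_sum, cell_background
        Optional per-frame raw disk sums ``I_R`` and per-pixel cell
        backgrounds ``I_B`` retained for provenance.
    """

    values: np.ndarray
    frame_interval: float = 1.0
    position: tuple[float, float] | None = None
    cell_id: int | None = None
    raw_sum: np.ndarray | None = None
    cell_background: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Idealization:
    """Piecewise-constant idealization of a trace.

    Levels partition the trace: level ``i`` covers frames
    ``[start_i, start_i + duration_i)`` where ``start_0 = 0`` and
    ``start_{i+1} = start_i + duration_i``.  ``change_points`` holds the
    first frame of each level after the first.  Level uncertainties are the
    standard errors of the level means, ``sqrt(variance / duration)`` --
    the inverse Fisher information of a Gaussian mean.
    """

    change_points: np.ndarray
    level_means: np.ndarray
    level_variances: np.ndarray
    level_durations: np.ndarray

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=int)
        self.level_means = np.asarray(self.level_means, dtype=float)
        self.level_variances = np.asarray(self.level_variances, dtype=float)
        self.level_durations = np.asarray(self.level_durations, dtype=int)
        if not (
            len(self.level_means)
            == len(self.level_variances)
            == len(self.level_durations)
            == len(self.change_points) + 1
        ):
            raise ValueError("inconsistent idealization arrays")

    @property
    def n_levels(self) -> int:
        return len(self.level_means)

    @property
    def n_frames(self) -> int:
        return int(self.level_durations.sum())

    @property
    def level_uncertainties(self) -> np.ndarray:
        """Std of each level mean, sqrt(var / duration)."""
        return np.sqrt(self.level_variances / self.level_durations)

    @property
    def level_starts(self) -> np.ndarray:
        return np.concatenate([[0], self.change_points])

    def reconstruct(self) -> np.ndarray:
        """The smoothed trace I'(t): level means repeated over durations."""
        return np.repeat(self.level_means, self.level_durations)
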