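"""Colour-threshold calibration against control and senescent images.

The colour threshold is set experimentally: the baseline is taken on
control cells (low passage, low confluency, background SA-β-gal activity
only), and a usable threshold must leave the control signal between 0 and
10% of the signal from senescent (or positive-control) cells.  The 10%
bound was chosen for a doxorubicin/H₂O₂-treated VSMC model and may need
revision for other systems, so it is a parameter (``max_control_ratio``).

Among thresholds satisfying the bound, :func:`calibrate_threshold` returns
the one retaining the most senescent signal — the constraint comes from the
method, the retention objective is this package's choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .signal import ColorThreshold, apply_color_threshold, measure_signal

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "default_grid",
    "evaluate_threshold",
    "calibrate_threshold",
]


class CalibrationError(RuntimeError):
    """No threshold in the search grid satisfied the control/senescent bound."""

    def __init__(self, message: str, best_ratio: float | None = None):
        super().__init__(message)
        self.best_ratio = best_ratio


@dataclass(frozen=True)
class CalibrationResult:
    """A threshold with its control and senescent mean integrated densities.

    ``ratio = control_mean_id / senescent_mean_id`` (``inf`` when the
    senescent mean is 0, which always fails).
    """

    threshold: ColorThreshold
    control_mean_id: float
    senescent_mean_id: float
    ratio: float
    max_control_ratio: float = 0.10

    @property
    def passes(self) -> bool:
        return (
            self.senescent_mean_id > 0
            and 0.0 <= self.ratio <= self.max_control_ratio
        )


def _mean_id(images: Sequence[np.ndarray], thr: ColorThreshold, metric: str) -> float:
    total = 0.0
    for img in images:
        mask = apply_color_threshold(img, thr)
        m = measure_signal(img, mask)
        total += m.area_px if metric == "area" else m.integrated_density
    return total / len(images)


def evaluate_threshold(
    controls: Sequence[np.ndarray],
    senescents: Sequence[np.ndarray],
    thr: ColorThreshold,
    max_control_ratio: float = 0.10,
    metric: str = "id",
) -> CalibrationResult:
    """Evaluate one threshold: unweighted mean signal per group and ratio.

    ``metric`` is ``"id"`` (integrated density, the default and the value
    used downstream) or ``"area"`` (positive-pixel count).
    """
    if not len(controls) or not len(senescents):
        raise ValueError("both image groups must be non-empty")
    if metric not in ("id", "area"):
        raise ValueError(f"unknown metric {metric!r}")
    c_mean = _mean_id(controls, thr, metric)
    s_mean = _mean_id(senescents, thr, metric)
    ratio = c_mean / s_mean if s_mean > 0 else math.inf
    return CalibrationResult(thr, c_mean, s_mean, ratio, max_control_ratio)


def default_grid(step: int = 5) -> list[ColorThreshold]:
    """Default calibration search grid.

    Stained pixels are darker in red and green but keep blue, so the grid
    sweeps a common red/green upper bound from 255 down to 0 in steps of
    ``step``, with all minima at 0 and the blue maximum at 255.
    """
    values = list(range(255, -1, -step))
    if values[-1] != 0:
        values.append(0)
    return [
        ColorThreshold(r_min=0, r_max=v, g_min=0, g_max=v, b_min=0, b_max=255)
        for v in values
    ]


def calibrate_threshold(
    controls: Sequence[np.ndarray],
    senescents: Sequence[np.ndarray],
    grid: Iterable[ColorThreshold] | None = None,
    max_control_ratio: float = 0.10,
    metric: str = "id",
) -> CalibrationResult:
    """Exhaustively search a threshold grid for the best passing threshold.

    Returns the candidate with the largest senescent mean signal among
    those with ``ratio <= max_control_ratio``; ties break to the
    lexicographically smallest ``(r_max, g_max)``.  Raises
    :class:`CalibrationError` reporting the best achieved ratio when no
    candidate passes.
    """
    candidates = list(default_grid() if grid is None else grid)
    if not candidates:
        raise ValueError("empty threshold grid")
    best: CalibrationResult | None = None
    best_ratio = math.inf
    for thr in candidates:
        res = evaluate_threshold(
            controls, senescents, thr, max_control_ratio, metric
        )
        best_ratio = min(best_ratio, res.ratio)
        if not res.passes:
            continue
        if (
            best is None
            or res.senescent_mean_id > best.senescent_mean_id
            or (
                res.senescent_mean_id == best.senescent_mean_id
                and (res.threshold.r_max, res.threshold.g_max)
                < (best.threshold.r_max, best.threshold.g_max)
            )
        ):
            best = res
    if best is None:
        raise CalibrationError(
            "no threshold achieved a control/senescent ratio <= "
            f"{max_control_ratio:g}; best achieved ratio was {best_ratio:g}",
            best_ratio=best_ratio,
        )
    return best
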