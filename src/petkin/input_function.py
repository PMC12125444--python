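"""Building the kinetic-model input from a whole-blood blood-pool curve.

An image-derived input function (IDIF) read from a large blood pool (here the
descending aorta) measures *whole-blood* activity. Compartment models need the
activity of unmetabolized (parent) tracer in *plasma*, so two population-based
correction layers are applied before fitting:

1. plasma correction — multiply by the plasma-to-whole-blood activity ratio
   (constant or a piecewise-linear table over time);
2. metabolite correction — multiply by the parent fraction ``p(t)`` (percent
   of plasma activity still carried by intact tracer), modeled bi-exponentially

   ``p(t) = alpha * exp(-(t - t0)/tau1) + (100 - alpha) * exp(-(t - t0)/tau2)``

   for ``t >= t0``, with ``p = 100`` before ``t0`` (no metabolism yet) and the
   result clamped to [0, 100].

The module also provides the delay shift used during joint delay estimation
and the peak-window perturbation used by the IDIF sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import TimeActivityCurve, interpolate_curve

__all__ = [
    "ParentFractionModel",
    "PlasmaRatioModel",
    "InputFunctionSet",
    "parent_fraction",
    "apply_plasma_correction",
    "apply_metabolite_correction",
    "shift_input",
    "perturb_peak",
    "build_input_set",
]

# optimization box for the tracer-arrival delay, seconds
DELAY_BOUNDS_S = (0.0, 20.0)


@dataclass(frozen=True)
class ParentFractionModel:
    """Bi-exponential parent-fraction model.

    alpha is in percent; tau1, tau2 and t0 are minutes.
    """

    alpha: float
    tau1: float
    tau2: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 100.0):
            raise ValueError("alpha must be within [0, 100] percent")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be > 0 min")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0 min")


@dataclass(frozen=True)
class PlasmaRatioModel:
    """Plasma-to-whole-blood activity ratio, piecewise linear in time (min).

    A single entry means a constant ratio; outside the table the nearest end
    value is held (constant extrapolation).
    """

    times: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        ratios = np.atleast_1d(np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ratios", ratios)
        if times.shape != ratios.shape or times.ndim != 1 or times.size == 0:
            raise ValueError("times and ratios must be equal-length 1-D arrays")
        if np.any(ratios <= 0):
            raise ValueError("ratios must be > 0")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def constant(cls, ratio: float) -> "PlasmaRatioModel":
        return cls(times=np.array([0.0]), ratios=np.array([float(ratio)]))

    def at(self, t_min: np.ndarray) -> np.ndarray:
        """Ratio at times ``t_min`` (minutes)."""
        return np.interp(np.asarray(t_min, dtype=float), self.times, self.ratios)


@dataclass(frozen=True, eq=False)
class InputFunctionSet:
    """Whole-blood curve plus its derived plasma and parent-plasma curves.

    All three curves share one frame schedule. C_wb enters the model through
    the blood-volume term; the metabolite-corrected parent plasma curve C_p
    drives tissue exchange.
    """

    whole_blood: TimeActivityCurve
    plasma: TimeActivityCurve
    parent_plasma: TimeActivityCurve
    parent_model: ParentFractionModel
    ratio_model: PlasmaRatioModel

    def __post_init__(self) -> None:
        sched = self.whole_blood.schedule
        if self.plasma.schedule != sched or self.parent_plasma.schedule != sched:
            raise ValueError("all input-function curves must share one schedule")
        t_min = sched.mids / 60.0
        past_t0 = t_min >= self.parent_model.t0
        if np.any(
            self.parent_plasma.values[past_t0] > self.plasma.values[past_t0] + 1e-9
        ):
            raise ValueError("parent plasma exceeds total plasma after t0")

    @property
    def schedule(self):
        return self.whole_blood.schedule


def parent_fraction(t_min: np.ndarray, model: ParentFractionModel) -> np.ndarray:
    """Percent parent fraction at times ``t_min`` (minutes), clamped to [0, 100]."""
    t = np.asarray(t_min, dtype=float)
    dt = t - model.t0
    p = model.alpha * np.exp(-dt / model.tau1) + (100.0 - model.alpha) * np.exp(
        -dt / model.tau2
    )
    p = np.where(dt < 0, 100.0, p)
    return np.clip(p, 0.0, 100.0)


def apply_plasma_correction(
    wb: TimeActivityCurve, ratio: PlasmaRatioModel
) -> TimeActivityCurve:
    """Whole blood -> total plasma via the plasma-to-whole-blood ratio."""
    t_min = wb.schedule.mids / 60.0
    return wb.with_values(wb.values * ratio.at(t_min), label=f"{wb.label}_plasma")


def apply_metabolite_correction(
    plasma: TimeActivityCurve, model: ParentFractionModel
) -> TimeActivityCurve:
    """Total plasma -> parent (unmetabolized) plasma via the parent fraction."""
    t_min = plasma.schedule.mids / 60.0
    p = parent_fraction(t_min, model)
    return plasma.with_values(plasma.values * p / 100.0, label=f"{plasma.label}_parent")


def build_input_set(
    wb: TimeActivityCurve,
    parent_model: ParentFractionModel,
    ratio_model: PlasmaRatioModel,
) -> InputFunctionSet:
    """Derive plasma and parent-plasma curves from a measured whole-blood curve."""
    plasma = apply_plasma_correction(wb, ratio_model)
    parent = apply_metabolite_correction(plasma, parent_model)
    return InputFunctionSet(wb, plasma, parent, parent_model, ratio_model)


def _shift_curve(tac: TimeActivityCurve, delay_s: float) -> TimeActivityCurve:
    mids = tac.schedule.mids
    shifted_t = np.clip(mids - delay_s, 0.0, None)
    return tac.with_values(interpolate_curve(tac, shifted_t))


def shift_input(ifs: InputFunctionSet, delay: float) -> InputFunctionSet:
    """Shift every input curve later in time by ``delay`` seconds.

    Models tracer arriving at the tissue ``delay`` s after it is seen in the
    blood pool; values before the delay are the (0,0)-anchored leading ramp,
    i.e. zero at t < delay for curves starting from zero. Whole blood and
    plasma are shifted together with the parent curve.
    """
    lo, hi = DELAY_BOUNDS_S
    if not (lo <= delay <= hi):
        raise ValueError(f"delay must be within [{lo}, {hi}] s")
    return InputFunctionSet(
        _shift_curve(ifs.whole_blood, delay),
        _shift_curve(ifs.plasma, delay),
        _shift_curve(ifs.parent_plasma, delay),
        ifs.parent_model,
        ifs.ratio_model,
    )


def peak_window(values: np.ndarray) -> slice:
    """The FWHM peak window: contiguous frames >= 50% of max, containing the max."""
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("curve has no positive peak")
    above = v >= 0.5 * vmax
    imax = int(np.argmax(v))
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < v.size - 1 and above[hi + 1]:
        hi += 1
    return slice(lo, hi + 1)


def perturb_peak(
    ifs: InputFunctionSet, factor: float, window: str = "fwhm"
) -> InputFunctionSet:
    """Scale the whole-blood peak by ``factor`` and re-derive the input set.

    The sensitivity analysis refits the model with the peak raised or lowered
    by a few percent; plasma and parent curves are re-derived so all three
    curves stay mutually consistent.

    window:
        'fwhm' (default) scales every sample in the contiguous >=50%-of-max
        run around the maximum; 'max-frame' scales only the single maximum
        sample. The two differ greatly in how much input area they move
        (see docs/methods.md): 'fwhm' perturbs the whole bolus, 'max-frame'
        only its top.
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be > 0")
    values = ifs.whole_blood.values.copy()
    if window == "fwhm":
        values[peak_window(values)] *= factor
    elif window == "max-frame":
        if values.max() <= 0:
            raise ValueError("curve has no positive peak")
        values[int(np.argmax(values))] *= factor
    else:
        raise ValueError("window must be 'fwhm' or 'max-frame'")
    wb = ifs.whole_blood.with_values(values)
    return build_input_set(wb, ifs.parent_model, ifs.ratio_model)
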