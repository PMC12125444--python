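"""Reversible two-tissue compartment model (2TCM) with joint delay estimation.

Model
-----
Plasma parent tracer C_p exchanges with a free/nonspecific tissue compartment
C_1 (rates K1 in, k2 out) which exchanges with a specifically bound
compartment C_2 (k3 in, k4 out):

    dC1/dt = K1*C_p(t - d) - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

The measured PET signal mixes tissue and blood:

    C_T(t) = (1 - vb) * (C1 + C2)(t) + vb * C_wb(t - d)

(a convention switch allows the additive variant C_T = C1 + C2 + vb*C_wb).
The tissue sum has the analytic impulse response

    h(t) = [phi1 * exp(-theta1 t) + phi2 * exp(-theta2 t)]

with macro-rates theta_{1,2} = 0.5*[(k2+k3+k4) +/- sqrt((k2+k3+k4)^2 - 4 k2 k4)]
and amplitudes phi1 = K1 (theta1-k3-k4)/(theta1-theta2),
phi2 = K1 (k3+k4-theta2)/(theta1-theta2); the repeated-root limit
h(t) = K1 (1 + (k3+k4-theta) t) exp(-theta t) is used when theta1 ~ theta2.
(C1+C2) = h (*) C_p on a uniform fine grid (trapezoidal convolution), then
averaged over each frame to match how PET frames integrate the signal.

The total distribution volume is V_T = (K1/k2)(1 + k3/k4), and
DVR = V_T(target)/V_T(reference).

Fitting is bounded weighted least squares over (vb, K1, k2, k3, k4, delay);
the tracer-arrival delay is optimized jointly (continuously within its
bounds), not grid-searched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .curves import FrameSchedule, TimeActivityCurve, interpolate_curve
from .input_function import InputFunctionSet

__all__ = [
    "TwoTissueParams",
    "FitOptions",
    "TwoTissueFit",
    "solve_2tcm",
    "fit_2tcm",
    "compute_vt",
    "compute_dvr",
    "PARAM_BOUNDS",
]

# Optimization box from the study protocol: all five kinetic parameters in
# [0, 1] (vb in mL/mL, K1 in mL.cm^-3.min^-1, k2..k4 in min^-1) and the
# tracer-arrival delay in [0, 20] s.
PARAM_BOUNDS = {
    "vb": (0.0, 1.0),
    "K1": (0.0, 1.0),
    "k2": (0.0, 1.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 1.0),
    "delay": (0.0, 20.0),
}

_PARAM_ORDER = ("vb", "K1", "k2", "k3", "k4", "delay")


@dataclass(frozen=True)
class TwoTissueParams:
    """2TCM parameter vector. Rates are min^-1 (K1 mL.cm^-3.min^-1), delay s."""

    vb: float
    K1: float
    k2: float
    k3: float
    k4: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            lo, hi = PARAM_BOUNDS[name]
            val = getattr(self, name)
            if not np.isfinite(val) or not (lo - 1e-12 <= val <= hi + 1e-12):
                raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_ORDER])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "TwoTissueParams":
        return cls(**dict(zip(_PARAM_ORDER, (float(v) for v in x))))


@dataclass(frozen=True)
class FitOptions:
    """Options for the bounded weighted least-squares fit.

    weighting:
        'duration' (default) weights each frame proportionally to its
        duration, down-weighting the noisy 2-s frames; 'uniform' weights all
        frames equally.
    vb_convention:
        'one-minus-vb' uses C_T = (1-vb)(C1+C2) + vb*C_wb; 'additive' uses
        C_T = (C1+C2) + vb*C_wb.
    grid_step:
        uniform fine-grid step for the convolution, seconds.
    """

    bounds: dict = field(default_factory=lambda: dict(PARAM_BOUNDS))
    initials: dict = field(
        default_factory=lambda: {
            "vb": 0.01, "K1": 0.01, "k2": 0.01, "k3": 0.01, "k4": 0.01,
            "delay": 5.0,
        }
    )
    weighting: str = "duration"
    vb_convention: str = "one-minus-vb"
    grid_step: float = 1.0
    max_restarts: int = 5
    restart_seed: int = 20260925

    def __post_init__(self) -> None:
        if self.weighting not in ("duration", "uniform"):
            raise ValueError("weighting must be 'duration' or 'uniform'")
        if self.vb_convention not in ("one-minus-vb", "additive"):
            raise ValueError("vb_convention must be 'one-minus-vb' or 'additive'")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0 s")


@dataclass(frozen=True)
class TwoTissueFit:
    """Result of a 2TCM fit, with the macro-parameter V_T when defined."""

    params: TwoTissueParams
    vt: float | None
    residual_sumsq: float
    converged: bool
    n_frames_used: int
    model_curve: TimeActivityCurve

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "vt": self.vt,
            "residual_sumsq": self.residual_sumsq,
            "converged": self.converged,
            "n_frames_used": self.n_frames_used,
        }


def _impulse_response(params: TwoTissueParams, t_min: np.ndarray) -> np.ndarray:
    """Analytic tissue impulse response h(t) of the reversible 2TCM, t in min."""
    k2, k3, k4 = params.k2, params.k3, params.k4
    K1 = params.K1
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4  # >= (k2-k4)^2 + ... >= 0 for non-negative rates
    root = np.sqrt(max(disc, 0.0))
    theta1 = 0.5 * (s + root)
    theta2 = 0.5 * (s - root)
    if root > 1e-10 * max(s, 1.0):
        phi1 = K1 * (theta1 - k3 - k4) / root
        phi2 = K1 * (k3 + k4 - theta2) / root
        return phi1 * np.exp(-theta1 * t_min) + phi2 * np.exp(-theta2 * t_min)
    # repeated root: h = K1 (1 + (k3+k4-theta) t) e^{-theta t}
    theta = 0.5 * s
    return K1 * (1.0 + (k3 + k4 - theta) * t_min) * np.exp(-theta * t_min)


class _ForwardModel:
    """Pre-computed fine-grid machinery for repeated 2TCM evaluations.

    Building the fine grid, the input interpolants and the frame-boundary
    bookkeeping once per fit makes the optimizer's many forward evaluations
    cheap.
    """

    def __init__(
        self,
        ifs: InputFunctionSet,
        schedule: FrameSchedule,
        grid_step: float = 1.0,
        vb_convention: str = "one-minus-vb",
    ):
        self.schedule = schedule
        self.vb_convention = vb_convention
        end = schedule.total_seconds
        n = int(np.ceil(end / grid_step)) + 1
        self.t_s = np.linspace(0.0, end, n)
        self.dt_min = (self.t_s[1] - self.t_s[0]) / 60.0
        self.t_min = self.t_s / 60.0
        # interpolation nodes of the (0,0)-anchored input curves
        in_end = ifs.schedule.total_seconds
        if in_end + 1e-9 < end:
            raise ValueError("input curves do not cover the tissue schedule")
        self._cp_nodes_t = np.concatenate([[0.0], ifs.schedule.mids])
        self._cp_nodes_v = np.concatenate([[0.0], ifs.parent_plasma.values])
        self._wb_nodes_v = np.concatenate([[0.0], ifs.whole_blood.values])
        # frame-average weights: cumulative trapezoid evaluated at boundaries
        self._bounds_s = np.concatenate([schedule.starts, [end]])

    def _shifted(self, nodes_v: np.ndarray, delay_s: float) -> np.ndarray:
        return np.interp(self.t_s - delay_s, self._cp_nodes_t, nodes_v)

    def _frame_average(self, fine: np.ndarray) -> np.ndarray:
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (fine[1:] + fine[:-1]) * np.diff(self.t_s))]
        )
        at_bounds = np.interp(self._bounds_s, self.t_s, cum)
        return np.diff(at_bounds) / self.schedule.durations

    def frame_values(self, params: TwoTissueParams) -> np.ndarray:
        cp = self._shifted(self._cp_nodes_v, params.delay)
        wb = self._shifted(self._wb_nodes_v, params.delay)
        h = _impulse_response(params, self.t_min)
        n = cp.size
        conv = fftconvolve(cp, h)[:n] * self.dt_min
        # trapezoid end correction; cp[0 - delay] is 0 by the (0,0) anchor
        conv -= 0.5 * self.dt_min * (cp * h[0] + cp[0] * h)
        tissue = conv
        if self.vb_convention == "one-minus-vb":
            fine = (1.0 - params.vb) * tissue + params.vb * wb
        else:
            fine = tissue + params.vb * wb
        return self._frame_average(fine)


def solve_2tcm(
    params: TwoTissueParams,
    ifs: InputFunctionSet,
    schedule: FrameSchedule,
    grid_step: float = 1.0,
    vb_convention: str = "one-minus-vb",
    label: str = "model",
) -> TimeActivityCurve:
    """Forward-model the frame-averaged tissue TAC for given 2TCM parameters."""
    fm = _ForwardModel(ifs, schedule, grid_step, vb_convention)
    return TimeActivityCurve(schedule, fm.frame_values(params), label)


def _weights(schedule: FrameSchedule, weighting: str) -> np.ndarray:
    if weighting == "duration":
        w = schedule.durations / schedule.durations.sum() * schedule.n_frames
    else:
        w = np.ones(schedule.n_frames)
    return w


def fit_2tcm(
    tac: TimeActivityCurve,
    ifs: InputFunctionSet,
    opts: FitOptions | None = None,
) -> TwoTissueFit:
    """Fit the reversible 2TCM to a tissue TAC by bounded weighted least squares.

    The tracer-arrival delay is a free parameter estimated jointly with the
    five kinetic parameters. Deterministic: restarts (used only on optimizer
    non-convergence) draw jittered initials from a fixed seed.
    """
    opts = opts or FitOptions()
    if not np.all(np.isfinite(tac.values)):
        raise ValueError("TAC contains non-finite values")
    fm = _ForwardModel(ifs, tac.schedule, opts.grid_step, opts.vb_convention)
    sqrt_w = np.sqrt(_weights(tac.schedule, opts.weighting))
    obs = tac.values

    lo = np.array([opts.bounds[n][0] for n in _PARAM_ORDER])
    hi = np.array([opts.bounds[n][1] for n in _PARAM_ORDER])
    x0 = np.array([opts.initials[n] for n in _PARAM_ORDER])
    x0 = np.clip(x0, lo, hi)
    # characteristic scales: rates ~0.1, delay ~5 s
    x_scale = np.array([0.05, 0.1, 0.1, 0.05, 0.05, 5.0])

    def residuals(x: np.ndarray) -> np.ndarray:
        model = fm.frame_values(TwoTissueParams.from_array(np.clip(x, lo, hi)))
        return sqrt_w * (model - obs)

    def run(x_init: np.ndarray):
        return least_squares(
            residuals,
            x_init,
            bounds=(lo, hi),
            method="trf",
            x_scale=x_scale,
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=4000,
        )

    res = run(x0)
    if not res.success:
        rng = np.random.default_rng(opts.restart_seed)
        for _ in range(opts.max_restarts):
            jitter = x0 * rng.uniform(0.5, 2.0, size=x0.size)
            jitter[-1] = rng.uniform(lo[-1], hi[-1])  # delay jittered over its box
            res_j = run(np.clip(jitter, lo, hi))
            if res_j.cost < res.cost:
                res = res_j
            if res.success:
                break

    params = TwoTissueParams.from_array(res.x)
    try:
        vt = compute_vt(params)
    except ValueError:
        vt = None
    model_curve = TimeActivityCurve(tac.schedule, fm.frame_values(params), "fit")
    return TwoTissueFit(
        params=params,
        vt=vt,
        residual_sumsq=float(2.0 * res.cost),
        converged=bool(res.success),
        n_frames_used=tac.schedule.n_frames,
        model_curve=model_curve,
    )


def compute_vt(params: TwoTissueParams) -> float:
    """Total distribution volume V_T = (K1/k2)(1 + k3/k4), mL/cm^3."""
    if params.k2 <= 0 or params.k4 <= 0:
        raise ValueError("V_T undefined: k2 and k4 must be > 0")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


def compute_dvr(vt_target: float, vt_reference: float) -> float:
    """Distribution volume ratio V_T(target) / V_T(reference)."""
    if vt_reference <= 0:
        raise ValueError("reference V_T must be > 0")
    return vt_target / vt_reference
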