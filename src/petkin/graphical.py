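"""Logan graphical analysis of the total distribution volume V_T.

For a reversible tracer, plotting

    y(t) = int_0^t C_T du / C_T(t)   against   x(t) = int_0^t C_p du / C_T(t)

becomes linear for t beyond an equilibration time t*; the slope of the late
linear segment estimates V_T and the offset is the intercept (minutes). The
input C_p is the metabolite-corrected parent plasma curve; no delay shift is
applied (the arrival delay is a compartment-model concept, and the late-time
integrals are insensitive to a few seconds of shift), though a fitted delay
may be supplied to reuse it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import linregress

from .curves import TimeActivityCurve, integrate_curve
from .input_function import InputFunctionSet, shift_input

__all__ = ["LoganResult", "logan_vt"]


@dataclass(frozen=True)
class LoganResult:
    vt: float
    intercept: float
    tstar: float
    n_points: int
    r_squared: float


def logan_vt(
    tac: TimeActivityCurve,
    ifs: InputFunctionSet,
    tstar: float = 20.0,
    delay: float = 0.0,
) -> LoganResult:
    """Estimate V_T by ordinary least squares on the Logan transform.

    Frames whose mid-time is at or beyond ``tstar`` (minutes) enter the
    regression; frames where C_T is not positive are excluded with a warning.
    At least 3 usable points are required.
    """
    if delay != 0.0:
        ifs = shift_input(ifs, delay)
    cp = ifs.parent_plasma
    mids_min = tac.schedule.mids / 60.0
    xs, ys = [], []
    n_excluded = 0
    for i, t_mid in enumerate(mids_min):
        if t_mid < tstar:
            continue
        ct = tac.values[i]
        if ct <= 0:
            n_excluded += 1
            continue
        t_s = tac.schedule.mids[i]
        ys.append(integrate_curve(tac, t_s) / ct)
        xs.append(integrate_curve(cp, t_s) / ct)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} frame(s) with non-positive C_T from the "
            "Logan regression",
            stacklevel=2,
        )
    if len(xs) < 3:
        raise ValueError(
            f"Logan regression needs >= 3 points with mid-time >= {tstar} min "
            f"and positive C_T; got {len(xs)}"
        )
    fit = linregress(xs, ys)
    return LoganResult(
        vt=float(fit.slope),
        intercept=float(fit.intercept),
        tstar=float(tstar),
        n_points=len(xs),
        r_squared=float(fit.rvalue**2),
    )
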