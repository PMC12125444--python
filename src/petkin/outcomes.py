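"""SUVR, scan-duration stability, IDIF sensitivity, and supporting statistics.

The semi-quantitative standardized uptake value ratio (SUVR) divides the
duration-weighted mean activity of a target region over a late window by the
same quantity in the reference region (inferior cerebellum; windows 60-90 min
and, exploratorily, 45-75 min).

The scan-duration analysis refits every subject and region on truncated data
(10..90 min in 10-min steps) and correlates each parameter at each duration
with its full-scan (90-min) estimate across subjects, with Benjamini-Hochberg
FDR over the whole parameter x duration family.

The sensitivity analysis scales the IDIF FWHM peak window by fixed factors
(0.90, 0.95, 1.05, 1.10), refits, and reports percent changes per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .curves import TimeActivityCurve, truncate_to_duration
from .input_function import InputFunctionSet, perturb_peak
from .kinetics import FitOptions, TwoTissueFit, compute_dvr, fit_2tcm

__all__ = [
    "SuvrResult",
    "DurationTable",
    "SensitivityTable",
    "compute_suvr",
    "duration_analysis",
    "sensitivity_analysis",
    "pearson",
    "bh_fdr",
    "KINETIC_PARAM_NAMES",
]

#: Parameters reported by the stability analysis.
KINETIC_PARAM_NAMES = ("vb", "K1", "k2", "k3", "k4", "delay", "vt", "dvr")

DEFAULT_DURATIONS = tuple(range(10, 100, 10))
DEFAULT_FACTORS = (0.90, 0.95, 1.05, 1.10)
DEFAULT_WINDOWS = ((60.0, 90.0), (45.0, 75.0))


@dataclass(frozen=True)
class SuvrResult:
    value: float
    window_start: float
    window_end: float
    target_label: str
    reference_label: str


@dataclass(frozen=True)
class DurationTable:
    """Tidy per-fit estimates plus across-subject correlations per duration.

    estimates:
        one row per subject x ROI x duration x parameter (column ``value``).
    correlations:
        one row per ROI x duration x parameter with Pearson ``r``, ``p``,
        BH-adjusted ``q`` and the pairwise-complete sample size ``n``.
    """

    estimates: pd.DataFrame
    correlations: pd.DataFrame
    durations: tuple


@dataclass(frozen=True)
class SensitivityTable:
    """Percent change of each fitted parameter per peak-scaling factor.

    ``delay`` is reported as an absolute change in seconds (a percent change
    of a near-zero delay is not meaningful); everything else as
    100*(perturbed - base)/base.
    """

    table: pd.DataFrame
    base_fit: TwoTissueFit

    def max_abs_change(self, params: tuple[str, ...]) -> float:
        sub = self.table[self.table["parameter"].isin(params)]
        return float(sub["change"].abs().max())


def compute_suvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: tuple[float, float],
) -> SuvrResult:
    """Duration-weighted mean ratio over frames fully inside ``window`` (min)."""
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValueError("window end must exceed window start")

    def window_mean(tac: TimeActivityCurve) -> float:
        sched = tac.schedule
        inside = (sched.starts >= start * 60.0 - 1e-9) & (
            sched.ends <= end * 60.0 + 1e-9
        )
        if not np.any(inside):
            raise ValueError(
                f"no frame fully inside the {start:g}-{end:g} min window"
            )
        d = sched.durations[inside]
        return float(np.sum(tac.values[inside] * d) / np.sum(d))

    ref_mean = window_mean(reference)
    if ref_mean <= 0:
        raise ValueError("reference mean activity must be > 0")
    return SuvrResult(
        value=window_mean(target) / ref_mean,
        window_start=start,
        window_end=end,
        target_label=target.label,
        reference_label=reference.label,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _truncate_ifs(ifs: InputFunctionSet, T: float) -> InputFunctionSet:
    return InputFunctionSet(
        truncate_to_duration(ifs.whole_blood, T),
        truncate_to_duration(ifs.plasma, T),
        truncate_to_duration(ifs.parent_plasma, T),
        ifs.parent_model,
        ifs.ratio_model,
    )


def _fit_row(fit: TwoTissueFit, ref_vt: float | None) -> dict[str, float]:
    p = fit.params
    row = {
        "vb": p.vb, "K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
        "delay": p.delay,
        "vt": fit.vt if fit.vt is not None else np.nan,
    }
    if ref_vt is not None and fit.vt is not None and ref_vt > 0:
        row["dvr"] = compute_dvr(fit.vt, ref_vt)
    else:
        row["dvr"] = np.nan
    return row


def duration_analysis(
    cohort,
    durations=DEFAULT_DURATIONS,
    opts: FitOptions | None = None,
    reference_roi: str = "inferior_cerebellum",
) -> DurationTable:
    """Refit every subject/ROI at each scan duration and correlate vs 90 min.

    ``cohort`` is a sequence of objects with ``subject_id``, ``tacs`` (dict
    roi -> TAC) and ``ifs`` attributes (e.g. SyntheticSubject). Fit failures
    are recorded as missing and excluded pairwise from the correlations.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ValueError("duration analysis needs >= 3 subjects for correlations")
    durations = tuple(float(d) for d in durations)
    full = max(durations)
    opts = opts or FitOptions()

    records = []
    for subj in cohort:
        for T in durations:
            ifs_T = _truncate_ifs(subj.ifs, T)
            ref_vt = None
            fits: dict[str, TwoTissueFit | None] = {}
            rois = list(subj.tacs)
            if reference_roi in rois:  # fit the reference first for DVR
                rois.remove(reference_roi)
                rois.insert(0, reference_roi)
            for roi in rois:
                try:
                    fit = fit_2tcm(truncate_to_duration(subj.tacs[roi], T), ifs_T, opts)
                except ValueError:
                    fit = None
                fits[roi] = fit
                if roi == reference_roi and fit is not None:
                    ref_vt = fit.vt
            for roi, fit in fits.items():
                if fit is None:
                    warnings.warn(
                        f"{subj.subject_id}/{roi}: fit failed at {T:g} min; "
                        "recorded as missing",
                        stacklevel=2,
                    )
                    continue
                row = _fit_row(fit, None if roi == reference_roi else ref_vt)
                for name, value in row.items():
                    records.append(
                        {
                            "subject": subj.subject_id,
                            "roi": roi,
                            "duration_min": T,
                            "parameter": name,
                            "value": value,
                            "converged": fit.converged,
                        }
                    )
    estimates = pd.DataFrame.from_records(records)

    corr_rows = []
    wide = estimates.pivot_table(
        index=["subject"], columns=["roi", "duration_min", "parameter"],
        values="value", aggfunc="first",
    )
    for roi in estimates["roi"].unique():
        for T in durations:
            for name in KINETIC_PARAM_NAMES:
                if (roi, full, name) not in wide.columns or (roi, T, name) not in wide.columns:
                    continue
                x = wide[(roi, T, name)]
                y = wide[(roi, full, name)]
                ok = x.notna() & y.notna()
                n = int(ok.sum())
                if T == full:
                    # self-correlation: exactly 1 when the parameter varies
                    r, p = (1.0, 0.0) if n >= 3 and np.ptp(y[ok]) > 0 else (np.nan, np.nan)
                elif n >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                    r, p = pearson(x[ok].to_numpy(), y[ok].to_numpy())
                else:
                    r, p = np.nan, np.nan
                corr_rows.append(
                    {"roi": roi, "duration_min": T, "parameter": name,
                     "r": r, "p": p, "n": n}
                )
    correlations = pd.DataFrame.from_records(corr_rows)
    finite_p = correlations["p"].notna() & (correlations["duration_min"] != full)
    correlations["q"] = np.nan
    if finite_p.any():
        correlations.loc[finite_p, "q"] = bh_fdr(correlations.loc[finite_p, "p"].to_numpy())
    return DurationTable(estimates=estimates, correlations=correlations, durations=durations)


def sensitivity_analysis(
    tac: TimeActivityCurve,
    ifs: InputFunctionSet,
    factors=DEFAULT_FACTORS,
    opts: FitOptions | None = None,
    window: str = "fwhm",
) -> SensitivityTable:
    """Perturb the IDIF peak window by each factor, refit, report % changes."""
    opts = opts or FitOptions()
    base = fit_2tcm(tac, ifs, opts)
    if not base.converged:
        raise RuntimeError(
            "base fit did not converge; sensitivity analysis aborted "
            f"(residual_sumsq={base.residual_sumsq:.3g})"
        )
    rows = []
    for factor in factors:
        fit = fit_2tcm(tac, perturb_peak(ifs, float(factor), window), opts)
        bp, pp = base.params, fit.params
        for name in ("vb", "K1", "k2", "k3", "k4"):
            b, v = getattr(bp, name), getattr(pp, name)
            change = 100.0 * (v - b) / b if b != 0 else np.nan
            rows.append({"factor": factor, "parameter": name, "change": change,
                         "unit": "%", "converged": fit.converged})
        if base.vt is not None and fit.vt is not None:
            rows.append({"factor": factor, "parameter": "vt",
                         "change": 100.0 * (fit.vt - base.vt) / base.vt,
                         "unit": "%", "converged": fit.converged})
        rows.append({"factor": factor, "parameter": "delay",
                     "change": pp.delay - bp.delay, "unit": "s",
                     "converged": fit.converged})
    return SensitivityTable(table=pd.DataFrame.from_records(rows), base_fit=base)
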