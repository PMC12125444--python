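"""Readers and writers: TAC CSV files, correction configs, NIfTI ROI extraction.

TAC file dialect: delimited text with a required header and columns
``frame_start_s, frame_duration_s, value_kBq_per_mL``, one row per frame,
dot-decimal only. Frame timing in image headers is never trusted; the
schedule in the TAC/schedule file is authoritative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FrameSchedule, TimeActivityCurve
from .input_function import ParentFractionModel, PlasmaRatioModel

__all__ = [
    "read_tac",
    "write_tac",
    "read_correction_config",
    "write_correction_config",
    "extract_roi_tac",
]

TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "value_kBq_per_mL")


class TacParseError(ValueError):
    """Malformed TAC file, with the offending line when identifiable."""


def read_tac(path: str | Path, label: str | None = None) -> TimeActivityCurve:
    """Read a TAC CSV/TSV; the label defaults to the file stem."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise TacParseError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise TacParseError(f"{path}: missing required column(s) {missing}")
    data = {}
    for col in TAC_COLUMNS:
        try:
            data[col] = df[col].astype(float).to_numpy()
        except ValueError:
            for i, raw in enumerate(df[col]):
                try:
                    float(raw)
                except (TypeError, ValueError):
                    raise TacParseError(
                        f"{path}: line {i + 2}: cannot parse {col}={raw!r} "
                        "(dot-decimal numbers required)"
                    ) from None
            raise
    starts, durations = data["frame_start_s"], data["frame_duration_s"]
    if np.any(durations <= 0):
        bad = int(np.argmax(durations <= 0))
        raise TacParseError(f"{path}: line {bad + 2}: non-positive frame duration")
    expected = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    if not np.allclose(starts, expected, rtol=0, atol=1e-9):
        bad = int(np.argmax(~np.isclose(starts, expected, rtol=0, atol=1e-9)))
        raise TacParseError(
            f"{path}: line {bad + 2}: frame_start_s={starts[bad]:g} breaks the "
            f"contiguous frame order (expected {expected[bad]:g})"
        )
    schedule = FrameSchedule(starts=expected, durations=durations)
    return TimeActivityCurve(
        schedule, data["value_kBq_per_mL"], label if label is not None else path.stem
    )


def write_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    """Write a TAC with fixed 6-significant-digit formatting (deterministic)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    sched = tac.schedule
    with open(path, "w") as fh:
        fh.write(sep.join(TAC_COLUMNS) + "\n")
        for s, d, v in zip(sched.starts, sched.durations, tac.values):
            fh.write(sep.join(f"{x:.6g}" for x in (s, d, v)) + "\n")


def write_correction_config(
    path: str | Path,
    parent: ParentFractionModel,
    ratio: PlasmaRatioModel,
) -> None:
    payload: dict = {
        "alpha_percent": parent.alpha,
        "tau1_min": parent.tau1,
        "tau2_min": parent.tau2,
        "t0_min": parent.t0,
    }
    if ratio.times.size == 1:
        payload["ratio_constant"] = float(ratio.ratios[0])
    else:
        payload["ratio_times_min"] = [float(t) for t in ratio.times]
        payload["ratio_values"] = [float(r) for r in ratio.ratios]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_correction_config(
    path: str | Path,
) -> tuple[ParentFractionModel, PlasmaRatioModel]:
    """Read correction models from JSON or ``key = value`` plain text."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        payload = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            payload[key.strip()] = json.loads(value.strip())
    required = ("alpha_percent", "tau1_min", "tau2_min", "t0_min")
    missing = [k for k in required if k not in payload]
    if missing:
        raise ValueError(f"{path}: missing correction key(s) {missing}")
    parent = ParentFractionModel(
        alpha=float(payload["alpha_percent"]),
        tau1=float(payload["tau1_min"]),
        tau2=float(payload["tau2_min"]),
        t0=float(payload["t0_min"]),
    )
    if "ratio_constant" in payload:
        ratio = PlasmaRatioModel.constant(float(payload["ratio_constant"]))
    elif "ratio_times_min" in payload and "ratio_values" in payload:
        ratio = PlasmaRatioModel(
            times=np.asarray(payload["ratio_times_min"], dtype=float),
            ratios=np.asarray(payload["ratio_values"], dtype=float),
        )
    else:
        raise ValueError(
            f"{path}: need either ratio_constant or ratio_times_min/ratio_values"
        )
    return parent, ratio


def extract_roi_tac(volume, mask, schedule: FrameSchedule, label: str = "roi") -> TimeActivityCurve:
    """Mean in-mask voxel value per frame from a 4D dynamic volume.

    ``volume`` and ``mask`` may be nibabel images or arrays; with images the
    affines must match exactly (no resampling is performed). The frame count
    of the volume must equal the schedule's; header timing is ignored.
    """
    vol_affine = mask_affine = None
    if hasattr(volume, "get_fdata"):
        vol_affine = volume.affine
        volume = volume.get_fdata()
    if hasattr(mask, "get_fdata"):
        mask_affine = mask.affine
        mask = mask.get_fdata()
    if vol_affine is not None and mask_affine is not None and not np.allclose(
        vol_affine, mask_affine, rtol=0, atol=1e-6
    ):
        raise ValueError("volume and mask orientation (affine) differ; no resampling is done")
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 4:
        raise ValueError("dynamic volume must be 4-D (x, y, z, frame)")
    if mask.shape != volume.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid {volume.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if volume.shape[3] != schedule.n_frames:
        raise ValueError(
            f"volume has {volume.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    values = volume[mask].mean(axis=0)
    return TimeActivityCurve(schedule, values, label)
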