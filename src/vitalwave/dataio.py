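"""File formats: trace CSV/NPZ bundles, cube bundles, vitals and feature tables.

CSV dialect everywhere: comma separated, '.' decimal, mandatory header
row, UTF-8.  Traces travel as two-column CSV (time_s, displacement_mm)
with a JSON sidecar for annotations, or as a single NPZ bundle.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EvalReport, LabeledDataset
from .features import FEATURE_NAMES, FeatureVector
from .radar_dsp import VitalSigns
from .synth import DisplacementTrace, Pattern, RadarCube, RadarParams


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace_csv(trace: DisplacementTrace, path) -> Path:
    """Write (time_s, displacement_mm) CSV plus a JSON annotation sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time, "displacement_mm": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "sampling_rate": trace.sampling_rate,
        "truth_pattern": trace.truth_pattern.value if trace.truth_pattern else None,
        "truth_apnea_intervals": [list(map(int, iv)) for iv in trace.truth_apnea_intervals],
        "rng_seed": trace.rng_seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace_csv(path) -> DisplacementTrace:
    """Read a trace CSV; the JSON sidecar is used when present, else the
    sampling rate is inferred from the time column."""
    path = Path(path)
    df = pd.read_csv(path)
    samples = df["displacement_mm"].to_numpy(float)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        return DisplacementTrace(
            samples=samples,
            sampling_rate=float(meta["sampling_rate"]),
            truth_pattern=Pattern(meta["truth_pattern"]) if meta.get("truth_pattern") else None,
            truth_apnea_intervals=[tuple(iv) for iv in meta.get("truth_apnea_intervals", [])],
            rng_seed=meta.get("rng_seed"),
        )
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return DisplacementTrace(samples=samples, sampling_rate=fs)


def save_trace_npz(trace: DisplacementTrace, path) -> Path:
    path = Path(path)
    np.savez(
        path,
        samples=trace.samples,
        sampling_rate=trace.sampling_rate,
        truth_pattern=trace.truth_pattern.value if trace.truth_pattern else "",
        truth_apnea_intervals=np.array(trace.truth_apnea_intervals, dtype=int).reshape(-1, 2),
        rng_seed=-1 if trace.rng_seed is None else trace.rng_seed,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_trace_npz(path) -> DisplacementTrace:
    with np.load(path, allow_pickle=False) as z:
        pattern = str(z["truth_pattern"])
        seed = int(z["rng_seed"])
        return DisplacementTrace(
            samples=z["samples"],
            sampling_rate=float(z["sampling_rate"]),
            truth_pattern=Pattern(pattern) if pattern else None,
            truth_apnea_intervals=[tuple(iv) for iv in z["truth_apnea_intervals"]],
            rng_seed=None if seed < 0 else seed,
        )


def save_cube_npz(cube: RadarCube, path) -> Path:
    path = Path(path)
    p = cube.params
    np.savez(
        path,
        data_real=cube.data.real,
        data_imag=cube.data.imag,
        params=np.array(
            [p.bandwidth_b, p.n_chirps, p.chirp_duration, p.start_freq, p.slow_rate, p.fast_rate]
        ),
        target_base_range_m=cube.target_base_range_m,
        dropped_frames=np.array(cube.dropped_frames, dtype=int),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_cube_npz(path) -> RadarCube:
    with np.load(path, allow_pickle=False) as z:
        b, n, tc, fc, fs, ff = z["params"]
        params = RadarParams(
            bandwidth_b=float(b),
            n_chirps=int(n),
            chirp_duration=float(tc),
            start_freq=float(fc),
            slow_rate=float(fs),
            fast_rate=float(ff),
        )
        return RadarCube(
            data=z["data_real"] + 1j * z["data_imag"],
            params=params,
            target_base_range_m=float(z["target_base_range_m"]),
            dropped_frames=z["dropped_frames"].tolist(),
        )


def write_vitals_csv(vs: VitalSigns, path, report_path=None) -> Path:
    """Write (time_s, respiration, heart) CSV; optional JSON rate report."""
    path = Path(path)
    t = np.arange(len(vs.respiration)) / vs.sampling_rate
    pd.DataFrame(
        {"time_s": t, "respiration": vs.respiration, "heart": vs.heart}
    ).to_csv(path, index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps({"sampling_rate": vs.sampling_rate}))
    if report_path is not None:
        Path(report_path).write_text(
            json.dumps(
                {
                    "resp_rate_bpm": vs.resp_rate_bpm,
                    "resp_confidence": vs.resp_confidence,
                    "heart_rate_bpm": vs.heart_rate_bpm,
                    "heart_confidence": vs.heart_confidence,
                },
                indent=1,
            )
        )
    return path


def read_vitals_csv(path) -> VitalSigns:
    path = Path(path)
    df = pd.read_csv(path)
    side = _sidecar(path)
    if side.exists():
        fs = float(json.loads(side.read_text())["sampling_rate"])
    else:
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
    return VitalSigns(
        respiration=df["respiration"].to_numpy(float),
        heart=df["heart"].to_numpy(float),
        sampling_rate=fs,
    )


def write_features_csv(features: list[FeatureVector], path) -> Path:
    path = Path(path)
    rows = []
    for fv in features:
        row = {name: getattr(fv, name) for name in FEATURE_NAMES}
        row["label"] = fv.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_features_csv(path) -> LabeledDataset:
    df = pd.read_csv(path)
    return LabeledDataset(
        features=df[list(FEATURE_NAMES)].to_numpy(float),
        labels=df["label"].to_numpy(int),
    )


def write_eval_report(report: EvalReport, path, confusion_csv=None) -> Path:
    path = Path(path)
    payload = {
        "accuracy": report.accuracy,
        "kappa": report.kappa,
        "per_fold_accuracy": list(report.per_fold),
        "confusion_rows_true_cols_predicted": report.confusion.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    if confusion_csv is not None:
        labels = [str(i + 1) for i in range(report.confusion.shape[0])]
        pd.DataFrame(report.confusion, index=labels, columns=labels).to_csv(
            confusion_csv, index_label="true\\predicted"
        )
    return path
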