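"""End-to-end orchestration: simulate -> demodulate -> apnea -> featurize -> classify.

Every stage writes its artifacts under the run directory and records a
SHA-256 hash in the manifest, so identical config + seed reproduce
identical manifests.  All randomness flows from the single run seed
through named per-stage substreams.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import apnea as ap
from . import classify as cl
from . import dataio, features as ft, radar_dsp as dsp, synth
from .config import RunConfig
from .synth import Pattern, PATTERN_LABELS

log = logging.getLogger("vitalwave")


def _substream(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    h = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def featurize_trace(trace: synth.DisplacementTrace, bands=((0.1, 0.6), (0.8, 4.0))):
    """Respiration-band filter a trace and extract its 8 pattern features."""
    vs = dsp.bandpass_separate(
        trace.samples, trace.sampling_rate, resp_band=tuple(bands[0]), heart_band=tuple(bands[1])
    )
    label = PATTERN_LABELS.get(trace.truth_pattern)
    return ft.extract_features(vs.respiration, trace.sampling_rate, label=label)


def build_feature_dataset(
    n_per_pattern: int,
    seed: int = 0,
    duration_s: float = 60.0,
    sampling_rate: float = 20.0,
    noise_sigma_mm: float = 0.1,
    patterns=tuple(PATTERN_LABELS),
) -> cl.LabeledDataset:
    """Labelled feature matrix from seeded synthetic traces (one seed per trace)."""
    rows, labels = [], []
    i = 0
    for pattern in patterns:
        for _ in range(n_per_pattern):
            trace = synth.random_trace(
                pattern,
                seed=_substream(seed, "trace", i),
                duration_s=duration_s,
                sampling_rate=sampling_rate,
                noise_sigma_mm=noise_sigma_mm,
            )
            fv = featurize_trace(trace)
            rows.append(fv.as_array())
            labels.append(PATTERN_LABELS[Pattern(pattern)])
            i += 1
    return cl.LabeledDataset(np.array(rows), np.array(labels))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain described by ``config``; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "schema_version": config.schema_version, "stages": {}}
    sim = config.simulate
    bands = (tuple(config.bands.respiration), tuple(config.bands.heart))

    # --- simulate: physiologically varied traces per pattern -------------
    log.info("stage simulate: %d patterns x %d traces", len(sim.patterns), sim.n_per_pattern)
    trace_files, fvs = [], []
    i = 0
    for pattern in sim.patterns:
        for _ in range(sim.n_per_pattern):
            trace = synth.random_trace(
                pattern,
                seed=_substream(config.seed, "trace", i),
                duration_s=sim.duration_s,
                sampling_rate=sim.sampling_rate,
                noise_sigma_mm=sim.noise_sigma_mm,
                heartbeat=sim.heartbeat,
            )
            path = out / f"trace_{pattern}_{i:03d}.csv"
            dataio.write_trace_csv(trace, path)
            trace_files.append(path)
            fvs.append(featurize_trace(trace, bands))
            i += 1
    manifest["stages"]["simulate"] = {str(p.name): _hash_file(p) for p in trace_files}

    # --- process: radar chain on one apnea-protocol acquisition ----------
    log.info("stage process: apnea-protocol acquisition through the radar chain")
    proto = synth.random_trace(
        Pattern.APNEA_PROTOCOL,
        seed=_substream(config.seed, "protocol"),
        duration_s=sim.duration_s,
        sampling_rate=sim.sampling_rate,
        noise_sigma_mm=sim.noise_sigma_mm,
        heartbeat=sim.heartbeat,
    )
    cube = synth.simulate_if_cube(
        proto,
        base_range_m=config.radar.base_range_m,
        dropout_rate=config.radar.dropout_rate,
        seed=_substream(config.seed, "dropout"),
    )
    vs, _ = dsp.process_cube(cube, resp_band=bands[0], heart_band=bands[1])
    vitals_path = out / "vitals_apnea_protocol.csv"
    dataio.write_vitals_csv(vs, vitals_path, report_path=out / "rates_apnea_protocol.json")
    manifest["stages"]["process"] = {
        "vitals": _hash_file(vitals_path),
        "resp_rate_bpm": vs.resp_rate_bpm,
        "heart_rate_bpm": vs.heart_rate_bpm,
    }

    # --- apnea judgment on the respiration channel ------------------------
    acfg = config.apnea
    ej, intervals = ap.apnea_judgment(
        vs.respiration, window=acfg.window, hop=acfg.hop, mode=acfg.mode, min_len=acfg.min_len
    )
    report = {
        "segments": len(ej.energies_e),
        "window": acfg.window,
        "hop": acfg.hop,
        "intervals": [],
    }
    for iv in intervals:
        entry = {"start": iv.start, "stop": iv.stop}
        if proto.truth_apnea_intervals:
            truth_seg = ap.samples_to_segments(
                proto.truth_apnea_intervals[0], acfg.window, acfg.hop
            )
            entry["accuracy_vs_truth"] = ap.detection_accuracy(iv, truth_seg)
        report["intervals"].append(entry)
    apnea_path = out / "apnea_report.json"
    apnea_path.write_text(json.dumps(report, indent=1))
    manifest["stages"]["apnea"] = {"report": _hash_file(apnea_path)}

    # --- featurize ---------------------------------------------------------
    feat_path = out / "features.csv"
    dataio.write_features_csv(fvs, feat_path)
    manifest["stages"]["featurize"] = {"features": _hash_file(feat_path), "rows": len(fvs)}

    # --- classify ----------------------------------------------------------
    data = dataio.read_features_csv(feat_path)
    ccfg = config.classify
    if ccfg.cv_folds:
        result = cl.kfold_cv(data, k=ccfg.cv_folds, model=ccfg.model, seed=config.seed)
    else:
        rng = np.random.default_rng(_substream(config.seed, "split"))
        # stratified holdout: split each class separately, as in a balanced
        # train/test design
        test_idx, train_idx = [], []
        for c in np.unique(data.labels):
            members = np.flatnonzero(data.labels == c)
            members = rng.permutation(members)
            n_test = int(round(len(members) * ccfg.test_fraction))
            test_idx.extend(members[:n_test])
            train_idx.extend(members[n_test:])
        test, train = data.subset(np.array(test_idx)), data.subset(np.array(train_idx))
        pred = cl.train_predict(train, test, model=ccfg.model, seed=config.seed)
        result = cl.confusion_and_kappa(test.labels, pred, labels=sorted(set(data.labels)))
    eval_path = out / "eval.json"
    dataio.write_eval_report(result, eval_path, confusion_csv=out / "confusion.csv")
    manifest["stages"]["classify"] = {
        "eval": _hash_file(eval_path),
        "accuracy": result.accuracy,
        "kappa": result.kappa,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the canonical small corpus: one trace per pattern, one
    apnea-protocol trace with an injected mutation spike, one radar cube.

    Byte-stable across runs for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for i, pattern in enumerate(Pattern):
        trace = synth.random_trace(pattern, seed=_substream(seed, "fixture", i))
        if pattern is Pattern.APNEA_PROTOCOL:
            trace, spikes = synth.inject_spikes(trace, n_spikes=1, seed=_substream(seed, "spike"))
            (out / "spike_indices.json").write_text(json.dumps(spikes))
        path = out / f"trace_{pattern.value}.csv"
        dataio.write_trace_csv(trace, path)
        files[path.name] = _hash_file(path)
    static = synth.generate_pattern(
        synth.PatternSpec.default(Pattern.NORMAL), sampling_rate=20.0
    )
    cube = synth.simulate_if_cube(static, base_range_m=0.30)
    cube_path = dataio.save_cube_npz(cube, out / "cube_normal.npz")
    files[cube_path.name] = _hash_file(cube_path)
    (out / "fixture_manifest.json").write_text(json.dumps(files, indent=1, sort_keys=True))
    return files
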