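"""Persistence: events CSV, HDF5 trace/ground-truth container, JSON reports.

Layout of the HDF5 container written by :func:`save_dataset`::

    /encoding/data      (n_trials, n_samples) float, microvolts
    /encoding/times     (n_samples,) seconds            [attrs: sfreq, lock]
    /retrieval/...      same layout
    /ground_truth/
        knot_fractions
        fingerprint_keys  (N, 2) int  [participant, trial]
        fingerprint_freqs (N, n_channels) carrier frequencies, Hz
        fingerprints      (N, n_channels, n_knots) envelopes
        modulation_keys / modulations
        artifact_trials  (M, 3) strings [participant, trial, phase]
        attrs: encoding_window, retrieval_window, effects (JSON)

The events table travels separately as a plain CSV (comma, header, UTF-8).
"""

from __future__ import annotations

import json
import hashlib
import os

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet
from .synth import GroundTruth

__all__ = [
    "write_events_csv", "read_events_csv", "save_dataset", "load_dataset",
    "save_tfr", "load_tfr", "save_report_bundle", "config_hash",
]


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _save_epochs(group: h5py.Group, epochs: EpochSet) -> None:
    group.create_dataset("data", data=epochs.data, compression=None)
    group.create_dataset("times", data=epochs.times)
    group.attrs["sfreq"] = epochs.sfreq
    group.attrs["lock"] = epochs.lock


def _load_epochs(group: h5py.Group, events: pd.DataFrame) -> EpochSet:
    return EpochSet(data=group["data"][()], times=group["times"][()],
                    sfreq=float(group.attrs["sfreq"]),
                    lock=str(group.attrs["lock"]), events=events)


def save_dataset(h5_path, csv_path, encoding: EpochSet, retrieval: EpochSet,
                 events: pd.DataFrame, ground_truth: GroundTruth | None = None) -> None:
    """Write traces + ground truth to HDF5 and the event table to CSV."""
    write_events_csv(events, csv_path)
    with h5py.File(h5_path, "w") as f:
        _save_epochs(f.create_group("encoding"), encoding)
        _save_epochs(f.create_group("retrieval"), retrieval)
        if ground_truth is None:
            return
        g = f.create_group("ground_truth")
        g.create_dataset("knot_fractions", data=ground_truth.knot_fractions)
        if ground_truth.fingerprints:
            keys = np.array(sorted(ground_truth.fingerprints), dtype=np.int64)
            fps = [ground_truth.fingerprints[tuple(k)] for k in keys]
            g.create_dataset("fingerprint_keys", data=keys)
            g.create_dataset("fingerprint_freqs",
                             data=np.stack([f_.carrier_freqs for f_ in fps]))
            g.create_dataset("fingerprints",
                             data=np.stack([f_.envelope for f_ in fps]))
        if ground_truth.modulations:
            keys = np.array(sorted(ground_truth.modulations), dtype=np.int64)
            vals = np.array([ground_truth.modulations[tuple(k)] for k in keys])
            g.create_dataset("modulation_keys", data=keys)
            g.create_dataset("modulations", data=vals)
        if ground_truth.artifact_trials:
            arr = np.array([[str(a) for a in row] for row in ground_truth.artifact_trials],
                           dtype=h5py.string_dtype())
            g.create_dataset("artifact_trials", data=arr)
        g.attrs["encoding_window"] = ground_truth.encoding_window
        g.attrs["retrieval_window"] = ground_truth.retrieval_window
        g.attrs["effects"] = json.dumps(ground_truth.effects)


def load_dataset(h5_path, csv_path):
    """Inverse of :func:`save_dataset`; returns (encoding, retrieval, events, gt)."""
    events = read_events_csv(csv_path)
    enc_ev = events[events["phase"] == "encoding"].reset_index(drop=True)
    ret_ev = events[events["phase"] == "retrieval"].reset_index(drop=True)
    with h5py.File(h5_path, "r") as f:
        encoding = _load_epochs(f["encoding"], enc_ev)
        retrieval = _load_epochs(f["retrieval"], ret_ev)
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                knot_fractions=g["knot_fractions"][()],
                encoding_window=tuple(g.attrs["encoding_window"]),
                retrieval_window=tuple(g.attrs["retrieval_window"]),
                effects=json.loads(g.attrs["effects"]),
            )
            if "fingerprint_keys" in g:
                from .synth import Fingerprint
                for k, fr, env in zip(g["fingerprint_keys"][()],
                                      g["fingerprint_freqs"][()],
                                      g["fingerprints"][()]):
                    gt.fingerprints[(int(k[0]), int(k[1]))] = Fingerprint(
                        carrier_freqs=fr, envelope=env)
            if "modulation_keys" in g:
                for k, v in zip(g["modulation_keys"][()], g["modulations"][()]):
                    gt.modulations[(int(k[0]), int(k[1]))] = float(v)
            if "artifact_trials" in g:
                gt.artifact_trials = [
                    (int(r[0]), int(r[1]), r[2].decode() if isinstance(r[2], bytes) else str(r[2]))
                    for r in g["artifact_trials"][()]
                ]
    return encoding, retrieval, events, gt


def config_hash(section) -> str:
    """Stable short hash of a config section, for naming cached intermediates."""
    from .config import _asdict
    try:
        payload = _asdict(section)
    except TypeError:
        payload = section
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_report_bundle(out_dir, result) -> None:
    """Write report.json plus the group maps/cluster arrays to *out_dir*."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, default=float)
    g = result.group
    with h5py.File(os.path.join(out_dir, "maps.h5"), "w") as f:
        f.create_dataset("enc_times", data=g["enc_times"])
        f.create_dataset("ret_times", data=g["ret_times"])
        for k, v in g["maps"].items():
            f.create_dataset(f"maps/{k}", data=v)
        f.create_dataset("conjunction_mask", data=g["conjunction_mask"])
        f.create_dataset("conjunction_min_t", data=g["conjunction_min_t"])
        f.create_dataset("tf/t_map", data=g["res_tf"].stat_map)
        f.create_dataset("tf/times", data=g["tf_times"])
        for k, v in g["tf_maps"].items():
            f.create_dataset(f"tf/{k}", data=v)
        f.create_dataset("median_split_cells", data=g["median_split_cells"])


def save_tfr(path_or_group, tfr, name: str = "tfr") -> None:
    """Persist a TFR with labelled dimensions and normalization metadata."""
    own = isinstance(path_or_group, (str, bytes, os.PathLike))
    f = h5py.File(path_or_group, "a") if own else path_or_group
    try:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("power", data=tfr.power)
        g.create_dataset("frequency_hz", data=tfr.grid.frequencies)
        g.create_dataset("time_s", data=tfr.times)
        g.create_dataset("valid", data=tfr.valid)
        g.attrs["dims"] = ("trial", "frequency_hz", "time_s")
        g.attrs["normalization"] = tfr.normalization
        g.attrs["lock"] = tfr.lock
        if tfr.baseline is not None:
            g.attrs["baseline"] = tfr.baseline
        if tfr.events is not None:
            g.attrs["events_json"] = tfr.events.to_json(orient="split")
    finally:
        if own:
            f.close()


def load_tfr(path_or_group, name: str = "tfr"):
    """Inverse of :func:`save_tfr`."""
    from .spectral import FrequencyGrid, TimeFrequencyRepresentation

    own = isinstance(path_or_group, (str, bytes, os.PathLike))
    f = h5py.File(path_or_group, "r") if own else path_or_group
    try:
        g = f[name]
        freqs = g["frequency_hz"][()]
        default = FrequencyGrid.default()
        if freqs.size == default.n_frequencies and np.allclose(
                freqs, default.frequencies):
            grid = default
        else:
            grid = FrequencyGrid(frequencies=freqs,
                                 regimes=np.array(["hanning"] * freqs.size))
        events = None
        if "events_json" in g.attrs:
            import io as _io
            events = pd.read_json(_io.StringIO(g.attrs["events_json"]),
                                  orient="split")
        return TimeFrequencyRepresentation(
            power=g["power"][()], times=g["time_s"][()], grid=grid,
            valid=g["valid"][()], normalization=str(g.attrs["normalization"]),
            baseline=tuple(g.attrs["baseline"]) if "baseline" in g.attrs else None,
            lock=str(g.attrs["lock"]), events=events)
    finally:
        if own:
            f.close()
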