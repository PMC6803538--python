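"""Native on-disk format: plain-text TSV matrices + JSON metadata.

Every domain object round-trips losslessly (floats are written with 17
significant digits).  Each directory carries a ``meta.json`` with a
``format`` name and ``format_version``; mismatches raise ``SchemaError``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .network import ConnectivityNetwork, NodalFeatureTable
from .paradigm import ParadigmConfig, Trial, TrialSchedule
from .preprocessing import EpochSet
from .synth import GeneratorConfig, RawRecording, SyntheticGroundTruth

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Raised when an on-disk artifact does not match the expected schema."""


def _write_meta(path: Path, fmt: str, extra: dict) -> None:
    meta = {"format": fmt, "format_version": FORMAT_VERSION, **extra}
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_meta(path: Path, fmt: str) -> dict:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"missing meta.json in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"malformed meta.json in {path}: {err}") from err
    if meta.get("format") != fmt:
        raise SchemaError(f"expected format {fmt!r}, found {meta.get('format')!r}")
    if meta.get("format_version") != FORMAT_VERSION:
        raise SchemaError(
            f"unsupported format_version {meta.get('format_version')!r} "
            f"(supported: {FORMAT_VERSION})"
        )
    return meta


def _save_matrix(path: Path, arr: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame(np.atleast_2d(arr)).to_csv(
        path, sep="\t", header=False, index=False, float_format=_FLOAT_FMT
    )


def _load_matrix(path: Path) -> np.ndarray:
    import pandas as pd

    return np.atleast_2d(
        pd.read_csv(
            path, sep="\t", header=None, dtype=float,
            float_precision="round_trip",
        ).to_numpy()
    )


# -- TrialSchedule ----------------------------------------------------------


def save_schedule(schedule: TrialSchedule, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    schedule.to_frame().to_csv(path / "schedule.tsv", sep="\t", index=False)
    _write_meta(
        path,
        "trial_schedule",
        {
            "total_duration_s": schedule.total_duration_s,
            "config": dataclasses.asdict(schedule.config),
        },
    )


def load_schedule(path: str | Path) -> TrialSchedule:
    import pandas as pd

    path = Path(path)
    meta = _read_meta(path, "trial_schedule")
    df = pd.read_csv(path / "schedule.tsv", sep="\t")
    trials = tuple(
        Trial(
            int(r["index"]),
            str(r["condition"]),
            int(r["color"]),
            int(r["session"]),
            float(r["observation_onset_s"]),
        )
        for _, r in df.iterrows()
    )
    return TrialSchedule(
        trials, float(meta["total_duration_s"]), ParadigmConfig(**meta["config"])
    )


# -- EpochSet ---------------------------------------------------------------


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_tr, n_ch, n_t = epochs.data.shape
    _save_matrix(path / "data.tsv", epochs.data.reshape(n_tr * n_ch, n_t))
    _write_meta(
        path,
        "epoch_set",
        {
            "shape": [n_tr, n_ch, n_t],
            "rate_hz": epochs.rate_hz,
            "labels": [str(x) for x in epochs.labels],
            "modality": epochs.modality,
            "window_s": list(epochs.window_s),
            "baseline_window_s": list(epochs.baseline_window_s)
            if epochs.baseline_window_s
            else None,
            "channel_names": epochs.channel_names,
            "colors": [int(c) for c in epochs.colors]
            if epochs.colors is not None
            else None,
        },
    )


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = _read_meta(path, "epoch_set")
    n_tr, n_ch, n_t = meta["shape"]
    flat = _load_matrix(path / "data.tsv")
    if flat.shape != (n_tr * n_ch, n_t):
        raise SchemaError(
            f"data.tsv shape {flat.shape} does not match metadata "
            f"{(n_tr * n_ch, n_t)}"
        )
    return EpochSet(
        data=flat.reshape(n_tr, n_ch, n_t),
        rate_hz=float(meta["rate_hz"]),
        labels=np.array(meta["labels"]),
        modality=meta["modality"],
        window_s=tuple(meta["window_s"]),
        baseline_window_s=tuple(meta["baseline_window_s"])
        if meta["baseline_window_s"]
        else None,
        channel_names=meta["channel_names"],
        colors=np.array(meta["colors"]) if meta["colors"] is not None else None,
    )


# -- ConnectivityNetwork ----------------------------------------------------


def save_network(net: ConnectivityNetwork, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _save_matrix(path / "weights.tsv", net.weights)
    np.savetxt(path / "binary.tsv", net.binary.astype(int), fmt="%d", delimiter="\t")
    # human-inspectable edge list of the binary graph
    iu, ju = np.nonzero(np.triu(net.binary, k=1))
    with open(path / "edges.txt", "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t"
                     f"{net.weights[i, j]:.6g}\n")
    _write_meta(
        path,
        "connectivity_network",
        {"density": net.density, "node_ids": net.node_ids,
         "modality": net.modality},
    )


def load_network(path: str | Path) -> ConnectivityNetwork:
    path = Path(path)
    meta = _read_meta(path, "connectivity_network")
    return ConnectivityNetwork(
        weights=_load_matrix(path / "weights.tsv"),
        binary=_load_matrix(path / "binary.tsv").astype(bool),
        density=float(meta["density"]),
        node_ids=list(meta["node_ids"]),
        modality=meta["modality"],
    )


# -- NodalFeatureTable ------------------------------------------------------


def save_features(table: NodalFeatureTable, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "features.tsv", "w") as fh:
        fh.write("label\t" + "\t".join(table.columns) + "\n")
        for lab, row in zip(table.labels, table.values):
            fh.write(str(lab) + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
    _write_meta(path, "nodal_features", {"modality": table.modality})


def load_features(path: str | Path) -> NodalFeatureTable:
    path = Path(path)
    meta = _read_meta(path, "nodal_features")
    with open(path / "features.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "label":
            raise SchemaError("features.tsv must start with a 'label' column")
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return NodalFeatureTable(
        values=np.asarray(rows),
        columns=header[1:],
        labels=np.array(labels),
        modality=meta["modality"],
    )


# -- RawRecording -----------------------------------------------------------


def save_recording(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _save_matrix(path / "eeg.tsv", rec.eeg)
    _save_matrix(path / "eog.tsv", rec.eog)
    n_ch, n_wl, n_t = rec.fnirs_intensity.shape
    _save_matrix(path / "fnirs.tsv", rec.fnirs_intensity.reshape(n_ch * n_wl, n_t))
    save_schedule(rec.schedule, path / "schedule")
    (path / "ground_truth.json").write_text(rec.ground_truth.to_json())
    _write_meta(
        path,
        "raw_recording",
        {
            "fnirs_shape": [n_ch, n_wl, n_t],
            "generator": dataclasses.asdict(rec.generator),
            "eeg_channel_names": rec.eeg_channel_names,
            "fnirs_channel_names": rec.fnirs_channel_names,
        },
    )


def load_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    meta = _read_meta(path, "raw_recording")
    truth_raw = json.loads((path / "ground_truth.json").read_text())
    for key in ("eeg_communities", "fnirs_communities"):
        truth_raw[key] = {c: tuple(v) for c, v in truth_raw[key].items()}
    for key in ("erp_window_ms",):
        truth_raw[key] = tuple(truth_raw[key])
    gen_raw = meta["generator"]
    for key in ("wavelengths_nm", "dpf"):
        gen_raw[key] = tuple(gen_raw[key])
    n_ch, n_wl, n_t = meta["fnirs_shape"]
    return RawRecording(
        eeg=_load_matrix(path / "eeg.tsv"),
        eog=_load_matrix(path / "eog.tsv"),
        fnirs_intensity=_load_matrix(path / "fnirs.tsv").reshape(n_ch, n_wl, n_t),
        schedule=load_schedule(path / "schedule"),
        ground_truth=SyntheticGroundTruth(**truth_raw),
        generator=GeneratorConfig(**gen_raw),
        eeg_channel_names=list(meta["eeg_channel_names"]),
        fnirs_channel_names=list(meta["fnirs_channel_names"]),
    )
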