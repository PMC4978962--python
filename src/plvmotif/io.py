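"""Reading and writing the package's on-disk formats.

Connectivity and ratio matrices travel as CSV with node ids as header;
trial arrays as a chunked binary container (one ``.npy`` per trial set)
with a JSON sidecar carrying sampling rate, band and node ids; run
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal import BandSpec, ConnectivityMatrix, RatioMatrix, TrialSet


def band_to_dict(band: BandSpec) -> dict:
    return {"name": band.name, "f_lo": band.f_lo, "f_hi": band.f_hi}


def band_from_dict(d: dict) -> BandSpec:
    return BandSpec(str(d["name"]), float(d["f_lo"]), float(d["f_hi"]))


def save_matrix_csv(path, matrix: np.ndarray, node_ids: list[str]) -> None:
    pd.DataFrame(matrix, index=node_ids, columns=node_ids).to_csv(path)


def load_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(dtype=float), list(frame.columns)


def save_connectivity(path, conn: ConnectivityMatrix, node_ids: list[str]) -> None:
    save_matrix_csv(path, conn.plv, node_ids)


def save_ratio(path, ratio: RatioMatrix, node_ids: list[str]) -> None:
    save_matrix_csv(path, ratio.ratio, node_ids)


def save_trialset(directory, trials: TrialSet, node_ids: list[str] | None = None) -> Path:
    """Write ``<subject>_<session>.npy`` plus a JSON sidecar; returns the stem."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"{trials.subject_id}_{trials.session}"
    np.save(stem.with_suffix(".npy"), trials.data)
    meta = {
        "subject_id": trials.subject_id,
        "session": trials.session,
        "band": band_to_dict(trials.band),
        "fs": trials.fs,
        "kind": trials.kind,
        "n_trials": trials.n_trials,
        "node_ids": node_ids,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return stem


def load_trialset(stem) -> TrialSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    return TrialSet(
        subject_id=meta["subject_id"],
        session=meta["session"],
        band=band_from_dict(meta["band"]),
        fs=float(meta["fs"]),
        data=data,
        kind=meta["kind"],
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
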