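"""Plain-text input/output: parameter files, event tables, manifests, results.

Parameter files are YAML or JSON mappings whose keys mirror
CircuitParameters field names. Event tables are delimited text with columns
``gfp`` and ``mcherry``, one file per clone, tied together by a manifest CSV
(clone_id, variant, file).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import CircuitParameters
from .engine import Trajectory
from .flow import ArchetypeMask, ClusteringResult, ResponseProfile

__all__ = [
    "load_parameters",
    "save_parameters",
    "read_events",
    "write_events",
    "read_manifest",
    "write_manifest",
    "write_trajectory",
    "write_sweep",
    "write_distances",
    "write_assignments",
    "write_mask",
]


def load_parameters(path) -> CircuitParameters:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    return CircuitParameters.from_dict(data)


def save_parameters(params: CircuitParameters, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_events(path, clone_id: str | None = None, sep: str = ",", **metadata) -> ResponseProfile:
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "gfp" not in cols or "mcherry" not in cols:
        raise ValueError(f"{path}: event table needs 'gfp' and 'mcherry' columns")
    events = df[[cols["gfp"], cols["mcherry"]]].to_numpy(dtype=float)
    return ResponseProfile(clone_id or Path(path).stem, events, metadata)


def write_events(profile: ResponseProfile, path, sep: str = ",") -> None:
    pd.DataFrame(profile.events, columns=["gfp", "mcherry"]).to_csv(path, sep=sep, index=False)


def read_manifest(path) -> list:
    """Read a manifest CSV (clone_id, variant, file) and load every profile.

    Relative file paths resolve against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("clone_id", "file"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest needs a {col!r} column")
    profiles = []
    for _, row in df.iterrows():
        f = Path(row["file"])
        if not f.is_absolute():
            f = path.parent / f
        meta = {k: row[k] for k in df.columns if k not in ("clone_id", "file")}
        profiles.append(read_events(f, clone_id=str(row["clone_id"]), **meta))
    return profiles


def write_manifest(profiles: list, directory, sep: str = ",") -> Path:
    """Write one event CSV per profile plus a manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        fname = f"{p.clone_id}.csv"
        write_events(p, directory / fname, sep=sep)
        rows.append({"clone_id": p.clone_id, **p.metadata, "file": fname})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(traj.states, columns=list(traj.species))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def write_sweep(summaries: list, path) -> None:
    rows = [
        {
            "copies_A": s.copies_A,
            "copies_B": s.copies_B,
            "n_runs": s.n_runs,
            **s.fractions,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_distances(D: np.ndarray, clone_ids: list, path) -> None:
    pd.DataFrame(D, index=clone_ids, columns=clone_ids).to_csv(path)


def write_assignments(result: ClusteringResult, clone_ids: list, path) -> None:
    pd.DataFrame(
        {
            "clone_id": clone_ids,
            "cluster": result.assignments,
            "medoid_clone": [clone_ids[result.medoid_indices[c]] for c in result.assignments],
        }
    ).to_csv(path, index=False)


def write_mask(mask: ArchetypeMask, path) -> None:
    pd.DataFrame(mask.grid).to_csv(path, index=False, header=False)
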