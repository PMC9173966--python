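"""Readers, writers, checkpoints and run manifests.

Two interchangeable on-disk forms exist for recordings: delimited text (one
CSV column per channel, values to six significant digits) with a JSON
sidecar carrying the sampling rate, channel names and annotations; and a
binary array container (numpy ``.npz``) for large runs, which round-trips
bit-exactly.  Cohort tables are plain CSV with one row per patient, muscle
and timepoint.  Manifests record SHA-256 hashes of every produced file so a
rerun can be verified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, SpectralParams
from .networks import (
    DecisionFusionNetwork,
    MultiViewNetwork,
    NetworkBase,
    NetworkSpec,
    PoolingOfViewNetwork,
    SingleViewNetwork,
)
from .synth import EmgRecording
from .training import MultiViewDataset

COHORT_COLUMNS = [
    "patient_id", "group", "hb_category", "muscle", "timepoint",
    "rms", "mf", "mpf",
]


# --- recordings -------------------------------------------------------------


def write_recording(rec: EmgRecording, path: str | Path, fmt: str = "csv") -> Path:
    """Write a recording as ``<stem>.csv`` + ``<stem>.json`` or ``<stem>.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        data_path = path.with_suffix(".csv")
        header = ",".join(rec.channel_names)
        np.savetxt(data_path, rec.samples, delimiter=",", fmt="%.6g",
                   header=header, comments="")
        sidecar = {
            "fs": rec.fs,
            "channels": list(rec.channel_names),
            "annotations": [list(a) for a in rec.annotations],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return data_path
    if fmt == "npz":
        data_path = path.with_suffix(".npz")
        np.savez(
            data_path,
            samples=rec.samples,
            fs=np.array([rec.fs]),
            channels=np.array(rec.channel_names),
            annotations=np.array(rec.annotations, dtype=int).reshape(-1, 3),
        )
        return data_path
    raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path) -> EmgRecording:
    """Read either container back; the format is chosen by file suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return EmgRecording(
                samples=z["samples"],
                fs=float(z["fs"][0]),
                channel_names=tuple(str(c) for c in z["channels"]),
                annotations=[tuple(int(v) for v in row)
                             for row in z["annotations"]],
            )
    if path.suffix == ".csv":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing sidecar {sidecar_path.name} next to {path.name}"
            )
        meta = json.loads(sidecar_path.read_text())
        lines = path.read_text().strip().splitlines()
        header = lines[0].split(",")
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            cells = line.split(",")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path.name}: ragged row at line {lineno} "
                    f"({len(cells)} cells, expected {len(header)})"
                )
            rows.append([float(c) for c in cells])
        if list(meta["channels"]) != header:
            raise ValueError(f"{path.name}: channel mismatch with sidecar")
        return EmgRecording(
            samples=np.array(rows),
            fs=float(meta["fs"]),
            channel_names=tuple(meta["channels"]),
            annotations=[tuple(a) for a in meta["annotations"]],
        )
    raise ValueError(f"unsupported recording file {path.name!r}")


# --- cohorts ----------------------------------------------------------------


def cohort_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for (muscle, tp), sp in sorted(r.params.items()):
            rows.append(
                [r.patient_id, r.group, r.hb_category, muscle, tp,
                 sp.rms, sp.mf, sp.mpf]
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[ClinicalRecord]:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for (pid, group, cat), sub in df.groupby(
        ["patient_id", "group", "hb_category"], sort=True
    ):
        params = {
            (row.muscle, row.timepoint): SpectralParams(row.rms, row.mf, row.mpf)
            for row in sub.itertuples()
        }
        records.append(ClinicalRecord(str(pid), str(group), str(cat), params))
    return records


def write_cohort(records: list[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(records).to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> list[ClinicalRecord]:
    return frame_to_cohort(pd.read_csv(path))


# --- feature datasets -------------------------------------------------------


def write_dataset(ds: MultiViewDataset, path: str | Path) -> Path:
    """Feature dataset as ``.npz`` arrays plus a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"view_{v}": x for v, x in zip(ds.view_ids, ds.xs)}
    np.savez(path.with_suffix(".npz"), y=ds.y, trial_ids=ds.trial_ids, **arrays)
    manifest = {
        "view_ids": list(ds.view_ids),
        "layouts": [list(s) for s in ds.view_shapes],
        "label_map": sorted(int(c) for c in np.unique(ds.y)),
        "n_samples": len(ds),
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return path.with_suffix(".npz")


def read_dataset(path: str | Path) -> MultiViewDataset:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".manifest.json").read_text())
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
        view_ids = tuple(manifest["view_ids"])
        return MultiViewDataset(
            xs=[z[f"view_{v}"] for v in view_ids],
            y=z["y"],
            trial_ids=z["trial_ids"],
            view_ids=view_ids,
        )


# --- model checkpoints ------------------------------------------------------

_ARCHS = {
    "multiview": MultiViewNetwork,
    "single-view": SingleViewNetwork,
    "spliced-multiview": SingleViewNetwork,
    "pooling-of-view": PoolingOfViewNetwork,
    "decision-fusion": DecisionFusionNetwork,
}


def _build_arch(arch: str, spec: NetworkSpec, seed: int, extra: dict) -> NetworkBase:
    if arch == "multiview":
        return MultiViewNetwork(spec, seed=seed)
    if arch in ("single-view", "spliced-multiview"):
        return SingleViewNetwork(spec, seed=seed, mode=arch,
                                 view_index=extra.get("view_index", 0))
    if arch == "pooling-of-view":
        return PoolingOfViewNetwork(spec, seed=seed,
                                    pool_layer=extra.get("pool_layer", 5),
                                    reducer=extra.get("reducer", "max"))
    if arch == "decision-fusion":
        return DecisionFusionNetwork(spec, seed=seed)
    raise ValueError(f"unknown architecture {arch!r}")


def save_model(model: NetworkBase, path: str | Path,
               view_ids: tuple[int, ...] = (), label_map=None) -> Path:
    """Parameter ``.npz`` plus a JSON sidecar holding the spec and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **params)
    extra = {}
    if isinstance(model, SingleViewNetwork):
        extra["view_index"] = model.view_index
    if isinstance(model, PoolingOfViewNetwork):
        extra["pool_layer"] = model.pool_layer
        extra["reducer"] = model.reducer
    sidecar = {
        "arch": model.arch,
        "seed": model.seed,
        "spec": asdict(model.spec),
        "extra": extra,
        "view_ids": list(view_ids),
        "label_map": list(label_map) if label_map is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> NetworkBase:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = sidecar["spec"]
    spec_d["view_shapes"] = tuple(tuple(s) for s in spec_d["view_shapes"])
    spec = NetworkSpec(**spec_d)
    model = _build_arch(sidecar["arch"], spec, sidecar["seed"], sidecar["extra"])
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
        for i, p in enumerate(model.parameters()):
            p.value[...] = z[f"p{i}"]
    return model


# --- manifests --------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class Manifest:
    """File inventory with content hashes, per producing stage."""

    stage: str
    files: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def add(self, path: str | Path, root: str | Path) -> None:
        rel = str(Path(path).relative_to(root))
        self.files[rel] = sha256_file(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @staticmethod
    def read(path: str | Path) -> "Manifest":
        d = json.loads(Path(path).read_text())
        return Manifest(stage=d["stage"], files=d["files"], config=d["config"])

    def verify(self, root: str | Path) -> bool:
        root = Path(root)
        return all(
            sha256_file(root / rel) == digest for rel, digest in self.files.items()
        )
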