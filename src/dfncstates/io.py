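"""Plain-text on-disk formats: per-subject TSV timecourses with JSON sidecars,
CSV phenotype/OCR/centroid tables, JSON ground truth, and run manifests with
per-file checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import StateModel, StateVector
from .timecourses import ComponentTimecourses
from .windows import DfncWindows, TaperSpec

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


# ---------------------------------------------------------------------------
# timecourses
# ---------------------------------------------------------------------------


def save_timecourses(tcs: Iterable[ComponentTimecourses], out_dir: str | Path) -> list[Path]:
    """Write each subject as ``<id>.tsv`` (header = component ids) plus a
    ``<id>.json`` sidecar carrying the TR."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tc in tcs:
        path = out_dir / f"{tc.subject_id}.tsv"
        header = "\t".join(tc.component_ids)
        np.savetxt(path, tc.data, fmt=_FLOAT_FMT, delimiter="\t",
                   header=header, comments="")
        sidecar = out_dir / f"{tc.subject_id}.json"
        _atomic_write_json(sidecar, {"subject_id": tc.subject_id, "tr_seconds": tc.tr})
        paths.append(path)
    return paths


def load_timecourses(in_dir: str | Path) -> list[ComponentTimecourses]:
    """Load all per-subject TSVs in a directory, sorted by subject id.

    Subjects with ragged rows or non-finite values are rejected with a log
    entry; the rest are returned.
    """
    in_dir = Path(in_dir)
    out = []
    for path in sorted(in_dir.glob("*.tsv")):
        sid = path.stem
        sidecar = path.with_suffix(".json")
        tr = 2.36
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            tr = float(meta.get("tr_seconds", tr))
        try:
            df = pd.read_csv(path, sep="\t")
            data = df.to_numpy(dtype=float)
            if not np.isfinite(data).all():
                raise ValueError("non-finite values")
            out.append(ComponentTimecourses(
                subject_id=sid, data=data, tr=tr,
                component_ids=tuple(df.columns)))
        except (ValueError, pd.errors.ParserError) as exc:
            logger.warning("rejecting subject %s: %s", sid, exc)
    return out


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def save_windows(windows: Iterable[DfncWindows], out_dir: str | Path) -> list[Path]:
    """Per-subject windowed connectivity as ``<id>.windows.tsv`` plus a JSON
    sidecar with the pair ordering convention, window starts and taper."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for w in windows:
        path = out_dir / f"{w.subject_id}.windows.tsv"
        np.savetxt(path, w.matrix, fmt=_FLOAT_FMT, delimiter="\t")
        meta = {
            "subject_id": w.subject_id,
            "n_components": w.n_components,
            "pair_order": "row-major upper triangle, 0-based, i<j",
            "window_starts": [int(s) for s in w.window_starts],
            "taper": {"rect_width": w.taper.rect_width,
                      "gaussian_sigma": w.taper.gaussian_sigma,
                      "step": w.taper.step},
        }
        _atomic_write_json(out_dir / f"{w.subject_id}.windows.json", meta)
        paths.append(path)
    return paths


def load_windows(in_dir: str | Path) -> list[DfncWindows]:
    in_dir = Path(in_dir)
    out = []
    for path in sorted(in_dir.glob("*.windows.tsv")):
        sid = path.name.removesuffix(".windows.tsv")
        meta = json.loads(path.with_suffix(".json").read_text())
        taper = TaperSpec(**meta["taper"])
        out.append(DfncWindows(
            subject_id=sid,
            matrix=np.loadtxt(path, delimiter="\t", ndmin=2),
            window_starts=np.asarray(meta["window_starts"], dtype=int),
            n_components=int(meta["n_components"]),
            taper=taper,
        ))
    return out


# ---------------------------------------------------------------------------
# tables and models
# ---------------------------------------------------------------------------


def save_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
    return path


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_ocr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def save_state_model(model: StateModel, path: str | Path) -> Path:
    """Centroids as CSV (one row per connectivity pair, one column per state)
    plus metadata columns-free JSON next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(model.centroids.T,
                      columns=[f"state_{k + 1}" for k in range(model.K)])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "K": model.K, "inertia": model.inertia, "n_init": model.n_init,
        "max_iter": model.max_iter, "seed": model.seed,
        "distance": model.distance, "converged": model.converged,
        "k_sweep": {str(k): v for k, v in (model.k_sweep or {}).items()},
    }
    _atomic_write_json(path.with_suffix(".json"), meta)
    return path


def load_state_model(path: str | Path) -> StateModel:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    sweep = {int(k): float(v) for k, v in meta.get("k_sweep", {}).items()} or None
    return StateModel(
        K=int(meta["K"]), centroids=df.to_numpy(dtype=float).T,
        inertia=float(meta["inertia"]), n_init=int(meta["n_init"]),
        max_iter=int(meta["max_iter"]), seed=meta.get("seed"),
        distance=meta.get("distance", "euclidean"),
        converged=bool(meta.get("converged", True)), k_sweep=sweep,
    )


def save_state_vectors(vectors: Sequence[StateVector], path: str | Path) -> Path:
    rows = []
    for sv in vectors:
        for w, lab in enumerate(sv.labels):
            rows.append((sv.subject_id, w, int(lab)))
    df = pd.DataFrame(rows, columns=["subject_id", "window", "state"])
    return save_table(df, path)


def load_state_vectors(path: str | Path) -> list[StateVector]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("window")
        out.append(StateVector(subject_id=str(sid),
                               labels=grp["state"].to_numpy(dtype=int)))
    return out


def save_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "subject_ids": list(truth["subject_ids"]),
        "state_sequences": [np.asarray(s).tolist() for s in truth["state_sequences"]],
        "ocr": np.asarray(truth["ocr"]).tolist(),
        "effect": np.asarray(truth["effect"]).tolist(),
        "effect_timepoints": list(truth["effect_timepoints"]),
    }
    _atomic_write_json(path, payload)
    return path


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Per-stage record of a pipeline run: config hash, input/output
    checksums, and warnings.  Written atomically after each stage."""

    config_hash: str
    stages: dict = field(default_factory=dict)

    def record_stage(self, name: str, inputs: Sequence[Path] = (),
                     outputs: Sequence[Path] = (), skipped: bool = False,
                     warnings_: Sequence[str] = ()) -> None:
        self.stages[name] = {
            "skipped": skipped,
            "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).exists()},
            "outputs": {str(p): sha256_file(p) for p in outputs if Path(p).exists()},
            "warnings": list(warnings_),
        }

    def stage_is_current(self, name: str) -> bool:
        """True when the stage's recorded inputs and outputs all still exist
        with unchanged checksums (checksum-based staleness detection)."""
        rec = self.stages.get(name)
        if rec is None:
            return False
        for group in ("inputs", "outputs"):
            for p, digest in rec[group].items():
                if not Path(p).exists() or sha256_file(p) != digest:
                    return False
        return True

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        _atomic_write_json(path, {"config_hash": self.config_hash,
                                  "stages": self.stages})
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        m = cls(config_hash=payload["config_hash"])
        m.stages = payload["stages"]
        return m


def _atomic_write_json(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    os.replace(tmp, path)
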