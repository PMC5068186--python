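"""Readers/writers for the pipeline's on-disk formats.

Volumes travel as NIfTI (.nii.gz); configs, ground truth, landmarks,
ROIs and uptake results as JSON; metric tables and agreement reports as
CSV.  Every manifest embeds the configuration hash and seed so re-runs
are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .phantom import PhantomConfig, PhantomTruth
from .quantify import UptakeResult
from .volume import GatedSeries


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=1, sort_keys=True))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def config_hash(config: PhantomConfig) -> str:
    blob = json.dumps(_to_jsonable(config.to_dict()), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_config(config: PhantomConfig, path: str | Path) -> None:
    dump_json(config.to_dict(), path)


def load_config(path: str | Path) -> PhantomConfig:
    return PhantomConfig.from_dict(load_json(path))


def save_series(series: GatedSeries, outdir: str | Path, stem: str) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for g, vol in enumerate(series.gates):
        p = outdir / f"{stem}_gate{g}.nii.gz"
        vol.save(str(p))
        files.append(p.name)
    dump_json({"gate_counts": series.gate_counts,
               "phase_windows": series.phase_windows},
              outdir / f"{stem}_gates.json")
    files.append(f"{stem}_gates.json")
    return files


def save_truth(truth: PhantomTruth, outdir: str | Path, stem: str) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_json(truth.to_dict(), outdir / f"{stem}_truth.json")
    return [f"{stem}_truth.json"]


def save_result(result: UptakeResult, path: str | Path) -> None:
    d = result.to_row()
    d["slices"] = [dataclasses.asdict(s) for s in result.slice_stats]
    d["mds_mean_pair"] = list(result.mds_mean_pair)
    d["mds_max_pair"] = list(result.mds_max_pair)
    d["blood_pool_slice_values"] = result.blood_pool.slice_values
    dump_json(d, path)
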