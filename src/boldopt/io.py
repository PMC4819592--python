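"""File I/O: volumetric ROI extraction, run logs, simulation tables, config.

Run logs are comma-delimited with a header (iteration, visual_pos,
auditory_pos, objective, tag); summaries are JSON; configuration files
are YAML key-value documents.  Volumetric inputs are NIfTI images read
with nibabel; registration and motion correction are assumed to have
been done upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .signal import RoiTimeSeries
from .simloop import RunLog, RunLogEntry, SimResult

__all__ = [
    "RoiExtractionSpec",
    "extract_roi_timeseries",
    "write_runlog",
    "read_runlog",
    "write_sim_result",
    "write_summary",
    "read_config",
]


class RoiExtractionError(ValueError):
    """Base class for ROI extraction failures."""


class DimensionMismatchError(RoiExtractionError):
    pass


class NonBinaryMaskError(RoiExtractionError):
    pass


class RoiExtractionSpec:
    """A 4-D functional image plus named binary 3-D ROI masks.

    ``drop_initial`` volumes are discarded from the start of each
    extracted series to allow for T1 equilibration (default 10 TRs).
    """

    def __init__(self, image_path, mask_paths: dict, drop_initial: int = 10,
                 tr_seconds: float = 2.0):
        self.image_path = Path(image_path)
        self.mask_paths = {k: Path(v) for k, v in mask_paths.items()}
        if drop_initial < 0:
            raise ValueError("drop_initial must be nonnegative")
        self.drop_initial = drop_initial
        self.tr_seconds = tr_seconds


def extract_roi_timeseries(spec: RoiExtractionSpec) -> dict[str, RoiTimeSeries]:
    """Per-TR masked means for each named ROI.

    Each volume's value is the mean over voxels where the mask equals
    1 (for a single binary mask this coincides, up to scale, with the
    indicator-regression estimate of the region's signal).
    """
    try:
        img = nib.load(str(spec.image_path))
    except Exception as exc:
        raise RoiExtractionError(f"cannot read image {spec.image_path}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionMismatchError(f"expected a 4-D image, got shape {data.shape}")
    out = {}
    for name, path in spec.mask_paths.items():
        try:
            mask_img = nib.load(str(path))
        except Exception as exc:
            raise RoiExtractionError(f"cannot read mask {path}") from exc
        mask = np.asarray(mask_img.dataobj)
        if mask.shape != data.shape[:3]:
            raise DimensionMismatchError(
                f"mask {name} shape {mask.shape} != image grid {data.shape[:3]}"
            )
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise NonBinaryMaskError(f"mask {name} is not binary (values {uniq})")
        if not np.any(mask):
            raise NonBinaryMaskError(f"mask {name} selects no voxels")
        series = data[mask.astype(bool)].mean(axis=0)[spec.drop_initial :]
        out[name] = RoiTimeSeries(series, tr_seconds=spec.tr_seconds, roi_label=name)
    return out


_RUNLOG_COLUMNS = ["iteration", "visual_pos", "auditory_pos", "objective", "tag"]


def write_runlog(run: RunLog, path) -> None:
    rows = [
        (e.iteration, e.coordinate[0], e.coordinate[1], repr(e.value), e.tag)
        for e in run.entries
    ]
    df = pd.DataFrame(rows, columns=_RUNLOG_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# study={run.study} seed={run.seed} config={json.dumps(run.config)}\n")
        df.to_csv(fh, index=False)


def read_runlog(path) -> RunLog:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(part.split("=", 1) for part in header.split(" ", 2))
        df = pd.read_csv(fh)
    entries = [
        RunLogEntry(
            int(r.iteration),
            (int(r.visual_pos), int(r.auditory_pos)),
            float(r.objective),
            str(r.tag),
        )
        for r in df.itertuples()
    ]
    return RunLog(
        entries=entries,
        study=int(meta["study"]),
        seed=int(meta["seed"]),
        config=json.loads(meta["config"]),
    )


def write_sim_result(result: SimResult, path) -> None:
    """One row per post-burn-in iteration of a CNR condition."""
    df = pd.DataFrame(
        {
            "iteration": result.iterations,
            "distance_mean": result.distance_mean,
            "distance_sem": result.distance_sem,
            "correlation_mean": result.correlation_mean,
            "correlation_sem": result.correlation_sem,
        }
    )
    df.insert(0, "cnr", result.cnr)
    df.to_csv(path, index=False)


def write_summary(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_config(path) -> dict:
    """Plain-text YAML key-value configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a key-value mapping")
    return cfg
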