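"""Tabular and volumetric I/O.

All tables are comma-separated UTF-8 with a mandatory header row, '.'
decimal separator, and empty fields for missing values — fixed regardless
of locale so runs are reproducible across machines.  Configuration files
and run manifests are plain ``key: value`` structured text (YAML subset).

NIfTI-1 import extracts within-mask voxel vectors in ascending linear
(C-order) index of the mask grid; the ordering is part of the contract so
real-data runs are reproducible.
"""

from __future__ import annotations

import datetime
import importlib.metadata
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .conditions import ConditionLabel
from .exceptions import ValidationError
from .rsa import PatternSet
from .simulate import GeneratorConfig
from .tuning import TuningFit

__all__ = [
    "write_table",
    "read_table",
    "patterns_to_frame",
    "frame_to_patterns",
    "curves_to_frame",
    "fits_to_frame",
    "load_config",
    "save_config",
    "write_manifest",
    "import_roi_patterns",
]


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy table in the package's fixed CSV dialect."""
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def patterns_to_frame(pattern_sets) -> pd.DataFrame:
    """Tidy pattern table: subject, arrangement, numerosity, exemplar,
    voxel_0 ... voxel_{V-1}."""
    rows = []
    for ps in pattern_sets:
        for e in range(ps.n_exemplars):
            row = {
                "subject_id": ps.subject_id,
                "arrangement": ps.condition.arrangement,
                "numerosity": ps.condition.numerosity,
                "exemplar": e,
            }
            row.update({f"voxel_{v}": ps.patterns[e, v] for v in range(ps.n_voxels)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_patterns(df: pd.DataFrame) -> list[PatternSet]:
    """Inverse of :func:`patterns_to_frame`."""
    voxel_cols = sorted(
        (c for c in df.columns if c.startswith("voxel_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not voxel_cols:
        raise ValidationError("pattern table has no voxel_* columns")
    sets = []
    for (sid, arr, n), grp in df.groupby(
        ["subject_id", "arrangement", "numerosity"], observed=True, sort=True
    ):
        grp = grp.sort_values("exemplar")
        sets.append(
            PatternSet(
                str(sid),
                ConditionLabel(str(arr), int(n)),
                grp[voxel_cols].to_numpy(dtype=float),
            )
        )
    return sets


def curves_to_frame(curves, arrangement: str | None = None) -> pd.DataFrame:
    """Similarity curves as a tidy table
    (arrangement, reference_n, probe_n, error_rate)."""
    rows = []
    for c in curves:
        for p, v in zip(c.probes, c.values):
            rows.append(
                {
                    "arrangement": arrangement,
                    "reference_n": c.reference_n,
                    "probe_n": p,
                    "error_rate": v,
                }
            )
    return pd.DataFrame(rows)


def fits_to_frame(fits: list[TuningFit]) -> pd.DataFrame:
    """Width-fit summary table (one row per arrangement)."""
    return pd.concat([f.to_frame() for f in fits], ignore_index=True)


def load_config(path) -> GeneratorConfig:
    """Load a generator configuration from a ``key: value`` text file.

    Unknown keys raise :class:`~numtuning.exceptions.SchemaError` naming
    the offender before any computation runs.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return GeneratorConfig.from_dict(data)


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _package_version() -> str:
    try:
        return importlib.metadata.version("numtuning")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def write_manifest(out_dir, command: str, seed: int, config: GeneratorConfig | None,
                   inputs: list[str] | None = None,
                   outputs: list[str] | None = None) -> Path:
    """Write the run manifest (one per CLI invocation) alongside outputs.

    Captures every parameter needed to regenerate the outputs: command,
    full config snapshot, seed, input/output paths, package version, and a
    timestamp.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": int(seed),
        "config": config.to_dict() if config is not None else None,
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "package_version": _package_version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def import_roi_patterns(volume_files, mask_file, labels: pd.DataFrame) -> pd.DataFrame:
    """Extract within-mask voxel vectors from per-condition coefficient maps.

    Parameters
    ----------
    volume_files : sequence of paths
        NIfTI-1 images, one coefficient map per (subject, condition,
        exemplar); all must share grid shape and affine with the mask.
    mask_file : path
        NIfTI-1 binary mask (non-zero = inside).
    labels : DataFrame
        Columns ``filename, subject_id, arrangement, numerosity, exemplar``
        mapping each volume's basename to its labels.

    Returns
    -------
    DataFrame in the tidy pattern-table layout, voxels ordered by ascending
    linear (C-order) index of the mask grid.
    """
    mask_img = nib.load(str(mask_file))
    mask = np.asarray(mask_img.dataobj)
    flat_idx = np.flatnonzero(mask.ravel(order="C"))
    if flat_idx.size == 0:
        raise ValidationError("mask contains no voxels")
    required = {"filename", "subject_id", "arrangement", "numerosity", "exemplar"}
    missing = required - set(labels.columns)
    if missing:
        raise ValidationError(f"labels table missing columns: {sorted(missing)}")
    label_map = {str(Path(f).name): row for f, row in
                 zip(labels["filename"], labels.to_dict("records"))}
    rows = []
    for vf in volume_files:
        name = Path(vf).name
        if name not in label_map:
            raise ValidationError(f"unlabeled volume: {name}")
        img = nib.load(str(vf))
        if img.shape != mask_img.shape or not np.allclose(img.affine, mask_img.affine):
            raise ValidationError(
                f"volume {name} grid/affine does not match the mask"
            )
        lab = label_map[name]
        ConditionLabel(str(lab["arrangement"]), int(lab["numerosity"]))  # validates
        data = np.asarray(img.dataobj, dtype=float).ravel(order="C")[flat_idx]
        row = {
            "subject_id": str(lab["subject_id"]),
            "arrangement": str(lab["arrangement"]),
            "numerosity": int(lab["numerosity"]),
            "exemplar": int(lab["exemplar"]),
        }
        row.update({f"voxel_{v}": data[v] for v in range(data.size)})
        rows.append(row)
    return pd.DataFrame(rows)
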