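"""Readers and writers for the formats the pipeline touches.

Voxel ordering convention (package-wide): in-mask voxels are extracted in
ascending linear index order, 0-based, x-fastest.  Every voxel-index TSV
written here states this in its header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from memtrace.searchlight import roi_coordinates

VOXEL_ORDER_NOTE = (
    "# voxel order: ascending linear index, 0-based, x-fastest (Fortran order)"
)


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary ROI mask NIfTI; returns (bool array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, img.affine


def write_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_pattern_set(
    path: str | Path,
    patterns: np.ndarray,
    roi_mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> None:
    """Write trials x voxels patterns as a 4-D NIfTI inside the ROI mask.

    Out-of-mask voxels are zero; frame t holds trial t's pattern.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    coords = roi_coordinates(mask)
    if patterns.shape[1] != len(coords):
        raise ValueError(
            f"pattern voxel count {patterns.shape[1]} does not match mask "
            f"in-mask count {len(coords)}"
        )
    vol = np.zeros(mask.shape + (patterns.shape[0],))
    vol[tuple(coords.T)] = patterns.T
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_pattern_set(
    path: str | Path,
    roi_mask: np.ndarray,
    n_trials: int | None = None,
) -> np.ndarray:
    """Read a 4-D NIfTI into a trials x voxels matrix using the mask order."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    mask = np.asarray(roi_mask, dtype=bool)
    if data.ndim != 4:
        raise ValueError("pattern file must be a 4-D volume")
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: volume {data.shape[:3]} vs mask {mask.shape}"
        )
    coords = roi_coordinates(mask)
    patterns = data[tuple(coords.T)].T  # trials x voxels
    if n_trials is not None and patterns.shape[0] != n_trials:
        raise ValueError(
            f"trial-count mismatch: volume has {patterns.shape[0]} frames, "
            f"trial table has {n_trials} rows"
        )
    return patterns


def write_voxel_index(path: str | Path, roi_mask: np.ndarray) -> None:
    """TSV mapping pattern columns to mask coordinates, with the order note."""
    coords = roi_coordinates(np.asarray(roi_mask, dtype=bool))
    with open(path, "w") as fh:
        fh.write(VOXEL_ORDER_NOTE + "\n")
        pd.DataFrame(coords, columns=["i", "j", "k"]).rename_axis("voxel").to_csv(
            fh, sep="\t"
        )


def write_trial_table(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scores(path: str | Path, scores: pd.DataFrame) -> None:
    """Tidy score TSV: subject, time_point_months, set, variant, score, n."""
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def scores_to_tidy(
    table: pd.DataFrame, variant: str, n_trials: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Wide subject x age score table -> tidy rows for the score TSV."""
    tidy = table.reset_index().melt(
        id_vars="subject", var_name="time_point_months", value_name="score"
    )
    tidy["variant"] = variant
    return tidy.sort_values(["subject", "time_point_months"]).reset_index(drop=True)


def tidy_to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    wide = tidy.pivot(index="subject", columns="time_point_months", values="score")
    wide.columns = [float(c) for c in wide.columns]
    return wide[sorted(wide.columns)]


def write_rsm(path: str | Path, matrix: np.ndarray, labels: pd.DataFrame) -> None:
    names = [
        f"m{int(r.memory_id)}_{r.set}_{r.time_point_months:g}M"
        for r in labels.itertuples()
    ]
    pd.DataFrame(matrix, index=names, columns=names).to_csv(path)


def write_map(
    path: str | Path, volume: np.ndarray, affine: np.ndarray | None = None
) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(volume, affine), str(path))


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
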