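"""NIfTI and table readers/writers plus the ranked-report writer."""

from __future__ import annotations

import difflib
import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .classify import ScreenResult

__all__ = [
    "CANONICAL_PREDICTORS",
    "load_volume",
    "save_volume",
    "load_table",
    "write_report",
]

# the 43 canonical predictor column names
CANONICAL_PREDICTORS = (
    "Normalized Grey Matter Volume",
    "Normalized White Matter Volume",
    "Normalized Whole Brain Volume",
    "Skeleton AD",
    "Skeleton FA",
    "Skeleton MD",
    "Skeleton RD",
    "T2-FLAIR Lesion Burden-absolute lesion volume",
    "T2-FLAIR Lesion Burden-relative lesion volume",
    "T2-FLAIR spatially distinct lesion count",
    "veBOLD",
    "veCBF",
    "veCMRO2",
    "ven",
    "10/36 Delayed Recall",
    "10/36 Immediate Recall",
    "25 Foot Walk",
    "9-Hole Peg Test-Dominant Hand",
    "9-Hole Peg Test-Non-dominant Hand",
    "Box Completion",
    "Controlled Oral Word Association Test",
    "Number Comparison",
    "Paced Auditory Serial Addition Test 2",
    "Paced Auditory Serial Addition Test 3",
    "Selective Reminding Task Delayed",
    "Selective Reminding Task Long-term Storage",
    "Symbol-digit Modalities Test",
    "Trail Making Task Form A",
    "Trail Making Task Form B",
    "Trail Making Task Form B-A",
    "WAIS-III Digit Span Backward",
    "WAIS-III Digit Span Forward",
    "WAIS-III Digit Span Total",
    "WAIS-III Digit symbol coding",
    "Modified Fatigue Impact Score",
    "SF-36 Bodily Pain Scale",
    "SF-36 Emotion",
    "SF-36 General Health Scale",
    "SF-36 Mental Health Scale",
    "SF-36 Physical Functioning Scale",
    "SF-36 Role Physical Function Scale",
    "SF-36 Social Functioning Scale",
    "SF-36 Vitality Scale",
)

# gas-challenge summary measures: reported group-wise but not model predictors
AUXILIARY_COLUMNS = ("M", "CBF response to CO2")


def load_volume(path):
    """Load a NIfTI volume/series -> (data array, voxel sizes in mm)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as err:  # malformed header, wrong magic, truncated file
        raise ValueError(f"cannot read NIfTI file {path}: {err}") from err
    return data, zooms


def save_volume(path, data, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Save an array as NIfTI-1 with a diagonal affine from the voxel sizes."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_table(path) -> pd.DataFrame:
    """Load a participant table (CSV/TSV) with a two-level ``group`` column.

    Predictor columns are coerced to numeric (bad cells become missing).
    Column names not among the canonical predictor vocabulary trigger a
    warning with the closest canonical match; the column is retained.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "group" not in df.columns:
        raise ValueError("participant table must contain a 'group' column")
    levels = pd.unique(df["group"].dropna())
    if len(levels) != 2:
        raise ValueError(f"'group' must have exactly two levels, got {list(levels)}")
    for col in df.columns:
        if col == "group":
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if (
            col not in CANONICAL_PREDICTORS
            and col not in AUXILIARY_COLUMNS
            and not col.startswith("null_")
        ):
            close = difflib.get_close_matches(col, CANONICAL_PREDICTORS, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            warnings.warn(f"unknown predictor column {col!r}{hint}", stacklevel=2)
    return df


def _config_hash(config) -> str:
    blob = json.dumps(vars(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(screen: ScreenResult, out_dir) -> dict:
    """Write the ranked results CSV and a full JSON record.

    The JSON carries run metadata (seed, config hash, package version)
    sufficient to reproduce the run exactly.  Returns the paths written.
    """
    from . import __version__

    if not screen.results:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = screen.to_frame()
    csv_path = out / "predictor_ranking.csv"
    frame.to_csv(csv_path, index=False)

    record = {
        "metadata": {
            "seed": screen.config.seed,
            "config_hash": _config_hash(screen.config),
            "config": vars(screen.config),
            "version": __version__,
        },
        "results": frame.to_dict(orient="records"),
        "group_comparisons": {
            name: vars(cmp) for name, cmp in screen.comparisons.items()
        },
        "skipped": screen.skipped,
    }
    json_path = out / "predictor_results.json"
    json_path.write_text(json.dumps(record, indent=2, default=float))
    return {"csv": csv_path, "json": json_path}
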