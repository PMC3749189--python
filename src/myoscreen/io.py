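"""Readers, writers, run logging and the curated hit-table resource.

All tabular formats are UTF-8 tab-separated text with a single header
row; field images travel as per-channel 16-bit grayscale TIFF files named
``{plate}_{well}_{field}_{channel}.tif``.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .hcs_imaging import FieldImage
from .screen_analysis import ROLES, LayoutEntry, PlateLayout

__all__ = [
    "read_plate_layout",
    "write_plate_layout",
    "read_screen_workbook",
    "read_table",
    "write_table",
    "load_curated_hit_table",
    "write_field_images",
    "read_field_images",
    "write_run_log",
    "file_sha256",
]

CHANNELS = ("hoechst", "mhc")

#: Metric columns expected in a screen workbook / well-metrics table.
WORKBOOK_METRICS = ("pct_myotubes", "cell_count")


def _read_delimited(path: Path) -> pd.DataFrame:
    # accept tab- or comma-separated files
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    if not head.strip():
        raise ValueError(f"{path}: empty file")
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    # only empty cells are missing; words like "null"/"NA" stay literal
    return pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[""])


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-separated table with a header row."""
    return _read_delimited(Path(path))


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 tab-separated text with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Parse and validate a plate layout table.

    Expects columns ``well``, ``reagent``, ``role`` and optionally
    ``concentration`` and ``replicate``.  Roles come from the closed
    vocabulary; duplicate wells, unknown roles and missing mock wells are
    rejected with descriptive errors.
    """
    table = _read_delimited(Path(path))
    cols = {c.lower(): c for c in table.columns}
    for needed in ("well", "reagent", "role"):
        if needed not in cols:
            raise ValueError(f"{path}: layout is missing a {needed!r} column")
    entries: dict[str, LayoutEntry] = {}
    for i, row in table.iterrows():
        well = str(row[cols["well"]])
        if well in entries:
            raise ValueError(f"{path}: duplicate well id {well!r} (row {i + 2})")
        role = str(row[cols["role"]])
        if role not in ROLES:
            raise ValueError(
                f"{path}: unknown role {role!r} in well {well!r} "
                f"(expected one of {sorted(ROLES)})"
            )
        entries[well] = LayoutEntry(
            reagent_id=str(row[cols["reagent"]]),
            role=role,
            concentration=float(row[cols["concentration"]])
            if "concentration" in cols
            else 100.0,
            replicate=int(row[cols["replicate"]]) if "replicate" in cols else 1,
        )
    return PlateLayout(entries=entries)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> Path:
    rows = [
        {
            "well": w,
            "reagent": e.reagent_id,
            "role": e.role,
            "concentration": e.concentration,
            "replicate": e.replicate,
        }
        for w, e in layout.entries.items()
    ]
    return write_table(pd.DataFrame(rows), path)


def read_screen_workbook(path: str | Path) -> pd.DataFrame:
    """Read a well-level raw screen table (spreadsheet or delimited text).

    One row per well/replicate with reagent, plate, well and the metric
    columns.  Non-numeric metric cells raise a row-level error naming the
    offending lines; percent values above 250 produce a warning but the
    rows are retained.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        table = pd.read_excel(path)
    else:
        table = _read_delimited(path)
    if table.empty:
        raise ValueError(f"{path}: table has no data rows")
    present = [m for m in WORKBOOK_METRICS if m in table.columns]
    if not present:
        raise ValueError(
            f"{path}: no metric columns found (expected any of {WORKBOOK_METRICS})"
        )
    bad_lines: list[int] = []
    for m in present:
        coerced = pd.to_numeric(table[m], errors="coerce")
        bad = table[m].notna() & coerced.isna()
        bad_lines.extend((table.index[bad] + 2).tolist())  # +2: header + 1-based
        table[m] = coerced
        if (coerced < 0).any():
            raise ValueError(f"{path}: negative values in column {m!r}")
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric metric cells on lines {sorted(set(bad_lines))}"
        )
    if "pct_myotubes" in table.columns and (table["pct_myotubes"] > 250).any():
        warnings.warn(
            f"{path}: pct_myotubes values above 250% retained; check units",
            stacklevel=2,
        )
    return table


def load_curated_hit_table() -> pd.DataFrame:
    """The curated final hit table shipped with the package.

    One row per hit entry (slash-joined family entries count once) with
    its category, relative myotube percentage, relative cell count and
    the significance codes of both Mann-Whitney tests.
    """
    ref = resources.files("myoscreen").joinpath("data/table1_hits.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# field images


def write_field_images(
    fields: Mapping[tuple[str, str, int], FieldImage] | list[FieldImage],
    out_dir: str | Path,
    config: Mapping[str, Any] | None = None,
) -> list[Path]:
    """Write per-channel 16-bit TIFF pairs plus a plain-text config sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(fields, Mapping):
        fields = list(fields.values())
    written = []
    for fld in fields:
        for channel in CHANNELS:
            arr = getattr(fld, channel)
            name = f"{fld.plate_id}_{fld.well_id}_{fld.field_index}_{channel}.tif"
            path = out_dir / name
            tifffile.imwrite(path, np.asarray(arr, dtype=np.uint16))
            written.append(path)
    if config is not None:
        sidecar = out_dir / "generation_config.json"
        sidecar.write_text(json.dumps(dict(config), indent=2, default=str))
        written.append(sidecar)
    return written


def read_field_images(in_dir: str | Path) -> list[FieldImage]:
    """Load every hoechst/mhc TIFF pair of a directory into FieldImages."""
    in_dir = Path(in_dir)
    fields = []
    for hoechst_path in sorted(in_dir.glob("*_hoechst.tif")):
        stem = hoechst_path.name[: -len("_hoechst.tif")]
        mhc_path = in_dir / f"{stem}_mhc.tif"
        if not mhc_path.exists():
            raise FileNotFoundError(f"missing mhc channel for field {stem!r}")
        plate_id, well_id, field_index = stem.rsplit("_", 2)
        fields.append(
            FieldImage(
                hoechst=tifffile.imread(hoechst_path),
                mhc=tifffile.imread(mhc_path),
                plate_id=plate_id,
                well_id=well_id,
                field_index=int(field_index),
            )
        )
    return fields


# ---------------------------------------------------------------------------
# run log


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(
    out_path: str | Path,
    stage: str,
    params: Mapping[str, Any],
    seed: int | None = None,
    inputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write a machine-readable run log (parameters, seed, versions, checksums)."""
    log = {
        "stage": stage,
        "seed": seed,
        "params": {k: str(v) for k, v in params.items()},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": {
            str(k): file_sha256(v) for k, v in (inputs or {}).items()
        },
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return out_path
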