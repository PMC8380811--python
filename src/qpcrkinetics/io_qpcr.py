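"""Reading, writing and design validation for the pipeline's tabular formats.

All tables are plain CSV and live in pandas DataFrames with fixed schemas:

* ``ct_long.csv``    — assay_id, sample_id, ct, chip_id (one row per reaction;
  a non-detect is stored as NaN in memory and an empty cell on disk)
* ``samples.csv``    — sample_id, cell_type, time_point, replicate,
  is_calibrator, qc_flags
* ``panel.csv``      — assay_id, gene_symbol, is_control_candidate,
  annotation_groups (semicolon-separated subset of
  TRANSCRIPTION / SIGNALING / ECM)

The ``time_point`` column holds canonical labels ("0", "1.5", ... or the
literal "monolayer"); see :mod:`qpcrkinetics.design`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .design import SamplingDesign

CT_COLUMNS = ["assay_id", "sample_id", "ct", "chip_id"]
SAMPLE_COLUMNS = ["sample_id", "cell_type", "time_point", "replicate", "is_calibrator", "qc_flags"]
PANEL_COLUMNS = ["assay_id", "gene_symbol", "is_control_candidate", "annotation_groups"]

#: Tokens in the ct column treated as "no threshold crossing" by default.
#: "999" and "NoCall" are common microfluidic-export dialects; an empty cell
#: is how this package itself serializes a non-detect.
DEFAULT_NONDETECT_TOKENS = ("", "999", "NoCall")

ANNOTATION_GROUPS = ("TRANSCRIPTION", "SIGNALING", "ECM")


class Dataset(NamedTuple):
    """A loaded Ct dataset: measurements, sample metadata and gene panel."""

    ct: pd.DataFrame
    samples: pd.DataFrame
    panel: pd.DataFrame


def parse_groups(cell: str | float) -> frozenset[str]:
    """Split a semicolon-separated annotation-group cell into a set."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    groups = frozenset(g.strip() for g in str(cell).split(";") if g.strip())
    unknown = groups - set(ANNOTATION_GROUPS)
    if unknown:
        raise ValueError(f"unknown annotation groups: {sorted(unknown)}")
    return groups


def _parse_bool(column: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = column.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = column[out.isna()].iloc[0]
        raise ValueError(f"cannot parse boolean value {bad!r}")
    return out.astype(bool)


def read_ct_long(
    ct_path: str | Path,
    samples_path: str | Path,
    panel_path: str | Path,
    design: SamplingDesign | None = None,
    nondetect_tokens: Sequence[str] = DEFAULT_NONDETECT_TOKENS,
) -> Dataset:
    """Load a long-format Ct table with its sample metadata and gene panel.

    Non-detect tokens in the ct column become NaN.  If ``design`` is given,
    every expected (cell type, time point, replicate) cell is checked; missing
    cells are reported as a warning, duplicated cells are a hard error.

    Raises
    ------
    ValueError
        On a duplicate (assay_id, sample_id) pair, on a data sample absent
        from the metadata, or on malformed Ct values.
    """
    ct = pd.read_csv(ct_path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(ct, CT_COLUMNS, ct_path)
    ct = ct[CT_COLUMNS].copy()

    tokens = {str(t) for t in nondetect_tokens}
    raw = ct["ct"].str.strip()
    is_nondetect = raw.isin(tokens)
    values = pd.to_numeric(raw.where(~is_nondetect), errors="coerce")
    bad = ~is_nondetect & values.isna()
    if bad.any():
        raise ValueError(f"unparseable ct value {raw[bad].iloc[0]!r} in {ct_path}")
    detected = values.dropna()
    out_of_range = detected[(detected <= 0) | (detected > 40)]
    if not out_of_range.empty:
        raise ValueError(
            f"ct value {out_of_range.iloc[0]:g} outside (0, 40] in {ct_path}"
        )
    ct["ct"] = values.astype(float)

    dup = ct.duplicated(subset=["assay_id", "sample_id"])
    if dup.any():
        pair = ct.loc[dup, ["assay_id", "sample_id"]].iloc[0]
        raise ValueError(
            f"duplicate measurement for assay {pair['assay_id']!r}, "
            f"sample {pair['sample_id']!r}"
        )

    samples = read_samples(samples_path)
    panel = read_panel(panel_path)

    unknown = set(ct["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"samples present in data but absent from metadata: {sorted(unknown)[:5]}")
    unknown_assays = set(ct["assay_id"]) - set(panel["assay_id"])
    if unknown_assays:
        warnings.warn(f"assays absent from panel: {sorted(unknown_assays)[:5]}", stacklevel=2)

    if design is not None:
        missing = validate_design(samples, design)
        if missing:
            warnings.warn(f"{len(missing)} design cells have no sample, e.g. {missing[:3]}", stacklevel=2)

    return Dataset(ct=ct, samples=samples, panel=panel)


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(samples, SAMPLE_COLUMNS[:5], path)
    if "qc_flags" not in samples.columns:
        samples["qc_flags"] = ""
    samples = samples[SAMPLE_COLUMNS].copy()
    samples["replicate"] = samples["replicate"].astype(int)
    samples["is_calibrator"] = _parse_bool(samples["is_calibrator"])
    n_cal = int(samples["is_calibrator"].sum())
    if n_cal != 1:
        raise ValueError(f"exactly one calibrator sample must be designated, found {n_cal}")
    experimental = samples[~samples["is_calibrator"]]
    dup = experimental.duplicated(subset=["cell_type", "time_point", "replicate"])
    if dup.any():
        cell = experimental.loc[dup, ["cell_type", "time_point", "replicate"]].iloc[0]
        raise ValueError(f"duplicate design cell {tuple(cell)}")
    return samples


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(panel, PANEL_COLUMNS[:3], path)
    if "annotation_groups" not in panel.columns:
        panel["annotation_groups"] = ""
    panel = panel[PANEL_COLUMNS].copy()
    panel["is_control_candidate"] = _parse_bool(panel["is_control_candidate"])
    if panel["gene_symbol"].duplicated().any():
        dup = panel.loc[panel["gene_symbol"].duplicated(), "gene_symbol"].iloc[0]
        raise ValueError(f"duplicate gene symbol {dup!r} in panel")
    for _, row in panel.iterrows():
        groups = parse_groups(row["annotation_groups"])
        if row["is_control_candidate"] and groups:
            raise ValueError(
                f"endogenous-control candidate {row['gene_symbol']!r} must not "
                f"carry annotation groups"
            )
    return panel


def validate_design(samples: pd.DataFrame, design: SamplingDesign) -> list[tuple[str, str, int]]:
    """Return every design cell with no experimental sample mapped to it.

    Non-experimental rows (the calibrator) are ignored.
    """
    experimental = samples[~samples["is_calibrator"]]
    present = {
        (row.cell_type, row.time_point, int(row.replicate))
        for row in experimental.itertuples()
    }
    return [cell for cell in design.expected_cells() if cell not in present]


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a table as deterministic CSV.

    Columns keep their order; rows are sorted by all non-float columns (the
    key columns of every table in this package), floats are serialized with 6
    significant digits and NaN as an empty cell, so two writes of the same
    table are byte-identical.

    Raises
    ------
    ValueError
        For an empty table (no file is created).
    """
    if records is None or len(records) == 0:
        raise ValueError("refusing to write an empty table")
    key_cols = [c for c in records.columns if records[c].dtype.kind not in "fc"]
    out = records.sort_values(key_cols, kind="mergesort") if key_cols else records
    out.to_csv(path, index=False, float_format="%.6g", na_rep="", lineterminator="\n")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
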