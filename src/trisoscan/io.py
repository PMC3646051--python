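"""Trio-table and intensity-table TSV dialects, plus the packaged fixture.

The trio table is tab-separated with a header and optional '#'-prefixed
comment lines carrying provenance (seed, version).  Dosage columns are
minor-allele counts; one row per trio x SNP.  Two role layouts are
accepted: cdjp_dosage/ndjp_dosage, or father_dosage/mother_dosage with
an ndjp_side column.  The intensity table holds six raw probe
intensities per individual x SNP (three per allele).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = [
    "TrioTableError",
    "read_trio_table",
    "write_trio_table",
    "read_intensity_table",
    "write_intensity_table",
    "load_rs2837770_triads",
]

_META_COLUMNS = ["trio_id", "snp_id", "position", "minor_allele", "major_allele"]
_ROLE_LAYOUT = ["cdjp_dosage", "ndjp_dosage", "child_dosage", "ploidy"]
_SIDE_LAYOUT = ["father_dosage", "mother_dosage", "ndjp_side", "child_dosage", "ploidy"]
_INTENSITY_COLUMNS = ["individual_id", "snp_id", "a1", "a2", "a3", "b1", "b2", "b3"]


class TrioTableError(ValueError):
    """Malformed trio table; the message lists the offending lines."""


def _data_line_numbers(path) -> np.ndarray:
    """1-based file line number of each data row (skipping comments + header)."""
    numbers = []
    header_seen = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            numbers.append(i)
    return np.asarray(numbers)


def read_trio_table(path) -> pd.DataFrame:
    """Read and validate a trio genotype TSV.

    Violations (non-integer or out-of-range dosages, unknown ploidy,
    duplicate trio x SNP rows) raise :class:`TrioTableError` naming the
    offending file lines.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"trio_id": str, "snp_id": str})
    cols = set(df.columns)
    if not (set(_ROLE_LAYOUT) <= cols or set(_SIDE_LAYOUT) <= cols):
        raise TrioTableError(
            f"{path}: header must contain {_ROLE_LAYOUT} or {_SIDE_LAYOUT}"
        )
    lines = _data_line_numbers(path)
    if len(lines) != len(df):
        lines = np.arange(2, len(df) + 2)  # fall back to row order

    def _complain(mask: np.ndarray, what: str):
        if mask.any():
            bad = ", ".join(str(n) for n in lines[np.asarray(mask)][:20])
            raise TrioTableError(f"{path}: {what} at line(s) {bad}")

    _complain(~df["ploidy"].isin((2, 3)).to_numpy(), "ploidy must be 2 or 3")
    parent_cols = [c for c in ("cdjp_dosage", "ndjp_dosage", "father_dosage",
                               "mother_dosage") if c in cols]
    for c in parent_cols + ["child_dosage"]:
        vals = pd.to_numeric(df[c], errors="coerce")
        _complain(((vals % 1 != 0) | vals.isna()).to_numpy(), f"non-integer {c}")
        df[c] = vals.astype(int)
    for c in parent_cols:
        _complain(((df[c] < 0) | (df[c] > 2)).to_numpy(), f"{c} outside {{0,1,2}}")
    _complain(
        ((df["child_dosage"] < 0) | (df["child_dosage"] > df["ploidy"])).to_numpy(),
        "child_dosage outside ploidy bounds",
    )
    if "ndjp_side" in cols:
        _complain(~df["ndjp_side"].isin(("maternal", "paternal")).to_numpy(),
                  "ndjp_side must be 'maternal' or 'paternal'")
    _complain(df.duplicated(["trio_id", "snp_id"], keep=False).to_numpy(),
              "duplicate trio x SNP row")
    return df


def write_trio_table(df: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write a trio table in canonical column order with provenance comments."""
    ordered = [c for c in _META_COLUMNS + _SIDE_LAYOUT + _ROLE_LAYOUT if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df[ordered].to_csv(fh, sep="\t", index=False)


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"individual_id": str, "snp_id": str})
    missing = [c for c in _INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise TrioTableError(f"{path}: intensity table missing columns {missing}")
    if (df[["a1", "a2", "a3", "b1", "b2", "b3"]] < 0).any().any():
        raise TrioTableError(f"{path}: negative probe intensity")
    return df


def write_intensity_table(df: pd.DataFrame, path,
                          comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df[_INTENSITY_COLUMNS].to_csv(fh, sep="\t", index=False)


def load_rs2837770_triads() -> pd.DataFrame:
    """The packaged 26-triad rs2837770 genotype fixture (trisomic children)."""
    ref = importlib.resources.files("trisoscan.data") / "rs2837770_triads.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_trio_table(path)
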