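"""Delimited-text readers and writers for pipeline artifacts.

All tables are TSV with a header row, '.' decimal point, UTF-8.  Time-series
files carry the region label in the first column and one sample per
remaining column; floats are written with ``repr`` so values round-trip
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hoi import OmegaMatrix, RegionTimeSeries

__all__ = [
    "read_timeseries_matrix",
    "write_timeseries_matrix",
    "read_omega",
    "write_omega",
    "read_cohort_table",
    "write_report",
]

_REJECTED_SUFFIXES = {".nii", ".gz", ".edf", ".vhdr", ".bdf", ".fif"}


class ParseError(ValueError):
    """Malformed input file."""


def _check_suffix(path: Path) -> None:
    if path.suffix.lower() in _REJECTED_SUFFIXES:
        raise ParseError(
            f"{path}: neuroimaging/EEG container formats are not supported; "
            "provide parcellated TSV matrices (preprocessing is out of scope)"
        )


def read_timeseries_matrix(
    path: str | Path,
    modality: str = "fMRI",
    tr: float | None = None,
    sampling_rate: float | None = None,
) -> RegionTimeSeries:
    """Read a region x samples TSV (first column = region label)."""
    path = Path(path)
    _check_suffix(path)
    labels: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ParseError(
                    f"{path}: ragged row {lineno} has {len(cells)} cells, expected {width}"
                )
            labels.append(cells[0])
            values = []
            for col, cell in enumerate(cells[1:], start=2):
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell at row {lineno}, column {col}: {cell!r}"
                    ) from None
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: empty time-series file")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ParseError(f"{path}: duplicate region labels {dupes}")
    return RegionTimeSeries(
        values=np.array(rows, dtype=float),
        region_labels=labels,
        modality=modality,
        tr=tr,
        sampling_rate=sampling_rate,
        subject_id=path.stem.replace("_timeseries", ""),
    )


def write_timeseries_matrix(ts: RegionTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for label, row in zip(ts.region_labels, ts.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_omega(m: OmegaMatrix, path: str | Path) -> None:
    """Square TSV with label header row/column plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region\t" + "\t".join(m.region_labels) + "\n")
        for label, row in zip(m.region_labels, m.omega):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "normalized": m.normalized,
        "normalization_constant": m.normalization_constant,
        "modality": m.modality,
        "n_samples": m.n_samples,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_omega(path: str | Path) -> OmegaMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return OmegaMatrix(
        omega=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        normalized=bool(meta.get("normalized", False)),
        normalization_constant=float(meta.get("normalization_constant", 0.0)),
        modality=meta.get("modality", "fMRI"),
        n_samples=int(meta.get("n_samples", 0)),
    )


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: cohort table missing columns {sorted(missing)}")
    return df


def write_report(results: dict, out_dir: str | Path, config_hash: str = "") -> None:
    """Write result tables as TSV plus a fixed-precision summary file.

    ``results`` maps names to DataFrames (written as ``<name>.tsv``) or
    scalars (collected into the summary).  Re-rendering identical results is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for name, value in sorted(results.items()):
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        else:
            scalars[name] = value
    lines = ["# braingap summary (floats rendered with %.6g)"]
    if config_hash:
        lines.append(f"config_hash\t{config_hash}")
    for name, value in sorted(scalars.items()):
        if isinstance(value, float):
            lines.append(f"{name}\t{value:.6g}")
        else:
            lines.append(f"{name}\t{value}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
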