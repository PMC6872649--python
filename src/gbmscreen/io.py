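"""Readers and writers for the pipeline's plain-text formats.

Viability tables are long-format CSV/TSV with columns (cell_line, drug,
concentration, unit, replicate, viability); expression matrices are
gene-id-first-column TSV or GCT 1.2; clinical tables are TSV with
(sample, subtype, os_days, event).  Concentrations are stored internally in
nM; micromolar inputs are converted on read.  All writers round-trip
losslessly at the printed precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries
from .exceptions import SchemaError, UnitError, ValidationError

log = logging.getLogger(__name__)

VIABILITY_COLUMNS = ["cell_line", "drug", "concentration", "unit", "replicate", "viability"]
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "μm": 1e3, "mm": 1e6, "m": 1e9}


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_viability_table(path) -> list[DoseResponseSeries]:
    """Read a long-format viability table into per-(cell line, drug) series.

    Each series must use a single concentration unit (mixed units within one
    series are rejected); units are converted to nM internally.
    """
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"viability table missing column(s): {missing}")
    bad = df.index[pd.to_numeric(df["viability"], errors="coerce").isna()]
    if len(bad):
        raise ValidationError(f"non-numeric viability at data row(s): {list(bad[:5] + 2)}")
    series = []
    for (line, drug), grp in df.groupby(["cell_line", "drug"], sort=True):
        units = {str(u).strip().lower() for u in grp["unit"]}
        if len(units) != 1:
            raise UnitError(f"mixed concentration units in series {line}/{drug}: {sorted(units)}")
        unit = units.pop()
        if unit not in _UNIT_TO_NM:
            raise UnitError(f"unrecognised concentration unit {unit!r} in series {line}/{drug}")
        factor = _UNIT_TO_NM[unit]
        conc = np.sort(grp["concentration"].astype(float).unique()) * factor
        reps = tuple(
            grp.loc[np.isclose(grp["concentration"].astype(float) * factor, c), "viability"]
            .astype(float)
            .to_numpy()
            for c in conc
        )
        series.append(DoseResponseSeries(str(line), str(drug), conc, reps, unit="nM"))
    return series


def write_viability_table(series: list[DoseResponseSeries], path) -> None:
    rows = []
    for s in series:
        for dose, reps in zip(s.doses, s.viability):
            for j, v in enumerate(reps, start=1):
                rows.append((s.cell_line, s.drug, repr(float(dose)), s.unit, j, repr(float(v))))
    pd.DataFrame(rows, columns=VIABILITY_COLUMNS).to_csv(path, sep=_sep(path), index=False)


def read_expression_matrix(path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    Duplicate gene identifiers are rejected; GCT dimension lines are checked
    against the body.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise SchemaError(f"expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise SchemaError("malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise SchemaError(
                f"GCT dimension line declares {n_genes}x{n_samples}, body is {df.shape[0]}x{df.shape[1]}"
            )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValidationError(f"unknown expression format {format!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers: {dup[:10]}")
    df.index.name = "gene"
    return df.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            out = expr.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        out = expr.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV (sample, subtype, os_days, event), indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    need = ["sample", "subtype", "os_days", "event"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {missing}")
    df = df.set_index("sample")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 or 1")
    return df


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    clinical.rename_axis("sample").to_csv(path, sep="\t")
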