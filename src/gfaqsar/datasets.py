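"""Descriptor/activity tables and the packaged HDM2-inhibitor datasets.

The unit of work throughout the package is the :class:`DescriptorTable`: an
ordered collection of ligands, each carrying a named set of molecular
descriptors and, for training compounds, an observed activity expressed as
pIC50 on the millimolar scale.  Two tables of 1,4-benzodiazepine-2,5-dione
(BDP) HDM2 antagonists ship with the package: ``table2`` (59 compounds x 8
descriptors from a commercial molecular-properties calculator) and
``table3`` (the same 59 compounds x 11 descriptors from the E-Dragon
descriptor engine, plus two designed compounds "I" and "II" without measured
activity).  Both tables also carry the originally published predicted
activities and residuals, which are used only for transcription checks and
comparisons, never for fitting.

CSV dialect: one header row, ``ligand_id`` first, descriptor columns in
table order, then the optional activity columns ``pIC50_obs``,
``pIC50_pred`` and ``residual``.  Empty activity cells mean "absent", which
is how prediction-only compounds are represented.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SchemaError, TableParseError, ValidationError

#: Columns that are never descriptors.
RESERVED_COLUMNS = ("ligand_id", "pIC50_obs", "pIC50_pred", "residual")

#: Descriptor schema of the packaged 8-descriptor table.
TABLE2_DESCRIPTORS = (
    "LogD",
    "Num_RotatableBonds",
    "Num_StereoAtoms",
    "V_DIST_equ",
    "CHI_1",
    "Dipole_X",
    "Shadow_Xlength",
    "Shadow_XZ",
)

#: Descriptor schema of the packaged 11-descriptor table.  The last
#: descriptor appears in the source both as "SeaC2C3aa" and
#: "SeaC2C3aa.Count16"; the short form is the canonical name here.
TABLE3_DESCRIPTORS = (
    "IDE",
    "MATS7v",
    "DP09",
    "Mor14m",
    "Mor30p",
    "G2e",
    "E2e",
    "Tp",
    "R5u",
    "BELp6",
    "SeaC2C3aa",
)

KNOWN_SCHEMAS = {"table2": TABLE2_DESCRIPTORS, "table3": TABLE3_DESCRIPTORS}

#: Half an ulp of the 3-decimal printed activities: tolerance for the
#: obs - pred = residual transcription cross-check.
RESIDUAL_TOLERANCE = 0.002


@dataclass
class LigandRecord:
    """One compound: identifier, descriptor values and optional activities.

    ``pic50_pred_printed`` and ``residual_printed`` are the values printed in
    the source tables; they document the original models and are not inputs
    to any fit.
    """

    ligand_id: str
    descriptors: dict[str, float]
    pic50_obs: float | None = None
    pic50_pred_printed: float | None = None
    residual_printed: float | None = None

    @property
    def is_training(self) -> bool:
        return self.pic50_obs is not None


@dataclass
class DescriptorTable:
    """An ordered set of :class:`LigandRecord` sharing one descriptor schema."""

    schema: tuple[str, ...]
    records: list[LigandRecord] = field(default_factory=list)
    name: str = "user"

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.ligand_id in seen:
                raise ValidationError(
                    f"duplicate ligand_id {rec.ligand_id!r} in table {self.name!r}"
                )
            seen.add(rec.ligand_id)
            missing = [d for d in self.schema if d not in rec.descriptors]
            if missing:
                raise SchemaError(
                    f"ligand {rec.ligand_id!r} lacks descriptor(s) {missing}"
                )
            for d in self.schema:
                v = rec.descriptors[d]
                if v is None or not math.isfinite(v):
                    raise ValidationError(
                        f"non-finite value for {d!r} in ligand {rec.ligand_id!r}"
                    )
            if (
                rec.pic50_obs is not None
                and rec.pic50_pred_printed is not None
                and rec.residual_printed is not None
            ):
                gap = abs(
                    rec.pic50_obs - rec.pic50_pred_printed - rec.residual_printed
                )
                if gap > RESIDUAL_TOLERANCE:
                    raise ValidationError(
                        f"ligand {rec.ligand_id!r}: obs - pred != residual "
                        f"(gap {gap:.4f} > {RESIDUAL_TOLERANCE})"
                    )

    # -- views -------------------------------------------------------------
    @property
    def training_records(self) -> list[LigandRecord]:
        return [r for r in self.records if r.is_training]

    @property
    def prediction_records(self) -> list[LigandRecord]:
        return [r for r in self.records if not r.is_training]

    @property
    def n_training(self) -> int:
        return len(self.training_records)

    def record(self, ligand_id: str) -> LigandRecord:
        for r in self.records:
            if r.ligand_id == str(ligand_id):
                return r
        raise KeyError(f"no ligand {ligand_id!r} in table {self.name!r}")

    def matrix(self, terms: Sequence[str], records: Iterable[LigandRecord] | None = None) -> np.ndarray:
        """Descriptor matrix (rows = records, columns = ``terms``)."""
        missing = [t for t in terms if t not in self.schema]
        if missing:
            raise SchemaError(f"term(s) {missing} not in schema of {self.name!r}")
        recs = list(records) if records is not None else self.training_records
        return np.array(
            [[r.descriptors[t] for t in terms] for r in recs], dtype=float
        ).reshape(len(recs), len(terms))

    def response(self, records: Iterable[LigandRecord] | None = None) -> np.ndarray:
        recs = list(records) if records is not None else self.training_records
        vals = [r.pic50_obs for r in recs]
        if any(v is None for v in vals):
            raise ValidationError("response requested for record(s) without pIC50_obs")
        return np.array(vals, dtype=float)

    def subset_records(self, ligand_ids: Sequence[str]) -> list[LigandRecord]:
        return [self.record(i) for i in ligand_ids]


# ---------------------------------------------------------------------------
# I/O


def _parse_cell(text: str, row: int, column: str) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise TableParseError(
            f"cannot parse {text!r} as a number (row {row}, column {column!r})"
        ) from None


def load_table(
    path: str | Path,
    schema_name: str | None = None,
    name: str | None = None,
) -> DescriptorTable:
    """Read a descriptor table from CSV.

    Parameters
    ----------
    path:
        CSV file in the package dialect (see module docstring).
    schema_name:
        ``"table2"`` or ``"table3"`` to enforce the corresponding packaged
        schema, or ``None`` to take the schema from the header (every
        non-reserved column, in file order).
    name:
        Label stored on the table; defaults to ``schema_name`` or the file
        stem.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path} is empty") from None
        header = [h.strip() for h in header]
        if "ligand_id" not in header:
            raise SchemaError(f"{path}: no 'ligand_id' column")
        if schema_name is not None:
            try:
                schema = KNOWN_SCHEMAS[schema_name]
            except KeyError:
                raise SchemaError(
                    f"unknown schema {schema_name!r}; expected one of {sorted(KNOWN_SCHEMAS)}"
                ) from None
            missing = [c for c in schema if c not in header]
            if missing:
                raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema_name!r}")
        else:
            schema = tuple(c for c in header if c not in RESERVED_COLUMNS)
        idx = {c: header.index(c) for c in header}
        records: list[LigandRecord] = []
        for rownum, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            def cell(col: str) -> float | None:
                if col not in idx or idx[col] >= len(row):
                    return None
                return _parse_cell(row[idx[col]], rownum, col)

            descriptors = {}
            for d in schema:
                v = cell(d)
                if v is None:
                    raise TableParseError(
                        f"empty descriptor cell (row {rownum}, column {d!r})"
                    )
                descriptors[d] = v
            records.append(
                LigandRecord(
                    ligand_id=row[idx["ligand_id"]].strip(),
                    descriptors=descriptors,
                    pic50_obs=cell("pIC50_obs"),
                    pic50_pred_printed=cell("pIC50_pred"),
                    residual_printed=cell("residual"),
                )
            )
    return DescriptorTable(
        schema=schema,
        records=records,
        name=name or schema_name or path.stem,
    )


def write_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a table back to CSV; ``load_table`` of the result round-trips."""
    path = Path(path)

    def fmt(v: float | None) -> str:
        if v is None:
            return ""
        return repr(v)

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ligand_id", *table.schema, "pIC50_obs", "pIC50_pred", "residual"])
        for rec in table.records:
            writer.writerow(
                [rec.ligand_id]
                + [repr(rec.descriptors[d]) for d in table.schema]
                + [fmt(rec.pic50_obs), fmt(rec.pic50_pred_printed), fmt(rec.residual_printed)]
            )


def _packaged(filename: str) -> Path:
    return Path(resources.files("gfaqsar.data") / filename)


def load_table2() -> DescriptorTable:
    """The packaged 8-descriptor BDP table (59 training compounds)."""
    return load_table(_packaged("table2.csv"), schema_name="table2")


def load_table3() -> DescriptorTable:
    """The packaged 11-descriptor BDP table (59 training + designed I, II)."""
    return load_table(_packaged("table3.csv"), schema_name="table3")


# ---------------------------------------------------------------------------
# Unit conversion


def ic50_to_pic50(ic50_micromolar: float) -> float:
    """Convert an IC50 in uM to pIC50 on the millimolar scale.

    pIC50 = -log10(IC50 in mM) = 3 - log10(IC50 in uM).  An IC50 of 1000 uM
    (1 mM) maps to 0; smaller (more potent) IC50 gives larger pIC50.
    """
    if not (ic50_micromolar > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_micromolar!r}")
    return 3.0 - math.log10(ic50_micromolar)
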