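"""Patient cohort data model and delimited-file I/O.

A cohort is a collection of per-patient molecule expression profiles, each
expressed as percent change of the patient-specific disease steady state
relative to a non-tumorigenic baseline.  Every record carries the predicted
PD-L1 percent change, the percent changes of the 14 canonical
immunosuppressive molecules (ISMs), a weighted dendritic-cell (DC)
infiltration index, and optionally the 9 chemokine percent changes from
which that index is built.

The package ships a transcription of the published 29-patient NSCLC cohort
(13 discovery + 16 validation patients treated with pembrolizumab) as a
reference fixture; its recorded predicted-response and match columns are
kept as metadata only and are never consumed by the classifier.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ISM_NAMES",
    "CHEMOKINE_NAMES",
    "Dataset",
    "Response",
    "PatientRecord",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "bundled_fixture",
    "sa97v5_chemokine_profile",
]

#: Canonical names of the 14 immunosuppressive molecules, in report order.
ISM_NAMES: tuple[str, ...] = (
    "TGFB1", "IDO1", "IL6", "VEGFA", "TDO2", "PGE2", "IL10",
    "LGALS9", "FASLG", "CD47", "CTLA4", "PDCD1LG2", "GM3", "GD2",
)

#: Canonical names of the 9 DC-trafficking chemokines, in report order.
CHEMOKINE_NAMES: tuple[str, ...] = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL7", "CCL11", "CCL20",
    "CX3CL1", "CXCL14",
)

# Spelling variants that appear in the literature for the same molecules.
MOLECULE_SYNONYMS: dict[str, str] = {
    "CX3CL": "CX3CL1",
    "PD-L1": "PDL1",
    "PD-L2": "PDCD1LG2",
    "PDL2": "PDCD1LG2",
    "VEGF": "VEGFA",
    "FASL": "FASLG",
    "TGFB": "TGFB1",
    "IDO": "IDO1",
    "DC INDEX": "DC_index",
    "DC_INDEX": "DC_index",
}

_METADATA_COLUMNS = ("predicted_response", "score")

_REQUIRED_COLUMNS = (
    ("study_id", "dataset", "clinical_response", "PDL1")
    + ISM_NAMES
    + ("DC_index",)
)


class SchemaError(ValueError):
    """A cohort file does not conform to the expected column schema."""


class CohortValidationError(ValueError):
    """A parsed cohort violates a record- or cohort-level invariant."""


class Dataset(str, enum.Enum):
    DISCOVERY = "discovery"
    VALIDATION = "validation"


class Response(str, enum.Enum):
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"


def canonical_molecule(name: str) -> str:
    """Map a molecule spelling variant to its canonical name."""
    stripped = name.strip()
    return MOLECULE_SYNONYMS.get(stripped.upper(), stripped)


@dataclass
class PatientRecord:
    """One patient's percent-change expression profile plus labels.

    ``meta`` holds reference annotations (e.g. the published predicted
    response) that must never feed back into classification.
    """

    study_id: str
    dataset: Dataset
    clinical_response: Response
    pdl1_pct: float
    ism_pct: dict[str, float]
    dc_index_pct: float
    chemokine_pct: dict[str, float] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dataset = Dataset(self.dataset)
        self.clinical_response = Response(self.clinical_response)
        self.validate()

    def validate(self) -> None:
        if not self.study_id:
            raise CohortValidationError("study_id must be non-empty")
        got = set(self.ism_pct)
        expected = set(ISM_NAMES)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise CohortValidationError(
                f"record {self.study_id!r}: ism_pct must contain exactly the "
                f"14 canonical molecules (missing={missing}, extra={extra})"
            )
        if self.chemokine_pct is not None:
            got_c = set(self.chemokine_pct)
            expected_c = set(CHEMOKINE_NAMES)
            if got_c != expected_c:
                raise CohortValidationError(
                    f"record {self.study_id!r}: chemokine_pct must contain "
                    f"exactly the 9 canonical chemokines "
                    f"(missing={sorted(expected_c - got_c)}, "
                    f"extra={sorted(got_c - expected_c)})"
                )
        for label, value in self._numeric_items():
            if not math.isfinite(value):
                raise CohortValidationError(
                    f"record {self.study_id!r}: non-finite value for {label}"
                )

    def _numeric_items(self) -> Iterator[tuple[str, float]]:
        yield "PDL1", self.pdl1_pct
        yield "DC_index", self.dc_index_pct
        yield from self.ism_pct.items()
        if self.chemokine_pct is not None:
            yield from self.chemokine_pct.items()


@dataclass
class Cohort:
    """An ordered collection of patient records with unique study IDs."""

    records: list[PatientRecord]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise CohortValidationError(
                    f"duplicate study_id {rec.study_id!r} in cohort"
                )
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def get(self, study_id: str) -> PatientRecord:
        for rec in self.records:
            if rec.study_id == study_id:
                return rec
        raise KeyError(study_id)

    def subset(self, dataset: Dataset | str) -> "Cohort":
        dataset = Dataset(dataset)
        return Cohort(
            [r for r in self.records if r.dataset == dataset],
            name=f"{self.name}:{dataset.value}" if self.name else dataset.value,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per patient (canonical column order)."""
        rows = []
        has_chemokines = all(r.chemokine_pct is not None for r in self.records)
        for rec in self.records:
            row: dict[str, object] = {
                "study_id": rec.study_id,
                "dataset": rec.dataset.value,
                "clinical_response": rec.clinical_response.value,
            }
            for key in _METADATA_COLUMNS:
                if key in rec.meta:
                    row[key] = rec.meta[key]
            row["PDL1"] = rec.pdl1_pct
            row.update({m: rec.ism_pct[m] for m in ISM_NAMES})
            row["DC_index"] = rec.dc_index_pct
            if has_chemokines:
                row.update({c: rec.chemokine_pct[c] for c in CHEMOKINE_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


# Some published tables typeset negative values with a Unicode minus sign and
# a thin space between sign and digits; accept those on ingestion.
_NUMERIC_TRANSLATION = str.maketrans({"−": "-", " ": "", " ": "", " ": ""})


def _parse_numeric(cell: object, row_label: str, column: str) -> float:
    text = str(cell).translate(_NUMERIC_TRANSLATION)
    try:
        return float(text)
    except ValueError:
        raise SchemaError(
            f"unparseable numeric value {cell!r} in row {row_label!r}, "
            f"column {column!r}"
        ) from None


def _dialect_sep(path: Path | str, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".tab")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def load_cohort(path: Path | str, dialect: str | None = None, name: str | None = None) -> Cohort:
    """Read a patient cohort from a delimited file.

    Molecule column headers are normalised to canonical spelling; numeric
    cells may use ASCII or Unicode minus signs.  Chemokine columns are
    optional but must be all-present or all-absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    sep = _dialect_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [canonical_molecule(c) for c in frame.columns]

    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r} in {path}")

    chemo_present = [c for c in CHEMOKINE_NAMES if c in frame.columns]
    if chemo_present and len(chemo_present) != len(CHEMOKINE_NAMES):
        missing = sorted(set(CHEMOKINE_NAMES) - set(chemo_present))
        raise SchemaError(
            f"chemokine columns are partial in {path}: missing {missing}"
        )

    records = []
    for _, row in frame.iterrows():
        sid = str(row["study_id"]).strip()
        meta = {
            key: str(row[key]).strip()
            for key in _METADATA_COLUMNS
            if key in frame.columns and pd.notna(row[key])
        }
        records.append(
            PatientRecord(
                study_id=sid,
                dataset=str(row["dataset"]).strip().lower(),
                clinical_response=str(row["clinical_response"]).strip().lower(),
                pdl1_pct=_parse_numeric(row["PDL1"], sid, "PDL1"),
                ism_pct={
                    m: _parse_numeric(row[m], sid, m) for m in ISM_NAMES
                },
                dc_index_pct=_parse_numeric(row["DC_index"], sid, "DC_index"),
                chemokine_pct=(
                    {c: _parse_numeric(row[c], sid, c) for c in CHEMOKINE_NAMES}
                    if chemo_present
                    else None
                ),
                meta=meta,
            )
        )
    return Cohort(records, name=name if name is not None else path.stem)


def write_cohort(cohort: Cohort, path: Path | str, dialect: str | None = None) -> None:
    """Write a cohort to a delimited file.

    Values are written at full float precision so that a load/write/load
    round trip reproduces the cohort exactly.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    if len(cohort) == 0:
        header = list(_REQUIRED_COLUMNS)
        # keep DC_index last, as in the canonical layout
        try:
            path.write_text(sep.join(header) + "\n")
        except OSError as exc:
            raise OSError(f"failed to write cohort to {path}: {exc}") from exc
        return
    frame = cohort.to_frame()
    try:
        frame.to_csv(path, sep=sep, index=False, float_format=None)
    except OSError as exc:
        raise OSError(f"failed to write cohort to {path}: {exc}") from exc


def _data_path(filename: str):
    return resources.files("immunotree.data").joinpath(filename)


def bundled_fixture() -> Cohort:
    """The packaged 29-patient reference cohort (13 discovery + 16 validation).

    The ``predicted_response`` and ``score`` metadata columns record the
    published per-patient predictions and match/mismatch calls; they serve as
    an oracle for validating the classifier and are never inputs to it.
    """
    with resources.as_file(_data_path("table1.csv")) as path:
        return load_cohort(path, dialect="csv", name="reference")


def sa97v5_chemokine_profile() -> dict[str, float]:
    """The published 9-chemokine percent-change profile of patient SA97V5."""
    with resources.as_file(_data_path("sa97v5_chemokines.csv")) as path:
        frame = pd.read_csv(path)
    row = frame.iloc[0]
    return {c: float(row[c]) for c in CHEMOKINE_NAMES}
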