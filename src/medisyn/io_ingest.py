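"""Read/write the two source-table dialects and the serialized store.

Both upstream resources export delimited tables; the default dialects are
tab-separated UTF-8 with a header row and named columns (column order is
irrelevant).  Rows that fail validation are collected as
:class:`~medisyn.errors.ValidationIssue` entries rather than silently
dropped, so ``records + issues == data rows`` always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import DialectError, StoreFormatError, ValidationIssue
from .records import (
    BioactivityRecord,
    BiomarkerRecord,
    Effect,
    EvidenceLevel,
    SourceRef,
    TargetKey,
)
from .synthesis import LinkedStore, aggregate_activities

STORE_SCHEMA_VERSION = "medisyn-store/1"

#: Built-in synonyms for evidence labels, applied after normalisation
#: (lower-case, hyphens/spaces folded to underscores).
DEFAULT_EVIDENCE_ALIASES: dict[str, str] = {
    "fda_guidelines": "guidelines",
    "nccn_guidelines": "guidelines",
    "clinical_guidelines": "guidelines",
    "preclinical": "pre_clinical",
    "case_reports": "case_report",
    "early_trial": "early_trials",
    "late_trial": "late_trials",
}

_UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,  # µM
    "μm": 1e3,  # μM (Greek mu)
    "mm": 1e6,
    "m": 1e9,
}


@dataclass(frozen=True)
class TableDialect:
    """Shape of a delimited source table: separator, columns, label handling."""

    required_columns: tuple[str, ...]
    sep: str = "\t"
    list_sep: str = ";"
    thousands: str = ","
    encoding: str = "utf-8"
    evidence_aliases: dict[str, str] = field(default_factory=dict)

    def with_aliases(self, aliases: dict[str, str]) -> "TableDialect":
        merged = {**self.evidence_aliases, **aliases}
        return replace(self, evidence_aliases=merged)


BIOMARKER_DIALECT = TableDialect(
    required_columns=(
        "drug",
        "target",
        "effect",
        "evidence_level",
        "tumor_types",
        "source_title",
        "source_doi",
    ),
    evidence_aliases=dict(DEFAULT_EVIDENCE_ALIASES),
)

BIOACTIVITY_DIALECT = TableDialect(
    required_columns=(
        "drug",
        "target",
        "measurement_type",
        "value",
        "unit",
        "source_title",
        "source_doi",
    ),
)


@dataclass
class IngestResult:
    """Parsed records plus the validation issues of rejected rows."""

    records: list
    issues: list[ValidationIssue]

    def issues_tsv(self) -> str:
        lines = ["row\tcolumn\tmessage"]
        lines.extend(i.as_tsv_row() for i in self.issues)
        return "\n".join(lines) + "\n"


def _read_table(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=dialect.sep,
        dtype=str,
        keep_default_na=False,
        encoding=dialect.encoding,
    )
    missing = [c for c in dialect.required_columns if c not in df.columns]
    if missing:
        raise DialectError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _norm_label(text: str) -> str:
    return " ".join(text.split()).lower().replace("-", "_").replace(" ", "_")


def _parse_sources(row: pd.Series, dataset: str) -> tuple[SourceRef, ...]:
    title = row.get("source_title", "").strip()
    doi = row.get("source_doi", "").strip()
    abstract = row.get("source_abstract", "").strip()
    if not (title or doi):
        return ()
    return (SourceRef(title=title, abstract=abstract, doi=doi, dataset=dataset),)


def read_biomarkers(
    path: str | Path, dialect: TableDialect = BIOMARKER_DIALECT
) -> IngestResult:
    """Parse a treatment-biomarker table into :class:`BiomarkerRecord` rows.

    Effect and evidence labels are matched case-insensitively after
    trimming; evidence synonyms resolve through ``dialect.evidence_aliases``.
    """
    df = _read_table(path, dialect)
    records: list[BiomarkerRecord] = []
    issues: list[ValidationIssue] = []
    effect_labels = {e.value for e in Effect}
    evidence_labels = {e.value for e in EvidenceLevel}
    for pos in range(len(df)):
        i = pos + 1
        row = df.iloc[pos]
        try:
            drug = row["drug"].strip()
            if not drug:
                raise _RowError("drug", "empty drug name")
            try:
                target = TargetKey.parse(row["target"])
            except ValueError as e:
                raise _RowError("target", str(e))
            effect_raw = _norm_label(row["effect"])
            if effect_raw not in effect_labels:
                raise _RowError(
                    "effect",
                    f"unknown effect {row['effect']!r}; allowed: "
                    + ", ".join(sorted(effect_labels)),
                )
            ev_raw = _norm_label(row["evidence_level"])
            ev_raw = dialect.evidence_aliases.get(ev_raw, ev_raw)
            if ev_raw not in evidence_labels:
                raise _RowError(
                    "evidence_level",
                    f"unknown evidence level {row['evidence_level']!r}; allowed: "
                    + ", ".join(e.value for e in EvidenceLevel),
                )
            tumors = frozenset(
                t.strip()
                for t in row["tumor_types"].split(dialect.list_sep)
                if t.strip()
            )
            records.append(
                BiomarkerRecord(
                    drug_name=drug,
                    target=target,
                    effect=Effect(effect_raw),
                    evidence_level=EvidenceLevel(ev_raw),
                    tumor_types=tumors,
                    sources=_parse_sources(row, "CGI"),
                )
            )
        except _RowError as e:
            issues.append(ValidationIssue(row=i, column=e.column, message=e.message))
    return IngestResult(records=records, issues=issues)


def read_bioactivities(
    path: str | Path, dialect: TableDialect = BIOACTIVITY_DIALECT
) -> IngestResult:
    """Parse a bioactivity table into :class:`BioactivityRecord` rows.

    Values are converted to nM from the row's unit (nM, uM/µM, mM, M); a
    missing or empty unit means the value is already in nM.
    """
    df = _read_table(path, dialect)
    records: list[BioactivityRecord] = []
    issues: list[ValidationIssue] = []
    for pos in range(len(df)):
        i = pos + 1
        row = df.iloc[pos]
        try:
            drug = row["drug"].strip()
            if not drug:
                raise _RowError("drug", "empty drug name")
            try:
                target = TargetKey.parse(row["target"])
            except ValueError as e:
                raise _RowError("target", str(e))
            mtype = row["measurement_type"].strip()
            if not mtype:
                raise _RowError("measurement_type", "empty measurement type")
            raw = row["value"].strip().replace(dialect.thousands, "")
            try:
                value = float(raw)
            except ValueError:
                raise _RowError("value", f"non-numeric value {row['value']!r}")
            unit = row.get("unit", "").strip().lower() or "nm"
            if unit not in _UNIT_TO_NM:
                raise _RowError(
                    "unit",
                    f"unsupported unit {row['unit']!r}; allowed: nM, uM, mM, M",
                )
            value_nm = value * _UNIT_TO_NM[unit]
            if not value_nm > 0:
                raise _RowError("value", f"activity value must be positive, got {raw}")
            records.append(
                BioactivityRecord(
                    drug_name=drug,
                    target=target,
                    measurement_type=mtype,
                    value_nM=value_nm,
                    sources=_parse_sources(row, "DTC"),
                )
            )
        except _RowError as e:
            issues.append(ValidationIssue(row=i, column=e.column, message=e.message))
    return IngestResult(records=records, issues=issues)


class _RowError(Exception):
    def __init__(self, column: str, message: str):
        self.column = column
        self.message = message


# ---------------------------------------------------------------------------
# LinkedStore serialization (single JSON document, schema-versioned)
# ---------------------------------------------------------------------------


def _source_to_json(s: SourceRef) -> dict:
    return {"title": s.title, "abstract": s.abstract, "doi": s.doi, "dataset": s.dataset}


def _source_from_json(d: dict) -> SourceRef:
    return SourceRef(**d)


def _target_to_json(t: TargetKey) -> dict:
    return {"gene": t.gene, "mutation": t.mutation}


def _target_from_json(d: dict) -> TargetKey:
    return TargetKey(gene=d["gene"], mutation=d["mutation"])


def _biomarker_to_json(r: BiomarkerRecord) -> dict:
    return {
        "drug_name": r.drug_name,
        "target": _target_to_json(r.target),
        "effect": r.effect.value,
        "evidence_level": r.evidence_level.value,
        "tumor_types": sorted(r.tumor_types),
        "sources": [_source_to_json(s) for s in r.sources],
    }


def _biomarker_from_json(d: dict) -> BiomarkerRecord:
    return BiomarkerRecord(
        drug_name=d["drug_name"],
        target=_target_from_json(d["target"]),
        effect=Effect(d["effect"]),
        evidence_level=EvidenceLevel(d["evidence_level"]),
        tumor_types=frozenset(d["tumor_types"]),
        sources=tuple(_source_from_json(s) for s in d["sources"]),
    )


def _bioactivity_to_json(r: BioactivityRecord) -> dict:
    return {
        "drug_name": r.drug_name,
        "target": _target_to_json(r.target),
        "measurement_type": r.measurement_type,
        "value_nM": r.value_nM,
        "sources": [_source_to_json(s) for s in r.sources],
    }


def _bioactivity_from_json(d: dict) -> BioactivityRecord:
    return BioactivityRecord(
        drug_name=d["drug_name"],
        target=_target_from_json(d["target"]),
        measurement_type=d["measurement_type"],
        value_nM=d["value_nM"],
        sources=tuple(_source_from_json(s) for s in d["sources"]),
    )


def _pair_key(drug: str, target: TargetKey) -> str:
    return f"{drug}\t{target.display}"


def write_store(store: LinkedStore, path: str | Path) -> None:
    """Serialize a validated store to a single JSON document."""
    store.validate()
    doc = {
        "schema_version": STORE_SCHEMA_VERSION,
        "drugs": store.drugs,
        "targets": [_target_to_json(t) for t in sorted(store.targets)],
        "tumor_types": store.tumor_types,
        "cgi_cells": {
            _pair_key(d, t): [_biomarker_to_json(r) for r in recs]
            for (d, t), recs in sorted(store.cgi_cells.items())
        },
        "dtc_records": {
            _pair_key(d, t): [_bioactivity_to_json(r) for r in recs]
            for (d, t), recs in sorted(store.dtc_records.items())
        },
        "mutation_tumor_links": [
            {"target": _target_to_json(t), "tumor": tu}
            for t, tu in sorted(store.mutation_tumor_links)
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def read_store(path: str | Path) -> LinkedStore:
    """Load a store written by :func:`write_store`; exact round-trip.

    Median summaries are recomputed from the raw measurements, which by
    construction reproduces the serialized store's summaries.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise StoreFormatError(f"{path}: not a valid store document ({e})")
    if not isinstance(doc, dict) or doc.get("schema_version") != STORE_SCHEMA_VERSION:
        raise StoreFormatError(
            f"{path}: unsupported schema version "
            f"{doc.get('schema_version') if isinstance(doc, dict) else None!r}; "
            f"expected {STORE_SCHEMA_VERSION!r}"
        )
    store = LinkedStore(
        drugs=dict(doc["drugs"]),
        targets={_target_from_json(t) for t in doc["targets"]},
        tumor_types=dict(doc["tumor_types"]),
    )
    for key, recs in doc["cgi_cells"].items():
        drug, tdisp = key.split("\t")
        pair = (drug, TargetKey.parse(tdisp))
        store.cgi_cells[pair] = [_biomarker_from_json(r) for r in recs]
    for key, recs in doc["dtc_records"].items():
        drug, tdisp = key.split("\t")
        pair = (drug, TargetKey.parse(tdisp))
        parsed = [_bioactivity_from_json(r) for r in recs]
        store.dtc_records[pair] = parsed
        store.dtc_cells[pair] = aggregate_activities(parsed)
    store.mutation_tumor_links = {
        (_target_from_json(l["target"]), l["tumor"])
        for l in doc["mutation_tumor_links"]
    }
    store.validate()
    return store
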