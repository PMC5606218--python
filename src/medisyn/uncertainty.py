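"""Cross-source consistency, evidence credibility and provenance.

Each (drug, target) cell of the matrix is assigned exactly one
:class:`ConsistencyState` from the two sources' claims:

* both absent -> ``missing``
* one source only -> ``cgi_only`` / ``dtc_only``
* responsive + (highly) potent, or resistant + inactive -> ``consistent``
* resistant + (highly) potent, or responsive + inactive -> ``conflicting``
* any pairing with a weakly potent median -> ``ambiguous`` (a weak signal
  neither reinforces nor contradicts a curated effect)

Conflicts are judged against the median-derived potency class of the pair,
not against individual measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import CellNotFoundError
from .records import (
    EVIDENCE_RANK,
    BiomarkerRecord,
    Effect,
    EvidenceLevel,
    EvidenceRank,
    PotencyLevel,
    TargetKey,
)
from .synthesis import ActivitySummary, LinkedStore

__all__ = [
    "ConsistencyState",
    "classify_consistency",
    "evidence_rank",
    "cell_effect",
    "conflict_report",
    "provenance_lookup",
    "ConflictRow",
    "ProvenanceDetail",
]


class ConsistencyState(str, Enum):
    CONSISTENT = "consistent"
    CONFLICTING = "conflicting"
    AMBIGUOUS = "ambiguous"
    CGI_ONLY = "cgi_only"
    DTC_ONLY = "dtc_only"
    MISSING = "missing"


def classify_consistency(
    cgi_effect: Effect | None, dtc_potency: PotencyLevel | None
) -> ConsistencyState:
    """Total mapping from the two sources' claims to one consistency state."""
    if cgi_effect is None and dtc_potency is None:
        return ConsistencyState.MISSING
    if dtc_potency is None:
        return ConsistencyState.CGI_ONLY
    if cgi_effect is None:
        return ConsistencyState.DTC_ONLY
    if dtc_potency == PotencyLevel.WEAKLY_POTENT:
        return ConsistencyState.AMBIGUOUS
    active = dtc_potency in (PotencyLevel.HIGHLY_POTENT, PotencyLevel.POTENT)
    if cgi_effect == Effect.RESPONSIVE:
        return ConsistencyState.CONSISTENT if active else ConsistencyState.CONFLICTING
    return ConsistencyState.CONFLICTING if active else ConsistencyState.CONSISTENT


def evidence_rank(level: EvidenceLevel | str) -> EvidenceRank:
    """Ordinal credibility rank of an evidence level (pre-clinical=1 ... guidelines=5)."""
    if not isinstance(level, EvidenceLevel):
        try:
            level = EvidenceLevel(level)
        except ValueError:
            raise ValueError(
                f"unknown evidence level {level!r}; allowed: "
                + ", ".join(e.value for e in EvidenceLevel)
            )
    return EvidenceRank(level=level)


def cell_effect(records: list[BiomarkerRecord]) -> tuple[Effect, BiomarkerRecord]:
    """Representative effect of a curated cell holding >= 1 biomarker rows.

    The row with the highest evidence rank wins; on a rank tie a resistant
    claim takes precedence (the conservative choice for treatment triage).
    """
    if not records:
        raise ValueError("cell has no biomarker records")
    best = max(
        records,
        key=lambda r: (EVIDENCE_RANK[r.evidence_level], r.effect == Effect.RESISTANT),
    )
    return best.effect, best


@dataclass(frozen=True)
class ProvenanceDetail:
    """Details-on-demand payload for one cell in one dataset."""

    dataset: str  # "CGI" or "DTC"
    relation: str  # human-readable description of the drug-target relation
    sources: tuple  # SourceRef entries
    source_urls: tuple[str, ...] = ()  # resolvable DOI URLs, same order


def _cgi_detail(records: list[BiomarkerRecord], store: LinkedStore) -> ProvenanceDetail:
    effect, best = cell_effect(records)
    tumors = sorted({t for r in records for t in r.tumor_types})
    relation = f"{effect.value} ({best.evidence_level.value})"
    if tumors:
        relation += "; tumor types: " + ", ".join(tumors)
    sources = tuple(s for r in records for s in r.sources)
    return ProvenanceDetail(
        dataset="CGI",
        relation=relation,
        sources=sources,
        source_urls=tuple(s.doi_url for s in sources if s.doi),
    )


def _dtc_detail(summary: ActivitySummary, raw: list) -> ProvenanceDetail:
    measured = ", ".join(f"{r.measurement_type}={r.value_nM:g} nM" for r in raw)
    relation = (
        f"median {summary.median_value_nM:g} nM ({summary.potency.label}) "
        f"from {summary.n_measurements} measurement(s): {measured}"
    )
    return ProvenanceDetail(
        dataset="DTC",
        relation=relation,
        sources=summary.sources,
        source_urls=tuple(s.doi_url for s in summary.sources if s.doi),
    )


def provenance_lookup(
    store: LinkedStore, drug: str, target: TargetKey, dataset: str
) -> ProvenanceDetail:
    """Details for a clicked cell in the named dataset.

    Raises :class:`CellNotFoundError` if the pair is absent from that
    dataset, so that a typo is not mistaken for missing data.
    """
    from .synthesis import canonical_drug_key

    dkey = canonical_drug_key(drug)
    pair = (dkey, target)
    if dataset == "CGI":
        recs = store.cgi_cells.get(pair)
        if not recs:
            raise CellNotFoundError(
                f"no CGI record for ({store.drug_display(dkey)}, {target.display})"
            )
        return _cgi_detail(recs, store)
    if dataset == "DTC":
        summary = store.dtc_cells.get(pair)
        if summary is None:
            raise CellNotFoundError(
                f"no DTC record for ({store.drug_display(dkey)}, {target.display})"
            )
        return _dtc_detail(summary, store.dtc_records[pair])
    raise ValueError(f"dataset must be CGI or DTC, got {dataset!r}")


@dataclass(frozen=True)
class ConflictRow:
    """One conflicting or ambiguous (drug, target) pair with both provenances."""

    drug: str  # display name
    drug_key: str
    target: TargetKey
    state: ConsistencyState
    cgi_effect: Effect
    cgi_evidence: EvidenceLevel
    dtc_median_nM: float
    dtc_potency: PotencyLevel
    cgi_detail: ProvenanceDetail
    dtc_detail: ProvenanceDetail

    def as_tsv_row(self) -> str:
        cgi_doi = ";".join(s.doi for s in self.cgi_detail.sources if s.doi)
        dtc_doi = ";".join(s.doi for s in self.dtc_detail.sources if s.doi)
        return "\t".join(
            [
                self.drug,
                self.target.display,
                self.state.value,
                self.cgi_effect.value,
                self.cgi_evidence.value,
                f"{self.dtc_median_nM:g}",
                self.dtc_potency.label,
                cgi_doi,
                dtc_doi,
            ]
        )


CONFLICT_TSV_HEADER = (
    "drug\ttarget\tstate\tcgi_effect\tcgi_evidence\tdtc_median_nM\t"
    "dtc_potency\tcgi_doi\tdtc_doi"
)


def conflict_report(
    store: LinkedStore, targets: list[TargetKey] | None = None
) -> list[ConflictRow]:
    """All conflicting or ambiguous cells of a store, most credible first.

    Rows are sorted conflicting before ambiguous, then by descending CGI
    evidence rank, then alphabetically by drug key.  ``targets`` optionally
    restricts the report to the given columns.
    """
    rows: list[ConflictRow] = []
    wanted = set(targets) if targets is not None else None
    for pair in sorted(set(store.cgi_cells) & set(store.dtc_cells)):
        dkey, target = pair
        if wanted is not None and target not in wanted:
            continue
        effect, best = cell_effect(store.cgi_cells[pair])
        summary = store.dtc_cells[pair]
        state = classify_consistency(effect, summary.potency)
        if state not in (ConsistencyState.CONFLICTING, ConsistencyState.AMBIGUOUS):
            continue
        rows.append(
            ConflictRow(
                drug=store.drug_display(dkey),
                drug_key=dkey,
                target=target,
                state=state,
                cgi_effect=effect,
                cgi_evidence=best.evidence_level,
                dtc_median_nM=summary.median_value_nM,
                dtc_potency=summary.potency,
                cgi_detail=_cgi_detail(store.cgi_cells[pair], store),
                dtc_detail=_dtc_detail(summary, store.dtc_records[pair]),
            )
        )
    rows.sort(
        key=lambda r: (
            r.state != ConsistencyState.CONFLICTING,
            -EVIDENCE_RANK[r.cgi_evidence],
            r.drug_key,
            r.target,
        )
    )
    return rows


def conflict_report_tsv(rows: list[ConflictRow]) -> str:
    return "\n".join([CONFLICT_TSV_HEADER] + [r.as_tsv_row() for r in rows]) + "\n"
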