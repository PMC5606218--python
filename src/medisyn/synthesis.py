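"""Harmonize and link the two curated sources into a :class:`LinkedStore`.

The linkage model: biomarker rows and bioactivity rows are keyed by the
canonical ``(drug, target)`` pair after entity harmonization.  Replicate
bioactivity measurements for one pair are pooled and summarised by their
median (robust to outliers), and the median is binned into an ordinal
potency class on the standard nanomolar thresholds:

==================  =================
class               median activity
==================  =================
highly potent       (0, 10] nM
potent              (10, 1000] nM
weakly potent       (1000, 10000] nM
inactive            > 10000 nM
==================  =================

Bins are left-open/right-closed, so a boundary value keeps the more potent
class.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .records import (
    BioactivityRecord,
    BiomarkerRecord,
    PotencyLevel,
    SourceRef,
    TargetKey,
)

__all__ = [
    "canonicalize",
    "canonical_drug_key",
    "classify_potency",
    "aggregate_activities",
    "build_store",
    "merge_statistics",
    "ActivitySummary",
    "LinkedStore",
    "ClassCounts",
    "MergeStats",
]


def canonicalize(text: str) -> str:
    """Canonical matching key for a free-text entity name.

    Trims, collapses internal whitespace and case-folds.  Display casing is
    preserved separately (first occurrence wins, see :func:`build_store`).
    """
    if not text or not text.strip():
        raise ValueError("cannot canonicalize empty text")
    return " ".join(text.split()).casefold()


# drug and tumour names share the same folding rule
canonical_drug_key = canonicalize


def classify_potency(value_nM: float) -> PotencyLevel:
    """Bin a nanomolar activity value into its potency class.

    Left-open/right-closed bins: (0,10] highly potent, (10,1000] potent,
    (1000,10000] weakly potent, (10000,inf) inactive.
    """
    if not value_nM > 0:
        raise ValueError(f"activity value must be positive, got {value_nM}")
    if value_nM <= 10:
        return PotencyLevel.HIGHLY_POTENT
    if value_nM <= 1000:
        return PotencyLevel.POTENT
    if value_nM <= 10000:
        return PotencyLevel.WEAKLY_POTENT
    return PotencyLevel.INACTIVE


@dataclass(frozen=True)
class ActivitySummary:
    """Median summary of all replicate bioactivities for one (drug, target)."""

    median_value_nM: float
    n_measurements: int
    measurement_types: tuple[str, ...]  # sorted multiset
    potency: PotencyLevel
    sources: tuple[SourceRef, ...]

    def __post_init__(self) -> None:
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")
        if self.potency != classify_potency(self.median_value_nM):
            raise ValueError("potency inconsistent with median value")


def _dedupe_sources(sources: list[SourceRef]) -> tuple[SourceRef, ...]:
    """De-duplicate by DOI when present, else by (title, dataset)."""
    seen: set = set()
    out: list[SourceRef] = []
    for s in sources:
        key = ("doi", s.doi) if s.doi else ("title", s.title, s.dataset)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return tuple(out)


def aggregate_activities(records: list[BioactivityRecord]) -> ActivitySummary:
    """Pool replicate measurements of one pair into a median-based summary.

    Measurement types (Kd, Ki, IC50, ...) are pooled; the even-n median is
    the arithmetic mean of the two central values.
    """
    if not records:
        raise ValueError("cannot aggregate an empty measurement list")
    values = [r.value_nM for r in records]
    median = float(statistics.median(values))
    sources: list[SourceRef] = []
    for r in records:
        sources.extend(r.sources)
    return ActivitySummary(
        median_value_nM=median,
        n_measurements=len(records),
        measurement_types=tuple(sorted(r.measurement_type for r in records)),
        potency=classify_potency(median),
        sources=_dedupe_sources(sources),
    )


Pair = tuple[str, TargetKey]


@dataclass
class LinkedStore:
    """Harmonized union of both sources keyed by canonical (drug, target) pairs.

    ``drugs`` and ``tumor_types`` map canonical keys to their display form
    (casing of the first occurrence).  ``cgi_cells`` keeps every curated
    biomarker row for a pair; ``dtc_cells`` keeps the median summary and
    ``dtc_records`` the raw measurements behind it (needed for
    details-on-demand).  ``mutation_tumor_links`` ties each non-wild-type
    target to the tumour types it was curated in.
    """

    drugs: dict[str, str] = field(default_factory=dict)
    targets: set[TargetKey] = field(default_factory=set)
    tumor_types: dict[str, str] = field(default_factory=dict)
    cgi_cells: dict[Pair, list[BiomarkerRecord]] = field(default_factory=dict)
    dtc_cells: dict[Pair, ActivitySummary] = field(default_factory=dict)
    dtc_records: dict[Pair, list[BioactivityRecord]] = field(default_factory=dict)
    mutation_tumor_links: set[tuple[TargetKey, str]] = field(default_factory=set)

    # -- convenience views -------------------------------------------------
    def drug_display(self, key: str) -> str:
        return self.drugs.get(key, key)

    def tumor_display(self, key: str) -> str:
        return self.tumor_types.get(key, key)

    def all_pairs(self) -> set[Pair]:
        return set(self.cgi_cells) | set(self.dtc_cells)

    def targets_of_drug(self, drug_key: str) -> set[TargetKey]:
        return {t for (d, t) in self.all_pairs() if d == drug_key}

    def drugs_of_target(self, target: TargetKey) -> set[str]:
        return {d for (d, t) in self.all_pairs() if t == target}

    def tumors_of_target(self, target: TargetKey) -> set[str]:
        return {tu for (t, tu) in self.mutation_tumor_links if t == target}

    def validate(self) -> None:
        """Check referential integrity of the store."""
        for d, t in self.all_pairs():
            if d not in self.drugs:
                raise ValueError(f"pair references unknown drug {d!r}")
            if t not in self.targets:
                raise ValueError(f"pair references unknown target {t.display}")
        for t, tu in self.mutation_tumor_links:
            if t.is_wild_type:
                raise ValueError("tumour links may only reference mutations")
            if tu not in self.tumor_types:
                raise ValueError(f"link references unknown tumour {tu!r}")


def build_store(
    biomarkers: list[BiomarkerRecord],
    bioactivities: list[BioactivityRecord],
) -> LinkedStore:
    """Link validated record lists into a :class:`LinkedStore`.

    Conservation: every biomarker row lands in exactly one ``cgi_cells``
    list, and the ``n_measurements`` over ``dtc_cells`` sum to the number
    of bioactivity rows.
    """
    store = LinkedStore()

    def intern_drug(name: str) -> str:
        key = canonical_drug_key(name)
        store.drugs.setdefault(key, " ".join(name.split()))
        return key

    for rec in biomarkers:
        dkey = intern_drug(rec.drug_name)
        store.targets.add(rec.target)
        store.cgi_cells.setdefault((dkey, rec.target), []).append(rec)
        for tumor in rec.tumor_types:
            tkey = canonicalize(tumor)
            store.tumor_types.setdefault(tkey, " ".join(tumor.split()))
            if not rec.target.is_wild_type:
                store.mutation_tumor_links.add((rec.target, tkey))

    grouped: dict[Pair, list[BioactivityRecord]] = {}
    for rec in bioactivities:
        dkey = intern_drug(rec.drug_name)
        store.targets.add(rec.target)
        grouped.setdefault((dkey, rec.target), []).append(rec)
    for pair, recs in grouped.items():
        store.dtc_records[pair] = recs
        store.dtc_cells[pair] = aggregate_activities(recs)

    return store


@dataclass(frozen=True)
class ClassCounts:
    """Per-source counts of one entity class with inclusion-exclusion views."""

    count_cgi: int
    count_dtc: int
    count_both: int

    @property
    def count_union(self) -> int:
        return self.count_cgi + self.count_dtc - self.count_both

    @property
    def count_total(self) -> int:
        """Sum of the per-source counts (shared members counted twice)."""
        return self.count_cgi + self.count_dtc


@dataclass(frozen=True)
class MergeStats:
    """Cross-source accounting of the five entity classes of a store."""

    mutations: ClassCounts
    wild_type_genes: ClassCounts
    drugs: ClassCounts
    drug_target_pairs: ClassCounts
    tumor_types: ClassCounts

    def as_rows(self) -> list[tuple[str, int, int, int, int]]:
        return [
            (name, c.count_cgi, c.count_dtc, c.count_both, c.count_union)
            for name, c in (
                ("mutations", self.mutations),
                ("wild_type_genes", self.wild_type_genes),
                ("drugs", self.drugs),
                ("drug_target_pairs", self.drug_target_pairs),
                ("tumor_types", self.tumor_types),
            )
        ]


def merge_statistics(store: LinkedStore) -> MergeStats:
    """Exact set-membership counts per entity class, per source and shared."""
    cgi_pairs = set(store.cgi_cells)
    dtc_pairs = set(store.dtc_cells)

    def counts(cgi: set, dtc: set) -> ClassCounts:
        return ClassCounts(len(cgi), len(dtc), len(cgi & dtc))

    cgi_targets = {t for (_, t) in cgi_pairs}
    dtc_targets = {t for (_, t) in dtc_pairs}
    return MergeStats(
        mutations=counts(
            {t for t in cgi_targets if not t.is_wild_type},
            {t for t in dtc_targets if not t.is_wild_type},
        ),
        wild_type_genes=counts(
            {t for t in cgi_targets if t.is_wild_type},
            {t for t in dtc_targets if t.is_wild_type},
        ),
        drugs=counts({d for (d, _) in cgi_pairs}, {d for (d, _) in dtc_pairs}),
        drug_target_pairs=counts(cgi_pairs, dtc_pairs),
        tumor_types=counts(set(store.tumor_types), set()),
    )
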