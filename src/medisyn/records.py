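"""Domain types shared across the package.

The two curated sources are modelled row-for-row: a :class:`BiomarkerRecord`
is one curated statement that a tumour mutation confers responsiveness or
resistance to a drug at a clinical evidence level; a
:class:`BioactivityRecord` is one measured interaction strength (Kd, Ki,
IC50, ...) between a drug and a target, in nanomolar.  A *target* is either
a point mutation, written ``GENE(MUT)``, or a wild-type gene, written bare.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum


class Effect(str, Enum):
    """Curated drug response of a tumour carrying the target mutation."""

    RESPONSIVE = "responsive"
    RESISTANT = "resistant"


class EvidenceLevel(str, Enum):
    """Clinical approval status of a biomarker, lowest to highest."""

    PRE_CLINICAL = "pre_clinical"
    CASE_REPORT = "case_report"
    EARLY_TRIALS = "early_trials"
    LATE_TRIALS = "late_trials"
    GUIDELINES = "guidelines"


#: Ordinal credibility rank of each evidence level (1 = lowest).
EVIDENCE_RANK: dict[EvidenceLevel, int] = {
    EvidenceLevel.PRE_CLINICAL: 1,
    EvidenceLevel.CASE_REPORT: 2,
    EvidenceLevel.EARLY_TRIALS: 3,
    EvidenceLevel.LATE_TRIALS: 4,
    EvidenceLevel.GUIDELINES: 5,
}


class PotencyLevel(IntEnum):
    """Ordinal potency class of a bioactivity value.

    Integer values encode the total order so that ``a > b`` means
    "a is more potent than b".
    """

    INACTIVE = 0
    WEAKLY_POTENT = 1
    POTENT = 2
    HIGHLY_POTENT = 3

    @property
    def label(self) -> str:
        return self.name.lower()


_TARGET_RE = re.compile(r"^(?P<gene>[^()\s]+)(?:\((?P<mut>[^()]+)\))?$")


@dataclass(frozen=True, order=True)
class TargetKey:
    """Canonical identity of a target: a gene plus an optional variant.

    ``mutation == ""`` denotes the wild-type gene.  Display form is
    ``GENE`` for wild type and ``GENE(MUTATION)`` otherwise, e.g.
    ``ABL1(T315I)``.
    """

    gene: str
    mutation: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("target gene must be non-empty")

    @property
    def is_wild_type(self) -> bool:
        return self.mutation == ""

    @property
    def display(self) -> str:
        return self.gene if self.is_wild_type else f"{self.gene}({self.mutation})"

    @property
    def wild_type(self) -> "TargetKey":
        """The wild-type key of this target's gene."""
        return TargetKey(self.gene)

    @classmethod
    def parse(cls, text: str) -> "TargetKey":
        """Parse ``"GENE(MUT)"`` or bare ``"GENE"`` into a key.

        Raises ``ValueError`` on unbalanced parentheses or empty tokens.
        """
        token = " ".join(text.split())
        if not token:
            raise ValueError("empty target token")
        m = _TARGET_RE.match(token)
        if m is None:
            raise ValueError(f"unparseable target token {text!r}")
        gene = m.group("gene").upper()
        mut = (m.group("mut") or "").strip().upper()
        if "(" in token and not mut:
            raise ValueError(f"empty mutation in target token {text!r}")
        return cls(gene=gene, mutation=mut)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display


@dataclass(frozen=True)
class SourceRef:
    """Provenance of one curated record: the publication it was extracted from."""

    title: str = ""
    abstract: str = ""
    doi: str = ""
    dataset: str = "CGI"  # "CGI" or "DTC"

    def __post_init__(self) -> None:
        if not (self.title or self.doi):
            raise ValueError("a source needs at least a title or a DOI")
        if self.dataset not in ("CGI", "DTC"):
            raise ValueError(f"dataset must be CGI or DTC, got {self.dataset!r}")

    @property
    def doi_url(self) -> str:
        return f"https://doi.org/{self.doi}" if self.doi else ""


@dataclass(frozen=True)
class BiomarkerRecord:
    """One curated (drug, mutation) treatment-biomarker statement."""

    drug_name: str
    target: TargetKey
    effect: Effect
    evidence_level: EvidenceLevel
    tumor_types: frozenset[str] = frozenset()
    sources: tuple[SourceRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.drug_name.strip():
            raise ValueError("drug_name must be non-empty")


@dataclass(frozen=True)
class BioactivityRecord:
    """One measured (drug, target) bioactivity value, stored in nM."""

    drug_name: str
    target: TargetKey
    measurement_type: str  # "Kd", "Ki", "IC50" or free text
    value_nM: float
    sources: tuple[SourceRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.drug_name.strip():
            raise ValueError("drug_name must be non-empty")
        if not self.measurement_type:
            raise ValueError("measurement_type must be non-empty")
        if not (self.value_nM > 0 and self.value_nM < float("inf")):
            raise ValueError(f"value_nM must be positive and finite, got {self.value_nM}")


@dataclass(frozen=True)
class EvidenceRank:
    """An evidence level together with its ordinal rank (1-5)."""

    level: EvidenceLevel
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rank", EVIDENCE_RANK[self.level])
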