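"""Synthetic source tables with controlled cardinalities and planted conflicts.

The generator emits a biomarker table and a bioactivity table whose
per-source, shared and union entity counts are exact by construction, plus
a ground-truth manifest (planted conflicting pairs, per-pair replicate
values, expected counts) so every downstream assertion has an oracle.

Entity names are synthetic but format-faithful (``GENE007(L107A)``,
``DRUG042``, ``COMBO003A + COMBO003B``).  Pair placement is deterministic
given the spec; the seed drives only row attributes (effects, evidence
levels, activity values, tumour assignment, which shared pairs conflict).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import UnsatisfiableSpecError

__all__ = ["FixtureSpec", "FixtureTables", "generate_fixture", "table2_spec"]

#: Activity-value ranges (nM) that keep a pooled median inside the intended
#: potency class; the margins at class boundaries absorb replicate spread.
DEFAULT_ACTIVITY_RANGES: dict[str, tuple[float, float]] = {
    "highly_potent": (1.0, 10.0),
    "potent": (10.5, 1000.0),
    "weakly_potent": (1050.0, 10000.0),
    "inactive": (10500.0, 100000.0),
    # planted conflicts: resistant effect + median in the (highly) potent range
    "conflict": (1.0, 1000.0),
}

_DTC_CLASSES = ("highly_potent", "potent", "weakly_potent", "inactive")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Cardinalities, overlaps and conflict plan of one synthetic dataset pair."""

    n_mut_cgi: int
    n_mut_dtc: int
    n_mut_both: int
    n_drug_cgi: int
    n_drug_dtc: int
    n_drug_both: int
    n_pairs_cgi: int
    n_pairs_dtc: int
    n_pairs_both: int
    n_pairs_dtc_wild_type: int = 0
    n_tumor_types: int = 0
    n_wild_type_genes: int = 0
    conflict_fraction: float = 0.0
    activity_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_RANGES)
    )
    replicate_counts: tuple[int, ...] = (1, 2, 3, 5)
    seed: int = 0

    @property
    def n_planted_conflicts(self) -> int:
        """round(conflict_fraction * n_pairs_both), Python (half-to-even) rounding."""
        return round(self.conflict_fraction * self.n_pairs_both)

    def validate(self) -> None:
        def req(cond: bool, msg: str) -> None:
            if not cond:
                raise UnsatisfiableSpecError(msg)

        for name in (
            "n_mut_cgi", "n_mut_dtc", "n_mut_both",
            "n_drug_cgi", "n_drug_dtc", "n_drug_both",
            "n_pairs_cgi", "n_pairs_dtc", "n_pairs_both",
            "n_pairs_dtc_wild_type", "n_tumor_types", "n_wild_type_genes",
        ):
            req(getattr(self, name) >= 0, f"{name} must be non-negative")
        req(0.0 <= self.conflict_fraction <= 1.0, "conflict_fraction must be in [0,1]")
        req(self.n_mut_both <= min(self.n_mut_cgi, self.n_mut_dtc),
            "n_mut_both exceeds a per-source mutation count")
        req(self.n_drug_both <= min(self.n_drug_cgi, self.n_drug_dtc),
            "n_drug_both exceeds a per-source drug count")
        req(self.n_pairs_both <= min(self.n_pairs_cgi, self.n_pairs_dtc),
            "n_pairs_both exceeds a per-source pair count")
        req(self.n_pairs_both <= self.n_drug_both * self.n_mut_both,
            "n_pairs_both exceeds the shared drug x shared mutation grid")
        req(self.n_pairs_dtc_wild_type <= self.n_pairs_dtc,
            "wild-type pairs exceed total DTC pairs")
        req((self.n_wild_type_genes == 0) == (self.n_pairs_dtc_wild_type == 0),
            "wild-type genes require wild-type pairs and vice versa")
        if self.n_wild_type_genes:
            req(self.n_pairs_dtc_wild_type >= self.n_wild_type_genes,
                "not enough wild-type pairs to cover every wild-type gene")
            req(self.n_pairs_dtc_wild_type
                <= self.n_drug_dtc * self.n_wild_type_genes,
                "wild-type pairs exceed the drug x gene grid")
        req(self.n_tumor_types <= self.n_pairs_cgi or self.n_tumor_types == 0,
            "not enough biomarker rows to mention every tumour type")
        req(self.n_pairs_cgi >= max(self.n_mut_cgi, self.n_drug_cgi),
            "n_pairs_cgi cannot cover every CGI mutation and drug")
        req(self.n_pairs_dtc - self.n_pairs_dtc_wild_type >= self.n_mut_dtc,
            "DTC mutation pairs cannot cover every DTC mutation")
        req(self.n_pairs_dtc >= self.n_drug_dtc,
            "n_pairs_dtc cannot cover every DTC drug")
        for cls, (lo, hi) in self.activity_ranges.items():
            req(0 < lo <= hi, f"activity range for {cls} must be positive and ordered")
        req(all(n >= 1 for n in self.replicate_counts) and self.replicate_counts != (),
            "replicate_counts must be positive")


def table2_spec(seed: int = 0, conflict_fraction: float = 0.25) -> FixtureSpec:
    """Spec matching the published per-source marginals of the two resources.

    Mutations 350/217/31 (CGI/DTC/shared), wild-type genes 16 (DTC only),
    drugs 166/116/24, drug-target pairs 546/1859/42 with 665 DTC pairs on
    wild-type targets, 52 tumour types (CGI only).
    """
    return FixtureSpec(
        n_mut_cgi=350, n_mut_dtc=217, n_mut_both=31,
        n_drug_cgi=166, n_drug_dtc=116, n_drug_both=24,
        n_pairs_cgi=546, n_pairs_dtc=1859, n_pairs_both=42,
        n_pairs_dtc_wild_type=665,
        n_tumor_types=52,
        n_wild_type_genes=16,
        conflict_fraction=conflict_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pair placement (deterministic given the spec)
# ---------------------------------------------------------------------------


def _round_robin_pairs(n: int, rows: list[str], cols: list[str], label: str) -> list[tuple[str, str]]:
    """n distinct (row, col) pairs covering all rows and cols when n allows."""
    if n > len(rows) * len(cols):
        raise UnsatisfiableSpecError(f"{label}: {n} pairs exceed the grid")
    pairs: list[tuple[str, str]] = []
    used: set[tuple[str, str]] = set()
    for i in range(n):
        r = rows[i % len(rows)]
        ci = i % len(cols)
        for k in range(len(cols)):
            c = cols[(ci + k) % len(cols)]
            if (r, c) not in used:
                used.add((r, c))
                pairs.append((r, c))
                break
        else:  # row exhausted; scan globally
            for r2 in rows:
                done = False
                for c2 in cols:
                    if (r2, c2) not in used:
                        used.add((r2, c2))
                        pairs.append((r2, c2))
                        done = True
                        break
                if done:
                    break
    return pairs


def _build_dataset_pairs(
    n_pairs: int,
    shared: list[tuple[str, str]],
    drugs_all: list[str],
    drugs_only: list[str],
    muts_all: list[str],
    muts_only: list[str],
    drugs_shared: set[str],
    muts_shared: set[str],
    precovered_drugs: set[str],
    label: str,
) -> list[tuple[str, str]]:
    """Exactly ``n_pairs`` distinct (drug, mutation) pairs for one source.

    The designated shared pairs are included verbatim; every other pair is
    "safe" — it involves a source-exclusive drug or mutation, so it cannot
    coincide with a pair of the other source.  Covers every drug and every
    mutation of the source, or raises :class:`UnsatisfiableSpecError`.
    """
    pairs = list(shared)
    used = set(pairs)
    if len(pairs) > n_pairs:
        raise UnsatisfiableSpecError(f"{label}: fewer pairs than designated shared pairs")
    covered_d = {d for d, _ in pairs} | precovered_drugs
    covered_m = {m for _, m in pairs}

    rotation = {"d": 0, "m": 0}

    def place(entity: str, pool: list[str], as_mut: bool) -> None:
        if len(pairs) >= n_pairs:
            raise UnsatisfiableSpecError(
                f"{label}: not enough pairs to cover every entity"
            )
        if not pool:
            raise UnsatisfiableSpecError(
                f"{label}: no safe partner available for {entity!r}"
            )
        slot = "d" if as_mut else "m"
        start = rotation[slot]
        rotation[slot] += 1
        for k in range(len(pool)):
            cand = pool[(start + k) % len(pool)]
            pair = (cand, entity) if as_mut else (entity, cand)
            if pair not in used:
                used.add(pair)
                pairs.append(pair)
                covered_d.add(pair[0])
                covered_m.add(pair[1])
                return
        raise UnsatisfiableSpecError(f"{label}: partner grid exhausted for {entity!r}")

    for m in muts_all:
        if m not in covered_m:
            place(m, drugs_only if m in muts_shared else drugs_all, as_mut=True)
    for d in drugs_all:
        if d not in covered_d:
            place(d, muts_only if d in drugs_shared else muts_all, as_mut=False)

    # safe fillers, deterministic scan order
    def stream():
        for d in drugs_all:
            for m in muts_only:
                yield (d, m)
        for d in drugs_only:
            for m in muts_shared:
                yield (d, m)

    for cand in stream():
        if len(pairs) >= n_pairs:
            break
        if cand not in used:
            used.add(cand)
            pairs.append(cand)
    if len(pairs) < n_pairs:
        raise UnsatisfiableSpecError(
            f"{label}: only {len(pairs)} distinct safe pairs constructible, "
            f"{n_pairs} requested"
        )
    return pairs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

BIOMARKER_HEADER = "drug\ttarget\teffect\tevidence_level\ttumor_types\tsource_title\tsource_doi"
BIOACTIVITY_HEADER = "drug\ttarget\tmeasurement_type\tvalue\tunit\tsource_title\tsource_doi"

_EVIDENCE = ("pre_clinical", "case_report", "early_trials", "late_trials", "guidelines")
_MEASUREMENTS = ("Kd", "Ki", "IC50")


@dataclass
class FixtureTables:
    """Generated tables plus the ground-truth manifest."""

    biomarkers_tsv: str
    bioactivities_tsv: str
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "biomarkers": out / "biomarkers.tsv",
            "bioactivities": out / "bioactivities.tsv",
            "manifest": out / "manifest.json",
        }
        paths["biomarkers"].write_text(self.biomarkers_tsv, encoding="utf-8")
        paths["bioactivities"].write_text(self.bioactivities_tsv, encoding="utf-8")
        paths["manifest"].write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths


def _make_names(spec: FixtureSpec) -> dict:
    n_mut_union = spec.n_mut_cgi + spec.n_mut_dtc - spec.n_mut_both
    n_genes = max(spec.n_wild_type_genes, (n_mut_union + 2) // 3, 1)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    mutations = [
        f"{genes[i % n_genes]}({_AA[i % 20]}{100 + i}{_AA[(i * 7 + 3) % 20]})"
        for i in range(n_mut_union)
    ]
    mut_shared = mutations[: spec.n_mut_both]
    mut_cgi_only = mutations[spec.n_mut_both : spec.n_mut_cgi]
    mut_dtc_only = mutations[spec.n_mut_cgi : n_mut_union]

    n_drug_union = spec.n_drug_cgi + spec.n_drug_dtc - spec.n_drug_both
    drugs = []
    for i in range(n_drug_union):
        if spec.n_drug_both <= i < spec.n_drug_cgi and (i - spec.n_drug_both) % 10 == 7:
            drugs.append(f"COMBO{i + 1:03d}A + COMBO{i + 1:03d}B")
        else:
            drugs.append(f"DRUG{i + 1:03d}")
    drug_shared = drugs[: spec.n_drug_both]
    drug_cgi_only = drugs[spec.n_drug_both : spec.n_drug_cgi]
    drug_dtc_only = drugs[spec.n_drug_cgi : n_drug_union]

    # wild-type genes: prefer genes of DTC mutations so that selecting those
    # mutations exercises the auto-added wild-type column
    dtc_muts = mut_shared + mut_dtc_only
    ordered: list[str] = []
    seen: set[str] = set()
    for m in dtc_muts:
        g = m.split("(")[0]
        if g not in seen:
            seen.add(g)
            ordered.append(g)
    for g in genes:
        if g not in seen:
            seen.add(g)
            ordered.append(g)
    wt_genes = ordered[: spec.n_wild_type_genes]

    tumors = [f"Tumor Type {i + 1:03d}" for i in range(spec.n_tumor_types)]
    return {
        "mut_shared": mut_shared,
        "mut_cgi_only": mut_cgi_only,
        "mut_dtc_only": mut_dtc_only,
        "drug_shared": drug_shared,
        "drug_cgi_only": drug_cgi_only,
        "drug_dtc_only": drug_dtc_only,
        "wt_genes": wt_genes,
        "tumors": tumors,
    }


def generate_fixture(spec: FixtureSpec) -> FixtureTables:
    """Generate both tables plus the manifest; byte-deterministic given the spec."""
    spec.validate()
    rng = random.Random(spec.seed)
    names = _make_names(spec)

    shared_pairs = _round_robin_pairs(
        spec.n_pairs_both, names["drug_shared"], names["mut_shared"], "shared pairs"
    )

    cgi_pairs = _build_dataset_pairs(
        spec.n_pairs_cgi,
        shared_pairs,
        names["drug_shared"] + names["drug_cgi_only"],
        names["drug_cgi_only"],
        names["mut_shared"] + names["mut_cgi_only"],
        names["mut_cgi_only"],
        set(names["drug_shared"]),
        set(names["mut_shared"]),
        set(),
        "CGI",
    )

    wt_pairs = _round_robin_pairs(
        spec.n_pairs_dtc_wild_type,
        names["drug_shared"] + names["drug_dtc_only"],
        names["wt_genes"],
        "wild-type pairs",
    )
    dtc_mut_pairs = _build_dataset_pairs(
        spec.n_pairs_dtc - spec.n_pairs_dtc_wild_type,
        shared_pairs,
        names["drug_shared"] + names["drug_dtc_only"],
        names["drug_dtc_only"],
        names["mut_shared"] + names["mut_dtc_only"],
        names["mut_dtc_only"],
        set(names["drug_shared"]),
        set(names["mut_shared"]),
        {d for d, _ in wt_pairs},
        "DTC",
    )
    dtc_pairs = dtc_mut_pairs + wt_pairs

    # conflict plan over the shared pairs
    k = spec.n_planted_conflicts
    conflict_pairs = set(rng.sample(shared_pairs, k)) if k else set()
    consistent_shared = [p for p in shared_pairs if p not in conflict_pairs]

    # per-shared-pair plan: (cgi effect, dtc value class)
    plan: dict[tuple[str, str], tuple[str, str]] = {}
    for p in sorted(conflict_pairs):
        plan[p] = ("resistant", "conflict")
    for p in consistent_shared:
        if rng.random() < 0.5:
            plan[p] = ("responsive", rng.choice(("highly_potent", "potent")))
        else:
            plan[p] = ("resistant", "inactive")

    # ---------------- biomarker table ----------------
    bm_rows: list[str] = []
    for i, (drug, mut) in enumerate(cgi_pairs):
        if (drug, mut) in plan:
            effect = plan[(drug, mut)][0]
        else:
            effect = rng.choice(("responsive", "resistant"))
        evidence = rng.choice(_EVIDENCE)
        tumor_list: list[str] = []
        if i < spec.n_tumor_types:
            tumor_list.append(names["tumors"][i])
        if names["tumors"] and rng.random() < 0.3:
            extra = rng.choice(names["tumors"])
            if extra not in tumor_list:
                tumor_list.append(extra)
        bm_rows.append(
            "\t".join(
                [
                    drug,
                    mut,
                    effect,
                    evidence,
                    ";".join(tumor_list),
                    f"Curated biomarker study {i + 1:04d}",
                    f"10.24440/cgi.{i + 1:04d}",
                ]
            )
        )
    biomarkers_tsv = "\n".join([BIOMARKER_HEADER] + bm_rows) + "\n"

    # ---------------- bioactivity table ----------------
    ba_rows: list[str] = []
    replicates: dict[str, list[float]] = {}
    intended: dict[str, str] = {}
    for i, (drug, target) in enumerate(dtc_pairs):
        if (drug, target) in plan:
            cls = plan[(drug, target)][1]
        else:
            cls = rng.choice(_DTC_CLASSES)
        lo, hi = spec.activity_ranges[cls]
        n_rep = rng.choice(spec.replicate_counts)
        values = [round(rng.uniform(lo, hi), 4) for _ in range(n_rep)]
        key = f"{drug}\t{target}"
        replicates[key] = values
        intended[key] = cls
        for j, v in enumerate(values):
            ba_rows.append(
                "\t".join(
                    [
                        drug,
                        target,
                        rng.choice(_MEASUREMENTS),
                        repr(v),
                        "nM",
                        f"Bioactivity assay {i + 1:04d}.{j + 1}",
                        f"10.24440/dtc.{i + 1:04d}.{j + 1}",
                    ]
                )
            )
    bioactivities_tsv = "\n".join([BIOACTIVITY_HEADER] + ba_rows) + "\n"

    manifest = {
        "spec": {**asdict(spec), "replicate_counts": list(spec.replicate_counts)},
        "rounding_rule": "planted conflicts = round(conflict_fraction * n_pairs_both), half-to-even",
        "n_planted_conflicts": k,
        "planted_conflicts": sorted([d, m] for d, m in conflict_pairs),
        "shared_pairs": sorted([d, m] for d, m in shared_pairs),
        "replicates": replicates,
        "intended_potency_class": intended,
        "expected_counts": {
            "mutations": _counts(spec.n_mut_cgi, spec.n_mut_dtc, spec.n_mut_both),
            "wild_type_genes": _counts(0, spec.n_wild_type_genes, 0),
            "drugs": _counts(spec.n_drug_cgi, spec.n_drug_dtc, spec.n_drug_both),
            "drug_target_pairs": _counts(
                spec.n_pairs_cgi, spec.n_pairs_dtc, spec.n_pairs_both
            ),
            "tumor_types": _counts(spec.n_tumor_types, 0, 0),
        },
    }
    return FixtureTables(
        biomarkers_tsv=biomarkers_tsv,
        bioactivities_tsv=bioactivities_tsv,
        manifest=manifest,
    )


def _counts(cgi: int, dtc: int, both: int) -> dict[str, int]:
    return {
        "cgi": cgi,
        "dtc": dtc,
        "both": both,
        "union": cgi + dtc - both,
        "total": cgi + dtc,
    }
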