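"""Shared builders: hand-made stores and randomized small fixtures."""

from __future__ import annotations

import random

import pytest

from medisyn import (
    BioactivityRecord,
    BiomarkerRecord,
    Effect,
    EvidenceLevel,
    FixtureSpec,
    SourceRef,
    TargetKey,
    assemble_matrix,
    build_store,
    generate_fixture,
    read_bioactivities,
    read_biomarkers,
)


def cgi_source(n: int = 1) -> tuple[SourceRef, ...]:
    return (SourceRef(title=f"study {n}", doi=f"10.1/cgi.{n}", dataset="CGI"),)


def dtc_source(n: int = 1) -> tuple[SourceRef, ...]:
    return (SourceRef(title=f"assay {n}", doi=f"10.1/dtc.{n}", dataset="DTC"),)


def bm(drug, target, effect, evidence, tumors=(), n=1):
    return BiomarkerRecord(
        drug_name=drug,
        target=TargetKey.parse(target),
        effect=Effect(effect),
        evidence_level=EvidenceLevel(evidence),
        tumor_types=frozenset(tumors),
        sources=cgi_source(n),
    )


def ba(drug, target, value, mtype="IC50", n=1):
    return BioactivityRecord(
        drug_name=drug,
        target=TargetKey.parse(target),
        measurement_type=mtype,
        value_nM=value,
        sources=dtc_source(n),
    )


@pytest.fixture
def golden_store():
    """Tiny hand-built store whose 3x2 matrix shows one consistent, one
    conflicting, two missing and one inactive-slash cell."""
    biomarkers = [
        bm("axitinib", "ABL1(T315I)", "responsive", "pre_clinical",
           ["Chronic Myeloid Leukemia"], n=1),
        bm("bosutinib", "ABL1(T315I)", "resistant", "guidelines",
           ["Chronic Myeloid Leukemia"], n=2),
        bm("nilotinib", "ABL1(T315I)", "responsive", "early_trials", [], n=3),
    ]
    bioactivities = [
        ba("axitinib", "ABL1(T315I)", 2.0, "Kd", n=1),
        ba("bosutinib", "ABL1(T315I)", 50.0, "IC50", n=2),
        ba("axitinib", "ABL1", 25000.0, "Ki", n=3),
    ]
    return build_store(biomarkers, bioactivities)


@pytest.fixture
def golden_matrix(golden_store):
    return assemble_matrix(golden_store, [TargetKey.parse("ABL1(T315I)")])


def small_spec(seed: int = 0, conflict_fraction: float = 0.4) -> FixtureSpec:
    """Scaled-down fixture spec for fast per-test generation."""
    return FixtureSpec(
        n_mut_cgi=12, n_mut_dtc=9, n_mut_both=4,
        n_drug_cgi=8, n_drug_dtc=7, n_drug_both=3,
        n_pairs_cgi=20, n_pairs_dtc=24, n_pairs_both=5,
        n_pairs_dtc_wild_type=6,
        n_tumor_types=5,
        n_wild_type_genes=3,
        conflict_fraction=conflict_fraction,
        seed=seed,
    )


def store_from_spec(spec: FixtureSpec, tmp_path):
    """Generate a fixture, round it through the table readers, link it."""
    tables = generate_fixture(spec)
    paths = tables.write(tmp_path / f"fx{spec.seed}")
    bmres = read_biomarkers(paths["biomarkers"])
    bares = read_bioactivities(paths["bioactivities"])
    assert not bmres.issues and not bares.issues
    return build_store(bmres.records, bares.records), tables.manifest


def random_small_store(rng: random.Random):
    """Random store with <=10 drugs and <=4 mutation targets, for sort oracles."""
    n_drugs = rng.randint(2, 10)
    n_muts = rng.randint(1, 4)
    drugs = [f"D{i}" for i in range(n_drugs)]
    muts = [f"G{i}(A{i}B)" for i in range(n_muts)]
    biomarkers, bioactivities = [], []
    for d in drugs:
        for m in muts:
            r = rng.random()
            if r < 0.35:
                biomarkers.append(
                    bm(d, m, rng.choice(["responsive", "resistant"]),
                       rng.choice([e.value for e in EvidenceLevel]))
                )
            if 0.2 < r < 0.55:
                for _ in range(rng.randint(1, 3)):
                    bioactivities.append(
                        ba(d, m, round(rng.uniform(0.5, 50000), 3),
                           rng.choice(["Kd", "Ki", "IC50"]))
                    )
    # make sure every mutation relates to at least one drug
    for m in muts:
        if not any(r.target.display == m for r in biomarkers) and not any(
            r.target.display == m for r in bioactivities
        ):
            biomarkers.append(bm(drugs[0], m, "responsive", "pre_clinical"))
    return build_store(biomarkers, bioactivities), [TargetKey.parse(m) for m in muts]
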