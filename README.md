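# medisyn

Uncertainty-aware linkage of two curated oncology resources: a **cancer
treatment-biomarker** table (one row per drug–mutation pair, stating that a
tumour carrying the mutation is *responsive* or *resistant* to the drug, at
one of five clinical evidence levels) and a **drug–target bioactivity**
table (one row per measured Kd/Ki/IC50 value in nanomolar).  The package
harmonizes the entities of both tables, links them by canonical
(drug, target) pair into a drug × target matrix model, and makes three kinds
of uncertainty explicit:

* **missing data** — every (drug, target) cell of the matrix carries a
  state, so absent pairs stay visible;
* **cross-source consistency** — each both-source cell is classified as
  `consistent`, `conflicting` or `ambiguous` (e.g. a curated *resistant*
  claim against a measured potent median is a conflict worth investigating);
* **evidence credibility** — biomarker rows carry an ordinal evidence rank
  (pre-clinical = 1 < case report < early trials < late trials <
  guidelines = 5) and every cell links back to its publication sources.

It is aimed at translational researchers triaging drug options for a given
set of tumour mutations, and at curators hunting for contradictions between
databases.

## The model

Targets are mutations `GENE(MUT)` or wild-type genes `GENE`.  Replicate
bioactivities for one pair are pooled and summarised by their **median**
m (nM), robust to outliers, then binned into an ordinal potency class with
left-open/right-closed boundaries:

| class          | median activity   |
|----------------|-------------------|
| highly potent  | 0 < m ≤ 10 nM     |
| potent         | 10 < m ≤ 1000 nM  |
| weakly potent  | 1000 < m ≤ 10⁴ nM |
| inactive       | m > 10⁴ nM        |

The consistency state of a both-source cell follows from (effect, potency):
responsive×(highly) potent and resistant×inactive are consistent;
resistant×(highly) potent and responsive×inactive are conflicts; any pairing
with a weakly potent median is ambiguous.

Three drug-sorting procedures order the matrix rows: by relation to one
target (both-source drugs first, curated-only second, measured-only third,
most potent first within a group), by total potency
`score(d) = Σ pActivity = Σ −log₁₀(m·10⁻⁹)` over the selected mutations, and
by the number of mutations the drug is curated as responsive to.

A deterministic SVG renderer encodes the curated effect as a green/red bar
(length and saturation grow with evidence rank) and the measured potency as
an overlaid black bar (narrower for weaker potency; a slash marks inactive
pairs), with tumour-type link rows above the matrix.

Because the upstream services are not bundled, a first-class fixture
generator emits synthetic source tables with exact per-source / shared /
union cardinalities, planted conflicts and a ground-truth manifest;
`table2_spec()` reproduces the published marginals of the two resources
(350/217/31 mutations, 166/116/24 drugs, 546/1859/42 pairs, 52 tumour
types, 16 wild-type genes).

## Worked example

```python
import medisyn as ms

tables = ms.generate_fixture(ms.table2_spec(seed=1))
paths = tables.write("scratch/fixture")

biomarkers = ms.read_biomarkers(paths["biomarkers"]).records
bioactivities = ms.read_bioactivities(paths["bioactivities"]).records
store = ms.build_store(biomarkers, bioactivities)

for row in ms.merge_statistics(store).as_rows():
    print(row)
```

prints one tuple per entity class, `(name, count_cgi, count_dtc,
count_both, count_union)`:

```
('mutations', 350, 217, 31, 536)
('wild_type_genes', 0, 16, 0, 16)
('drugs', 166, 116, 24, 258)
('drug_target_pairs', 546, 1859, 42, 2363)
('tumor_types', 52, 0, 0, 52)
```

i.e. 536 distinct point mutations, 258 distinct drugs or drug combinations
and 2363 distinct drug–target pairs after linkage (the 42 shared pairs are
counted once; summed per-source pairs are 546 + 1859 = 2405).  Continuing:

```python
rows = ms.conflict_report(store)
print(len(rows), rows[0].state.value, rows[0].drug, rows[0].target.display)
```

```
10 conflicting DRUG008 GENE001(A100E)
```

— the ten planted resistant-but-potent pairs, most credible first, each
carrying both sources' provenance.  Rendering a matrix:

```python
mut = rows[0].target
matrix = ms.assemble_matrix(store, [mut])
matrix.drug_rows = ms.sort_by_target(matrix, mut)
svg, sidecar_json = ms.render(matrix)
```

The same flows are available from the shell:

```sh
medisyn fixture --spec table2 --seed 1 --out-dir scratch/fixture
medisyn ingest --biomarkers scratch/fixture/biomarkers.tsv \
               --bioactivities scratch/fixture/bioactivities.tsv \
               --out scratch/store.json
medisyn stats scratch/store.json
medisyn report scratch/store.json --out scratch/conflicts.tsv
medisyn render scratch/store.json --mutations "GENE001(A100E)" \
               --sort "target:GENE001(A100E)" --out scratch/matrix.svg
```

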