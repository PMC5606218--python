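# Methods

## Data model and linkage

Two curated sources are linked. Biomarker rows state that a tumour carrying
a point mutation is *responsive* or *resistant* to a drug, with one of five
ordinal clinical evidence levels (pre-clinical < case report < early trials
< late trials < guidelines) and zero or more tumour-type annotations.
Bioactivity rows are single measured interaction strengths (Kd, Ki, IC50 or
other assay types) between a drug and a target, stored in nanomolar; lower
values mean stronger binding or inhibition.

Entities are harmonized by a deliberately conservative canonicalization:
trim, collapse internal whitespace, case-fold for matching, with the display
casing of the first occurrence preserved. Target tokens `GENE(MUT)` parse
into a (gene, variant) key; a bare `GENE` is the wild type. No external
dictionary (HGNC, ChEMBL) is consulted, so two spellings of the same drug
that differ beyond case/whitespace remain distinct entities — a known
limitation that matches how the upstream exports behave. Drug combinations
("A + B") are atomic entities with their own identity.

The linked store keys everything by canonical (drug, target) pair. Curated
rows are kept verbatim per cell (duplicates included — conservation is an
invariant: cell record counts sum to the number of valid input rows).
Replicate bioactivities per pair are pooled across measurement types and
summarised by their median; the even-n median is the arithmetic mean of the
two central values. Pooling across Kd/Ki/IC50 is the default because a cell
carries one activity value; a per-measurement-type split can be obtained by
filtering the raw records retained in the store.

## Potency binning

The median is binned on the standard nanomolar thresholds 10 / 1000 / 10000
into highly potent / potent / weakly potent / inactive. Bin intervals are
left-open/right-closed — (0,10], (10,1000], (1000,10⁴], (10⁴,∞) — so a
boundary value keeps the more potent class; the convention is applied
uniformly and the classifier is a total, monotone step function (property
tested over random positive values).

## Consistency states

Each (drug, target) matrix cell receives exactly one state. Single-source
cells are `cgi_only`/`dtc_only`; empty cells are `missing`. For both-source
cells the curated effect is compared with the median-derived potency class
(never with individual replicates): responsive×{highly potent, potent} and
resistant×inactive are `consistent`; resistant×{highly potent, potent} and
responsive×inactive are `conflicting`; any pairing with a weakly potent
median is `ambiguous`, since a weak signal neither reinforces nor
contradicts a curated claim. The responsive×inactive conflict is the mirror
of the resistant×potent case. When a cell holds several curated rows with
different effects, the row with the highest evidence rank represents the
cell; an exact rank tie resolves toward *resistant*, the conservative choice
for treatment triage.

The conflict report lists conflicting and ambiguous cells, conflicting
first, then by descending curated evidence rank, then alphabetically by
drug — highest-credibility contradictions are the ones worth a curator's
time first.

## Sorting

* **By target**: both-source drugs, then curated-only, then measured-only
  (curated clinical evidence outranks bioassay data), with unrelated drugs
  trailing in their original order (stable). "Most potent first" is read as
  ascending median nM; within the curated-only group and for all ties the
  order is alphabetical by canonical drug key. The measured-only group is
  ordered by the pair median, consistent with the aggregation rule.
* **By potency sum**: score(d) = Σ over selected mutation columns of
  pActivity = −log₁₀(median in molar), 0 where no measurement exists;
  descending. Summing pActivity rather than raw nM makes the sum reward
  potency instead of penalizing it; a raw-nM mode (`raw_sum=True`,
  ascending) exists for sensitivity checks.
* **By responsive count**: number of selected mutation columns whose curated
  effect is responsive; descending, ties alphabetical.

All three sorts are permutations of the row set and are checked against
independent brute-force comparators on randomized small matrices.

## Rendering

The renderer produces a static SVG plus a schema-versioned sidecar JSON of
the matrix model. Encodings: curated effect by hue (green `#2E8B57`
responsive, red `#C0392B` resistant), evidence rank by bar length (rank/5 of
the cell width) and saturation (20/40/60/80/100 % toward the full hue);
measured potency by an overlaid black bar whose length fraction is
1.0/0.6/0.3 for highly potent/potent/weakly potent, with a 45° slash for
inactive pairs; tumour–mutation links as horizontal lines in the header
rows. The exact colours and geometry are configuration (`RenderConfig`,
validated for monotone ramps), not contract; the contract is byte
determinism — identical (matrix, config) yields identical bytes, enforced by
sorted iteration and fixed number formatting, and frozen in a golden-file
test. Cells carry stable `id` attributes (`cell:<drug>:<target>`) so a
front-end can attach interaction handlers; event wiring itself is out of
scope, and `highlight_sets` returns the related-entity sets a front-end
would highlight.

## Synthetic fixture generator

The generator emulates the *structure* of the two exports: per-source,
shared and union cardinalities of mutations, wild-type genes, drugs,
drug–target pairs and tumour types are exact by construction. Pair placement
is deterministic given the spec: designated shared pairs come from a
round-robin over the shared drug × shared mutation grid; every other pair
involves a source-exclusive drug or mutation so cross-source overlap cannot
arise by accident; coverage passes guarantee every declared entity appears
in at least one row, or the spec is rejected as unsatisfiable with the
violated constraint named. The seed drives only row attributes: effects,
evidence levels (uniform over the five levels), activity values (uniform
within the intended class range, with margins at class boundaries so pooled
medians stay in class), replicate counts (from {1,2,3,5}), measurement
types, tumour assignment and which shared pairs conflict.

Planted conflicts pair a resistant curated effect with activity values drawn
from (0, 1000] nM; their count is round(conflict_fraction × shared pairs),
Python half-to-even rounding, stated in the manifest to avoid off-by-one
ambiguity. `table2_spec()` fixes the published per-source marginals; its
default conflict fraction of 0.25 (≈10 of the 42 shared pairs) reflects that
cross-source contradictions are a minority but not rare among shared pairs.
The generator does **not** emulate realistic activity-value distributions,
entity-name vocabularies, missing-field noise or curation errors beyond the
planted conflicts — passing tests therefore demonstrate correct accounting,
classification and ordering logic, not robustness to real-world name
variation.

## Numerical and degenerate-input choices

Activity values must be positive and finite; units nM/µM/mM/M are converted
to nM on ingest and a missing unit column means nM (all thresholds are
quoted in nM). Rows failing validation are collected with row number,
column and message — never silently dropped — so records + rejects equal the
input rows. Store serialization is a single schema-versioned JSON document;
a version mismatch is a hard error rather than a best-effort parse.
Matrices with zero columns cannot be rendered; selecting a wild-type gene
directly is rejected (wild-type columns are derived), and an unknown
mutation raises an error carrying nearest-match suggestions.

## Problem sizes

The test suite and the acceptance script run the full-scale fixture
(546 biomarker rows, ~5100 bioactivity rows) once for merge accounting, and
use scaled-down fixtures (≈20/24 pairs) for the repeated conflict-recovery
runs and randomized matrices of ≤10 drugs × ≤4 mutations for the sorting
and partition properties — small enough to hand-verify, large enough to
exercise every state and group.
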