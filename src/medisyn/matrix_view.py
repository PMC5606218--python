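"""Drug x target matrix assembly, sorting, highlighting and SVG rendering.

The matrix has one column per user-selected mutation (plus the wild-type
gene column whenever the wild type exists in the data — drugs often bind
the unmutated protein too, which anticipates side effects), tumour-type
rows above and drug rows below.  Two overlaid layers fill each cell: a
coloured bar for the curated treatment effect (green responsive / red
resistant; length and saturation grow with the clinical evidence rank) and
a black bar for the measured potency class (narrower for weaker potency;
a slash marks an inactive pair).  Empty cells expose missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import UnknownTargetError
from .records import (
    EVIDENCE_RANK,
    BiomarkerRecord,
    Effect,
    PotencyLevel,
    TargetKey,
)
from .synthesis import ActivitySummary, LinkedStore
from .uncertainty import ConsistencyState, cell_effect, classify_consistency

__all__ = [
    "MatrixCell",
    "MatrixModel",
    "RenderConfig",
    "assemble_matrix",
    "sort_by_target",
    "sort_by_potency_sum",
    "sort_by_responsive_count",
    "highlight_sets",
    "render",
    "pactivity",
]


@dataclass(frozen=True)
class MatrixCell:
    """Payloads and consistency state of one (drug, target) cell."""

    cgi: tuple[BiomarkerRecord, ...] = ()
    dtc: ActivitySummary | None = None
    state: ConsistencyState = ConsistencyState.MISSING


@dataclass
class MatrixModel:
    """Ordered drugs x targets grid with tumour rows and per-cell states."""

    columns: list[TargetKey]
    drug_rows: list[str]  # canonical drug keys, display via `drug_display`
    tumor_rows: list[str]  # canonical tumour keys
    cells: dict[tuple[str, TargetKey], MatrixCell]
    tumor_cells: set[tuple[str, TargetKey]]  # (tumor key, mutation) links
    drug_display: dict[str, str] = field(default_factory=dict)
    tumor_display: dict[str, str] = field(default_factory=dict)
    selected_mutations: list[TargetKey] = field(default_factory=list)

    def cell(self, drug: str, target: TargetKey) -> MatrixCell:
        return self.cells[(drug, target)]

    def state_counts(self) -> dict[ConsistencyState, int]:
        counts = {s: 0 for s in ConsistencyState}
        for c in self.cells.values():
            counts[c.state] += 1
        return counts


def _nearest_targets(store: LinkedStore, token: TargetKey, k: int = 3) -> list[str]:
    """Cheap nearest-match suggestions: same gene first, then prefix matches."""
    candidates = sorted(t.display for t in store.targets if t.gene == token.gene)
    if not candidates:
        candidates = sorted(
            t.display for t in store.targets if t.gene.startswith(token.gene[:3])
        )
    return candidates[:k]


def assemble_matrix(
    store: LinkedStore, selected_mutations: list[TargetKey]
) -> MatrixModel:
    """Build the matrix for the selected mutations.

    Columns are the selected mutations in selection order, followed by the
    wild-type gene column of each selected mutation whose wild type exists
    in the data (each gene at most once).  Drug rows are exactly the drugs
    related to at least one column target; tumour rows are the tumour types
    linked to at least one selected mutation.  Every (drug, column) cell
    carries a consistency state, so missing pairs stay visible.
    """
    if not selected_mutations:
        raise ValueError("select at least one mutation")
    columns: list[TargetKey] = []
    for mut in selected_mutations:
        if mut.is_wild_type:
            raise ValueError(f"{mut.display} is a wild-type gene, not a mutation")
        if mut not in store.targets:
            raise UnknownTargetError(mut.display, _nearest_targets(store, mut))
        if mut not in columns:
            columns.append(mut)
    selected = list(columns)
    for mut in selected:
        wt = mut.wild_type
        if wt in store.targets and wt not in columns:
            columns.append(wt)

    drug_rows = sorted({d for col in columns for d in store.drugs_of_target(col)})
    tumor_rows = sorted({tu for mut in selected for tu in store.tumors_of_target(mut)})
    tumor_cells = {
        (tu, mut)
        for mut in selected
        for tu in store.tumors_of_target(mut)
    }

    cells: dict[tuple[str, TargetKey], MatrixCell] = {}
    for d in drug_rows:
        for col in columns:
            pair = (d, col)
            cgi = tuple(store.cgi_cells.get(pair, ()))
            dtc = store.dtc_cells.get(pair)
            effect = cell_effect(list(cgi))[0] if cgi else None
            potency = dtc.potency if dtc is not None else None
            cells[pair] = MatrixCell(
                cgi=cgi, dtc=dtc, state=classify_consistency(effect, potency)
            )

    return MatrixModel(
        columns=columns,
        drug_rows=drug_rows,
        tumor_rows=tumor_rows,
        cells=cells,
        tumor_cells=tumor_cells,
        drug_display={d: store.drug_display(d) for d in drug_rows},
        tumor_display={t: store.tumor_display(t) for t in tumor_rows},
        selected_mutations=selected,
    )


# ---------------------------------------------------------------------------
# Sorting
# ---------------------------------------------------------------------------

_GROUP_BOTH, _GROUP_CGI, _GROUP_DTC, _GROUP_UNRELATED = 0, 1, 2, 3

_STATE_GROUP = {
    ConsistencyState.CONSISTENT: _GROUP_BOTH,
    ConsistencyState.CONFLICTING: _GROUP_BOTH,
    ConsistencyState.AMBIGUOUS: _GROUP_BOTH,
    ConsistencyState.CGI_ONLY: _GROUP_CGI,
    ConsistencyState.DTC_ONLY: _GROUP_DTC,
    ConsistencyState.MISSING: _GROUP_UNRELATED,
}


def sort_by_target(matrix: MatrixModel, target: TargetKey) -> list[str]:
    """Order drugs by their relation to one column.

    Both-source drugs come first, curated-only second, measured-only third
    (curated evidence outranks bioassay evidence); within the both-source
    and measured-only groups most potent first (ascending median nM), ties
    and the curated-only group alphabetical.  Unrelated drugs follow in
    their original order.
    """
    if target not in matrix.columns:
        raise UnknownTargetError(target.display, [c.display for c in matrix.columns])

    def key(idx_drug: tuple[int, str]):
        idx, d = idx_drug
        cell = matrix.cells[(d, target)]
        group = _STATE_GROUP[cell.state]
        if group in (_GROUP_BOTH, _GROUP_DTC):
            return (group, cell.dtc.median_value_nM, d, 0)
        if group == _GROUP_CGI:
            return (group, 0.0, d, 0)
        return (group, 0.0, "", idx)  # unrelated: stable original order

    return [d for _, d in sorted(enumerate(matrix.drug_rows), key=key)]


def pactivity(value_nM: float) -> float:
    """pActivity = -log10(value in molar); 10 nM -> 8, higher = more potent."""
    import math

    if not value_nM > 0:
        raise ValueError("activity value must be positive")
    return -math.log10(value_nM * 1e-9)


def sort_by_potency_sum(matrix: MatrixModel, raw_sum: bool = False) -> list[str]:
    """Order drugs by total measured potency over the selected mutations.

    Default score is the sum of pActivity over the selected mutation
    columns where measurements exist (absent cells contribute 0), so that
    summation rewards potency; ``raw_sum=True`` sums raw nM medians instead
    (then ascending, since lower nM is more potent).  Descending score, ties
    alphabetical.
    """

    def score(d: str) -> float:
        total = 0.0
        for mut in matrix.selected_mutations:
            dtc = matrix.cells[(d, mut)].dtc
            if dtc is not None:
                total += dtc.median_value_nM if raw_sum else pactivity(dtc.median_value_nM)
        return total

    sign = 1.0 if raw_sum else -1.0
    return sorted(matrix.drug_rows, key=lambda d: (sign * score(d), d))


def sort_by_responsive_count(matrix: MatrixModel) -> list[str]:
    """Order drugs by how many selected mutations they are curated as
    responsive to; descending, ties alphabetical."""

    def count(d: str) -> int:
        n = 0
        for mut in matrix.selected_mutations:
            cgi = matrix.cells[(d, mut)].cgi
            if cgi and cell_effect(list(cgi))[0] == Effect.RESPONSIVE:
                n += 1
        return n

    return sorted(matrix.drug_rows, key=lambda d: (-count(d), d))


# ---------------------------------------------------------------------------
# Highlighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HighlightSet:
    """Entities related to the focused drug, cell or tumour."""

    drugs: frozenset[str] = frozenset()
    targets: frozenset[TargetKey] = frozenset()
    tumors: frozenset[str] = frozenset()


def highlight_sets(
    matrix: MatrixModel,
    focus: str | tuple,
) -> HighlightSet:
    """Related-entity sets for a focus point.

    ``focus`` is one of ``("drug", key)``, ``("cell", (drug, target))`` or
    ``("tumor", key)``.  A drug focus yields its related targets plus the
    tumour types of those targets; a cell focus yields its mutation, its
    drug and the wild-type column of that gene if present; a tumour focus
    yields its related mutations in view.
    """
    kind, ref = focus
    if kind == "drug":
        if ref not in matrix.drug_rows:
            raise KeyError(f"unknown drug {ref!r}")
        targets = frozenset(
            col
            for col in matrix.columns
            if matrix.cells[(ref, col)].state != ConsistencyState.MISSING
        )
        tumors = frozenset(
            tu for (tu, mut) in matrix.tumor_cells if mut in targets
        )
        return HighlightSet(targets=targets, tumors=tumors)
    if kind == "cell":
        drug, target = ref
        if (drug, target) not in matrix.cells:
            raise KeyError(f"unknown cell ({drug!r}, {target.display})")
        targets = {target}
        wt = target.wild_type
        if not target.is_wild_type and wt in matrix.columns:
            targets.add(wt)
        return HighlightSet(drugs=frozenset({drug}), targets=frozenset(targets))
    if kind == "tumor":
        if ref not in matrix.tumor_rows:
            raise KeyError(f"unknown tumor {ref!r}")
        return HighlightSet(
            targets=frozenset(mut for (tu, mut) in matrix.tumor_cells if tu == ref)
        )
    raise ValueError(f"unknown focus kind {kind!r}")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """Bit-exact visual-encoding parameters.

    Exact values are configuration, not contract; determinism is the
    contract.  The saturation ramp must strictly increase with evidence
    rank and the overlay width fractions strictly decrease with lower
    potency.
    """

    responsive_hue: str = "#2E8B57"
    resistant_hue: str = "#C0392B"
    saturation_ramp: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    potency_width_fractions: tuple[float, ...] = (1.0, 0.6, 0.3)  # highly/potent/weakly
    cell_width: int = 56
    cell_height: int = 26
    label_width: int = 160
    header_height: int = 72
    font_family: str = "sans-serif"
    font_size: int = 11

    def __post_init__(self) -> None:
        if len(self.saturation_ramp) != 5 or any(
            a >= b for a, b in zip(self.saturation_ramp, self.saturation_ramp[1:])
        ):
            raise ValueError("saturation_ramp must be 5 strictly increasing values")
        if len(self.potency_width_fractions) != 3 or any(
            a <= b
            for a, b in zip(self.potency_width_fractions, self.potency_width_fractions[1:])
        ):
            raise ValueError(
                "potency_width_fractions must be 3 strictly decreasing values"
            )


def _blend_with_white(hex_color: str, saturation: float) -> str:
    """Desaturate toward white: s=1 keeps the hue, s=0 is white."""
    r = int(hex_color[1:3], 16)
    g = int(hex_color[3:5], 16)
    b = int(hex_color[5:7], 16)
    mix = lambda c: round(255 + (c - 255) * saturation)
    return f"#{mix(r):02X}{mix(g):02X}{mix(b):02X}"


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


_POTENCY_FRACTION_INDEX = {
    PotencyLevel.HIGHLY_POTENT: 0,
    PotencyLevel.POTENT: 1,
    PotencyLevel.WEAKLY_POTENT: 2,
}


def render(matrix: MatrixModel, config: RenderConfig = RenderConfig()) -> tuple[str, str]:
    """Render the matrix as a static SVG plus a sidecar JSON of the model.

    Output is byte-identical for identical (matrix, config).  Each cell is
    a ``<g>`` group with a stable ``id`` so a front-end can wire events.
    """
    if not matrix.columns:
        raise ValueError("cannot render a matrix with zero columns")

    cw, ch = config.cell_width, config.cell_height
    grid_x = config.label_width
    grid_y = config.header_height + len(matrix.tumor_rows) * ch
    width = grid_x + len(matrix.columns) * cw
    height = grid_y + len(matrix.drug_rows) * ch
    font = (
        f'font-family="{config.font_family}" font-size="{config.font_size}"'
    )

    out: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
    ]

    # column headers (rotated would be nicer; keep horizontal for determinism)
    for j, col in enumerate(matrix.columns):
        x = grid_x + j * cw + cw // 2
        out.append(
            f'<text x="{x}" y="{config.header_height - 8}" text-anchor="middle" '
            f'{font}>{_esc(col.display)}</text>'
        )

    # tumour rows: label + horizontal line in linked cells
    for i, tumor in enumerate(matrix.tumor_rows):
        y = config.header_height + i * ch
        cy = y + ch // 2
        out.append(
            f'<text x="{grid_x - 6}" y="{cy + 4}" text-anchor="end" {font}>'
            f"{_esc(matrix.tumor_display.get(tumor, tumor))}</text>"
        )
        for j, col in enumerate(matrix.columns):
            if (tumor, col) in matrix.tumor_cells:
                x0 = grid_x + j * cw + 4
                x1 = grid_x + (j + 1) * cw - 4
                out.append(
                    f'<g id="tumor:{_esc(tumor)}:{_esc(col.display)}">'
                    f'<line x1="{x0}" y1="{cy}" x2="{x1}" y2="{cy}" '
                    f'stroke="#555555" stroke-width="2"/></g>'
                )

    # drug rows: CGI bar + DTC overlay per cell
    for i, drug in enumerate(matrix.drug_rows):
        y = grid_y + i * ch
        cy = y + ch // 2
        out.append(
            f'<text x="{grid_x - 6}" y="{cy + 4}" text-anchor="end" {font}>'
            f"{_esc(matrix.drug_display.get(drug, drug))}</text>"
        )
        for j, col in enumerate(matrix.columns):
            cell = matrix.cells[(drug, col)]
            x = grid_x + j * cw
            parts = [
                f'<g id="cell:{_esc(drug)}:{_esc(col.display)}" '
                f'data-state="{cell.state.value}">',
                f'<rect x="{x}" y="{y}" width="{cw}" height="{ch}" fill="none" '
                f'stroke="#DDDDDD"/>',
            ]
            inner = cw - 8
            if cell.cgi:
                effect, best = cell_effect(list(cell.cgi))
                rank = EVIDENCE_RANK[best.evidence_level]
                frac = rank / 5.0
                hue = (
                    config.responsive_hue
                    if effect == Effect.RESPONSIVE
                    else config.resistant_hue
                )
                fill = _blend_with_white(hue, config.saturation_ramp[rank - 1])
                bar_w = round(inner * frac)
                parts.append(
                    f'<rect x="{x + 4}" y="{y + 5}" width="{bar_w}" '
                    f'height="{ch - 10}" fill="{fill}"/>'
                )
            if cell.dtc is not None:
                if cell.dtc.potency == PotencyLevel.INACTIVE:
                    parts.append(
                        f'<line x1="{x + 6}" y1="{y + ch - 6}" x2="{x + cw - 6}" '
                        f'y2="{y + 6}" stroke="black" stroke-width="2"/>'
                    )
                else:
                    frac = config.potency_width_fractions[
                        _POTENCY_FRACTION_INDEX[cell.dtc.potency]
                    ]
                    bar_w = round(inner * frac)
                    parts.append(
                        f'<rect x="{x + 4}" y="{cy - 2}" width="{bar_w}" height="4" '
                        f'fill="black"/>'
                    )
            parts.append("</g>")
            out.append("".join(parts))

    out.append("</svg>")
    svg = "\n".join(out) + "\n"
    return svg, model_to_json(matrix)


def model_to_json(matrix: MatrixModel) -> str:
    """Deterministic, schema-versioned JSON serialization of a matrix model."""
    doc = {
        "schema_version": "medisyn-matrix/1",
        "columns": [c.display for c in matrix.columns],
        "selected_mutations": [c.display for c in matrix.selected_mutations],
        "drug_rows": [
            {"key": d, "display": matrix.drug_display.get(d, d)}
            for d in matrix.drug_rows
        ],
        "tumor_rows": [
            {"key": t, "display": matrix.tumor_display.get(t, t)}
            for t in matrix.tumor_rows
        ],
        "tumor_cells": sorted(
            [tu, col.display] for (tu, col) in matrix.tumor_cells
        ),
        "cells": {
            f"{d}\t{col.display}": {
                "state": cell.state.value,
                "n_cgi_records": len(cell.cgi),
                "dtc_median_nM": (
                    cell.dtc.median_value_nM if cell.dtc is not None else None
                ),
                "dtc_potency": (
                    cell.dtc.potency.label if cell.dtc is not None else None
                ),
            }
            for (d, col), cell in sorted(matrix.cells.items())
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n"
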