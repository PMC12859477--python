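"""Per-cell perturbation assignment from per-guide expression calls.

Each cell falls into exactly one category based on the set of guides it was
called as expressing:

  unassigned   no guide called
  singlet_1ps  exactly one guide
  singlet_2ps  two or more guides, all targeting the same gene (typically the
               two protospacers of one dual-guide vector)
  doublet      two or more guides spanning incongruous targets, usually a
               droplet that contained more than one cell

Cells bearing either one guide or several guides against a single gene are
retained for downstream analysis; doublets and unassigned cells are not.
Congruence is judged on the target gene, not the vector: two protospacers
against the same gene from different vectors still make a singlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import GuideCountMatrix, GuideLibrary
from .mixture import GuideCall

__all__ = ["CellAssignment", "AssignmentSummary", "assign_cells", "summarize"]

CATEGORIES = ("unassigned", "singlet_1ps", "singlet_2ps", "doublet")


@dataclass(frozen=True)
class CellAssignment:
    cell_barcode: str
    called_guides: frozenset[str]
    category: str
    target: str | None
    retained_for_analysis: bool


@dataclass(frozen=True)
class AssignmentSummary:
    """Cohort-level summary of an assignment run.

    ``fraction_assigned_incl_doublets`` counts every cell with at least one
    called guide (doublets included); ``fraction_retained`` counts only
    singlet categories. Both conventions appear in the field's reporting, so
    both are carried.
    """

    n_cells: int
    fractions: dict[str, float]
    median_guide_umis_per_cell: float
    per_target_cells: dict[str, int]
    fraction_assigned_incl_doublets: float
    fraction_retained: float

    def __post_init__(self) -> None:
        if self.n_cells > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"category fractions sum to {total}, not 1")


def _categorize(called: frozenset[str], targets: dict[str, str]) -> tuple[str, str | None]:
    if not called:
        return "unassigned", None
    tset = {targets[g] for g in called}
    if len(called) == 1:
        return "singlet_1ps", next(iter(tset))
    if len(tset) == 1:
        return "singlet_2ps", next(iter(tset))
    return "doublet", None


def assign_cells(calls: Iterable[GuideCall], lib: GuideLibrary) -> list[CellAssignment]:
    """Fold per-guide calls into one assignment per cell.

    Every cell that appears in ``calls`` gets an assignment (cells whose
    calls are all negative come out unassigned). Order of the input calls is
    irrelevant; one call per (cell, guide) is expected.
    """
    targets = dict(zip(lib.table["guide_id"], lib.table["target"]))
    seen: dict[tuple[str, str], bool] = {}
    per_cell: dict[str, set[str]] = {}
    for c in calls:
        if c.guide_id not in targets:
            raise KeyError(f"call references unknown guide_id {c.guide_id!r}")
        key = (c.cell_barcode, c.guide_id)
        if key in seen:
            raise ValueError(f"multiple calls for cell {key[0]!r}, guide {key[1]!r}")
        seen[key] = True
        per_cell.setdefault(c.cell_barcode, set())
        if c.expressed:
            per_cell[c.cell_barcode].add(c.guide_id)

    out = []
    for bc in sorted(per_cell):
        called = frozenset(per_cell[bc])
        category, target = _categorize(called, targets)
        out.append(
            CellAssignment(
                cell_barcode=bc,
                called_guides=called,
                category=category,
                target=target,
                retained_for_analysis=category in ("singlet_1ps", "singlet_2ps"),
            )
        )
    return out


def summarize(
    assignments: Iterable[CellAssignment],
    counts: GuideCountMatrix,
    median_over_all_cells: bool = False,
) -> AssignmentSummary:
    """Cohort summary: category fractions, median guide UMIs per cell, per-target counts.

    Fractions are over all cells on the matrix axis; cells without an
    assignment record count as unassigned. The median total guide UMIs is
    taken over cells with at least one guide UMI (rank-plot convention)
    unless ``median_over_all_cells``.
    """
    by_bc = {a.cell_barcode: a for a in assignments}
    unknown = set(by_bc) - set(counts.barcodes)
    if unknown:
        raise ValueError(f"assignment barcodes not on matrix axis, e.g. {sorted(unknown)[0]!r}")

    n_cells = counts.n_cells
    tallies = dict.fromkeys(CATEGORIES, 0)
    per_target: dict[str, int] = {}
    for bc in counts.barcodes:
        a = by_bc.get(bc)
        cat = a.category if a is not None else "unassigned"
        tallies[cat] += 1
        if a is not None and a.target is not None:
            per_target[a.target] = per_target.get(a.target, 0) + 1

    fractions = {c: (tallies[c] / n_cells if n_cells else 0.0) for c in CATEGORIES}
    totals = counts.total_per_cell()
    pool = totals if median_over_all_cells else totals[totals >= 1]
    median_umis = float(np.median(pool)) if pool.size else float("nan")
    assigned = fractions["singlet_1ps"] + fractions["singlet_2ps"] + fractions["doublet"]
    retained = fractions["singlet_1ps"] + fractions["singlet_2ps"]
    return AssignmentSummary(
        n_cells=n_cells,
        fractions=fractions,
        median_guide_umis_per_cell=median_umis,
        per_target_cells=dict(sorted(per_target.items())),
        fraction_assigned_incl_doublets=assigned,
        fraction_retained=retained,
    )
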