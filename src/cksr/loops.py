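"""Reciprocal two-kinase phosphorylation loop detection.

When a kinase's substrate is itself a kinase that phosphorylates the first
kinase back, the pair forms a reciprocal phosphorylation loop — a feedback
motif (e.g. MEK1 and ERK1 in the MAPK/ERK pathway).  Loops are detected on the
general-level dataset: an unordered pair {A, B}, A != B, such that both
directed records A->B and B->A exist.  Kinases acting as substrates are matched
by canonical gene symbol, so kinase nomenclature should be normalized first.

By default detection runs on the union of the Ser/Thr and Tyr records (a loop
may mix residue classes, e.g. a Tyr kinase phosphorylated on serine); each
directed edge's residue class is recorded per loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ingest import KSRDataset, ResidueClass


@dataclass(frozen=True)
class ReciprocalLoop:
    """An unordered kinase pair with mutual phosphorylation, stored once.

    ``kinase_a < kinase_b`` lexicographically; ``class_a_to_b`` /
    ``class_b_to_a`` give the residue class of each directed edge.  A direction
    supported by sites of several residue classes is classed SER_THR if any
    S/T site supports it, else TYR, else OTHER.
    """

    kinase_a: str
    kinase_b: str
    class_a_to_b: str
    class_b_to_a: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.kinase_a, self.kinase_b)


def _dominant_class(classes: set[ResidueClass]) -> str:
    if ResidueClass.SER_THR in classes:
        return ResidueClass.SER_THR.value
    if ResidueClass.TYR in classes:
        return ResidueClass.TYR.value
    return ResidueClass.OTHER.value


def find_reciprocal_loops(
    ds: KSRDataset, residue_class: ResidueClass | None = None
) -> set[ReciprocalLoop]:
    """Find every unordered pair {A, B} with both A->B and B->A records.

    ``residue_class`` restricts detection to edges of one class; the default
    (None) uses the union of all classes.  Self-edges (autophosphorylation)
    never form loops.
    """
    edges: dict[tuple[str, str], set[ResidueClass]] = {}
    for r in ds.records:
        if residue_class is not None and r.residue_class is not residue_class:
            continue
        a, b = r.kinase.upper(), r.substrate.upper()
        if a == b:
            continue
        edges.setdefault((a, b), set()).add(r.residue_class)
    loops: set[ReciprocalLoop] = set()
    for (a, b), classes_ab in edges.items():
        if a < b and (b, a) in edges:
            loops.add(
                ReciprocalLoop(
                    kinase_a=a,
                    kinase_b=b,
                    class_a_to_b=_dominant_class(classes_ab),
                    class_b_to_a=_dominant_class(edges[(b, a)]),
                )
            )
    return loops


@dataclass
class LoopSummary:
    n_loops: int
    n_kinases: int
    n_directed_edges: int
    n_st_edges: int
    n_y_edges: int
    n_other_edges: int


def loop_summary(loops: set[ReciprocalLoop]) -> LoopSummary:
    """Aggregate counts over a loop set.

    Every loop contributes exactly two directed edges, so
    ``n_directed_edges == 2 * n_loops`` and the per-class edge counts sum to
    the directed edge count.
    """
    kinases: set[str] = set()
    by_class = {rc.value: 0 for rc in ResidueClass}
    for loop in loops:
        kinases.update(loop.pair)
        by_class[loop.class_a_to_b] += 1
        by_class[loop.class_b_to_a] += 1
    return LoopSummary(
        n_loops=len(loops),
        n_kinases=len(kinases),
        n_directed_edges=2 * len(loops),
        n_st_edges=by_class[ResidueClass.SER_THR.value],
        n_y_edges=by_class[ResidueClass.TYR.value],
        n_other_edges=by_class[ResidueClass.OTHER.value],
    )


def loops_table(loops: set[ReciprocalLoop]) -> pd.DataFrame:
    """Loop set as a table, one row per unordered pair.

    The ``annotation`` column is left empty for manual literature curation of
    previously described feedback loops.
    """
    rows = [
        {
            "kinase_a": lp.kinase_a,
            "kinase_b": lp.kinase_b,
            "class_a_to_b": lp.class_a_to_b,
            "class_b_to_a": lp.class_b_to_a,
            "annotation": "",
        }
        for lp in sorted(loops, key=lambda lp: lp.pair)
    ]
    return pd.DataFrame(
        rows, columns=["kinase_a", "kinase_b", "class_a_to_b", "class_b_to_a", "annotation"]
    )
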