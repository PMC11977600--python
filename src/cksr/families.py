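"""Kinome family-subgroup composition of convergent kinase groups.

The human kinome is conventionally partitioned into ten family subgroups —
AGC, CAMK, CK1, CMGC, RGC, STE, TK, TKL plus the atypical and "other" kinases.
Subgroup assignments follow the KinHub annotation (one group per kinase, from
its ``Group`` column).  For every convergent target the acting kinases are
tallied into a 10-component subgroup count vector, from which two predicates
are evaluated: whether kinases from >= 2 different subgroups converge on the
target (multi-family convergence), and whether >= 2 kinases from a single
subgroup do (same-family convergence, the CDK4/CDK6 pattern).

Kinases absent from the subgroup table are counted as unassigned rather than
defaulted into OTHER; OTHER is reserved for KinHub's explicit "Other" label.
Targets left with fewer than two assigned kinases are excluded from the family
counts, with the exclusion tally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .convergence import ConvergenceMap

logger = logging.getLogger(__name__)

#: The ten canonical kinome family subgroups, in reporting order.
SUBGROUPS: tuple[str, ...] = (
    "AGC", "CAMK", "CK1", "CMGC", "RGC", "STE", "TK", "TKL", "ATYPICAL", "OTHER",
)

_CANONICAL = {g.lower(): g for g in SUBGROUPS}


class SubgroupError(ValueError):
    """Subgroup table malformed or carrying an unrecognized group label."""


def load_subgroups(
    path: str | Path, name_col: str = "xName", group_col: str = "Group"
) -> dict[str, str]:
    """Load a KinHub-dialect table mapping kinase name -> family subgroup.

    Column names are matched case-insensitively.  Group labels are folded onto
    the ten canonical subgroups; an unrecognized label is a hard error naming
    the offending row, because a typo silently absorbed into OTHER would bias
    the family counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if name_col.lower() not in cols:
        raise SubgroupError(f"missing name column {name_col!r} in {path}")
    if group_col.lower() not in cols:
        raise SubgroupError(f"missing group column {group_col!r} in {path}")
    name_col = cols[name_col.lower()]
    group_col = cols[group_col.lower()]
    table: dict[str, str] = {}
    for i, row in df.iterrows():
        name = str(row[name_col]).strip().upper()
        raw_group = str(row[group_col]).strip()
        group = _CANONICAL.get(raw_group.lower())
        if group is None:
            raise SubgroupError(
                f"row {i} ({name}): unrecognized subgroup label {raw_group!r}"
            )
        table[name] = group
    return table


@dataclass
class SubgroupVector:
    """Per-target counts of acting kinases in each of the 10 subgroups."""

    target: str
    counts: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def multi_family(self) -> bool:
        """Kinases from >= 2 different subgroups act on the target."""
        return sum(1 for v in self.counts.values() if v > 0) >= 2

    @property
    def same_family_multi(self) -> bool:
        """>= 2 kinases from at least one single subgroup act on the target."""
        return any(v >= 2 for v in self.counts.values())

    def as_numeric_string(self) -> str:
        """The counts encoded as a 10-field string in canonical subgroup order."""
        return ",".join(str(self.counts.get(g, 0)) for g in SUBGROUPS)


def subgroup_vector(
    target: str, kinases: set[str], table: Mapping[str, str]
) -> SubgroupVector:
    """Count the subgroup membership of a target's active kinases."""
    if not kinases:
        raise ValueError("empty kinase set")
    counts = {g: 0 for g in SUBGROUPS}
    n_unassigned = 0
    for kin in kinases:
        group = table.get(kin.upper())
        if group is None:
            n_unassigned += 1
        else:
            counts[group] += 1
    if n_unassigned:
        logger.debug("%s: %d kinase(s) without subgroup assignment", target, n_unassigned)
    return SubgroupVector(target=target, counts=counts, n_unassigned=n_unassigned)


@dataclass
class FamilyConvergenceCounts:
    """Family-level convergence tallies over the convergent targets of a map."""

    n_multi_family: int
    n_same_family_multi: int
    n_analyzed: int
    n_excluded_unassigned: int


def family_convergence_counts(
    cm: ConvergenceMap, table: Mapping[str, str]
) -> FamilyConvergenceCounts:
    """Evaluate both family-convergence predicates over all cKSR targets.

    Only convergent targets (K >= 2) are analyzed; targets whose assigned
    kinase count falls below 2 after removing unassigned kinases are excluded
    and tallied separately.
    """
    n_multi = 0
    n_same = 0
    n_analyzed = 0
    n_excluded = 0
    for target, ks in cm.convergent_targets().items():
        vec = subgroup_vector(target, ks, table)
        if vec.n_assigned < 2:
            n_excluded += 1
            continue
        n_analyzed += 1
        if vec.multi_family:
            n_multi += 1
        if vec.same_family_multi:
            n_same += 1
    return FamilyConvergenceCounts(
        n_multi_family=n_multi,
        n_same_family_multi=n_same,
        n_analyzed=n_analyzed,
        n_excluded_unassigned=n_excluded,
    )


def subgroup_vectors_table(cm: ConvergenceMap, table: Mapping[str, str]) -> pd.DataFrame:
    """One row per convergent target: the 10 subgroup counts plus both flags."""
    rows = []
    for target, ks in sorted(cm.convergent_targets().items()):
        vec = subgroup_vector(target, ks, table)
        row: dict[str, object] = {"target": target, "K": len(ks)}
        for g in SUBGROUPS:
            row[g] = vec.counts.get(g, 0)
        row["n_unassigned"] = vec.n_unassigned
        row["multi_family"] = vec.multi_family
        row["same_family_multi"] = vec.same_family_multi
        rows.append(row)
    columns = ["target", "K", *SUBGROUPS, "n_unassigned", "multi_family", "same_family_multi"]
    return pd.DataFrame(rows, columns=columns)
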