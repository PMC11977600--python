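"""Substrate-centric convergence maps and K:1 topology histograms.

A convergent kinase-substrate relationship (cKSR) is a target — a substrate, or
a specific phosphosite on a substrate — acted on by at least two distinct
kinases.  The *general* level keys targets by substrate symbol alone (any
site); the *site-specific* level keys them by ``SUBSTRATE:SITE``.  For each
target the set of "active kinases" is compiled, and the distribution of K
(kinases per target) over targets gives the K:1 topology histogram.  K is
reported per topology bin from 1 to 50; larger values are accumulated in an
overflow bin with a warning rather than silently truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ingest import KSRDataset, ResidueClass

logger = logging.getLogger(__name__)

#: Largest K reported as its own topology bin.
K_CAP = 50


@dataclass
class ConvergenceMap:
    """Mapping from target key to its set of active kinases.

    ``level`` is ``"general"`` (target = substrate) or ``"site_specific"``
    (target = ``SUBSTRATE:SITE``).  Every kinase set is non-empty by
    construction.
    """

    level: str
    residue_class: ResidueClass
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def kinases(self) -> set[str]:
        """Union of all active-kinase sets."""
        out: set[str] = set()
        for ks in self.entries.values():
            out |= ks
        return out

    def convergent_targets(self) -> dict[str, set[str]]:
        """Entries with K >= 2 (the cKSRs)."""
        return {t: ks for t, ks in self.entries.items() if len(ks) >= 2}


@dataclass
class TopologyHistogram:
    """Counts of targets per K value (K:1 topologies), K capped at 50."""

    counts: dict[int, int]
    overflow_count: int
    total_targets: int
    convergent_targets: int
    convergent_fraction: float  # percent of targets with K >= 2
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [{"K": k, "n_targets": self.counts.get(k, 0)} for k in range(1, K_CAP + 1)]
        return pd.DataFrame(rows)


def build_convergence_map(
    ds: KSRDataset, level: str, residue_class: ResidueClass
) -> ConvergenceMap:
    """Compile the active-kinase set of every unique target in ``ds``.

    ``ds`` must contain records of the single requested residue class (split
    datasets first); a mixed-class dataset is an error because Ser/Thr and Tyr
    phosphorylation events are analyzed separately.
    """
    if level not in ("general", "site_specific"):
        raise ValueError(f"unknown level: {level!r}")
    entries: dict[str, set[str]] = {}
    for r in ds.records:
        if r.residue_class is not residue_class:
            raise ValueError(
                f"record {r.kinase}:{r.substrate}:{r.site} has class "
                f"{r.residue_class.value}, expected {residue_class.value}"
            )
        if level == "general":
            target = r.substrate.upper()
        else:
            target = f"{r.substrate.upper()}:{r.site.upper()}"
        entries.setdefault(target, set()).add(r.kinase.upper())
    return ConvergenceMap(level=level, residue_class=residue_class, entries=entries)


def topology_histogram(cm: ConvergenceMap) -> TopologyHistogram:
    """Tally targets by their number of active kinases K.

    For an empty map the convergent fraction is undefined; it is reported as
    0 with the ``empty`` flag set.
    """
    counts: dict[int, int] = {}
    overflow = 0
    for ks in cm.entries.values():
        k = len(ks)
        if k > K_CAP:
            overflow += 1
        else:
            counts[k] = counts.get(k, 0) + 1
    if overflow:
        logger.warning("%d target(s) with K > %d placed in overflow bin", overflow, K_CAP)
    total = len(cm.entries)
    convergent = total - counts.get(1, 0)
    if total == 0:
        return TopologyHistogram(
            counts={}, overflow_count=0, total_targets=0, convergent_targets=0,
            convergent_fraction=0.0, empty=True,
        )
    return TopologyHistogram(
        counts=counts,
        overflow_count=overflow,
        total_targets=total,
        convergent_targets=convergent,
        convergent_fraction=100.0 * convergent / total,
    )


def convergent_targets_table(cm: ConvergenceMap) -> pd.DataFrame:
    """One row per target: (target, K, '; '-joined sorted kinase names)."""
    rows = [
        {"target": t, "K": len(ks), "kinases": "; ".join(sorted(ks))}
        for t, ks in sorted(cm.entries.items())
    ]
    return pd.DataFrame(rows, columns=["target", "K", "kinases"])


def site_level_substrate_summary(cm_site: ConvergenceMap) -> dict[str, float | int]:
    """Substrate-based denominator for the site-specific analysis.

    Site-specific convergence can be expressed over two denominators: the
    number of sites (one per target of the site map) or the number of distinct
    substrates carrying at least one convergent site.  This helper reports the
    substrate-based view alongside the site-based one.
    """
    if cm_site.level != "site_specific":
        raise ValueError("expects a site-specific map")
    substrates: set[str] = set()
    convergent_substrates: set[str] = set()
    for target, ks in cm_site.entries.items():
        substrate = target.rsplit(":", 1)[0]
        substrates.add(substrate)
        if len(ks) >= 2:
            convergent_substrates.add(substrate)
    n = len(substrates)
    return {
        "n_substrates": n,
        "n_substrates_with_convergent_site": len(convergent_substrates),
        "substrate_fraction": (100.0 * len(convergent_substrates) / n) if n else 0.0,
    }
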