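"""Kinase-centric view: which kinases participate in convergent relationships.

A kinase "participates" in cKSRs when at least one of its targets is convergent
(phosphorylated by >= 2 kinases) — the criterion is on the target, not on the
kinase's own degree.  Degree histograms count, per kinase, its number of unique
targets (substrates at the general level, sites at the site-specific level).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .convergence import ConvergenceMap


@dataclass
class KinaseProfile:
    kinase: str
    n_targets_total: int
    n_cksr_targets: int

    @property
    def participates(self) -> bool:
        return self.n_cksr_targets >= 1


def kinase_profiles(cm: ConvergenceMap) -> dict[str, KinaseProfile]:
    """Per-kinase target counts (total, and convergent-only) from a map."""
    total: dict[str, int] = {}
    cksr: dict[str, int] = {}
    for target, ks in cm.entries.items():
        convergent = len(ks) >= 2
        for kin in ks:
            total[kin] = total.get(kin, 0) + 1
            if convergent:
                cksr[kin] = cksr.get(kin, 0) + 1
    return {
        kin: KinaseProfile(kinase=kin, n_targets_total=n, n_cksr_targets=cksr.get(kin, 0))
        for kin, n in total.items()
    }


def participating_kinases(cm: ConvergenceMap) -> set[str]:
    """Kinases acting on at least one convergent target (K >= 2)."""
    out: set[str] = set()
    for ks in cm.entries.values():
        if len(ks) >= 2:
            out |= ks
    return out


def kinase_degree_histogram(
    cm: ConvergenceMap, restrict_to_cksr: bool = False
) -> dict[int, int]:
    """Histogram of kinases by their number of (optionally convergent) targets.

    Returns ``{n_targets: n_kinases}``; kinases with zero counted targets do
    not appear, so the histogram sums to the number of kinases with >= 1
    counted target.
    """
    profiles = kinase_profiles(cm)
    hist: dict[int, int] = {}
    for p in profiles.values():
        n = p.n_cksr_targets if restrict_to_cksr else p.n_targets_total
        if n >= 1:
            hist[n] = hist.get(n, 0) + 1
    return hist


def participation_summary(
    cm_general: ConvergenceMap, cm_site: ConvergenceMap
) -> pd.DataFrame:
    """Per-kinase participation flags at both analysis levels.

    Both maps must come from the same residue class.  Site-level participation
    implies general-level participation (a shared site is a fortiori a shared
    substrate), so no row can be (False, True).
    """
    if cm_general.residue_class is not cm_site.residue_class:
        raise ValueError("maps have different residue classes")
    gen_profiles = kinase_profiles(cm_general)
    site_profiles = kinase_profiles(cm_site)
    rows = []
    for kin in sorted(set(gen_profiles) | set(site_profiles)):
        g = gen_profiles.get(kin)
        s = site_profiles.get(kin)
        rows.append(
            {
                "kinase": kin,
                "class": cm_general.residue_class.value,
                "n_substrates": g.n_targets_total if g else 0,
                "n_cksr_substrates": g.n_cksr_targets if g else 0,
                "n_sites": s.n_targets_total if s else 0,
                "n_cksr_sites": s.n_cksr_targets if s else 0,
                "participates_general": bool(g and g.participates),
                "participates_site": bool(s and s.participates),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kinase", "class", "n_substrates", "n_cksr_substrates",
            "n_sites", "n_cksr_sites", "participates_general", "participates_site",
        ],
    )
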