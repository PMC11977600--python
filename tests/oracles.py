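"""Brute-force reference implementations used as independent oracles.

Everything here is written as naive enumeration (nested loops, no shared code
with the library's set/dict-based paths) so that agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import numpy as np

from cksr.ingest import KSRRecord, ResidueClass


def random_table(rng: np.random.Generator, n_records: int) -> list[KSRRecord]:
    """A random kinase-substrate table with many forced collisions.

    Small symbol pools guarantee duplicate fingerprints, shared substrates,
    shared sites, self-edges and reciprocal pairs arise by chance.
    """
    kinases = [f"K{i}" for i in range(1, 13)]
    substrates = [f"SUB{i}" for i in range(1, 16)] + kinases[:6]
    sites = ["S1", "S2", "T3", "Y4", "Y5", "H6"]
    records = []
    for _ in range(n_records):
        records.append(
            KSRRecord(
                kinase=kinases[rng.integers(len(kinases))],
                substrate=substrates[rng.integers(len(substrates))],
                site=sites[rng.integers(len(sites))],
                kinase_species="human",
                substrate_species="human",
                n_reports=int(rng.integers(1, 4)),
            )
        )
    return records


def naive_fingerprints(records: list[KSRRecord], level: str) -> set[str]:
    out = set()
    for r in records:
        if level == "general":
            out.add(r.kinase.upper() + ":" + r.substrate.upper())
        else:
            out.add(r.kinase.upper() + ":" + r.substrate.upper() + ":" + r.site.upper())
    return out


def naive_convergence(
    records: list[KSRRecord], level: str, residue_class: ResidueClass
) -> dict[str, set[str]]:
    """O(n^2) pairwise tally: for each record, scan all records for co-targets."""
    entries: dict[str, set[str]] = {}
    for r in records:
        if r.residue_class is not residue_class:
            continue
        if level == "general":
            target = r.substrate.upper()
        else:
            target = r.substrate.upper() + ":" + r.site.upper()
        kinases = set()
        for other in records:
            if other.residue_class is not residue_class:
                continue
            if level == "general":
                same = other.substrate.upper() == r.substrate.upper()
            else:
                same = (
                    other.substrate.upper() == r.substrate.upper()
                    and other.site.upper() == r.site.upper()
                )
            if same:
                kinases.add(other.kinase.upper())
        entries[target] = kinases
    return entries


def naive_topology(entries: dict[str, set[str]]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for target in entries:
        k = len(entries[target])
        counts[k] = counts.get(k, 0) + 1
    return counts


def naive_degree(entries: dict[str, set[str]], restrict_to_cksr: bool) -> dict[int, int]:
    per_kinase: dict[str, int] = {}
    for target, ks in entries.items():
        if restrict_to_cksr and len(ks) < 2:
            continue
        for kin in ks:
            per_kinase[kin] = per_kinase.get(kin, 0) + 1
    hist: dict[int, int] = {}
    for n in per_kinase.values():
        hist[n] = hist.get(n, 0) + 1
    return hist


def naive_participating(entries: dict[str, set[str]]) -> set[str]:
    out = set()
    for target, ks in entries.items():
        if len(ks) >= 2:
            for kin in ks:
                out.add(kin)
    return out


def naive_family_counts(
    entries: dict[str, set[str]], subgroups: dict[str, str]
) -> tuple[int, int, int, int]:
    """(n_multi_family, n_same_family_multi, n_analyzed, n_excluded)."""
    n_multi = n_same = n_analyzed = n_excluded = 0
    for target, ks in entries.items():
        if len(ks) < 2:
            continue
        labels = []
        for kin in ks:
            if kin.upper() in subgroups:
                labels.append(subgroups[kin.upper()])
        if len(labels) < 2:
            n_excluded += 1
            continue
        n_analyzed += 1
        if len(set(labels)) >= 2:
            n_multi += 1
        seen_twice = False
        for lab in set(labels):
            if labels.count(lab) >= 2:
                seen_twice = True
        if seen_twice:
            n_same += 1
    return n_multi, n_same, n_analyzed, n_excluded


def naive_loops(records: list[KSRRecord]) -> set[tuple[str, str]]:
    """All-pairs O(n^2) check for mutual phosphorylation."""
    pairs = set()
    for r1 in records:
        for r2 in records:
            a, b = r1.kinase.upper(), r1.substrate.upper()
            if a != b and r2.kinase.upper() == b and r2.substrate.upper() == a:
                pairs.add((min(a, b), max(a, b)))
    return pairs
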