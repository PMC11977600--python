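"""Synthetic kinase-substrate and expression data with planted ground truth.

The real inputs of the convergence analysis (a PhosphoSitePlus-style
kinase-substrate table, a KinHub subgroup annotation, per-KSR report counts
and CCLE-style expression matrices) are registration-gated downloads.  This
module generates structurally faithful stand-ins with *constructed* — not
estimated — ground truth, so every pipeline stage can be verified exactly:

* topology planting: each class (Ser/Thr, Tyr) gets general-level targets
  (a substrate phosphorylated by K kinases on K distinct sites) and
  site-level targets (K kinases on one shared site), drawn from a requested
  ``{K: n_targets}`` distribution;
* reciprocal loops: mutually phosphorylating kinase pairs, by default in a
  kinase namespace disjoint from the topology kinases so expectations stay
  independent;
* per-kinase Bernoulli expression with known probabilities, so co-expression
  scores have closed-form expectations.

The :class:`GroundTruthManifest` records the exact expected output of every
deterministic stage (histograms, participating-kinase sets, family counts,
loop set) and the analytic expected co-expression score per group.

Default parameters mirror, at desk scale, the topology shape reported for the
experimentally validated human phosphorylation network: roughly half of
Ser/Thr substrates and a third of Tyr substrates convergent at the general
level, with a long-tailed K distribution dominated by K = 2..4, loops being
rare, and kinases broadly expressed across cell lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import analytic_coexpression_probability
from .families import SUBGROUPS
from .ingest import KSRDataset, KSRRecord, ResidueClass

ST = ResidueClass.SER_THR.value
TY = ResidueClass.TYR.value

#: Subgroups cycled over Ser/Thr kinases (Tyr kinases are assigned TK,
#: matching the concentration of tyrosine kinases in that group).
_ST_SUBGROUP_CYCLE = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TKL", "ATYPICAL", "OTHER")


def _default_general_topology() -> dict[str, dict[int, int]]:
    # ~48% convergent Ser/Thr substrates, ~35% Tyr, K=2..4 dominant
    return {
        ST: {1: 208, 2: 84, 3: 40, 4: 24, 5: 16, 6: 10, 7: 8, 8: 5, 9: 3, 10: 2},
        TY: {1: 104, 2: 30, 3: 11, 4: 8, 5: 4, 6: 2, 7: 1},
    }


def _default_site_topology() -> dict[str, dict[int, int]]:
    # ~24% convergent Ser/Thr sites, ~23% Tyr sites among planted site targets
    return {
        ST: {1: 152, 2: 30, 3: 10, 4: 4, 5: 2, 6: 2},
        TY: {1: 77, 2: 15, 3: 4, 4: 3, 5: 1},
    }


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; the defaults are the study conditions.

    ``planted_general`` / ``planted_site`` map residue class to a
    ``{K: n_targets}`` topology; ``expression_p`` is the per-kinase Bernoulli
    expression probability (a single float applied to every kinase, or a
    per-kinase dict); ``tpm_threshold`` is the TPM cutoff the expression calls
    are planted against.
    """

    seed: int = 0
    n_kinases: dict[str, int] = field(default_factory=lambda: {ST: 60, TY: 25})
    planted_general: dict[str, dict[int, int]] = field(default_factory=_default_general_topology)
    planted_site: dict[str, dict[int, int]] = field(default_factory=_default_site_topology)
    planted_loops: int = 8
    duplicate_rate: float = 0.1
    alias_fraction: float = 0.1
    report_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    expression_p: float | dict[str, float] = 0.6
    n_cell_lines: int = 500
    tpm_threshold: float = 10.0

    def validate(self) -> None:
        for cls, topo in list(self.planted_general.items()) + list(self.planted_site.items()):
            if cls not in self.n_kinases:
                raise ValueError(f"no kinase pool for class {cls!r}")
            for k, n in topo.items():
                if n < 0:
                    raise ValueError("planted counts must be non-negative")
                if k > self.n_kinases[cls]:
                    raise ValueError(
                        f"planted K={k} exceeds the {cls} kinase pool "
                        f"({self.n_kinases[cls]})"
                    )
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if not 0.0 <= self.alias_fraction <= 1.0:
            raise ValueError("alias_fraction must be in [0, 1]")
        if abs(sum(self.report_count_probs.values()) - 1.0) > 1e-9:
            raise ValueError("report_count_probs must sum to 1")
        probs = self.expression_probabilities(self.all_kinase_names())
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("expression probabilities must lie in [0, 1]")

    # -- deterministic namespaces -------------------------------------------
    def kinase_pool(self, cls: str) -> list[str]:
        prefix = "STK" if cls == ST else "TYK"
        return [f"{prefix}{i:03d}" for i in range(1, self.n_kinases[cls] + 1)]

    def loop_kinases(self) -> list[tuple[str, str]]:
        return [(f"LPA{i:02d}", f"LPB{i:02d}") for i in range(1, self.planted_loops + 1)]

    def all_kinase_names(self) -> list[str]:
        names = self.kinase_pool(ST) + self.kinase_pool(TY)
        for a, b in self.loop_kinases():
            names += [a, b]
        return names

    def expression_probabilities(self, kinases: list[str]) -> dict[str, float]:
        if isinstance(self.expression_p, dict):
            return {k: float(self.expression_p.get(k, 0.0)) for k in kinases}
        return {k: float(self.expression_p) for k in kinases}

    def subgroup_assignment(self) -> dict[str, str]:
        """Deterministic subgroup per kinase (Tyr pool -> TK; others cycled)."""
        table: dict[str, str] = {}
        st_names = self.kinase_pool(ST) + [k for pair in self.loop_kinases() for k in pair]
        for i, name in enumerate(st_names):
            table[name] = _ST_SUBGROUP_CYCLE[i % len(_ST_SUBGROUP_CYCLE)]
        for name in self.kinase_pool(TY):
            table[name] = "TK"
        return table


def _merge(*hists: dict[int, int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for h in hists:
        for k, n in h.items():
            if n:
                out[k] = out.get(k, 0) + n
    return {k: out[k] for k in sorted(out)}


@dataclass
class GroundTruthManifest:
    """Exact expected outputs of every deterministic pipeline stage.

    Histograms and sets are constructed during generation, not estimated;
    co-expression expectations are analytic (closed form under independent
    Bernoulli expression) and are recovered statistically, not exactly.
    """

    seed: int
    general_hist: dict[str, dict[int, int]]
    site_hist: dict[str, dict[int, int]]
    participating: dict[str, dict[str, list[str]]]  # level -> class -> kinases
    all_kinases: dict[str, list[str]]  # class -> kinases appearing in the table
    family_counts: dict[str, dict[str, dict[str, int]]]  # level -> class -> counts
    loops: list[tuple[str, str]]
    coexpression_analytic: dict[str, dict[str, dict[str, float]]]  # level -> class -> target -> %
    expression_probs: dict[str, float]
    subgroups: dict[str, str]

    def to_json(self) -> str:
        def _intkeys(h: dict[str, dict[int, int]]) -> dict:
            return {c: {str(k): v for k, v in hh.items()} for c, hh in h.items()}

        payload = {
            "seed": self.seed,
            "general_hist": _intkeys(self.general_hist),
            "site_hist": _intkeys(self.site_hist),
            "participating": self.participating,
            "all_kinases": self.all_kinases,
            "family_counts": self.family_counts,
            "loops": [list(p) for p in self.loops],
            "coexpression_analytic": self.coexpression_analytic,
            "expression_probs": self.expression_probs,
            "subgroups": self.subgroups,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)

        def _todict(h: dict) -> dict[str, dict[int, int]]:
            return {c: {int(k): v for k, v in hh.items()} for c, hh in h.items()}

        return cls(
            seed=d["seed"],
            general_hist=_todict(d["general_hist"]),
            site_hist=_todict(d["site_hist"]),
            participating=d["participating"],
            all_kinases=d["all_kinases"],
            family_counts=d["family_counts"],
            loops=[tuple(p) for p in d["loops"]],
            coexpression_analytic=d["coexpression_analytic"],
            expression_probs=d["expression_probs"],
            subgroups=d["subgroups"],
        )


def _family_predicates(kinases: set[str], subgroups: dict[str, str]) -> tuple[bool, bool, bool]:
    """(analyzable, multi_family, same_family_multi) by direct tally."""
    labels = [subgroups[k] for k in kinases if k in subgroups]
    if len(labels) < 2:
        return False, False, False
    distinct = len(set(labels))
    same = len(labels) > distinct  # some label occurs twice
    return True, distinct >= 2, same


def generate_ksr_table(spec: SyntheticSpec) -> tuple[KSRDataset, GroundTruthManifest]:
    """Build the KSR table and its exact ground-truth manifest.

    Construction per residue class: a general-level target with multiplicity K
    is a fresh substrate given K distinct kinases on K distinct sites (so each
    of its sites has exactly one kinase); a site-level target is a fresh
    substrate with one site shared by K distinct kinases (so its general-level
    K equals its site-level K).  Loop pairs are kinase-on-kinase Ser/Thr
    records in a disjoint namespace; each loop member is therefore also a
    1-kinase target at both levels.  Duplicate rows are optionally injected to
    exercise deduplication (they never alter the manifest).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    records: list[KSRRecord] = []
    # target -> kinase set, per class, per level
    gen_targets: dict[str, dict[str, set[str]]] = {ST: {}, TY: {}}
    site_targets: dict[str, dict[str, set[str]]] = {ST: {}, TY: {}}

    report_vals = sorted(spec.report_count_probs)
    report_p = [spec.report_count_probs[v] for v in report_vals]

    def _reports() -> int:
        return int(rng.choice(report_vals, p=report_p))

    def _add(kinase: str, substrate: str, site: str) -> None:
        records.append(
            KSRRecord(
                kinase=kinase, substrate=substrate, site=site,
                kinase_species="human", substrate_species="human",
                n_reports=_reports(),
            )
        )

    for cls, letters, tag in ((ST, "ST", "ST"), (TY, "Y", "TY")):
        pool = spec.kinase_pool(cls)
        # general-level targets: K kinases, K distinct sites
        i_sub = 0
        for k in sorted(spec.planted_general.get(cls, {})):
            for _ in range(spec.planted_general[cls][k]):
                i_sub += 1
                substrate = f"GSUB{tag}{i_sub:04d}"
                kinases = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
                for pos, kin in enumerate(kinases):
                    letter = letters[pos % len(letters)]
                    site = f"{letter}{10 * (pos + 1)}"
                    _add(kin, substrate, site)
                    site_targets[cls][f"{substrate}:{site}"] = {kin}
                gen_targets[cls][substrate] = set(kinases)
        # site-level targets: K kinases on one shared site
        i_sub = 0
        for k in sorted(spec.planted_site.get(cls, {})):
            for _ in range(spec.planted_site[cls][k]):
                i_sub += 1
                substrate = f"SSUB{tag}{i_sub:04d}"
                site = f"{letters[0]}100"
                kinases = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
                for kin in kinases:
                    _add(kin, substrate, site)
                gen_targets[cls][substrate] = set(kinases)
                site_targets[cls][f"{substrate}:{site}"] = set(kinases)

    # reciprocal loops: Ser/Thr kinase-on-kinase records, disjoint namespace
    loops: list[tuple[str, str]] = []
    for a, b in spec.loop_kinases():
        _add(a, b, "S50")
        _add(b, a, "S60")
        loops.append((a, b) if a < b else (b, a))
        gen_targets[ST][b] = {a}
        gen_targets[ST][a] = {b}
        site_targets[ST][f"{b}:S50"] = {a}
        site_targets[ST][f"{a}:S60"] = {b}

    # inject duplicates (exact copies, same report count) to exercise dedup
    n_dup = int(round(spec.duplicate_rate * len(records)))
    if n_dup:
        for idx in rng.choice(len(records), size=n_dup, replace=True):
            records.append(records[int(idx)])
        order = rng.permutation(len(records))
        records = [records[int(i)] for i in order]

    subgroups = spec.subgroup_assignment()
    probs = spec.expression_probabilities(spec.all_kinase_names())

    participating: dict[str, dict[str, list[str]]] = {"general": {}, "site_specific": {}}
    family_counts: dict[str, dict[str, dict[str, int]]] = {"general": {}, "site_specific": {}}
    coex: dict[str, dict[str, dict[str, float]]] = {"general": {}, "site_specific": {}}
    all_kin: dict[str, list[str]] = {}
    for cls in (ST, TY):
        for level, targets in (("general", gen_targets[cls]), ("site_specific", site_targets[cls])):
            conv = {t: ks for t, ks in targets.items() if len(ks) >= 2}
            participating[level][cls] = sorted(set().union(*conv.values()) if conv else set())
            n_analyzed = n_multi = n_same = n_excl = 0
            for ks in conv.values():
                ok, multi, same = _family_predicates(ks, subgroups)
                if not ok:
                    n_excl += 1
                    continue
                n_analyzed += 1
                n_multi += int(multi)
                n_same += int(same)
            family_counts[level][cls] = {
                "n_multi_family": n_multi,
                "n_same_family_multi": n_same,
                "n_analyzed": n_analyzed,
                "n_excluded_unassigned": n_excl,
            }
            coex[level][cls] = {
                t: 100.0 * analytic_coexpression_probability([probs[k] for k in sorted(ks)])
                for t, ks in conv.items()
            }
        all_kin[cls] = sorted({k for ks in gen_targets[cls].values() for k in ks})

    def _hist(targets: dict[str, set[str]]) -> dict[int, int]:
        h: dict[int, int] = {}
        for ks in targets.values():
            h[len(ks)] = h.get(len(ks), 0) + 1
        return {k: h[k] for k in sorted(h)}

    manifest = GroundTruthManifest(
        seed=spec.seed,
        general_hist={cls: _hist(gen_targets[cls]) for cls in (ST, TY)},
        site_hist={cls: _hist(site_targets[cls]) for cls in (ST, TY)},
        participating=participating,
        all_kinases=all_kin,
        family_counts=family_counts,
        loops=sorted(loops),
        coexpression_analytic=coex,
        expression_probs=probs,
        subgroups=subgroups,
    )
    ds = KSRDataset(
        records=records,
        provenance={"source": "synthetic", "seed": spec.seed},
    )
    return ds, manifest


def generate_expression_matrix(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate a log2(TPM+1) matrix with planted per-kinase expression calls.

    Each (cell line, kinase) is expressed independently with that kinase's
    Bernoulli probability.  Expressed entries are drawn above the planted TPM
    threshold (uniform in [threshold, 4 x threshold]), unexpressed entries
    below it (uniform in [0, 0.8 x threshold]), then stored as log2(TPM + 1),
    so thresholding the matrix at ``spec.tpm_threshold`` recovers the calls
    exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the KSR table
    genes = spec.all_kinase_names()
    probs = spec.expression_probabilities(genes)
    n = spec.n_cell_lines
    th = spec.tpm_threshold
    cols = {}
    for g in genes:
        expressed = rng.random(n) < probs[g]
        tpm = np.where(
            expressed,
            rng.uniform(th, 4.0 * th, size=n),
            rng.uniform(0.0, 0.8 * th, size=n),
        )
        cols[g] = np.log2(tpm + 1.0)
    index = [f"CELLLINE{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(cols, index=index)


def write_fixture_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full input bundle for a pipeline run, plus the manifest.

    Files: KSR table (plain TSV dialect; a stated fraction of kinase names
    written under a ``*_RAW`` alias to exercise nomenclature normalization),
    alias map, KinHub-dialect subgroup table, per-KSR report-count table,
    CCLE-dialect expression CSV, and the ground-truth manifest JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, manifest = generate_ksr_table(spec)

    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    aliased: set[str] = set()
    for r in ds.records:
        kinase = r.kinase
        if spec.alias_fraction and rng.random() < spec.alias_fraction:
            kinase = f"{r.kinase}_RAW"
            aliased.add(r.kinase)
        rows.append(
            {
                "kinase": kinase, "substrate": r.substrate, "site": r.site,
                "kin_species": r.kinase_species, "sub_species": r.substrate_species,
                "n_reports": r.n_reports,
            }
        )
    paths = {
        "ksr": out_dir / "ksr_table.tsv",
        "aliases": out_dir / "aliases.tsv",
        "subgroups": out_dir / "subgroups.tsv",
        "report_counts": out_dir / "report_counts.tsv",
        "expression": out_dir / "expression.csv",
        "manifest": out_dir / "manifest.json",
    }
    pd.DataFrame(rows).to_csv(paths["ksr"], sep="\t", index=False)

    alias_rows = [{"raw": f"{k}_RAW", "canonical": k} for k in sorted(aliased)]
    pd.DataFrame(alias_rows, columns=["raw", "canonical"]).to_csv(
        paths["aliases"], sep="\t", index=False, header=False
    )

    sub = manifest.subgroups
    pd.DataFrame(
        [{"xName": k, "Group": g.capitalize() if g in ("ATYPICAL", "OTHER") else g}
         for k, g in sorted(sub.items())]
    ).to_csv(paths["subgroups"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"kinase": r["kinase"], "substrate": r["substrate"], "site": r["site"],
             "n_reports": r["n_reports"]}
            for r in rows
        ]
    ).to_csv(paths["report_counts"], sep="\t", index=False)

    expr = generate_expression_matrix(spec)
    expr.columns = [f"{g} ({1000 + i})" for i, g in enumerate(expr.columns)]
    expr.to_csv(paths["expression"])

    paths["manifest"].write_text(manifest.to_json())
    return paths


def load_manifest(path: str | Path) -> GroundTruthManifest:
    return GroundTruthManifest.from_json(Path(path).read_text())
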