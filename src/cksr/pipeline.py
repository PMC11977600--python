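"""End-to-end orchestration: ingest -> convergence -> kinases -> families ->
loops -> co-expression, with a stable on-disk report bundle.

The pipeline is a pure function of (input files, configuration): rerunning on
identical inputs produces byte-identical outputs.  Every stage logs its record
counts so that records in = records kept + records filtered can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import convergence, coexpression, families, ingest, kinase_centric, loops
from .ingest import KSRDataset, ResidueClass

logger = logging.getLogger(__name__)

CLASSES = (ResidueClass.SER_THR, ResidueClass.TYR)
LEVELS = ("general", "site_specific")


@dataclass
class PipelineConfig:
    """Declarative configuration of one full analysis run."""

    ksr_path: str
    dialect: str = "plain_tsv"
    aliases_path: str | None = None
    subgroups_path: str | None = None
    expression_path: str | None = None
    expression_dialect: str = "ccle_csv"
    proteomics_path: str | None = None
    species: str = "human"
    min_reports: int = 1
    drop_self: bool = False
    tpm_thresholds: tuple[float, ...] = (5.0, 10.0, 20.0)
    rarity_cutoff: float = 2.5
    out_dir: str = "cksr_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "tpm_thresholds" in raw:
            raw["tpm_thresholds"] = tuple(float(t) for t in raw["tpm_thresholds"])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (
            ("ksr_path", self.ksr_path),
            ("aliases_path", self.aliases_path),
            ("subgroups_path", self.subgroups_path),
            ("expression_path", self.expression_path),
            ("proteomics_path", self.proteomics_path),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p} does not exist")
        if any(t <= 0 for t in self.tpm_thresholds):
            raise ValueError("tpm_thresholds must be positive")
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")


@dataclass
class PipelineResult:
    """In-memory results of a full run, keyed by residue class and level."""

    config: PipelineConfig
    maps: dict[tuple[str, str], convergence.ConvergenceMap] = field(default_factory=dict)
    histograms: dict[tuple[str, str], convergence.TopologyHistogram] = field(default_factory=dict)
    participation: dict[str, object] = field(default_factory=dict)  # class -> DataFrame
    family_counts: dict[tuple[str, str], families.FamilyConvergenceCounts] = field(
        default_factory=dict
    )
    loop_set: set[loops.ReciprocalLoop] = field(default_factory=set)
    # keyed (level, class, threshold label e.g. "tpm10" or "median")
    coexpression_scores: dict[tuple[str, str, str], list] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        """Headline fractions and counts of this run, per class and level."""
        out: dict = {"stages": self.stage_log, "classes": {}}
        for rc in CLASSES:
            cls = rc.value
            blk: dict = {}
            for level in LEVELS:
                hist = self.histograms.get((level, cls))
                if hist is None:
                    continue
                cm = self.maps[(level, cls)]
                part = kinase_centric.participating_kinases(cm)
                n_kin = len(cm.kinases())
                blk[level] = {
                    "total_targets": hist.total_targets,
                    "convergent_targets": hist.convergent_targets,
                    "convergent_fraction": round(hist.convergent_fraction, 1),
                    "n_kinases": n_kin,
                    "n_participating_kinases": len(part),
                    "participation_fraction": round(100.0 * len(part) / n_kin, 1)
                    if n_kin else 0.0,
                    "empty": hist.empty,
                }
                fc = self.family_counts.get((level, cls))
                if fc is not None:
                    blk[level]["family"] = dataclasses.asdict(fc)
            out["classes"][cls] = blk
        ls = loops.loop_summary(self.loop_set)
        out["loops"] = dataclasses.asdict(ls)
        coex: dict = {}
        for (level, cls, th_label), scores in self.coexpression_scores.items():
            s = coexpression.score_distribution_summary(
                scores, rarity_cutoff=self.config.rarity_cutoff
            )
            coex[f"{level}/{cls}/{th_label}"] = {
                "median": s.median,
                "mean": s.mean,
                "fraction_below_cutoff": s.fraction_below,
                "n_scored": s.n_scored,
                "n_unscored": s.n_unscored,
            }
        out["coexpression"] = coex
        return out


def _log_stage(result: PipelineResult, stage: str, n_in: int, n_out: int) -> None:
    result.stage_log.append(
        {"stage": stage, "records_in": n_in, "records_out": n_out,
         "records_filtered": n_in - n_out}
    )
    logger.info("%s: %d -> %d records", stage, n_in, n_out)


def run_full_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every analysis stage configured in ``cfg``.

    Stages whose inputs are not configured (alias map, subgroup table,
    expression matrices) are skipped with a log entry.  Any stage failure is
    re-raised annotated with the stage name.
    """
    cfg.validate()
    result = PipelineResult(config=cfg)

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ds: KSRDataset = _stage(
        "ingest", lambda: ingest.parse_psp_table(cfg.ksr_path, dialect=cfg.dialect)
    )
    _log_stage(result, "parse", len(ds) + ds.provenance.get("skipped_rows", 0), len(ds))

    n = len(ds)
    ds = _stage("filter_species", lambda: ingest.filter_species(ds, cfg.species))
    _log_stage(result, "filter_species", n, len(ds))

    if cfg.aliases_path:
        aliases = _stage("load_aliases", lambda: ingest.load_alias_map(cfg.aliases_path))
        ds = _stage("normalize_names", lambda: ingest.normalize_kinase_names(ds, aliases))
    else:
        logger.info("no alias map configured; kinase names used as-is")

    if cfg.min_reports > 1:
        n = len(ds)
        ds = _stage(
            "filter_reports", lambda: ingest.filter_by_report_count(ds, cfg.min_reports)
        )
        _log_stage(result, "filter_reports", n, len(ds))

    if cfg.drop_self:
        n = len(ds)
        ds = _stage("drop_self", lambda: ingest.drop_autophosphorylation(ds))
        _log_stage(result, "drop_self", n, len(ds))

    by_class = _stage("split_classes", lambda: ingest.split_residue_classes(ds))

    subgroups = None
    if cfg.subgroups_path:
        subgroups = _stage("load_subgroups", lambda: families.load_subgroups(cfg.subgroups_path))

    for rc in CLASSES:
        cls_ds = by_class[rc]
        for level in LEVELS:
            deduped = _stage(f"dedup/{level}/{rc.value}", lambda: ingest.deduplicate(cls_ds, level))
            _log_stage(result, f"dedup/{level}/{rc.value}", len(cls_ds), len(deduped))
            cm = _stage(
                f"map/{level}/{rc.value}",
                lambda: convergence.build_convergence_map(deduped, level, rc),
            )
            result.maps[(level, rc.value)] = cm
            result.histograms[(level, rc.value)] = convergence.topology_histogram(cm)
            if subgroups is not None:
                result.family_counts[(level, rc.value)] = families.family_convergence_counts(
                    cm, subgroups
                )
        result.participation[rc.value] = kinase_centric.participation_summary(
            result.maps[("general", rc.value)], result.maps[("site_specific", rc.value)]
        )

    # loops run on the general-deduplicated union of both residue classes
    union = ingest.deduplicate(ds, "general")
    result.loop_set = _stage("loops", lambda: loops.find_reciprocal_loops(union))

    matrices = []
    if cfg.expression_path:
        matrices.append(("tpm", cfg.expression_path, cfg.expression_dialect, "log2_tpm_plus1"))
    if cfg.proteomics_path:
        matrices.append(("median", cfg.proteomics_path, "plain_tsv", "ms_relative"))
    if not matrices:
        logger.info("no expression matrices configured; co-expression stage skipped")
    for mode, path, dialect, scale in matrices:
        m = _stage(
            f"load_expression/{mode}",
            lambda: coexpression.load_expression_matrix(path, dialect=dialect, scale=scale),
        )
        thresholds = cfg.tpm_thresholds if mode == "tpm" else (None,)
        for th in thresholds:
            if mode == "tpm":
                b = coexpression.binarize_expression(m, mode="tpm", tpm_threshold=th)
                th_label = f"tpm{th:g}"
            else:
                b = coexpression.binarize_expression(m, mode="median")
                th_label = "median"
            for rc in CLASSES:
                for level in LEVELS:
                    groups = result.maps[(level, rc.value)].convergent_targets()
                    result.coexpression_scores[(level, rc.value, th_label)] = (
                        coexpression.score_groups(groups, b)
                    )
    return result


def export_report(result: PipelineResult, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Write the report bundle: one TSV per table plus a JSON summary.

    File names are stable; two identical runs produce byte-identical files.
    """
    out_dir = Path(out_dir if out_dir is not None else result.config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df) -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written[name] = p

    short = {"general": "general", "site_specific": "site"}
    for (level, cls), cm in sorted(result.maps.items()):
        tag = f"{short[level]}_{cls.lower()}"
        _write(f"targets_{tag}.tsv", convergence.convergent_targets_table(cm))
        _write(f"histogram_{tag}.tsv", result.histograms[(level, cls)].to_frame())
    for cls, df in sorted(result.participation.items()):
        _write(f"kinases_{cls.lower()}.tsv", df)
    if result.family_counts:
        import pandas as pd

        rows = [
            {"level": level, "class": cls, **dataclasses.asdict(fc)}
            for (level, cls), fc in sorted(result.family_counts.items())
        ]
        _write("family_counts.tsv", pd.DataFrame(rows))
    _write("loops.tsv", loops.loops_table(result.loop_set))
    for (level, cls, th_label), scores in sorted(result.coexpression_scores.items()):
        tag = f"{short[level]}_{cls.lower()}_{th_label}"
        _write(f"coexpression_{tag}.tsv", coexpression.scores_table(scores))

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(result.summary(), indent=1, sort_keys=True))
    written["summary.json"] = summary_path
    return written
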