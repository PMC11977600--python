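"""Parsing, filtering, normalization and deduplication of kinase-substrate records.

Kinase-substrate relationships (KSRs) are experimentally validated assertions
that a kinase phosphorylates a substrate at a named residue (a phosphosite such
as ``S780``).  The canonical public source is the PhosphoSitePlus
``Kinase_Substrate_Dataset`` export, a tab-delimited table that may carry a few
non-tabular banner lines before its header row.  This module turns such a table
(or a plain TSV equivalent) into a :class:`KSRDataset`: a flat list of
:class:`KSRRecord` with the substrate species restricted, kinase names
normalized against a nomenclature alias map, and duplicate kinase/substrate(-site)
pairings removed via string fingerprints (``KINASE:SUBSTRATE`` or
``KINASE:SUBSTRATE:SITE``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_SITE_RE = re.compile(r"^[A-Za-z]\d+$")

#: Default column mapping for the PhosphoSitePlus kinase-substrate dialect.
PSP_COLUMNS: Mapping[str, str] = {
    "kinase": "GENE",
    "kinase_species": "KIN_ORGANISM",
    "substrate": "SUB_GENE",
    "substrate_species": "SUB_ORGANISM",
    "site": "SUB_MOD_RSD",
}

#: Column names of the plain TSV dialect.
PLAIN_COLUMNS: Mapping[str, str] = {
    "kinase": "kinase",
    "kinase_species": "kin_species",
    "substrate": "substrate",
    "substrate_species": "sub_species",
    "site": "site",
    "n_reports": "n_reports",
}


class ResidueClass(str, Enum):
    """Residue class of a phosphorylation event, derived from the site letter."""

    SER_THR = "SER_THR"
    TYR = "TYR"
    OTHER = "OTHER"


class FormatError(ValueError):
    """Input table does not conform to the declared dialect."""


def classify_residue(site: str) -> ResidueClass:
    """Classify a phosphosite string by its leading residue letter.

    S/T sites are Ser/Thr events, Y sites are Tyr events; any other residue
    letter (e.g. histidine) is OTHER.  Case-insensitive.
    """
    if not site or not site.strip():
        raise ValueError("empty site string")
    first = site.strip()[0].upper()
    if first in ("S", "T"):
        return ResidueClass.SER_THR
    if first == "Y":
        return ResidueClass.TYR
    return ResidueClass.OTHER


@dataclass(frozen=True)
class KSRRecord:
    """One kinase -> substrate(-site) phosphorylation assertion.

    ``n_reports`` counts independent experimental reports backing the record;
    0 means unknown (no report-count table supplied).
    """

    kinase: str
    substrate: str
    site: str
    kinase_species: str = ""
    substrate_species: str = ""
    n_reports: int = 0

    @property
    def residue_class(self) -> ResidueClass:
        return classify_residue(self.site)


@dataclass
class KSRDataset:
    """A list of KSR records plus provenance of how they were obtained."""

    records: list[KSRRecord]
    provenance: dict = field(default_factory=dict)
    fingerprint_level: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per record)."""
        return pd.DataFrame(
            [
                {
                    "kinase": r.kinase,
                    "substrate": r.substrate,
                    "site": r.site,
                    "residue_class": r.residue_class.value,
                    "kin_species": r.kinase_species,
                    "sub_species": r.substrate_species,
                    "n_reports": r.n_reports,
                }
                for r in self.records
            ],
            columns=[
                "kinase",
                "substrate",
                "site",
                "residue_class",
                "kin_species",
                "sub_species",
                "n_reports",
            ],
        )


def _clean_name(value: object) -> str:
    """Uppercase a gene symbol; ':' is the reserved fingerprint separator."""
    name = str(value).strip().upper()
    return name


def _find_header_row(path: Path, required: Iterable[str]) -> int:
    """Locate the header line of a PSP export, skipping banner lines."""
    required = set(required)
    with open(path, encoding="utf-8", errors="replace") as fh:
        for i, line in enumerate(fh):
            cols = set(c.strip() for c in line.rstrip("\n").split("\t"))
            if required <= cols:
                return i
            if i > 20:
                break
    raise FormatError(
        f"no header row containing columns {sorted(required)} found in {path}"
    )


def parse_psp_table(
    path: str | Path,
    dialect: str = "psp_v6",
    columns: Mapping[str, str] | None = None,
) -> KSRDataset:
    """Parse a kinase-substrate table into a :class:`KSRDataset`.

    Parameters
    ----------
    path
        Tab-delimited input file.
    dialect
        ``"psp_v6"`` for the PhosphoSitePlus export (banner lines tolerated
        before the header; no report-count column) or ``"plain_tsv"`` for the
        package's plain dialect with columns
        ``kinase, substrate, site, kin_species, sub_species, n_reports``.
    columns
        Optional override of the dialect's logical-to-physical column mapping.

    Malformed rows (empty names, empty or non ``letter+digits`` sites, a ':'
    inside a name) are skipped; the skip count is logged and recorded in the
    dataset provenance.
    """
    path = Path(path)
    if dialect == "psp_v6":
        colmap = dict(columns or PSP_COLUMNS)
        header_row = _find_header_row(path, colmap.values())
    elif dialect == "plain_tsv":
        colmap = dict(columns or PLAIN_COLUMNS)
        header_row = 0
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    try:
        df = pd.read_csv(path, sep="\t", skiprows=header_row, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc

    # the report-count column is optional in both dialects
    required = [c for k, c in colmap.items() if k != "n_reports"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")

    has_reports = colmap.get("n_reports") in df.columns

    records: list[KSRRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        kinase = _clean_name(row[colmap["kinase"]]) if pd.notna(row[colmap["kinase"]]) else ""
        substrate = (
            _clean_name(row[colmap["substrate"]]) if pd.notna(row[colmap["substrate"]]) else ""
        )
        site_raw = row[colmap["site"]]
        site = str(site_raw).strip().upper() if pd.notna(site_raw) else ""
        if not kinase or not substrate or ":" in kinase or ":" in substrate:
            n_skipped += 1
            continue
        if not _SITE_RE.match(site):
            n_skipped += 1
            continue
        n_reports = 0
        if has_reports and pd.notna(row[colmap["n_reports"]]):
            try:
                n_reports = int(float(row[colmap["n_reports"]]))
            except ValueError:
                n_skipped += 1
                continue
        records.append(
            KSRRecord(
                kinase=kinase,
                substrate=substrate,
                site=site,
                kinase_species=str(row.get(colmap["kinase_species"], "") or "").strip().lower(),
                substrate_species=str(row.get(colmap["substrate_species"], "") or "")
                .strip()
                .lower(),
                n_reports=n_reports,
            )
        )
    if n_skipped:
        logger.warning("skipped %d malformed row(s) while parsing %s", n_skipped, path)
    return KSRDataset(
        records=records,
        provenance={"source": str(path), "dialect": dialect, "skipped_rows": n_skipped},
    )


def filter_species(ds: KSRDataset, substrate_species: str) -> KSRDataset:
    """Keep only records whose *substrate* organism matches (case-insensitive).

    The kinase organism is deliberately not filtered; upstream kinases from
    other organisms acting on substrates of the requested species are retained
    with their organism kept as metadata.
    """
    want = substrate_species.strip().lower()
    kept = [r for r in ds.records if r.substrate_species == want]
    prov = dict(ds.provenance)
    prov["substrate_species"] = want
    return KSRDataset(records=kept, provenance=prov, fingerprint_level=ds.fingerprint_level)


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (raw_name, canonical_name) nomenclature map.

    The returned mapping is made idempotent: canonical names map to themselves.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["raw", "canonical"])
    aliases: dict[str, str] = {}
    for _, row in df.iterrows():
        raw = _clean_name(row["raw"])
        canonical = _clean_name(row["canonical"])
        if raw.lower() == "raw_name":  # tolerate a header line
            continue
        aliases[raw] = canonical
        aliases.setdefault(canonical, canonical)
    return aliases


def normalize_kinase_names(ds: KSRDataset, aliases: Mapping[str, str]) -> KSRDataset:
    """Replace kinase names by their canonical nomenclature where mapped.

    Unmapped names pass through unchanged and are collected in the provenance
    under ``unmapped_kinases``.  Substrate names are left untouched.
    """
    unmapped: set[str] = set()
    out: list[KSRRecord] = []
    for r in ds.records:
        canonical = aliases.get(r.kinase)
        if canonical is None:
            unmapped.add(r.kinase)
            out.append(r)
        else:
            out.append(replace(r, kinase=canonical))
    if unmapped:
        logger.warning("%d kinase name(s) not in the alias map", len(unmapped))
    prov = dict(ds.provenance)
    prov["unmapped_kinases"] = sorted(unmapped)
    return KSRDataset(records=out, provenance=prov, fingerprint_level=ds.fingerprint_level)


def make_fingerprint(record: KSRRecord, level: str) -> str:
    """Canonical dedup string: ``KINASE:SUBSTRATE`` or ``KINASE:SUBSTRATE:SITE``."""
    for name in (record.kinase, record.substrate, record.site):
        if ":" in name:
            raise ValueError(f"':' is reserved as the fingerprint separator: {name!r}")
    if level == "general":
        return f"{record.kinase.upper()}:{record.substrate.upper()}"
    if level == "site_specific":
        return f"{record.kinase.upper()}:{record.substrate.upper()}:{record.site.upper()}"
    raise ValueError(f"unknown fingerprint level: {level!r}")


def deduplicate(ds: KSRDataset, level: str) -> KSRDataset:
    """Keep one record per unique fingerprint at the given level.

    The first occurrence is kept (input order preserved); its ``n_reports``
    becomes the maximum over all duplicates sharing the fingerprint.
    """
    first: dict[str, int] = {}
    max_reports: dict[str, int] = {}
    for i, r in enumerate(ds.records):
        fp = make_fingerprint(r, level)
        if fp not in first:
            first[fp] = i
        max_reports[fp] = max(max_reports.get(fp, 0), r.n_reports)
    out = []
    for fp, i in first.items():
        r = ds.records[i]
        if r.n_reports != max_reports[fp]:
            r = replace(r, n_reports=max_reports[fp])
        out.append(r)
    prov = dict(ds.provenance)
    prov["dedup_level"] = level
    return KSRDataset(records=out, provenance=prov, fingerprint_level=level)


def filter_by_report_count(ds: KSRDataset, min_reports: int) -> KSRDataset:
    """Keep records backed by at least ``min_reports`` independent reports.

    Requires report counts to be populated for every record; a record with
    ``n_reports == 0`` (unknown) is an error, because silently dropping or
    keeping it would bias the multi-report subset.
    """
    for r in ds.records:
        if r.n_reports <= 0:
            raise ValueError(
                f"record {r.kinase}:{r.substrate}:{r.site} has no report count; "
                "supply the per-KSR report-count table before filtering"
            )
    kept = [r for r in ds.records if r.n_reports >= min_reports]
    prov = dict(ds.provenance)
    prov["min_reports"] = min_reports
    return KSRDataset(records=kept, provenance=prov, fingerprint_level=ds.fingerprint_level)


def split_residue_classes(ds: KSRDataset) -> dict[ResidueClass, KSRDataset]:
    """Split a dataset into Ser/Thr and Tyr subsets; OTHER sites are dropped.

    Phosphorylation on residues other than S/T/Y (e.g. histidine) falls outside
    the two analysis classes; the number dropped is logged and recorded in the
    provenance of both returned datasets.
    """
    by_class: dict[ResidueClass, list[KSRRecord]] = {
        ResidueClass.SER_THR: [],
        ResidueClass.TYR: [],
    }
    n_other = 0
    for r in ds.records:
        rc = r.residue_class
        if rc is ResidueClass.OTHER:
            n_other += 1
            continue
        by_class[rc].append(r)
    if n_other:
        logger.info("dropped %d record(s) on non-S/T/Y residues", n_other)
    out = {}
    for rc, recs in by_class.items():
        prov = dict(ds.provenance)
        prov["residue_class"] = rc.value
        prov["dropped_other_residue"] = n_other
        out[rc] = KSRDataset(records=recs, provenance=prov, fingerprint_level=ds.fingerprint_level)
    return out


def drop_autophosphorylation(ds: KSRDataset) -> KSRDataset:
    """Remove records where kinase and substrate are the same symbol (optional)."""
    kept = [r for r in ds.records if r.kinase != r.substrate]
    prov = dict(ds.provenance)
    prov["dropped_self"] = len(ds.records) - len(kept)
    return KSRDataset(records=kept, provenance=prov, fingerprint_level=ds.fingerprint_level)


def write_plain_tsv(ds: KSRDataset, path: str | Path) -> None:
    """Write the dataset in the plain TSV dialect."""
    df = ds.to_frame().drop(columns=["residue_class"])
    df.to_csv(path, sep="\t", index=False)
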