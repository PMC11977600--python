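import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cksr import ingest
from cksr.ingest import KSRDataset, ResidueClass, classify_residue, make_fingerprint

from .conftest import rec
from .oracles import naive_fingerprints, random_table


def write_psp(tmp_path, rows, banner=True):
    lines = []
    if banner:
        lines += ["Kinase-substrate export", "", "some banner text"]
    lines.append("GENE\tKIN_ORGANISM\tSUB_GENE\tSUB_ORGANISM\tSUB_MOD_RSD")
    lines += rows
    p = tmp_path / "psp.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestParsing:
    def test_psp_dialect_with_banner_lines(self, tmp_path):
        p = write_psp(tmp_path, ["CDK4\thuman\tRB\thuman\tS780"])
        ds = ingest.parse_psp_table(p, dialect="psp_v6")
        assert len(ds) == 1
        r = ds.records[0]
        assert (r.kinase, r.substrate, r.site) == ("CDK4", "RB", "S780")
        assert r.residue_class is ResidueClass.SER_THR
        assert r.n_reports == 0  # no report-count column in the PSP export

    def test_header_only_file_yields_empty_dataset(self, tmp_path):
        ds = ingest.parse_psp_table(write_psp(tmp_path, []), dialect="psp_v6")
        assert len(ds) == 0

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        p = write_psp(
            tmp_path,
            [
                "CDK4\thuman\tRB\thuman\t",       # empty site
                "CDK4\thuman\tRB\thuman\tS780",    # good
                "\thuman\tRB\thuman\tS780",        # empty kinase
                "A:B\thuman\tRB\thuman\tS1",       # reserved separator in name
            ],
        )
        ds = ingest.parse_psp_table(p, dialect="psp_v6")
        assert len(ds) == 1
        assert ds.provenance["skipped_rows"] == 3

    def test_missing_required_column_is_fatal_and_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("GENE\tKIN_ORGANISM\tSUB_GENE\tSUB_ORGANISM\nCDK4\thuman\tRB\thuman\n")
        with pytest.raises(ingest.FormatError, match="SUB_MOD_RSD"):
            ingest.parse_psp_table(p, dialect="psp_v6")

    def test_plain_tsv_round_trip(self, tmp_path):
        ds = KSRDataset(records=[rec("CDK4", "RB", "S780", n_reports=2)])
        out = tmp_path / "plain.tsv"
        ingest.write_plain_tsv(ds, out)
        back = ingest.parse_psp_table(out, dialect="plain_tsv")
        assert back.records == ds.records


class TestResidueClassification:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ("S780", ResidueClass.SER_THR),
            ("T37", ResidueClass.SER_THR),
            ("s12", ResidueClass.SER_THR),
            ("Y416", ResidueClass.TYR),
            ("y9", ResidueClass.TYR),
            ("H115", ResidueClass.OTHER),
        ],
    )
    def test_leading_letter_rule(self, site, expected):
        assert classify_residue(site) is expected

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            classify_residue("")

    def test_other_residues_dropped_from_class_split(self):
        ds = KSRDataset(records=[rec("K1", "S1", "S5"), rec("K1", "S2", "H3")])
        split = ingest.split_residue_classes(ds)
        assert len(split[ResidueClass.SER_THR]) == 1
        assert len(split[ResidueClass.TYR]) == 0
        assert split[ResidueClass.SER_THR].provenance["dropped_other_residue"] == 1


class TestSpeciesFilter:
    def test_keeps_matching_substrate_species_only(self):
        ds = KSRDataset(
            records=[
                rec("K1", "S1", "S5", sub_species="human"),
                rec("K2", "S1", "S5", sub_species="human"),
                rec("K1", "S2", "S5", sub_species="mouse"),
            ]
        )
        assert len(ingest.filter_species(ds, "Human")) == 2
        assert len(ingest.filter_species(ds, "rat")) == 0

    def test_kinase_species_not_filtered(self):
        ds = KSRDataset(records=[rec("K1", "S1", "S5", kin_species="mouse")])
        assert len(ingest.filter_species(ds, "human")) == 1

    def test_idempotent(self):
        ds = KSRDataset(
            records=[rec("K1", "S1", "S5"), rec("K1", "S2", "S5", sub_species="mouse")]
        )
        once = ingest.filter_species(ds, "human")
        twice = ingest.filter_species(once, "human")
        assert once.records == twice.records


class TestNormalization:
    def test_alias_substitution_and_passthrough(self):
        ds = KSRDataset(records=[rec("ERK1", "S1", "S5"), rec("XK999", "S1", "S5")])
        out = ingest.normalize_kinase_names(ds, {"ERK1": "MAPK3", "MAPK3": "MAPK3"})
        assert out.records[0].kinase == "MAPK3"
        assert out.records[1].kinase == "XK999"
        assert out.provenance["unmapped_kinases"] == ["XK999"]

    def test_canonical_name_unchanged(self):
        ds = KSRDataset(records=[rec("CDK6", "RB", "S780")])
        out = ingest.normalize_kinase_names(ds, {"CDK6": "CDK6"})
        assert out.records[0].kinase == "CDK6"

    def test_alias_map_loading_is_idempotent(self, tmp_path):
        p = tmp_path / "aliases.tsv"
        p.write_text("ERK1\tMAPK3\nERK2\tMAPK1\n")
        aliases = ingest.load_alias_map(p)
        assert aliases["ERK1"] == "MAPK3"
        assert aliases["MAPK3"] == "MAPK3"  # canonical maps to itself


class TestFingerprints:
    def test_general_and_site_specific_strings(self):
        r = rec("CDK4", "RB", "S780")
        assert make_fingerprint(r, "general") == "CDK4:RB"
        assert make_fingerprint(r, "site_specific") == "CDK4:RB:S780"

    def test_site_distinguishes_only_site_level(self):
        r1, r2 = rec("A", "S1", "S5"), rec("A", "S1", "T9")
        assert make_fingerprint(r1, "general") == make_fingerprint(r2, "general")
        assert make_fingerprint(r1, "site_specific") != make_fingerprint(r2, "site_specific")

    def test_reserved_separator_rejected(self):
        with pytest.raises(ValueError):
            make_fingerprint(rec("A:B", "S1", "S5"), "general")


class TestDeduplication:
    def test_exact_duplicates_collapse(self):
        ds = KSRDataset(records=[rec("CDK4", "RB", "S780"), rec("CDK4", "RB", "S780")])
        assert len(ingest.deduplicate(ds, "site_specific")) == 1

    def test_level_dependent_collapse(self):
        ds = KSRDataset(records=[rec("A", "S1", "S5"), rec("A", "S1", "T9")])
        assert len(ingest.deduplicate(ds, "general")) == 1
        assert len(ingest.deduplicate(ds, "site_specific")) == 2

    def test_first_occurrence_kept_reports_maxed(self):
        ds = KSRDataset(
            records=[rec("A", "S1", "S5", n_reports=1), rec("A", "S1", "S5", n_reports=3)]
        )
        out = ingest.deduplicate(ds, "site_specific")
        assert out.records[0].n_reports == 3

    @pytest.mark.parametrize("level", ["general", "site_specific"])
    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_bruteforce_fingerprint_set(self, level, seed):
        records = random_table(np.random.default_rng(seed), 200)
        ds = KSRDataset(records=records)
        assert len(ingest.deduplicate(ds, level)) == len(naive_fingerprints(records, level))

    def test_site_count_at_least_general_count(self):
        for seed in range(5):
            ds = KSRDataset(records=random_table(np.random.default_rng(seed), 150))
            n_gen = len(ingest.deduplicate(ds, "general"))
            n_site = len(ingest.deduplicate(ds, "site_specific"))
            assert n_site >= n_gen

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["K1", "K2", "K3"]),
            st.sampled_from(["S1", "S2"]),
            st.sampled_from(["S5", "T9", "Y4"]),
        ),
        max_size=30,
    ))
    def test_dedup_idempotent(self, triples):
        ds = KSRDataset(records=[rec(k, s, site) for k, s, site in triples])
        once = ingest.deduplicate(ds, "site_specific")
        twice = ingest.deduplicate(once, "site_specific")
        assert once.records == twice.records


class TestReportCountFilter:
    def test_threshold_and_identity(self):
        ds = KSRDataset(
            records=[
                rec("A", "S1", "S5", n_reports=1),
                rec("B", "S1", "S5", n_reports=2),
                rec("C", "S1", "S5", n_reports=3),
            ]
        )
        assert len(ingest.filter_by_report_count(ds, 2)) == 2
        assert ingest.filter_by_report_count(ds, 1).records == ds.records

    def test_unknown_counts_are_an_error(self):
        ds = KSRDataset(records=[rec("A", "S1", "S5", n_reports=0)])
        with pytest.raises(ValueError, match="report-count"):
            ingest.filter_by_report_count(ds, 2)

    def test_stricter_filter_output_is_subset(self):
        rng = np.random.default_rng(3)
        ds = KSRDataset(records=random_table(rng, 100))
        loose = set(id(r) for r in ingest.filter_by_report_count(ds, 1).records)
        strict = ingest.filter_by_report_count(ds, 2).records
        assert all(id(r) in loose for r in strict)


def test_drop_autophosphorylation():
    ds = KSRDataset(records=[rec("A", "A", "S5"), rec("A", "B", "S5")])
    out = ingest.drop_autophosphorylation(ds)
    assert len(out) == 1 and out.records[0].substrate == "B"
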