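from __future__ import annotations

import dataclasses

import pytest

from cksr import kinase_centric
from cksr.ingest import KSRDataset, KSRRecord
from cksr.pipeline import PipelineConfig, run_full_pipeline
from cksr.synthetic import SyntheticSpec, load_manifest, write_fixture_bundle


def rec(kinase, substrate, site, sub_species="human", kin_species="human", n_reports=0):
    return KSRRecord(
        kinase=kinase, substrate=substrate, site=site,
        kinase_species=kin_species, substrate_species=sub_species, n_reports=n_reports,
    )


@pytest.fixture
def rb_records():
    """The prototypical convergent pair: CDK4 and CDK6 on RB site S780."""
    return [rec("CDK4", "RB", "S780"), rec("CDK6", "RB", "S780")]


@pytest.fixture(scope="session")
def small_spec():
    """A compact synthetic study used by several integration tests."""
    return SyntheticSpec(
        seed=11,
        n_kinases={"SER_THR": 12, "TYR": 6},
        planted_general={"SER_THR": {1: 6, 2: 4, 3: 2}, "TYR": {1: 4, 2: 2}},
        planted_site={"SER_THR": {1: 5, 2: 3}, "TYR": {1: 3, 2: 1}},
        planted_loops=3,
        n_cell_lines=50,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(small_spec, out)
    return paths, load_manifest(paths["manifest"])


def run_bundle(paths, with_expression=True):
    """Run the full pipeline on a fixture bundle."""
    cfg = PipelineConfig(
        ksr_path=str(paths["ksr"]),
        aliases_path=str(paths["aliases"]),
        subgroups_path=str(paths["subgroups"]),
        expression_path=str(paths["expression"]) if with_expression else None,
    )
    return run_full_pipeline(cfg)


def assert_matches_manifest(result, manifest):
    """Every deterministic pipeline stage must equal the planted ground truth."""
    for cls in ("SER_THR", "TYR"):
        assert result.histograms[("general", cls)].counts == manifest.general_hist[cls]
        assert result.histograms[("site_specific", cls)].counts == manifest.site_hist[cls]
        for level in ("general", "site_specific"):
            cm = result.maps[(level, cls)]
            got = sorted(kinase_centric.participating_kinases(cm))
            assert got == manifest.participating[level][cls]
            fc = dataclasses.asdict(result.family_counts[(level, cls)])
            assert fc == manifest.family_counts[level][cls]
    got_loops = sorted(lp.pair for lp in result.loop_set)
    assert got_loops == manifest.loops
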