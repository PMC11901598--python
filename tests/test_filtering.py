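"""Filter cascade: stage semantics, boundaries, idempotence, composition."""

import numpy as np
import pytest

from polyshare import (
    FilterConfig,
    GenotypeMatrix,
    InputError,
    PopulationMap,
    apply_filter_cascade,
    filter_depth,
    filter_maf,
    filter_site_presence,
    focal_informative_filter,
    remove_indels,
)
from conftest import random_matrix


def _mono(calls, ref="A", alts=("G",), n=None):
    n = n or len(calls)
    return GenotypeMatrix.from_calls(
        [f"s{i}" for i in range(n)], [("v", 1, ref, list(alts), calls)]
    )


class TestRemoveIndels:
    def test_mixed_records(self):
        m = GenotypeMatrix.from_calls(
            ["a"],
            [
                ("v1", 1, "A", ["G"], [(0, 1)]),        # SNP
                ("v2", 2, "AT", ["A"], [(0, 1)]),       # 2-bp deletion
                ("v3", 3, "A", ["AT"], [(0, 1)]),       # insertion
                ("v4", 4, "A", ["G", "AT"], [(0, 1)]),  # mixed record
            ],
        )
        out = remove_indels(m)
        assert out.loci == ["v1"]

    def test_all_snp_identity(self, f1_matrix):
        assert remove_indels(f1_matrix) == f1_matrix


class TestMaf:
    def test_boundary_kept(self):
        # 39 ref copies, 1 alt copy over 20 samples: freq 0.025 >= 0.02
        calls = [(0, 1)] + [(0, 0)] * 19
        assert filter_maf(_mono(calls), 0.02).n_variants == 1

    def test_below_boundary_removed(self):
        # 199:1 -> freq 0.005 < 0.02
        calls = [(0, 1)] + [(0, 0)] * 99
        assert filter_maf(_mono(calls), 0.02).n_variants == 0

    def test_monomorphic_removed(self):
        assert filter_maf(_mono([(0, 0)] * 4), 0.02).n_variants == 0

    def test_all_missing_site_removed(self):
        assert filter_maf(_mono([None, None]), 0.0).n_variants == 0

    def test_missing_excluded_from_denominator(self):
        # known copies 1:1 -> MAF 0.5 regardless of missing calls
        calls = [(0, 1), None, None, None]
        assert filter_maf(_mono(calls), 0.5).n_variants == 1


class TestDepth:
    @pytest.mark.parametrize("dp,kept", [(9, False), (10, True), (300, True), (301, False)])
    def test_site_mean_closed_interval(self, dp, kept):
        m = GenotypeMatrix.from_calls(
            ["a"], [("v", 1, "A", ["G"], [(0, 1)])], depths=np.array([[dp]], dtype=np.int32)
        )
        out = filter_depth(m, 10, 300, "site_mean")
        assert (out.n_variants == 1) is kept

    def test_unknown_depth_kept_with_warning(self, caplog):
        m = _mono([(0, 1), (0, 0)])
        with caplog.at_level("WARNING", logger="polyshare"):
            out = filter_depth(m, 10, 300, "site_mean")
        assert out == m
        assert "unknown depth" in caplog.text

    def test_genotype_mode_masks_call_keeps_site(self):
        depths = np.array([[5, 50, 50, 50]], dtype=np.int32)
        m = GenotypeMatrix.from_calls(
            ["a", "b", "c", "d"],
            [("v", 1, "A", ["G"], [(0, 1), (0, 1), (0, 0), (1, 1)])],
            depths=depths,
        )
        out = filter_depth(m, 10, 300, "genotype")
        assert out.n_variants == 1
        assert out.known[0].tolist() == [False, True, True, True]

    def test_genotype_mode_removes_emptied_site(self):
        m = GenotypeMatrix.from_calls(
            ["a"], [("v", 1, "A", ["G"], [(0, 1)])], depths=np.array([[5]], dtype=np.int32)
        )
        assert filter_depth(m, 10, 300, "genotype").n_variants == 0


class TestSitePresence:
    @pytest.mark.parametrize("n_called,kept", [(1, False), (2, True)])
    def test_boundary(self, n_called, kept):
        calls = [(0, 1)] * n_called + [None] * (4 - n_called)
        out = filter_site_presence(_mono(calls), 2)
        assert (out.n_variants == 1) is kept

    def test_zero_min_is_identity(self, f1_matrix):
        assert filter_site_presence(f1_matrix, 0) == f1_matrix


class TestFocalInformative:
    def test_f1_removes_ubiquitous_site(self, f1_matrix, f1_popmap):
        cfg = FilterConfig.no_op()
        cfg.focal_min_carriers, cfg.drop_ubiquitous, cfg.require_focal_presence = 1, True, True
        out = focal_informative_filter(f1_matrix, f1_popmap, cfg)
        assert out.loci == ["v1", "v2", "v4"]  # v3 alt present in X, B and C

    def test_min_carriers_removes_all_when_unreachable(self, f1_popmap):
        m = GenotypeMatrix.from_calls(
            ["x1", "x2", "b1", "c1"],
            [("v", 1, "A", ["G"], [(0, 1), (0, 1), (0, 0), (0, 0)])],
        )
        cfg = FilterConfig.no_op()
        cfg.focal_min_carriers = 3  # only 2 focal samples carry the alt
        assert focal_informative_filter(m, f1_popmap, cfg).n_variants == 0

    def test_focal_all_missing_site_removed(self, f1_popmap):
        m = GenotypeMatrix.from_calls(
            ["x1", "x2", "b1", "c1"],
            [("v", 1, "A", ["G"], [None, None, (0, 1), (0, 1)])],
        )
        cfg = FilterConfig.no_op()
        cfg.require_focal_presence = True
        assert focal_informative_filter(m, f1_popmap, cfg).n_variants == 0

    def test_copy_count_unit(self, f1_popmap):
        # one focal hom-alt sample: 1 carrier individual but 2 allele copies
        m = GenotypeMatrix.from_calls(
            ["x1", "x2", "b1", "c1"],
            [("v", 1, "A", ["G"], [(1, 1), (0, 0), (0, 0), (0, 0)])],
        )
        cfg = FilterConfig.no_op()
        cfg.focal_min_carriers = 2
        assert focal_informative_filter(m, f1_popmap, cfg).n_variants == 0
        cfg.focal_carrier_unit = "copies"
        assert focal_informative_filter(m, f1_popmap, cfg).n_variants == 1

    def test_focal_without_samples_in_matrix_is_error(self):
        # the map knows lineage B, but the matrix carries no B sample
        m = GenotypeMatrix.from_calls(
            ["x1", "c1"], [("v", 1, "A", ["G"], [(0, 1), (0, 0)])]
        )
        pm = PopulationMap(
            assignment={"x1": "X", "c1": "C", "b1": "B"}, focal="B"
        )
        with pytest.raises(InputError):
            focal_informative_filter(m, pm, FilterConfig())


class TestCascade:
    def test_noop_config_is_identity(self, f1_matrix, f1_popmap):
        out, log = apply_filter_cascade(f1_matrix, f1_popmap, FilterConfig.no_op())
        assert out == f1_matrix
        assert all(s.n_removed == 0 for s in log.stages)

    def test_empty_matrix(self, f1_popmap):
        m = GenotypeMatrix.from_calls(["x1", "x2", "b1", "c1"], [])
        out, log = apply_filter_cascade(m, f1_popmap, FilterConfig())
        assert out.n_variants == 0
        assert all(s.n_in == 0 and s.n_out == 0 for s in log.stages)

    def test_equals_manual_composition(self, f1_popmap):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m, pm = random_matrix(rng, with_depths=True)
            cfg = FilterConfig(
                maf_min=0.05, depth_min=10, depth_max=80, min_samples_per_site=2,
                focal_min_carriers=1,
            )
            cascade, log = apply_filter_cascade(m, pm, cfg)
            manual = remove_indels(m)
            manual = filter_maf(manual, cfg.maf_min)
            manual = filter_depth(manual, cfg.depth_min, cfg.depth_max, cfg.depth_mode)
            manual = filter_site_presence(manual, cfg.min_samples_per_site)
            manual = focal_informative_filter(manual, pm, cfg)
            assert cascade == manual
            # log chains: out of stage k == in of stage k+1
            for a, b in zip(log.stages, log.stages[1:]):
                assert a.n_out == b.n_in

    @pytest.mark.parametrize("mode", ["site_mean", "genotype"])
    def test_each_stage_idempotent(self, mode):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m, pm = random_matrix(rng, with_depths=True)
            cfg = FilterConfig(maf_min=0.1, depth_min=20, depth_max=90,
                               min_samples_per_site=2, depth_mode=mode,
                               focal_min_carriers=1)
            stages = [
                remove_indels,
                lambda x: filter_maf(x, cfg.maf_min),
                lambda x: filter_depth(x, cfg.depth_min, cfg.depth_max, mode),
                lambda x: filter_site_presence(x, cfg.min_samples_per_site),
                lambda x: focal_informative_filter(x, pm, cfg),
            ]
            for stage in stages:
                once = stage(m)
                assert stage(once) == once


class TestConfig:
    def test_validation(self):
        with pytest.raises(InputError):
            FilterConfig(maf_min=0.7)
        with pytest.raises(InputError):
            FilterConfig(depth_min=100, depth_max=10)
        with pytest.raises(InputError):
            FilterConfig(depth_mode="bogus")

    def test_from_yaml(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("maf_min: 0.05\ndepth_min: 12\ndrop_ubiquitous: false\n")
        cfg = FilterConfig.from_file(p)
        assert cfg.maf_min == 0.05 and cfg.depth_min == 12 and not cfg.drop_ubiquitous

    def test_from_flat_keyvalue(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("maf_min=0.03\nmin_samples_per_site=5\n")
        cfg = FilterConfig.from_file(p)
        assert cfg.maf_min == 0.03 and cfg.min_samples_per_site == 5

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("bogus_key: 1\n")
        with pytest.raises(InputError):
            FilterConfig.from_file(p)
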