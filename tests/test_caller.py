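import numpy as np
import pytest

from tillcall.caller import (
    CallerConfig,
    call_population,
    call_position,
    candidate_alleles,
    classify_zygosity,
    control_is_concordant,
    population_coverage_ok,
)
from tillcall.core_io import ALLELES, PileupColumn

from _oracles import naive_call_population
from conftest import random_column


def column(ref="G", contig="ctg000001", pos=10, **sample_counts):
    """sample_counts: name=(nA,nC,nG,nT,nDel) or name=(...,nN)."""
    counts = {}
    for name, c in sample_counts.items():
        c = tuple(c) + (0,) * (6 - len(c))
        counts[name] = c
    return PileupColumn(contig_id=contig, pos=pos, ref_base=ref, counts=counts)


CFG = CallerConfig(min_mut_support=3, min_informative_samples=2)


class TestControlConcordance:
    def test_clean_control(self):
        col = column(ctrl=(0, 0, 30, 0, 0))
        assert control_is_concordant(col, "ctrl", CFG) == (True, "G")

    def test_varietal_snp_excluded(self):
        col = column(ctrl=(30, 0, 0, 0, 0))  # majority A against ref G
        assert control_is_concordant(col, "ctrl", CFG)[0] is False

    def test_minor_fraction_cap(self):
        # 3 alt / 23 total = 13% > 10% cap
        col = column(ctrl=(3, 0, 20, 0, 0))
        assert control_is_concordant(col, "ctrl", CFG)[0] is False
        # 2 alt / 22 total = 9.1% passes
        col = column(ctrl=(2, 0, 20, 0, 0))
        assert control_is_concordant(col, "ctrl", CFG)[0] is True

    def test_no_control_coverage(self):
        col = column(ctrl=(0, 0, 0, 0, 0))
        assert control_is_concordant(col, "ctrl", CFG)[0] is False


class TestCandidateAlleles:
    def test_unique_carrier(self):
        col = column(x=(12, 0, 8, 0, 0), y=(0, 0, 20, 0, 0))
        assert candidate_alleles(col, CFG, ["x", "y"]) == {"A": ["x"]}

    def test_shared_allele_not_unique(self):
        col = column(x=(12, 0, 8, 0, 0), y=(4, 0, 16, 0, 0))
        assert candidate_alleles(col, CFG, ["x", "y"]) == {"A": ["x", "y"]}

    def test_single_stray_read_ignored(self):
        # one error read in y stays below the presence floor of 2
        col = column(x=(12, 0, 8, 0, 0), y=(1, 0, 19, 0, 0))
        assert candidate_alleles(col, CFG, ["x", "y"]) == {"A": ["x"]}


class TestPopulationCoverage:
    def make(self, n_informative, n_total=10):
        counts = {"carrier": (12, 0, 0, 0, 0)}
        for i in range(n_total):
            depth = 3 if i < n_informative else 1
            counts[f"m{i}"] = (0, 0, depth, 0, 0)
        return column(**counts), ["carrier"] + [f"m{i}" for i in range(n_total)]

    def test_enough_informative(self):
        cfg = CallerConfig(min_informative_samples=5)
        col, mutants = self.make(6)
        assert population_coverage_ok(col, "carrier", "G", cfg, mutants) == (True, 6)

    def test_boundary_one_short(self):
        cfg = CallerConfig(min_informative_samples=5)
        col, mutants = self.make(4)
        ok, n = population_coverage_ok(col, "carrier", "G", cfg, mutants)
        assert (ok, n) == (False, 4)

    def test_threshold_scales_with_population(self):
        cfg = CallerConfig(min_informative_samples=2)
        col, mutants = self.make(2, n_total=4)
        assert population_coverage_ok(col, "carrier", "G", cfg, mutants)[0]


class TestZygosity:
    @pytest.mark.parametrize(
        "support,depth,expected",
        [
            (12, 12, "homozygous"),
            (6, 12, "heterozygous"),
            (1, 12, None),  # f ~ 0.083 below the het floor
            (11, 12, "homozygous"),  # f ~ 0.917
            (10, 12, "heterozygous"),  # f ~ 0.833 just below hom floor
        ],
    )
    def test_fraction_bands(self, support, depth, expected):
        assert classify_zygosity(support, depth, CFG) == expected

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            classify_zygosity(1, 0, CFG)


class TestCallPosition:
    def base_column(self, carrier_counts):
        counts = {"ctrl": (0, 0, 30, 0, 0), "x": carrier_counts}
        for i in range(4):
            counts[f"m{i}"] = (0, 0, 8, 0, 0)
        return column(**counts)

    MUTANTS = ["x", "m0", "m1", "m2", "m3"]
    CFG10 = CallerConfig(min_mut_support=10, min_informative_samples=3)

    def test_clean_homozygous_call(self):
        col = self.base_column((12, 0, 0, 0, 0))
        calls, verdicts = call_position(col, self.CFG10, self.MUTANTS, "ctrl")
        (call,) = calls
        assert call.sample_id == "x"
        assert (call.control_base, call.mutant_allele) == ("G", "A")
        assert call.zygosity == "homozygous"
        assert call.is_canonical_ems
        assert call.mut_support == 12 and call.sample_depth == 12

    def test_support_boundary(self):
        col = self.base_column((9, 0, 3, 0, 0))
        calls, verdicts = call_position(col, self.CFG10, self.MUTANTS, "ctrl")
        assert calls == []
        assert verdicts[0].status == "insufficient_support"

    def test_ref_n_not_callable(self):
        counts = {"ctrl": (0, 0, 30, 0, 0), "x": (12, 0, 0, 0, 0)}
        col = column(ref="N", **counts)
        calls, verdicts = call_position(col, self.CFG10, ["x"], "ctrl")
        assert calls == [] and verdicts[0].status == "ref_is_N"

    def test_deletion_allele_called(self):
        col = self.base_column((0, 0, 2, 0, 10))
        calls, _ = call_position(col, self.CFG10, self.MUTANTS, "ctrl")
        (call,) = calls
        assert call.mutation_kind == "deletion"
        assert call.mutant_allele == "DEL"
        assert not call.is_canonical_ems

    def test_multiallelic_column_can_yield_two_samples(self):
        counts = {
            "ctrl": (0, 0, 30, 0, 0),
            "x": (12, 0, 0, 0, 0),
            "y": (0, 0, 2, 10, 0),
            "m0": (0, 0, 8, 0, 0),
            "m1": (0, 0, 8, 0, 0),
            "m2": (0, 0, 8, 0, 0),
        }
        col = column(**counts)
        calls, _ = call_position(
            col, self.CFG10, ["x", "y", "m0", "m1", "m2"], "ctrl"
        )
        assert {(c.sample_id, c.mutant_allele) for c in calls} == {
            ("x", "A"), ("y", "T")
        }

    def test_quiet_column_emits_nothing(self):
        counts = {"ctrl": (0, 0, 30, 0, 0), "x": (1, 0, 9, 0, 0)}
        calls, verdicts = call_position(column(**counts), CFG, ["x"], "ctrl")
        assert calls == [] and verdicts == []


class TestCallPopulation:
    def test_empty(self):
        result = call_population([], CFG, ["ctrl", "x"], "ctrl")
        assert result.calls == [] and result.n_columns == 0

    def test_unknown_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            call_population([], CFG, ["x"], "ctrl")

    def test_missing_sample_in_column_rejected(self):
        col = column(ctrl=(0, 0, 9, 0, 0))
        with pytest.raises(ValueError, match="lacks"):
            call_population([col], CFG, ["ctrl", "x"], "ctrl")

    def test_matches_brute_force_enumeration(self):
        """Random multi-sample pileups: streaming caller == literal oracle."""
        rng = np.random.default_rng(99)
        samples = ["ctrl"] + [f"m{i}" for i in range(7)]
        cfg = CallerConfig(min_mut_support=3, min_informative_samples=3,
                           min_other_depth=2)
        for trial in range(30):
            cols = [
                random_column(rng, samples, pos=p + 1,
                              ref="ACGTN"[int(rng.integers(5))])
                for p in range(200)
            ]
            result = call_population(cols, cfg, samples, "ctrl")
            got = {
                (c.contig_id, c.pos, c.sample_id,
                 "*" if c.mutant_allele == "DEL" else c.mutant_allele,
                 c.zygosity)
                for c in result.calls
            }
            assert got == naive_call_population(cols, cfg, samples, "ctrl")

    def test_no_allele_called_twice_across_samples(self):
        rng = np.random.default_rng(5)
        samples = ["ctrl"] + [f"m{i}" for i in range(5)]
        cols = [random_column(rng, samples, pos=p + 1) for p in range(500)]
        cfg = CallerConfig(min_mut_support=2, min_informative_samples=1)
        result = call_population(cols, cfg, samples, "ctrl")
        keys = [(c.contig_id, c.pos, c.mutant_allele) for c in result.calls]
        assert len(keys) == len(set(keys))

    def test_callable_space_counts_depth_at_support_floor(self):
        cols = [
            column(pos=1, ctrl=(0, 0, 30, 0, 0), x=(0, 0, 5, 0, 0)),
            column(pos=2, ctrl=(0, 0, 30, 0, 0), x=(0, 0, 2, 0, 0)),
        ]
        result = call_population(cols, CFG, ["ctrl", "x"], "ctrl")
        assert result.callable_positions == {"x": 1}

    def test_call_count_monotone_in_stringency(self):
        rng = np.random.default_rng(17)
        samples = ["ctrl"] + [f"m{i}" for i in range(6)]
        cols = [random_column(rng, samples, pos=p + 1) for p in range(800)]

        def n_calls(**kw):
            cfg = CallerConfig(min_informative_samples=2, **kw)
            return len(call_population(cols, cfg, samples, "ctrl").calls)

        by_support = [n_calls(min_mut_support=s) for s in (2, 3, 5, 8, 10)]
        assert by_support == sorted(by_support, reverse=True)
        by_other_depth = [n_calls(min_other_depth=d) for d in (1, 2, 4, 8)]
        assert by_other_depth == sorted(by_other_depth, reverse=True)
        by_informative = [
            len(call_population(
                cols, CallerConfig(min_informative_samples=k),
                samples, "ctrl").calls)
            for k in (1, 3, 5)
        ]
        assert by_informative == sorted(by_informative, reverse=True)
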