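"""NG86 dN/dS, strata assignment, rate model and GC3 tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ng86_bruteforce
from conftest import random_coding_pair
from zwtools.divergence import (
    CodonAlignment,
    RateModel,
    assign_strata,
    autosomal_rate,
    ds_to_time,
    filter_pairs,
    gc3,
    gc3_compare,
    merge_strata,
    ng86_pair,
    pairs_to_frame,
    round_sig,
    sex_linked_rate,
    stratum_summary,
)


class TestNG86:
    def test_identical_sequences_have_zero_divergence(self):
        seq = "ATGGCCAAATTTGGGCAT" * 10
        p = ng86_pair(CodonAlignment("g", seq, seq))
        assert p.ds == 0.0 and p.dn == 0.0 and p.omega is None

    def test_fourfold_third_position_changes_are_purely_synonymous(self):
        # 20 codons; 4 differences, all at 4-fold-degenerate third positions
        z = ("GGT GCT CCT GTT " + "ATG CAT AAA GAA TTT " * 3 + "TGG").replace(" ", "")
        w = ("GGA GCA CCA GTA " + "ATG CAT AAA GAA TTT " * 3 + "TGG").replace(" ", "")
        p = ng86_pair(CodonAlignment("g", z, w))
        assert p.dn == 0.0 and p.ds > 0

    def test_symmetry_in_sequence_order(self, rng):
        s1, s2 = random_coding_pair(rng, 100)
        a = ng86_pair(CodonAlignment("g", s1, s2))
        b = ng86_pair(CodonAlignment("g", s2, s1))
        assert a.ds == pytest.approx(b.ds, abs=1e-15)
        assert a.dn == pytest.approx(b.dn, abs=1e-15)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            s1, s2 = random_coding_pair(rng, 200, p_sub=0.1)
            p = ng86_pair(CodonAlignment("g", s1, s2))
            o = ng86_bruteforce(s1, s2)
            assert p.s_sites == pytest.approx(o["S"], abs=1e-12)
            assert p.sd == pytest.approx(o["Sd"], abs=1e-12)
            assert p.nd == pytest.approx(o["Nd"], abs=1e-12)
            assert p.ds == pytest.approx(o["dS"], abs=1e-12)
            assert p.dn == pytest.approx(o["dN"], abs=1e-12)

    def test_gap_codons_dropped_pairwise(self):
        z = "ATG---AAATTT"
        w = "ATGGCCAAATTC"
        p = ng86_pair(CodonAlignment("g", z, w))
        assert p.n_codons == 3  # the gapped codon is dropped from both

    def test_internal_stop_rejected_and_length_checked(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_pair(CodonAlignment("g", "ATGTAAAAATTT", "ATGTACAAATTT"))
        with pytest.raises(ValueError, match="multiple of 3"):
            CodonAlignment("g", "ATGA", "ATGA")

    def test_saturated_pair_flagged(self):
        # ~all third positions differ within 4-fold codons: pS near 1
        z = "GGT" * 60
        w = "GGA" * 60
        p = ng86_pair(CodonAlignment("g", z, w))
        assert p.saturated and math.isnan(p.ds)


class TestFilter:
    @pytest.mark.parametrize(
        "ds,kept",
        [(2.5, False), (0.0005, False), (0.24, True), (2.0, True), (0.001, True)],
    )
    def test_ds_window_bounds_inclusive(self, ds, kept):
        df = pd.DataFrame({"gene": ["g"], "dS": [ds]})
        assert (len(filter_pairs(df)) == 1) is kept

    def test_saturated_nan_dropped(self):
        df = pd.DataFrame({"gene": ["a", "b"], "dS": [np.nan, 0.3]})
        assert filter_pairs(df)["gene"].tolist() == ["b"]


class TestStrata:
    def _pairs(self):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "dS": [0.35, 0.30, 0.33, 0.36, 0.31, 0.15, 0.17, 0.14, 0.16, 0.18],
                "z_position": [1e6, 2e6, 3e6, 4e6, 5e6, 90e6, 91e6, 92e6, 93e6, 94e6],
            }
        )

    def test_breakpoint_binning_is_exact(self):
        out, asg = assign_strata(self._pairs(), breakpoints=[50e6])
        assert (out.loc[out.z_position < 50e6, "cluster"] == 0).all()
        assert (out.loc[out.z_position > 50e6, "cluster"] == 1).all()
        # higher-dS cluster labelled S1 (older)
        assert (out.loc[out.cluster == 0, "stratum"] == "S1").all()
        assert (out.loc[out.cluster == 1, "stratum"] == "S2").all()

    def test_kmeans_recovers_disjoint_clusters(self):
        out, asg = assign_strata(self._pairs(), k_clusters=2, seed=0)
        exp = np.where(out["z_position"] < 50e6, "S1", "S2")
        assert (out["stratum"] == exp).all()

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            assign_strata(self._pairs(), k_clusters=11)

    def test_merge_into_superstrata(self):
        out, _ = assign_strata(self._pairs(), breakpoints=[50e6])
        merged = merge_strata(out, {"older": ["S1"], "recent": ["S2"]})
        assert set(merged["stratum"]) == {"older", "recent"}

    def test_summary_separated_groups(self):
        df = pd.DataFrame(
            {"dS": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "omega": 0.3,
             "stratum": ["a"] * 3 + ["b"] * 3}
        )
        res = stratum_summary(df)
        # complete separation: U = 0 for the first-named group
        assert res["mannwhitney"][("a", "b")]["U"] == 0.0
        assert res["per_stratum"].loc["a", "n"] == 3

    def test_summary_identical_distributions(self):
        df = pd.DataFrame(
            {"dS": [0.1, 0.2, 0.3] * 2, "omega": 0.3, "stratum": ["a"] * 3 + ["b"] * 3}
        )
        res = stratum_summary(df)
        assert res["mannwhitney"][("a", "b")]["p"] > 0.9


class TestRateModel:
    def test_autosomal_rate_chain(self):
        mu = autosomal_rate(0.94, 167e6)
        assert mu == pytest.approx(2.814e-9, rel=1e-3)
        assert round_sig(mu, 2) == pytest.approx(2.8e-9)
        assert autosomal_rate(2.0, 1e9) == pytest.approx(1e-9)

    def test_combined_rate_component_rounding(self):
        assert sex_linked_rate(RateModel()) == pytest.approx(3.8e-9, rel=1e-12)
        assert sex_linked_rate(
            RateModel(mu_a=2.4e-9, rounding=None)
        ) == pytest.approx(3.24e-9, rel=1e-12)
        assert sex_linked_rate(
            RateModel(mu_a=1e-9, z_ratio=1.0, female_fraction=1.0)
        ) == pytest.approx(2e-9)

    def test_ds_to_time_linear(self):
        assert ds_to_time(0.0, 3.8e-9) == 0.0
        t1 = ds_to_time(0.33, 3.8e-9)
        assert ds_to_time(0.66, 3.8e-9) == pytest.approx(2 * t1)
        assert round(t1 / 1e6) == 87
        assert round(ds_to_time(0.33, 3.24e-9) / 1e6) == 102

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            RateModel(mu_a=-1)
        with pytest.raises(ValueError):
            ds_to_time(0.3, 0)


class TestGC3:
    @pytest.mark.parametrize(
        "cds,expected", [("ATGGCC", 1.0), ("ATTAAA", 0.0), ("ATGGCCATT", 2 / 3)]
    )
    def test_third_position_gc(self, cds, expected):
        assert gc3(cds) == pytest.approx(expected)

    def test_ambiguous_thirds_excluded(self):
        assert gc3("ATNGCC") == 1.0  # only the C at position 6 is scorable

    def test_equal_lists_give_null_result(self):
        z = [0.5, 0.6, 0.4]
        res = gc3_compare(z, z)
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["frac_w_gt_z"] == 0.0

    def test_strict_inequality_fraction(self):
        res = gc3_compare([0.5, 0.5, 0.5, 0.5], [0.6, 0.5, 0.4, 0.7])
        assert res["frac_w_gt_z"] == pytest.approx(0.5)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_ng86_antisymmetric_under_sequence_swap(seed):
    rng = np.random.default_rng(seed)
    s1, s2 = random_coding_pair(rng, 30)
    a = ng86_pair(CodonAlignment("g", s1, s2))
    b = ng86_pair(CodonAlignment("g", s2, s1))
    assert a.sd == pytest.approx(b.sd, abs=1e-12)
    assert a.s_sites == pytest.approx(b.s_sites, abs=1e-12)
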