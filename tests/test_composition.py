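"""GC/CpG/repeat composition, K2P element ages and GC association tests."""

import math

import numpy as np
import pandas as pd
import pytest

from zwtools.composition import (
    composition_tests,
    cpg_content,
    gc_content,
    k2p_distance,
    mdg4_gc_association,
    merge_intervals,
    partial_spearman,
    window_composition,
)
from zwtools.simulate import (
    GenomeLayout,
    RepeatFamily,
    RepeatSimParams,
    simulate_genome,
    simulate_repeat_annotation,
)


class TestBaseComposition:
    @pytest.mark.parametrize(
        "seq,gc,cpg",
        [
            ("GCGC", 1.0, 1 / 3),  # dinucleotides GC, CG, GC
            ("ATAT", 0.0, 0.0),
            ("ANCG", 2 / 3, 1.0),  # only the CG dinucleotide position is scorable
        ],
    )
    def test_known_values(self, seq, gc, cpg):
        assert gc_content(seq) == pytest.approx(gc)
        assert cpg_content(seq) == pytest.approx(cpg)

    def test_all_ambiguous_is_missing(self):
        assert gc_content("NNNN") is None
        assert cpg_content("NNNN") is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestWindowComposition:
    def test_full_and_merged_coverage(self):
        seqs = {"s": "A" * 100}
        ann = pd.DataFrame(
            {
                "chrom": ["s", "s", "s"],
                "start": [0, 20, 30],
                "end": [100, 50, 80],
                "family": ["full", "part", "part"],
            }
        )
        comp = window_composition(seqs, 100, ann)
        row = comp.iloc[0]
        assert row["frac_full"] == 1.0
        # [20,50) and [30,80) merge to [20,80): 60% of the window
        assert row["frac_part"] == pytest.approx(0.6)
        assert row["repeat_fraction"] == 1.0  # union with [0,100)

    def test_terminal_short_window_flagged(self):
        comp = window_composition({"s": "ACGT" * 30}, 100)
        assert comp["short_window"].tolist() == [False, True]
        assert comp["length"].tolist() == [100, 20]
        assert comp["gc"].iloc[1] == pytest.approx(0.5)

    def test_window_size_validated(self):
        with pytest.raises(ValueError):
            window_composition({"s": "ACGT"}, 0)

    def test_input_order_invariance(self):
        seqs = {"a": "ACGTAC" * 50, "b": "GGCCTA" * 50}
        c1 = window_composition(seqs, 50)
        c2 = window_composition(dict(reversed(list(seqs.items()))), 50)
        pd.testing.assert_frame_equal(c1, c2)

    def test_simulated_densities_recovered_per_class(self):
        layout = GenomeLayout(
            [("a", "autosome", 400_000), ("w", "W", 400_000)], window_size=10_000
        )
        fams = [RepeatFamily("fam", 0.04, {"autosome": 1, "W": 5}, mean_length=200)]
        ann, truth = simulate_repeat_annotation(layout, RepeatSimParams(fams, seed=9),
                                                with_sequences=False)
        genome = simulate_genome(layout, seed=9)
        comp = window_composition(genome, 10_000, ann,
                                  classes={"a": "autosome", "w": "W"})
        realized = comp.groupby("class")["frac_fam"].mean()
        for cls in ("autosome", "W"):
            t = truth[truth["class"] == cls].iloc[0]
            se = math.sqrt(t["density"] * (1 - t["density"]) / t["class_bp"]) * 3
            assert abs(realized[cls] - t["density"]) <= max(se, 0.005)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert r.distance == 0.0 and r.transitions == 0.0

    def test_closed_form_transitions_only(self):
        # 1 transition in 10 sites: P=0.1, Q=0 -> d = -0.5*ln(0.8)
        r = k2p_distance("AACCGGTTAC", "GACCGGTTAC")
        assert r.transitions == pytest.approx(0.1)
        assert r.distance == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_cpg_correction_excludes_consensus_cpg_sites(self):
        # consensus all CpG: nothing scorable after correction
        r = k2p_distance("ATATAT", "CGCGCG", cpg_correct=True)
        assert r.n_sites == 0 and math.isnan(r.distance)
        # same pair uncorrected is scorable
        assert k2p_distance("ATATAT", "CGCGCG").n_sites == 6

    def test_saturation_flagged(self):
        r = k2p_distance("AG" * 10, "GA" * 10)  # all transitions
        assert r.saturated and math.isnan(r.distance)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")


class TestCompositionTests:
    def test_identical_distributions_give_high_p(self, rng):
        vals = rng.uniform(0.3, 0.5, 200)
        df = pd.DataFrame(
            {"gc": np.concatenate([vals, vals]), "cpg": 0.01, "repeat_fraction": 0.5,
             "class": ["autosome"] * 200 + ["W"] * 200}
        )
        res = composition_tests(df, metrics=("gc",))
        assert res["tests"][("gc", "W", "autosome")]["p"] > 0.9

    def test_shifted_gc_detected(self, rng):
        df = pd.DataFrame(
            {
                "gc": np.concatenate(
                    [rng.normal(0.36, 0.04, 500), rng.normal(0.44, 0.04, 500)]
                ),
                "class": ["autosome"] * 500 + ["W"] * 500,
            }
        )
        res = composition_tests(df, metrics=("gc",))
        assert res["tests"][("gc", "W", "autosome")]["p"] < 1e-10

    def test_single_class_rejected(self):
        df = pd.DataFrame({"gc": [0.3, 0.4], "class": ["W", "W"]})
        with pytest.raises(ValueError):
            composition_tests(df, metrics=("gc",))


class TestGCAssociation:
    def test_perfect_monotone_association(self):
        n = 30
        df = pd.DataFrame(
            {
                "frac_mdg4": np.linspace(0, 0.5, n),
                "gc": np.linspace(0.36, 0.48, n),
                "cpg": np.full(n, 0.01) + np.linspace(0, 1e-4, n),
                "repeat_fraction": np.linspace(0.2, 0.7, n),
            }
        )
        res = mdg4_gc_association(df)
        assert res["spearman_r"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "frac_mdg4": rng.uniform(0, 0.3, n),
                "gc": rng.normal(0.38, 0.02, n),
                "cpg": rng.uniform(0, 0.02, n),
                "repeat_fraction": rng.uniform(0.3, 0.6, n),
            }
        )
        res = mdg4_gc_association(df)
        assert abs(res["spearman_r"]) < 0.1

    def test_constant_column_rejected(self):
        df = pd.DataFrame(
            {"frac_mdg4": [0.1] * 12, "gc": np.linspace(0.3, 0.4, 12),
             "cpg": 0.01, "repeat_fraction": 0.5}
        )
        with pytest.raises(ValueError, match="constant"):
            mdg4_gc_association(df)

    def test_partial_spearman_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 200
        x = rng.normal(size=n)
        z1 = x + rng.normal(size=n)
        z2 = rng.normal(size=n)
        y = 0.5 * x + 0.5 * z1 + rng.normal(size=n)
        r, p = partial_spearman(x, y, np.vstack([z1, z2]))
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"],
                                    method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_gc_rich_family_drives_positive_association(self):
        layout = GenomeLayout(
            [("w", "W", 1_000_000)], window_size=2_000
        )
        fams = [
            RepeatFamily("mdg4", 0.2, {"W": 1}, gc=0.48, mean_length=400),
            RepeatFamily("other", 0.1, {"W": 1}, gc=0.36, mean_length=400),
        ]
        ann, _ = simulate_repeat_annotation(layout, RepeatSimParams(fams, seed=12))
        genome = simulate_genome(layout, ann, background_gc=0.36, seed=12)
        comp = window_composition(genome, 2_000, ann)
        res = mdg4_gc_association(comp)
        assert res["spearman_r"] > 0.3
        assert res["partial_r"] > 0
        # the non-focal family has background GC: no strong control signal
        assert abs(res["control_r"]) < abs(res["spearman_r"])


def test_merge_intervals_handles_nesting_and_adjacency():
    assert merge_intervals([(0, 10), (5, 8), (10, 12), (20, 25)]) == [(0, 12), (20, 25)]
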