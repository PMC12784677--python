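"""Mid-parent-value arithmetic, the deviation test, and pattern classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterosis.diffexpr import de_test
from heterosis.inheritance import (
    ADDITIVE_CLASSES,
    NONADDITIVE_CLASSES,
    ComparisonTriple,
    additivity_of,
    classify_all,
    classify_gene,
    conserved_call,
    mid_parent_value,
    mpv_deviation_test,
    summarize_patterns,
)
from heterosis.io import CountMatrix, size_factors
from heterosis.simulate import simulate_hybrid_counts


class TestMidParentValue:
    @pytest.mark.parametrize("p1,p2,expected", [(10, 20, 15), (7, 7, 7), (0, 0, 0)])
    def test_arithmetic_mean(self, p1, p2, expected):
        assert mid_parent_value(p1, p2) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mid_parent_value(-1, 5)


class TestMpvDeviationTest:
    def test_replicates_at_mpv_do_not_deviate(self):
        p, deviates = mpv_deviation_test(np.array([10.0, 10.0, 10.0, 10.0]), 10.0)
        assert p == 1.0 and not deviates

    def test_zero_variance_off_target_deviates(self):
        p, deviates = mpv_deviation_test(np.array([100.0] * 4), 10.0)
        assert p == 0.0 and deviates

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            mpv_deviation_test(np.array([5.0]), 5.0)

    def test_power_at_twofold_deviation(self):
        """Replicates at 2x MPV with 10% CV and n=4 deviate >= 95% of the time."""
        rng = np.random.default_rng(17)
        mpv = 100.0
        hits = sum(
            mpv_deviation_test(rng.normal(2 * mpv, 0.1 * 2 * mpv, size=4), mpv)[1]
            for _ in range(200)
        )
        assert hits >= 0.95 * 200


class TestConservedCall:
    @pytest.mark.parametrize(
        "l1,l2,expected",
        [(0.0, 0.0, True), (1.25, 0.0, False), (-1.24, 1.24, True), (0.0, -1.3, False)],
    )
    def test_strict_threshold(self, l1, l2, expected):
        assert conserved_call(l1, l2) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            conserved_call(np.inf, 0.0)


SWAP_MAP = {
    "I": "II", "II": "I",
    "III": "VI", "VI": "III",
    "IV": "V", "V": "IV",
    "VII": "VIII", "VIII": "VII",
    "IX": "IX", "X": "X",
    "XI": "XII", "XII": "XI",
    "conserved": "conserved", "ambiguous": "ambiguous",
}


class TestClassifyGene:
    def test_conserved_wins(self):
        t = ComparisonTriple(a=1, b=-1, c=1)
        assert classify_gene(t, mpv_deviates=False, conserved=True) == "conserved"

    @pytest.mark.parametrize(
        "a,b,c,deviates,expected",
        [
            (1, -1, 1, False, "I"),     # F1 between, parents differ, P2 high
            (-1, 1, -1, False, "II"),   # mirror
            (1, -1, 1, True, "ambiguous"),  # between parents yet off-MPV
            (0, -1, 1, True, "III"),    # F1 ~ low parent P1
            (0, 1, -1, True, "IV"),     # F1 ~ high parent P1
            (1, 0, 1, True, "V"),       # F1 ~ high parent P2
            (-1, 0, -1, True, "VI"),    # F1 ~ low parent P2
            (-1, -1, 1, True, "VII"),   # transgressive down, P2 high
            (-1, -1, -1, True, "VIII"),
            (1, 1, 0, True, "IX"),      # transgressive up, parents equal
            (-1, -1, 0, True, "X"),
            (1, 1, 1, True, "XI"),
            (1, 1, -1, True, "XII"),
        ],
    )
    def test_pattern_table(self, a, b, c, deviates, expected):
        label = classify_gene(
            ComparisonTriple(a=a, b=b, c=c), mpv_deviates=deviates, conserved=False
        )
        assert label == expected

    def test_mpv_consistent_dominance_signature_is_additive(self):
        # hybrid indistinguishable from the MPV: additive even though only
        # one hybrid-parent contrast is individually significant
        label = classify_gene(
            ComparisonTriple(a=1, b=0, c=1), mpv_deviates=False, conserved=False,
            hybrid_between=True,
        )
        assert label == "I"

    def test_hybrid_outside_parental_range_blocks_additive(self):
        label = classify_gene(
            ComparisonTriple(a=1, b=0, c=1), mpv_deviates=False, conserved=False,
            hybrid_between=False,
        )
        assert label == "V"

    def test_every_label_has_additivity(self):
        for label in list(ADDITIVE_CLASSES) + list(NONADDITIVE_CLASSES):
            assert additivity_of(label) in ("additive", "non-additive")
        assert additivity_of("conserved") == "conserved"

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.sampled_from([-1, 0, 1]),
        b=st.sampled_from([-1, 0, 1]),
        c=st.sampled_from([-1, 0, 1]),
        deviates=st.booleans(),
        conserved=st.booleans(),
        between=st.sampled_from([None, True, False]),
    )
    def test_parent_swap_permutes_classes(self, a, b, c, deviates, conserved, between):
        """Relabeling parent1<->parent2 maps classes by the exact mirror
        permutation I<->II, III<->VI, IV<->V, VII<->VIII, XI<->XII."""
        t = ComparisonTriple(a=a, b=b, c=c)
        direct = classify_gene(t, deviates, conserved, between)
        swapped = classify_gene(t.parent_swapped(), deviates, conserved, between)
        assert swapped == SWAP_MAP[direct]


def exact_counts_fixture():
    """Noise-free replicate counts with planted modes; parents 4-fold apart,
    transgressive offsets at 1.5 log2 units (clear of the strict DEG bound)."""
    base = 512.0
    hi = base * 4.0
    mpv = (base + hi) / 2.0
    rows = {
        "g_add": (base, hi, mpv, "additive"),
        "g_dom1": (base, hi, base, "dominant_p1"),
        "g_dom2": (base, hi, hi, "dominant_p2"),
        "g_over": (base, hi, hi * 2.0**1.5, "overdominant"),
        "g_under": (base, hi, base / 2.0**1.5, "underdominant"),
        "g_cons": (base, base, base, "conserved"),
    }
    data, modes = {}, {}
    for gid, (p1, p2, h, mode) in rows.items():
        data[gid] = [p1] * 4 + [p2] * 4 + [h] * 4
        modes[gid] = mode
    # housekeeping background so median-of-ratios normalization is anchored
    for i, level in enumerate([100, 150, 220, 330, 500, 750, 1100, 1600,
                               2400, 3600, 90, 130, 200, 300, 450, 680,
                               1000, 1500, 2200, 3300]):
        data[f"g_hk{i}"] = [level] * 12
    samples = [f"{g}_r{i}" for g in ("P1", "P2", "H1") for i in range(1, 5)]
    cm = CountMatrix(
        pd.DataFrame.from_dict(data, orient="index", columns=samples).astype(int)
    )
    design_rows = [
        {"sample": s, "group": s.split("_")[0],
         "role": {"P1": "parent1", "P2": "parent2", "H1": "hybrid"}[s.split("_")[0]]}
        for s in samples
    ]
    from heterosis.io import SampleDesign

    return cm, SampleDesign(pd.DataFrame.from_records(design_rows)), modes


EXPECTED_EXACT = {
    "additive": ADDITIVE_CLASSES,
    "dominant_p1": {"III", "IV"},
    "dominant_p2": {"V", "VI"},
    "overdominant": {"IX", "XI", "XII"},
    "underdominant": {"VII", "VIII", "X"},
}


class TestClassifyAll:
    @staticmethod
    def run_classify(cm, design):
        factors = size_factors(cm)
        de_h_p1 = de_test(cm, design, "P1", "H1", factors=factors)
        de_h_p2 = de_test(cm, design, "P2", "H1", factors=factors)
        de_p2_p1 = de_test(cm, design, "P1", "P2", factors=factors)
        return classify_all(cm, design, de_h_p1, de_h_p2, de_p2_p1, factors=factors)

    def test_exact_means_recover_planted_modes(self):
        cm, design, modes = exact_counts_fixture()
        calls = self.run_classify(cm, design).set_index("gene_id")
        assert "g_cons" not in calls.index  # DEG nowhere -> outside universe
        for gid, mode in modes.items():
            if mode == "conserved":
                continue
            assert calls.loc[gid, "class_label"] in EXPECTED_EXACT[mode], (
                gid, calls.loc[gid, "class_label"]
            )
        assert calls.loc["g_add", "class_label"] == "I"
        assert calls.loc["g_add", "mpv_p"] >= 0.05

    def test_transgressive_up_exceeds_both_parents(self):
        counts, design, _ = simulate_hybrid_counts(800, seed=9, n_hybrid_groups=1)
        calls = self.run_classify(counts, design)
        up = calls[calls["class_label"].isin(["IX", "XI", "XII"])]
        norm = counts.counts / size_factors(counts)
        for _, row in up.iterrows():
            h = norm.loc[row["gene_id"], design.samples_in_group("H1")].mean()
            p1 = norm.loc[row["gene_id"], design.samples_in_group("P1")].mean()
            p2 = norm.loc[row["gene_id"], design.samples_in_group("P2")].mean()
            assert h > p1 and h > p2

    def test_mismatched_universe_rejected(self, small_counts, small_design):
        factors = size_factors(small_counts)
        t1 = de_test(small_counts, small_design, "TJ", "LT", factors=factors)
        t2 = de_test(small_counts, small_design, "LC", "LT", factors=factors)
        t3 = de_test(small_counts, small_design, "TJ", "LC", factors=factors)
        with pytest.raises(ValueError, match="universe"):
            classify_all(
                small_counts, small_design, t1, t2.iloc[:-1], t3
            )

    def test_additive_calls_never_reject_mpv(self):
        counts, design, _ = simulate_hybrid_counts(1500, seed=13, n_hybrid_groups=1)
        calls = self.run_classify(counts, design)
        additive = calls[calls["additivity"] == "additive"]
        assert (additive["mpv_p"] >= 0.05).all()


class TestSummarizePatterns:
    @staticmethod
    def fake_calls(n_additive, n_nonadditive, n_conserved=0, n_ambiguous=0):
        labels = (
            ["I"] * n_additive
            + ["V"] * n_nonadditive
            + ["conserved"] * n_conserved
            + ["ambiguous"] * n_ambiguous
        )
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(labels))],
                "class_label": labels,
                "additivity": [additivity_of(label) for label in labels],
            }
        )

    def test_counts_and_partition(self):
        s = summarize_patterns(self.fake_calls(3, 5, 2, 1))
        assert s["classified"] == 8
        assert s["additive_count"] + s["nonadditive_count"] == s["classified"]
        assert s["conserved"] == 2 and s["ambiguous"] == 1

    def test_half_up_rounding_to_one_decimal(self):
        s = summarize_patterns(self.fake_calls(674, 4533 - 674))
        assert s["additive_pct"] == 14.9
        assert s["nonadditive_pct"] == 85.1

    def test_all_additive(self):
        s = summarize_patterns(self.fake_calls(10, 0))
        assert s["additive_pct"] == 100.0 and s["nonadditive_pct"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_patterns(self.fake_calls(0, 0))
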