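"""Normalization, mobility propensities, and window labeling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flexmotion as fm
from flexmotion.dataset import (
    AMINO_ACIDS,
    MOBILITY_GROUPS,
    category_score_stats,
    flexible_run_lengths,
    ss_category,
)


class TestNormalizeScores:
    def test_symmetric_three_point(self):
        prof = fm.normalize_scores(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(prof.scores, [-1, 0, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fm.normalize_scores(np.array([5.0, 5.0, 5.0]))

    @given(
        st.lists(
            st.integers(-100_000, 100_000), min_size=3, max_size=50, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_zscore_identities(self, raw):
        prof = fm.normalize_scores(np.array(raw) * 0.01)
        assert abs(prof.scores.mean()) < 1e-9
        assert abs(prof.scores.std(ddof=1) - 1) < 1e-9

    def test_masked_residues_propagate(self):
        mask = np.array([True, True, False, True])
        prof = fm.normalize_scores(np.array([1.0, 2.0, 99.0, 3.0]), mask)
        assert np.isnan(prof.scores[2])
        np.testing.assert_allclose(prof.scores[[0, 1, 3]], [-1, 0, 1])


class TestMobilityGroups:
    @pytest.mark.parametrize(
        "y,expected",
        [(1.5, "high_mob"), (1.0, "normal_mob"), (-1.0, "normal_mob"),
         (-2.0, "low_mob"), (0.0, "normal_mob")],
    )
    def test_thresholds(self, y, expected):
        assert fm.assign_mobility_groups(np.array([y]))[0] == expected


def _uniform_corpus():
    """Every amino acid appears once in every group."""
    seq = AMINO_ACIDS * 3
    grp = np.array(
        ["high_mob"] * 20 + ["normal_mob"] * 20 + ["low_mob"] * 20
    )
    return [seq], [grp]


class TestMobilityPropensity:
    def test_uniform_split_gives_log2_third(self):
        seqs, grps = _uniform_corpus()
        table = fm.compute_mobility_propensity(seqs, grps, pseudo_count=0)
        for g in MOBILITY_GROUPS:
            assert table.prop["A"][g] == pytest.approx(np.log2(1 / 3))

    def test_identical_distributions_give_all_zero_features(self):
        seqs, grps = _uniform_corpus()
        table = fm.compute_mobility_propensity(seqs, grps, pseudo_count=0)
        for aa in AMINO_ACIDS:
            assert not table.feature_vector(aa).any()

    def test_overrepresented_amino_acid_flagged(self):
        # count-and-threshold oracle: G overloaded in the high-mobility group
        seq = AMINO_ACIDS * 6 + "G" * 40
        grp = np.array(
            (["high_mob", "normal_mob", "low_mob"] * 40) + ["high_mob"] * 40
        )
        table = fm.compute_mobility_propensity([seq], [grp])
        assert table.features["G"]["high_mob_high"] == 1

    def test_invariant_under_corpus_duplication(self):
        seq = AMINO_ACIDS * 3 + "GGGPS"
        grp = np.array(
            ["high_mob"] * 20 + ["normal_mob"] * 20 + ["low_mob"] * 20
            + ["high_mob", "normal_mob", "low_mob", "high_mob", "low_mob"]
        )
        t1 = fm.compute_mobility_propensity([seq], [grp], pseudo_count=0)
        t2 = fm.compute_mobility_propensity(
            [seq, seq], [grp, grp], pseudo_count=0
        )
        for aa in AMINO_ACIDS:
            for g in MOBILITY_GROUPS:
                assert t1.prop[aa][g] == pytest.approx(t2.prop[aa][g])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fm.compute_mobility_propensity([], [])


class TestSsCategory:
    def test_deep_helix_residue_is_cs(self):
        # residue 5 (1-based) of a 10-residue helix run
        ss = "H" * 10 + "C" * 10
        cats = ss_category(ss)
        assert cats[4] == "CS"

    def test_boundary_residue_is_ps(self):
        ss = "H" * 10 + "C" * 10
        cats = ss_category(ss)
        assert cats[9] == "PS"   # last helix residue
        assert cats[10] == "PS"  # first coil residue

    def test_deep_coil_residue_is_rs(self):
        ss = "H" * 8 + "C" * 10 + "H" * 8
        cats = ss_category(ss)
        assert cats[12] == "RS"

    def test_every_residue_gets_exactly_one_category(self, corpus16):
        for chain in corpus16.chains:
            cats = ss_category(chain.annotated.ss)
            assert set(cats) <= {"CS", "PS", "RS"}
            assert len(cats) == len(chain.annotated)


class TestWindowLabels:
    def _make(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        annot = fm.AnnotatedSequence(
            sequence="A" * n,
            ss="C" * 5 + "H" * 10 + "C" * (n - 15),
            asa=np.full(n, 30.0),
        )
        raw = rng.normal(size=n) + 10
        return annot, fm.normalize_scores(raw)

    def test_terminal_exclusion(self):
        annot, prof = self._make()
        labels = fm.assign_window_labels(annot, prof, 11)
        centers = [lab.center for lab in labels]
        assert min(centers) == 5 and max(centers) == len(annot) - 6

    def test_even_window_rejected(self):
        annot, prof = self._make()
        with pytest.raises(ValueError, match="odd"):
            fm.assign_window_labels(annot, prof, 10)

    def test_boundary_score_goes_to_intermediate(self):
        n = 30
        annot = fm.AnnotatedSequence(
            sequence="A" * n, ss="C" * n, asa=np.full(n, 30.0)
        )
        scores = np.zeros(n)
        scores[10] = 1.0   # exactly mean + 1 SD under the supplied stats
        prof = fm.NormalizedProfile(
            scores=scores, mask=np.ones(n, bool), chain_mean=0, chain_sd=1
        )
        labels = fm.assign_window_labels(
            annot, prof, 11, category_stats={"CS": (0, 1), "PS": (0, 1), "RS": (0, 1)}
        )
        lab = next(l for l in labels if l.center == 10)
        assert lab.cls == "intermediate"

    def test_exactly_one_class_per_window(self, corpus16):
        chain = corpus16.chains[0]
        labels = fm.assign_window_labels(chain.annotated, chain.norm_internal, 11)
        assert all(lab.cls in ("flexible", "intermediate", "rigid")
                   for lab in labels)

    def test_gaussian_scores_give_expected_class_proportions(self):
        # under normal scores the ±1 SD rule puts ~16/68/16 % in the classes
        rng = np.random.default_rng(12)
        n = 3000
        annot = fm.AnnotatedSequence(
            sequence="A" * n, ss="C" * n, asa=np.full(n, 30.0)
        )
        prof = fm.NormalizedProfile(
            scores=rng.normal(size=n), mask=np.ones(n, bool),
            chain_mean=0, chain_sd=1,
        )
        labels = fm.assign_window_labels(annot, prof, 11)
        frac = Counter(lab.cls for lab in labels)
        total = len(labels)
        assert frac["flexible"] / total == pytest.approx(0.16, abs=0.05)
        assert frac["intermediate"] / total == pytest.approx(0.68, abs=0.05)
        assert frac["rigid"] / total == pytest.approx(0.16, abs=0.05)


class TestClassStatistics:
    def test_two_window_cell(self):
        labels = [
            fm.WindowLabel(center=5, category="CS", cls="flexible", score=0.5),
            fm.WindowLabel(center=9, category="CS", cls="flexible", score=1.5),
        ]
        stats = fm.class_statistics(labels)
        avg, sd = stats.stats[("CS", "flexible")]
        assert avg == pytest.approx(1.0)
        assert sd == pytest.approx(np.std([0.5, 1.5], ddof=1))

    def test_single_window_cell_flagged(self):
        labels = [fm.WindowLabel(center=5, category="RS", cls="rigid", score=-2.0)]
        stats = fm.class_statistics(labels)
        assert ("RS", "rigid") in stats.sparse_cells

    def test_cell_averages_ordered_by_class(self, corpus16):
        data = fm.prepare_training_data(corpus16, "internal")
        stats = data["class_stats"]
        for cat in ("CS", "PS", "RS"):
            cells = {
                cls: stats.stats[(cat, cls)][0]
                for cls in ("flexible", "intermediate", "rigid")
                if (cat, cls) in stats.stats
            }
            if {"flexible", "intermediate", "rigid"} <= set(cells):
                assert cells["rigid"] < cells["intermediate"] < cells["flexible"]


class TestRunLengths:
    def test_hand_countable_histogram(self):
        hist = fm.run_length_distribution([np.array([2.0, 2.0, 0.0, 2.0])])
        assert dict(hist) == {2: 1, 1: 1}

    def test_all_below_threshold(self):
        hist = fm.run_length_distribution([np.array([0.5, -1.0, 1.0])])
        assert not hist

    def test_total_count_matches_residues_above_threshold(self, corpus16):
        profiles = [c.norm_external.scores for c in corpus16.chains]
        hist = fm.run_length_distribution(profiles)
        total = sum(length * count for length, count in hist.items())
        above = sum(
            int(np.nansum(np.nan_to_num(p, nan=-9) > 1)) for p in profiles
        )
        assert total == above

    def test_per_residue_run_lengths(self):
        rl = flexible_run_lengths(np.array([2.0, 2.0, 0.0, 2.0, np.nan]))
        np.testing.assert_array_equal(rl, [2, 2, 0, 1, 0])
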