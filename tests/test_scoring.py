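from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hidtree import MarkerStats, ds_score, rank_markers, score_table, tally_marker
from hidtree.scoring import _ds_vector


def brute_force_ds(an, un, hn, hom_counts, denominator="homozygous"):
    """Independent double-loop evaluation of the DS definition in exact
    arithmetic: prefactor times the sum of P_i * P_j over all unordered pairs
    of present homozygous classes."""
    alleles = sorted(hom_counts)
    if len(alleles) < 2:
        return Fraction(0)
    total = an - un - hn if denominator == "homozygous" else an
    acc = Fraction(0)
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            acc += Fraction(hom_counts[alleles[i]], total) * Fraction(
                hom_counts[alleles[j]], total
            )
    return Fraction(an - un - hn, an) * acc


class TestTally:
    def test_subset_tally(self, make_matrix_fn):
        m = make_matrix_fn(
            {"mk1": ["0/0", "0/0", "1/1", "0/1", "./."]}, ["A", "B", "C", "D", "E"]
        )
        s = tally_marker(m, "mk1", ["A", "B", "C", "D"])
        assert (s.an, s.un, s.hn) == (4, 0, 1)
        assert s.hom_counts == {0: 2, 1: 1} and s.tg == 2

    def test_singleton_subset(self, make_matrix_fn):
        m = make_matrix_fn({"mk1": ["0/0", "1/1"]}, ["A", "B"])
        s = tally_marker(m, "mk1", ["A"])
        assert s.an == 1 and s.tg <= 1

    def test_disjoint_subsets_sum_to_whole(self, make_matrix_fn):
        m = make_matrix_fn(
            {"mk1": ["0/0", "1/1", "0/1", "./.", "1/1"]}, list("ABCDE")
        )
        whole = tally_marker(m, "mk1")
        left = tally_marker(m, "mk1", ["A", "B"])
        right = tally_marker(m, "mk1", ["C", "D", "E"])
        assert whole.an == left.an + right.an
        assert whole.un == left.un + right.un
        assert whole.hn == left.hn + right.hn
        for a in whole.hom_counts:
            assert whole.hom_counts[a] == left.hom_counts.get(a, 0) + right.hom_counts.get(a, 0)

    def test_unknown_ids_raise(self, make_matrix_fn):
        m = make_matrix_fn({"mk1": ["0/0", "1/1"]}, ["A", "B"])
        with pytest.raises(KeyError):
            tally_marker(m, "nope", ["A"])
        with pytest.raises(KeyError):
            tally_marker(m, "mk1", ["Z"])

    def test_inconsistent_stats_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MarkerStats(an=3, un=0, hn=0, hom_counts={0: 1})


class TestDsScore:
    def test_balanced_biallelic_maximum(self):
        s = MarkerStats(an=10, un=0, hn=0, hom_counts={0: 5, 1: 5})
        assert ds_score(s) == 0.25

    def test_all_het_scores_zero(self):
        s = MarkerStats(an=6, un=0, hn=6, hom_counts={})
        assert ds_score(s) == 0.0

    def test_missing_and_het_penalty(self):
        s = MarkerStats(an=10, un=1, hn=1, hom_counts={0: 4, 1: 4})
        assert ds_score(s) == pytest.approx(0.2)

    def test_triallelic_equal_thirds(self):
        s = MarkerStats(an=9, un=0, hn=0, hom_counts={0: 3, 1: 3, 2: 3})
        assert ds_score(s) == pytest.approx(1 / 3)

    def test_all_accession_denominator_variant(self):
        s = MarkerStats(an=10, un=1, hn=1, hom_counts={0: 4, 1: 4})
        assert ds_score(s, denominator="all") == pytest.approx(0.8 * 0.4 * 0.4)

    def test_empty_set_is_domain_error(self):
        with pytest.raises(ValueError, match="empty"):
            ds_score(MarkerStats(an=0, un=0, hn=0, hom_counts={}))

    @given(
        un=st.integers(0, 4),
        hn=st.integers(0, 4),
        counts=st.lists(st.integers(0, 6), min_size=1, max_size=4),
        denominator=st.sampled_from(["homozygous", "all"]),
    )
    def test_matches_exact_double_loop_oracle(self, un, hn, counts, denominator):
        hom = {a: c for a, c in enumerate(counts) if c > 0}
        an = un + hn + sum(hom.values())
        if an == 0:
            return
        s = MarkerStats(an=an, un=un, hn=hn, hom_counts=hom)
        expected = brute_force_ds(an, un, hn, hom, denominator)
        assert ds_score(s, denominator) == pytest.approx(float(expected), abs=1e-12)

    @given(perm_seed=st.integers(0, 10_000), relabel=st.booleans())
    def test_invariance_under_permutation_and_relabel(self, perm_seed, relabel):
        from hidtree import GenotypeMatrix

        rng = np.random.default_rng(perm_seed)
        calls = ["0/0"] * 3 + ["1/1"] * 2 + ["0/1"] * 2 + ["./."]
        if relabel:
            calls = [{"0/0": "1/1", "1/1": "0/0"}.get(c, c) for c in calls]
        order = rng.permutation(len(calls))
        accs = [f"A{i}" for i in range(len(calls))]
        m = GenotypeMatrix(
            ["mk1"], accs, np.array([[calls[i] for i in order]], dtype=object)
        )
        assert ds_score(tally_marker(m, "mk1")) == pytest.approx(
            ds_score(
                MarkerStats(an=8, un=1, hn=2, hom_counts={0: 3, 1: 2})
            )
        )

    def test_biallelic_argmax_is_even_split(self):
        an = 100
        scores = {
            k: ds_score(MarkerStats(an=an, un=0, hn=0, hom_counts={0: k, 1: an - k}))
            for k in range(1, an)
        }
        best = max(scores, key=lambda k: scores[k])
        assert best == 50 and scores[50] == 0.25
        assert all(scores[k] < 0.25 for k in scores if k != 50)


class TestRanking:
    def test_descending_order_and_tie_break(self, make_matrix_fn):
        m = make_matrix_fn(
            {
                "weak": ["0/0", "0/0", "0/0", "1/1"],
                "strong_b": ["0/0", "0/0", "1/1", "1/1"],
                "strong_a": ["1/1", "1/1", "0/0", "0/0"],
            },
            ["A", "B", "C", "D"],
        )
        ranked = rank_markers(m)
        assert [r[0] for r in ranked] == ["strong_b", "strong_a", "weak"]
        assert ranked[0][1] == ranked[1][1] == 0.25

    def test_excluded_markers_absent(self, make_matrix_fn):
        m = make_matrix_fn({"mk1": ["0/0", "1/1"], "mk2": ["0/0", "1/1"]}, ["A", "B"])
        assert rank_markers(m, excluded={"mk1", "mk2"}) == []
        assert [r[0] for r in rank_markers(m, excluded={"mk1"})] == ["mk2"]

    def test_unsplittable_markers_score_zero(self, make_matrix_fn):
        m = make_matrix_fn({"const": ["0/0", "0/0"], "het": ["0/1", "0/1"]}, ["A", "B"])
        assert all(ds == 0.0 for _, ds in rank_markers(m))

    def test_vectorised_scores_match_scalar_path(self):
        from hidtree import SimulationSpec, noisy_matrix

        m = noisy_matrix(SimulationSpec(n_accessions=15, n_markers=20, seed=3))
        cols = list(range(m.n_accessions))
        for denom in ("homozygous", "all"):
            vec = _ds_vector(m, cols, denominator=denom)
            for i, marker in enumerate(m.marker_ids):
                scalar = ds_score(tally_marker(m, marker), denominator=denom)
                assert vec[i] == pytest.approx(scalar, abs=1e-12)

    def test_subset_restriction_consistency(self, make_matrix_fn):
        m = make_matrix_fn(
            {"mk1": ["0/0", "1/1", "0/1", "0/0", "./."]}, list("ABCDE")
        )
        sub = ["A", "B", "C"]
        direct = tally_marker(m, "mk1", sub)
        assert ds_score(direct) == rank_markers(m, sub)[0][1]


def test_score_table_shape_and_values(make_matrix_fn):
    m = make_matrix_fn(
        {"mk1": ["0/0", "1/1", "0/1", "./."], "mk2": ["0/0", "0/0", "0/0", "0/0"]},
        list("ABCD"),
    )
    table = score_table(m)
    assert list(table.index) == ["mk1", "mk2"]
    assert table.loc["mk1", "DS"] == pytest.approx(0.5 * 0.25)
    assert table.loc["mk2", "DS"] == 0.0 and table.loc["mk2", "TG"] == 1
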