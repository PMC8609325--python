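"""Contact-matrix I/O, heat maps and P(s) curves against brute-force oracles."""

import numpy as np
import pytest

from microchrom.errors import InputFormatError, UndefinedValueError
from microchrom.hic import (
    build_matrix,
    distance_bin_edges,
    fit_decay_exponent,
    interaction_heatmap,
    mean_trans_by_class,
    partition_matrix_by_state,
    ps_curve,
    read_ginteractions,
    select_top_scaffolds,
    write_ginteractions,
)
from microchrom.rearrange import RegionClassMap
from microchrom.simulate import simulate_ancestor, simulate_hic

from conftest import make_karyotype, oracle_heatmap, oracle_ps

BS = 50_000


def small_matrix(rng, scaffold_bins, density=0.3):
    """Random symmetric matrix over scaffolds with the given bin counts."""
    lengths = {name: n * BS for name, n in scaffold_bins.items()}
    entries = []
    bins = [(s, i * BS) for s, n in scaffold_bins.items() for i in range(n)]
    for a in range(len(bins)):
        for b in range(a, len(bins)):
            if rng.random() < density:
                entries.append((*bins[a], *bins[b], float(rng.integers(1, 20))))
    return build_matrix(lengths, entries, bin_size=BS)


class TestGInteractionsIO:
    def test_seven_column_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\t0\t50000\ts1\t50000\t100000\t12.5\n")
        m = read_ginteractions(p)
        assert m.counts[0, 1] == 12.5 and m.counts[1, 0] == 12.5

    def test_empty_file_empty_matrix(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        m = read_ginteractions(p)
        assert m.n_bins == 0

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\t0\t50000\ts1\t50000\t100000\n")
        with pytest.raises(InputFormatError):
            read_ginteractions(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\t0\t50000\ts1\t50000\t100000\t-3\n")
        with pytest.raises(InputFormatError):
            read_ginteractions(p)

    def test_mismatched_bin_width_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\t0\t80000\ts1\t80000\t160000\t3\n")
        with pytest.raises(InputFormatError):
            read_ginteractions(p)

    def test_duplicate_and_transposed_lines_merge_by_sum(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "s1\t0\t50000\ts1\t50000\t100000\t2\n"
            "s1\t50000\t100000\ts1\t0\t50000\t3\n"
        )
        m = read_ginteractions(p)
        assert m.counts[0, 1] == 5.0

    def test_round_trip_byte_identical(self, tmp_path):
        m = small_matrix(np.random.default_rng(0), {"s1": 5, "s2": 3})
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_ginteractions(m, p1)
        back = read_ginteractions(p1, scaffold_lengths=m.scaffold_lengths())
        write_ginteractions(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSelectTopScaffolds:
    def test_keeps_largest_by_expected_n(self):
        m = small_matrix(np.random.default_rng(1), {"a": 2, "b": 5, "c": 3,
                                                    "d": 4, "e": 1})
        k = make_karyotype("sp", {"b": 5 * BS, "d": 4 * BS, "c": 3 * BS},
                           threshold=BS)
        sub = select_top_scaffolds(m, k)
        assert sub.scaffolds == ["b", "d", "c"]

    def test_ties_broken_by_name(self):
        m = small_matrix(np.random.default_rng(2), {"z": 3, "a": 3, "m": 3})
        k = make_karyotype("sp", {"a": 3 * BS, "m": 3 * BS}, threshold=BS)
        assert select_top_scaffolds(m, k).scaffolds == ["a", "m"]

    def test_too_few_scaffolds_rejected(self):
        m = small_matrix(np.random.default_rng(3), {"a": 3})
        k = make_karyotype("sp", {"a": 3 * BS, "b": 2 * BS}, threshold=BS)
        with pytest.raises(ValueError):
            select_top_scaffolds(m, k)


class TestHeatmap:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nscaf = int(rng.integers(1, 5))
            bins = {f"s{i}": int(rng.integers(1, 10)) for i in range(nscaf)}
            m = small_matrix(rng, bins)
            heat = interaction_heatmap(m)
            expect = oracle_heatmap(m)
            for (a, b), v in expect.items():
                assert heat.loc[a, b] == pytest.approx(v)

    def test_single_trans_pair(self):
        m = build_matrix({"a": 2 * BS, "b": 2 * BS},
                         [("a", 0, "b", BS, 8.0)], bin_size=BS)
        heat = interaction_heatmap(m)
        assert heat.loc["a", "b"] == pytest.approx(8.0 / 4)
        assert heat.loc["a", "b"] == heat.loc["b", "a"]

    def test_uniform_matrix_constant_table(self):
        entries = [("a", i * BS, "a", j * BS, 1.0)
                   for i in range(3) for j in range(i, 3)]
        entries += [("a", i * BS, "b", j * BS, 1.0)
                    for i in range(3) for j in range(2)]
        entries += [("b", i * BS, "b", j * BS, 1.0)
                    for i in range(2) for j in range(i, 2)]
        m = build_matrix({"a": 3 * BS, "b": 2 * BS}, entries, bin_size=BS)
        heat = interaction_heatmap(m)
        assert np.allclose(heat.to_numpy(), 1.0)

    def test_simulated_micro_micro_trans_enrichment(self):
        k = simulate_ancestor(n_macro=3, n_micro=6,
                              macro_size_range=(36_000_000, 50_000_000),
                              micro_size_range=(5_000_000, 12_000_000), seed=8)
        m = simulate_hic(k, micro_trans_factor=3.0, seed=8)
        t = mean_trans_by_class(m, k)
        assert t.loc["micro", "micro"] > t.loc["macro", "macro"]


class TestPsCurve:
    def test_adjacent_bin_contacts_only(self):
        # 4-bin scaffold, contacts only between adjacent bins
        c = 5.0
        entries = [("s", i * BS, "s", (i + 1) * BS, c) for i in range(3)]
        m = build_matrix({"s": 4 * BS}, entries, bin_size=BS)
        edges = distance_bin_edges(BS, 4 * BS, 3, spacing="linear")
        curves = ps_curve(m, None, max_dist=4 * BS, n_dist_bins=3,
                          spacing="linear")
        curve = curves["all"]
        assert curve.p[0] == pytest.approx(c)  # separation = 1 bin
        assert np.all(curve.p[1:][curve.n_pairs[1:] > 0] == 0)

    def test_uniform_contacts_flat_curve(self):
        entries = [("s", i * BS, "s", j * BS, 2.0)
                   for i in range(6) for j in range(i + 1, 6)]
        m = build_matrix({"s": 6 * BS}, entries, bin_size=BS)
        curves = ps_curve(m, None, max_dist=6 * BS, n_dist_bins=5,
                          spacing="linear")
        p = curves["all"].p
        valid = curves["all"].n_pairs > 0
        assert np.allclose(p[valid], 2.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            bins = {f"s{i}": int(rng.integers(2, 12)) for i in range(3)}
            m = small_matrix(rng, bins)
            classes = {"s0": "x", "s1": "y", "s2": "x"}
            edges = distance_bin_edges(BS, 12 * BS, 6)
            curves = ps_curve(m, classes, max_dist=12 * BS, n_dist_bins=6)
            expect = oracle_ps(m, classes, edges)
            for label, (p, pairs) in expect.items():
                np.testing.assert_allclose(curves[label].n_pairs, pairs)
                np.testing.assert_allclose(curves[label].p, p, equal_nan=True)

    def test_class_without_two_bins_is_undefined(self):
        m = build_matrix({"s": BS}, [], bin_size=BS)
        with pytest.raises(UndefinedValueError):
            ps_curve(m, None, max_dist=10 * BS, n_dist_bins=3)

    def test_probability_mode_unit_sum(self):
        entries = [("s", i * BS, "s", j * BS, float(i + j + 1))
                   for i in range(5) for j in range(i + 1, 5)]
        m = build_matrix({"s": 5 * BS}, entries, bin_size=BS)
        curves = ps_curve(m, None, max_dist=5 * BS, n_dist_bins=4,
                          spacing="linear", mode="probability")
        assert np.nansum(curves["all"].p) == pytest.approx(1.0)

    def test_exponent_fit_on_exact_power_law(self):
        n = 200
        alpha = 1.3
        entries = []
        for i in range(n):
            for j in range(i + 1, n):
                d = j - i
                entries.append(("s", i * BS, "s", j * BS, 100.0 * d ** -alpha))
        m = build_matrix({"s": n * BS}, entries, bin_size=BS)
        curves = ps_curve(m, None, max_dist=n * BS, n_dist_bins=20)
        assert fit_decay_exponent(curves["all"]) == pytest.approx(alpha, abs=0.05)


class TestPartition:
    def test_whole_scaffold_single_state(self):
        m = small_matrix(np.random.default_rng(10), {"a": 4, "b": 3})
        rmap = RegionClassMap(intervals=(("a", 0, 4 * BS, "micro"),
                                         ("b", 0, 3 * BS, "macro")))
        parts = partition_matrix_by_state(m, rmap)
        assert parts["micro"].n_bins == 4
        assert parts["micro"].total == pytest.approx(
            m.restrict(m.bin_indices("a")).total
        )

    def test_majority_assignment_with_left_tie_break(self):
        m = build_matrix({"a": 2 * BS}, [("a", 0, "a", BS, 1.0)], bin_size=BS)
        rmap = RegionClassMap(intervals=(
            ("a", 0, 25_000, "micro"), ("a", 25_000, 50_000, "macro"),
            ("a", 50_000, 100_000, "macro"),
        ))
        parts = partition_matrix_by_state(m, rmap)
        # bin 0 is split 50/50: earlier interval (micro) wins
        assert parts["micro"].n_bins == 1
        assert parts["macro"].n_bins == 1

    def test_bin_conservation(self):
        m = small_matrix(np.random.default_rng(11), {"a": 6})
        rmap = RegionClassMap(intervals=(("a", 0, 3 * BS, "micro"),
                                         ("a", 3 * BS, 6 * BS, "new_macro")))
        parts = partition_matrix_by_state(m, rmap)
        assert sum(p.n_bins for p in parts.values()) == 6
        assert sum(p.total for p in parts.values()) <= m.total
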