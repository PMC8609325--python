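"""Simulator ground-truth guarantees: determinism, bookkeeping, recovery."""

import numpy as np
import pytest

from microchrom.chain_io import reciprocal_best, write_chain
from microchrom.errors import ConfigurationError
from microchrom.rearrange import call_events
from microchrom.simulate import (
    apply_events,
    emit_chains,
    random_events,
    score_event_recovery,
    simulate_ancestor,
    simulate_hic,
    write_fasta,
)
from microchrom.karyo import fasta_gc

MB = 1_000_000


class TestAncestor:
    def test_default_karyotype_shape(self):
        k = simulate_ancestor(seed=0)
        assert len(k) == 39
        assert len(k.macros()) == 9 and len(k.micros()) == 30

    def test_deterministic_per_seed(self):
        a, b = simulate_ancestor(seed=5), simulate_ancestor(seed=5)
        assert a == b
        assert simulate_ancestor(seed=6) != a

    def test_sizes_respect_threshold_by_construction(self):
        k = simulate_ancestor(seed=1)
        assert all(c.length >= k.micro_threshold for c in k.macros())
        assert all(c.length < k.micro_threshold for c in k.micros())

    def test_gc_offset_realized(self):
        # Monte-Carlo: the class GC gap matches the configured offset
        gaps = []
        for seed in range(30):
            k = simulate_ancestor(gc_micro_offset=0.06, seed=seed)
            df_micro = np.mean([c.gc for c in k.micros()])
            df_macro = np.mean([c.gc for c in k.macros()])
            gaps.append(df_micro - df_macro)
        assert np.mean(gaps) == pytest.approx(0.06, abs=0.01)

    def test_impossible_constraints_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_ancestor(micro_size_range=(40 * MB, 50 * MB))

    def test_fasta_emission_matches_gc(self, tmp_path):
        k = simulate_ancestor(n_macro=1, n_micro=1,
                              macro_size_range=(36 * MB, 37 * MB),
                              micro_size_range=(1 * MB, 2 * MB), seed=2)
        # shrink to a writable size, keeping names/gc
        from dataclasses import replace
        small = replace(k, chromosomes=tuple(
            replace(c, length=20_000, n_genes=None) for c in k.chromosomes
        ))
        p = tmp_path / "g.fa"
        write_fasta(small, p, seed=3)
        gc = fasta_gc(p)
        for c in small.chromosomes:
            assert gc[c.name] == pytest.approx(c.gc, abs=0.02)


class TestApplyEvents:
    def test_fusion_lengths_add(self):
        k = simulate_ancestor(seed=3)
        a, b = (c.name for c in k.micros()[:2])
        hist = apply_events(k, [{"type": "micro_micro_fusion",
                                 "participants": [a, b]}])
        fused = hist.derived[f"{a}+{b}"]
        assert fused.length == k[a].length + k[b].length

    def test_fused_gc_is_length_weighted_mean(self):
        k = simulate_ancestor(seed=4)
        a, b = (c.name for c in k.micros()[:2])
        hist = apply_events(k, [{"type": "micro_micro_fusion",
                                 "participants": [a, b]}])
        ca, cb = k[a], k[b]
        expect = (ca.gc * ca.length + cb.gc * cb.length) / (ca.length + cb.length)
        assert hist.derived[f"{a}+{b}"].gc == pytest.approx(expect, abs=1e-12)

    def test_fission_below_threshold_creates_micro(self):
        k = simulate_ancestor(seed=5)
        mac = k.macros()[0].name
        hist = apply_events(k, [{"type": "fission", "participants": [mac],
                                 "breakpoint": 30 * MB}])
        assert hist.derived[f"{mac}.1"].length == 30 * MB
        assert hist.derived[f"{mac}.1"].chrom_class == "micro"
        assert hist.derived[f"{mac}.2"].chrom_class == "macro"

    def test_genome_wide_expansion_preserves_size_ordering(self):
        k = simulate_ancestor(seed=6)
        hist = apply_events(k, [{"type": "expansion", "participants": [],
                                 "factor": 1.5}])
        anc_order = sorted(k.names, key=lambda n: k[n].length)
        der_order = sorted(k.names, key=lambda n: hist.derived[n].length)
        assert anc_order == der_order
        assert hist.derived[k.names[0]].length == pytest.approx(
            1.5 * k[k.names[0]].length, rel=1e-6
        )

    def test_self_fusion_rejected(self):
        k = simulate_ancestor(seed=7)
        a = k.micros()[0].name
        with pytest.raises(ConfigurationError):
            apply_events(k, [{"type": "micro_micro_fusion",
                              "participants": [a, a]}])

    def test_replay_reproduces_derived_lengths(self):
        k = simulate_ancestor(seed=8)
        events = random_events(k, n_events=10, seed=8)
        hist = apply_events(k, events)
        for name, segs in hist.structure.items():
            assert hist.derived[name].length == sum(s.derived_length for s in segs)


class TestEmitChains:
    def test_no_events_no_noise_one_full_chain_per_chromosome(self):
        k = simulate_ancestor(seed=9)
        hist = apply_events(k, [])
        chains = emit_chains(hist, frag_rate=0.0, seed=0)
        assert len(chains) == len(k)
        for c in chains:
            assert c.aligned_bp == k[c.query.name].length
            assert (c.target.start, c.target.end) == (0, c.aligned_bp)

    def test_tandem_fusion_gives_abutting_target_spans(self):
        k = simulate_ancestor(seed=10)
        a, b = (c.name for c in k.micros()[:2])
        hist = apply_events(k, [{"type": "micro_micro_fusion",
                                 "participants": [a, b]}])
        chains = [c for c in emit_chains(hist, frag_rate=0, seed=0)
                  if c.target.name == f"{a}+{b}"]
        spans = sorted((c.target.start, c.target.end) for c in chains)
        assert len(spans) == 2
        assert spans[0][1] == spans[1][0]  # abutting at the fusion junction

    def test_gap_fraction_bounds_aligned_bp(self):
        k = simulate_ancestor(seed=11)
        hist = apply_events(k, random_events(k, n_events=5, seed=11))
        total = k.genome_length
        for gap_frac in (0.0, 0.05):
            chains = emit_chains(hist, frag_rate=0.5, gap_frac=gap_frac, seed=4)
            aligned = sum(c.aligned_bp for c in chains)
            assert aligned >= (1 - gap_frac) * total - len(chains)
            assert aligned <= total

    def test_byte_identical_per_seed(self, tmp_path):
        k = simulate_ancestor(seed=12)
        hist = apply_events(k, random_events(k, n_events=8, seed=12))
        p1, p2 = tmp_path / "a.chain", tmp_path / "b.chain"
        write_chain(emit_chains(hist, seed=9), p1)
        write_chain(emit_chains(hist, seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()
        write_chain(emit_chains(hist, seed=10), tmp_path / "c.chain")
        assert (tmp_path / "c.chain").read_bytes() != p1.read_bytes()

    def test_expansion_emits_consistent_target_coordinates(self):
        k = simulate_ancestor(seed=13)
        mic = k.micros()[0].name
        hist = apply_events(k, [{"type": "expansion", "participants": [mic],
                                 "factor": 1.5}])
        chains = [c for c in emit_chains(hist, frag_rate=0, seed=0)
                  if c.target.name == mic]
        (c,) = chains
        assert c.target.end == hist.derived[mic].length
        assert c.aligned_bp == k[mic].length


class TestGroundTruthSerialization:
    def test_json_round_trip_fields(self, tmp_path):
        import json

        k = simulate_ancestor(seed=14)
        hist = apply_events(k, random_events(k, n_events=6, seed=14), seed=14)
        p = tmp_path / "truth.json"
        hist.to_json(p)
        data = json.loads(p.read_text())
        assert data["seed"] == 14
        assert len(data["events"]) == 6
        assert set(data["structure"]) == set(hist.derived.names)


class TestSimulateHic:
    def test_k1_null_trans_means_equal(self):
        from microchrom.hic import mean_trans_by_class

        k = simulate_ancestor(n_macro=3, n_micro=6,
                              macro_size_range=(36 * MB, 50 * MB),
                              micro_size_range=(5 * MB, 12 * MB), seed=15)
        m = simulate_hic(k, micro_trans_factor=1.0, trans_base=0.2, seed=15)
        t = mean_trans_by_class(m, k)
        assert t.loc["micro", "micro"] == pytest.approx(
            t.loc["macro", "macro"], rel=0.1
        )

    def test_micro_trans_factor_scales_means(self):
        from microchrom.hic import mean_trans_by_class

        ratios = []
        for seed in range(5):
            k = simulate_ancestor(n_macro=3, n_micro=6,
                                  macro_size_range=(36 * MB, 50 * MB),
                                  micro_size_range=(5 * MB, 12 * MB), seed=seed)
            m = simulate_hic(k, micro_trans_factor=3.0, trans_base=0.1,
                             seed=seed)
            t = mean_trans_by_class(m, k)
            ratios.append(t.loc["micro", "micro"] / t.loc["macro", "macro"])
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.1)

    def test_bin_size_larger_than_smallest_chromosome_rejected(self):
        k = simulate_ancestor(seed=16)
        with pytest.raises(ConfigurationError):
            simulate_hic(k, bin_size=10**9)

    def test_invalid_parameters_rejected(self):
        k = simulate_ancestor(seed=17)
        with pytest.raises(ConfigurationError):
            simulate_hic(k, alpha_micro=0.0)
        with pytest.raises(ConfigurationError):
            simulate_hic(k, micro_trans_factor=0.5)


class TestRecoveryScoring:
    def test_zero_noise_perfect_recovery(self):
        for seed in range(3):
            k = simulate_ancestor(seed=seed)
            hist = apply_events(k, random_events(k, n_events=10, seed=seed))
            blocks = reciprocal_best(emit_chains(hist, frag_rate=0, seed=seed),
                                     min_len=100_000)
            calls = call_events(blocks, k, hist.derived)
            recall, precision = score_event_recovery(hist, calls)
            assert recall == 1.0 and precision == 1.0
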