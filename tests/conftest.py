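"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each statistic in the most naive way
possible (dense double loops, pairwise checks over the sorted chain list)
so that they share no code path with the implementation they verify.
"""

from __future__ import annotations

import numpy as np
import pytest

from microchrom.chain_io import AlignmentChain, ChainSide, SyntenyBlock, chain_to_block
from microchrom.karyo import ChromosomeRecord, Karyotype, classify_chromosomes


# ---------------------------------------------------------------------------
# Builders


def make_karyotype(species, chrom_sizes, threshold=35_000_000, gc=None, classify=True):
    """Karyotype from a {name: length} mapping (optionally {name: gc})."""
    gc = gc or {}
    chroms = tuple(
        ChromosomeRecord(name, length, gc=gc.get(name))
        for name, length in chrom_sizes.items()
    )
    k = Karyotype(species=species, chromosomes=chroms, micro_threshold=threshold)
    return classify_chromosomes(k) if classify else k


def make_block(q_chrom, q_start, q_end, t_chrom, t_start, t_end,
               aligned_bp=None, score=None, orientation="same"):
    if aligned_bp is None:
        aligned_bp = min(q_end - q_start, t_end - t_start)
    if score is None:
        score = float(aligned_bp)
    return SyntenyBlock(q_chrom=q_chrom, q_start=q_start, q_end=q_end,
                        t_chrom=t_chrom, t_start=t_start, t_end=t_end,
                        orientation=orientation, aligned_bp=aligned_bp, score=score)


def make_chain(score, t=("t1", 1000, "+", 0, 100), q=("q1", 1000, "+", 0, 100),
               blocks=None, chain_id=1):
    span_t = t[4] - t[3]
    span_q = q[4] - q[3]
    if blocks is None:
        assert span_t == span_q
        blocks = ((span_t, 0, 0),)
    return AlignmentChain(
        score=score,
        target=ChainSide(*t),
        query=ChainSide(*q),
        blocks=tuple(blocks),
        chain_id=chain_id,
    )


def random_chain_set(rng, n_chains, n_chroms=3, genome=1_000_000):
    """Random, possibly overlapping chains for oracle comparisons."""
    chains = []
    for cid in range(1, n_chains + 1):
        tname = f"t{rng.integers(1, n_chroms + 1)}"
        qname = f"q{rng.integers(1, n_chroms + 1)}"
        tlen = genome
        qlen = genome
        span = int(rng.integers(1_000, 200_000))
        ts = int(rng.integers(0, tlen - span))
        qs = int(rng.integers(0, qlen - span))
        strand = "+" if rng.random() < 0.8 else "-"
        chains.append(make_chain(
            score=float(rng.integers(1, 1000)),
            t=(tname, tlen, "+", ts, ts + span),
            q=(qname, qlen, strand, qs, qs + span),
            chain_id=cid,
        ))
    return chains


# ---------------------------------------------------------------------------
# Oracles


def oracle_reciprocal_best(chains, overlap_tol=0):
    """Greedy net re-derived pairwise over the sorted chain list."""

    def fwd(side):
        if side.strand == "+":
            return side.start, side.end
        return side.size - side.end, side.size - side.start

    def overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    accepted = []
    for c in sorted(chains, key=lambda c: (-c.score, c.chain_id)):
        ok = True
        for a in accepted:
            if a.query.name == c.query.name and \
                    overlap(fwd(a.query), fwd(c.query)) > overlap_tol:
                ok = False
                break
            if a.target.name == c.target.name and \
                    overlap((a.target.start, a.target.end),
                            (c.target.start, c.target.end)) > overlap_tol:
                ok = False
                break
        if ok:
            accepted.append(c)
    return [chain_to_block(c) for c in accepted]


def oracle_heatmap(matrix):
    """Dense double loop over every bin pair."""
    dense = matrix.counts.toarray()
    scafs = sorted(matrix.scaffold_lengths().items(), key=lambda kv: (-kv[1], kv[0]))
    out = {}
    for a, _ in scafs:
        ia = matrix.bin_indices(a)
        for b, _ in scafs:
            ib = matrix.bin_indices(b)
            total = 0.0
            for i in ia:
                for j in ib:
                    total += dense[i, j]
            out[(a, b)] = total / (len(ia) * len(ib))
    return out


def oracle_ps(matrix, classes, edges):
    """Enumerate every intra-scaffold bin pair, bin by separation."""
    dense = matrix.counts.toarray()
    n_bins = len(edges) - 1
    out = {}
    labels = sorted(set(classes.values()))
    for label in labels:
        pairs = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for scaf in matrix.scaffolds:
            if classes.get(scaf) != label:
                continue
            idx = matrix.bin_indices(scaf)
            starts = matrix.bins["start"].iloc[idx].to_numpy()
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    s = abs(int(starts[b]) - int(starts[a]))
                    k = None
                    for d in range(n_bins):
                        if edges[d] <= s < edges[d + 1]:
                            k = d
                            break
                    if k is None:
                        continue
                    pairs[k] += 1
                    counts[k] += dense[idx[a], idx[b]]
        with np.errstate(invalid="ignore"):
            p = np.where(pairs > 0, counts / np.maximum(pairs, 1), np.nan)
        out[label] = (p, pairs)
    return out


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def toy_pair():
    """Two tiny classified karyotypes sharing the 35-Mb threshold."""
    qk = make_karyotype("anc", {"A": 100_000_000, "a1": 10_000_000,
                                "a2": 8_000_000})
    tk = make_karyotype("der", {"B": 120_000_000, "b1": 12_000_000,
                                "b2": 6_000_000})
    return qk, tk
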