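"""Seeded simulator of karyotype evolution and of every pipeline input.

The simulator emulates the canonical bird/reptile genome architecture and
its evolution:

* an ancestral karyotype with a bimodal size distribution — by default
  9 macrochromosomes and 30 microchromosomes (the conserved avian state),
  microchromosomes GC-richer and more gene-dense than macros;
* rearrangement histories built from the observed event repertoire:
  micro–micro fusion (tandem or centric), fusion of a micro to a
  macrochromosome terminus or centromere, macro–macro fusion, fission of a
  macrochromosome (creating a new micro-sized chromosome from a terminal
  region), and length expansion emulating transposable-element insertion;
* alignment chains between ancestor (query) and derived (target) genomes,
  with geometric chain-splitting noise and small unaligned gaps;
* binned Hi-C contact matrices with power-law intra-chromosomal decay
  (class-specific exponent) and uniform trans contacts elevated by a
  factor k for micro–micro scaffold pairs, Poisson-sampled.

Everything is deterministic given the seed, and each history carries a
ground-truth event log so downstream callers can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from microchrom.chain_io import AlignmentChain, ChainSide
from microchrom.errors import ConfigurationError
from microchrom.hic import ContactMatrix, _bin_table
from microchrom.karyo import (
    ChromosomeRecord,
    Karyotype,
    MACRO,
    MICRO,
    classify_chromosomes,
)

DEFAULT_MICRO_THRESHOLD = 35_000_000


# ---------------------------------------------------------------------------
# Ancestral karyotype


def simulate_ancestor(
    n_macro: int = 9,
    n_micro: int = 30,
    micro_threshold: int = DEFAULT_MICRO_THRESHOLD,
    macro_size_range: tuple[int, int] = (45_000_000, 220_000_000),
    micro_size_range: tuple[int, int] = (6_000_000, 30_000_000),
    gc_macro_mean: float = 0.41,
    gc_micro_offset: float = 0.07,
    gc_sd: float = 0.01,
    gene_density_macro: float = 17.0,
    gene_density_micro: float = 40.0,
    seed: int = 0,
    species: str = "ancestor",
) -> Karyotype:
    """Sample a classified bimodal ancestral karyotype.

    Sizes are log-uniform within the class range (macros strictly at or
    above the threshold, micros strictly below); GC is normal around the
    class mean (micros offset upward); gene counts follow the class gene
    density.  Deterministic per seed.
    """
    if micro_size_range[1] > micro_threshold:
        raise ConfigurationError("micro size range extends above the threshold")
    if macro_size_range[0] < micro_threshold:
        raise ConfigurationError("macro size range extends below the threshold")
    rng = np.random.default_rng(seed)

    def sizes(n, lo, hi):
        s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        return np.sort(s)[::-1].astype(np.int64)

    chroms = []
    for name, length in zip(
        (f"M{i+1}" for i in range(n_macro)),
        sizes(n_macro, *macro_size_range),
    ):
        gc = float(np.clip(rng.normal(gc_macro_mean, gc_sd), 0.2, 0.8))
        n_genes = int(rng.poisson(gene_density_macro * length / 1e6))
        chroms.append(ChromosomeRecord(name, int(length), gc=gc, n_genes=n_genes))
    for name, length in zip(
        (f"m{i+1}" for i in range(n_micro)),
        sizes(n_micro, *micro_size_range),
    ):
        gc = float(np.clip(rng.normal(gc_macro_mean + gc_micro_offset, gc_sd), 0.2, 0.8))
        n_genes = int(rng.poisson(gene_density_micro * length / 1e6))
        chroms.append(ChromosomeRecord(name, int(length), gc=gc, n_genes=n_genes))
    k = Karyotype(
        species=species,
        chromosomes=tuple(chroms),
        micro_threshold=micro_threshold,
        expected_n=n_macro + n_micro,
    )
    return classify_chromosomes(k)


def write_fasta(karyotype: Karyotype, path, seed: int = 0, line_width: int = 70) -> None:
    """Emit i.i.d. sequences at each chromosome's GC (use with small genomes)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for c in karyotype.chromosomes:
            gc = c.gc if c.gc is not None else 0.42
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            seq = rng.choice(bases, size=c.length, p=p)
            fh.write(f">{c.name}\n")
            s = "".join(seq)
            for i in range(0, len(s), line_width):
                fh.write(s[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Rearrangement histories


@dataclass(frozen=True)
class Segment:
    """A derived-chromosome piece tracing back to one ancestor interval."""

    ancestor: str
    start: int
    end: int
    orientation: str = "+"
    expansion: float = 1.0

    @property
    def ancestral_length(self) -> int:
        return self.end - self.start

    @property
    def derived_length(self) -> int:
        return int(round(self.ancestral_length * self.expansion))


@dataclass(frozen=True)
class SimulatedHistory:
    """Ancestor, derived genome, the events linking them, and provenance."""

    ancestral: Karyotype
    derived: Karyotype
    events: tuple[dict, ...]
    structure: Mapping[str, tuple[Segment, ...]]  # derived name -> segments
    centromeres: Mapping[str, int]  # derived name -> position, when known
    seed: int

    def segments_of(self, derived_name: str) -> tuple[Segment, ...]:
        return tuple(self.structure[derived_name])

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "ancestral_species": self.ancestral.species,
            "derived_species": self.derived.species,
            "events": list(self.events),
            "structure": {
                name: [
                    {
                        "ancestor": s.ancestor, "start": s.start, "end": s.end,
                        "orientation": s.orientation, "expansion": s.expansion,
                    }
                    for s in segs
                ]
                for name, segs in self.structure.items()
            },
            "centromeres": dict(self.centromeres),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _derived_length(segments: Sequence[Segment]) -> int:
    return sum(s.derived_length for s in segments)


def _weighted_gc(segments: Sequence[Segment], karyotype: Karyotype) -> float | None:
    num = den = 0.0
    for s in segments:
        gc = karyotype[s.ancestor].gc
        if gc is None:
            return None
        w = s.derived_length
        num += gc * w
        den += w
    return num / den if den else None


def apply_events(
    karyotype: Karyotype,
    events: Sequence[Mapping],
    seed: int = 0,
    derived_species: str = "derived",
) -> SimulatedHistory:
    """Replay an ordered event list on an ancestral karyotype.

    Events are dicts with a ``type`` and ``participants`` (current
    chromosome names); supported types: ``micro_micro_fusion`` (mode
    tandem|centric), ``macro_micro_fusion_terminal`` / ``_centric``,
    ``macro_macro_fusion``, ``fission`` (with ``breakpoint``), and
    ``expansion`` (with ``factor``; empty participants = genome-wide).
    Fused chromosomes inherit the length-weighted mean GC of their parts.
    """
    working: dict[str, list[Segment]] = {
        c.name: [Segment(c.name, 0, c.length)] for c in karyotype.chromosomes
    }
    centromeres: dict[str, int] = {}
    log: list[dict] = []

    def take(name: str) -> list[Segment]:
        if name not in working:
            raise ConfigurationError(f"event references unknown chromosome {name!r}")
        return working.pop(name)

    for ev in events:
        etype = ev["type"]
        parts = list(ev.get("participants", []))
        if len(parts) != len(set(parts)):
            raise ConfigurationError(f"{etype}: cannot fuse a chromosome with itself")
        entry = {"type": etype, "participants": parts}
        if etype in ("micro_micro_fusion", "macro_micro_fusion_terminal",
                     "macro_micro_fusion_centric", "macro_macro_fusion"):
            if len(parts) < 2:
                raise ConfigurationError(f"{etype}: needs >= 2 participants")
            mode = ev.get("mode", "tandem")
            segs: list[Segment] = []
            junctions = []
            for p in parts:
                part_segs = take(p)
                if segs:
                    junctions.append(_derived_length(segs))
                segs.extend(part_segs)
            name = "+".join(parts)
            working[name] = segs
            if etype == "macro_micro_fusion_centric" or mode == "centric":
                centromeres[name] = junctions[0]
                entry["mode"] = "centric"
            else:
                entry["mode"] = ev.get("mode", "tandem"
                                       if etype == "micro_micro_fusion" else "terminal")
            entry["derived"] = [name]
        elif etype == "fission":
            (p,) = parts
            bp = int(ev["breakpoint"])
            segs = take(p)
            total = _derived_length(segs)
            if not 0 < bp < total:
                raise ConfigurationError(
                    f"fission breakpoint {bp} outside (0, {total}) for {p}"
                )
            left: list[Segment] = []
            right: list[Segment] = []
            pos = 0
            for s in segs:
                L = s.derived_length
                if pos + L <= bp:
                    left.append(s)
                elif pos >= bp:
                    right.append(s)
                else:
                    cut_derived = bp - pos
                    cut_anc = int(round(cut_derived / s.expansion))
                    if s.orientation == "+":
                        left.append(replace(s, end=s.start + cut_anc))
                        right.append(replace(s, start=s.start + cut_anc))
                    else:
                        left.append(replace(s, start=s.end - cut_anc))
                        right.append(replace(s, end=s.end - cut_anc))
                pos += L
            n1, n2 = f"{p}.1", f"{p}.2"
            working[n1] = left
            working[n2] = right
            entry["breakpoint"] = bp
            entry["derived"] = [n1, n2]
        elif etype == "expansion":
            factor = float(ev["factor"])
            if factor <= 0:
                raise ConfigurationError("expansion factor must be > 0")
            targets = parts or list(working)
            for p in targets:
                if p not in working:
                    raise ConfigurationError(f"unknown chromosome {p!r}")
                working[p] = [
                    replace(s, expansion=s.expansion * factor) for s in working[p]
                ]
            entry["factor"] = factor
            entry["derived"] = list(targets)
        else:
            raise ConfigurationError(f"unknown event type {etype!r}")
        log.append(entry)

    chroms = []
    for name, segs in working.items():
        length = _derived_length(segs)
        gc = _weighted_gc(segs, karyotype)
        chroms.append(ChromosomeRecord(name, length, gc=gc))
    derived = Karyotype(
        species=derived_species,
        chromosomes=tuple(chroms),
        micro_threshold=karyotype.micro_threshold,
        expected_n=len(chroms),
    )
    derived = classify_chromosomes(derived)
    return SimulatedHistory(
        ancestral=karyotype,
        derived=derived,
        events=tuple(log),
        structure={k: tuple(v) for k, v in working.items()},
        centromeres=centromeres,
        seed=seed,
    )


DEFAULT_EVENT_WEIGHTS = {
    "micro_micro_fusion": 0.5,
    "macro_micro_fusion_terminal": 0.3,
    "fission": 0.2,
}


def random_events(
    karyotype: Karyotype,
    n_events: int = 10,
    weights: Mapping[str, float] | None = None,
    seed: int = 0,
    min_fragment: int = 6_000_000,
) -> list[dict]:
    """Draw a random event list; each chromosome participates at most once.

    Fission breakpoints are placed so that a terminal fragment in the
    microchromosome size range splits off (the observed route to new
    micros) while the residue stays above the macro threshold.
    """
    rng = np.random.default_rng(seed)
    weights = dict(weights or DEFAULT_EVENT_WEIGHTS)
    thr = karyotype.micro_threshold
    free_micro = [c.name for c in karyotype.micros()]
    free_macro = [
        c.name for c in karyotype.macros()
        if c.length >= thr + min_fragment  # fissionable
    ]
    rng.shuffle(free_micro)
    rng.shuffle(free_macro)
    events: list[dict] = []
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()
    def feasible(t: str) -> bool:
        if t == "micro_micro_fusion":
            return len(free_micro) >= 2
        if t == "macro_micro_fusion_terminal":
            return bool(free_micro and free_macro)
        if t == "macro_macro_fusion":
            return len(free_macro) >= 2
        if t == "fission":
            return bool(free_macro)
        return False

    for _ in range(n_events):
        primary = types[int(rng.choice(len(types), p=probs))]
        chosen = next(
            (t for t in [primary] + [u for u in types if u != primary] if feasible(t)),
            None,
        )
        if chosen is None:
            break
        if chosen == "micro_micro_fusion":
            a, b = free_micro.pop(), free_micro.pop()
            events.append({"type": chosen, "participants": [a, b],
                           "mode": "tandem"})
        elif chosen == "macro_micro_fusion_terminal":
            mac, mic = free_macro.pop(), free_micro.pop()
            first = bool(rng.integers(2))
            parts = [mic, mac] if first else [mac, mic]
            events.append({"type": chosen, "participants": parts,
                           "mode": "terminal"})
        elif chosen == "macro_macro_fusion":
            a, b = free_macro.pop(), free_macro.pop()
            events.append({"type": chosen, "participants": [a, b]})
        else:  # fission of a terminal fragment into a new micro
            mac = free_macro.pop()
            L = karyotype[mac].length
            hi = min(thr - 1, L - thr)
            frag = int(rng.integers(min_fragment, max(hi, min_fragment) + 1))
            bp = frag if rng.integers(2) else L - frag
            events.append({"type": "fission", "participants": [mac],
                           "breakpoint": int(bp)})
    return events


# ---------------------------------------------------------------------------
# Chain emission


def emit_chains(
    history: SimulatedHistory,
    frag_rate: float = 0.2,
    gap_frac: float = 0.02,
    seed: int = 0,
) -> list[AlignmentChain]:
    """Chains between ancestor (query) and derived (target) genomes.

    Each conserved segment is split by Poisson-placed breaks
    (``frag_rate`` expected breaks per Mb) with small unaligned gaps
    totalling at most ``gap_frac`` of the segment, emulating alignment
    fragmentation.  Expanded segments receive target-side gaps so derived
    coordinates stay consistent with derived chromosome lengths.  Scores
    equal aligned bp; chain ids are sequential.
    """
    if frag_rate < 0 or not 0 <= gap_frac < 1:
        raise ConfigurationError("bad noise parameters")
    rng = np.random.default_rng(seed)
    anc_len = history.ancestral.lengths()
    der_len = history.derived.lengths()
    chains: list[AlignmentChain] = []
    cid = 1
    for dname in history.derived.names:
        t0 = 0
        for seg in history.segments_of(dname):
            L = seg.ancestral_length
            tlen = seg.derived_length

            def tmap(x: int) -> int:
                # derived coordinate of segment-relative ancestor offset x
                return t0 + int(round(x * seg.expansion))

            n_breaks = rng.poisson(frag_rate * L / 1e6) if frag_rate > 0 else 0
            pieces: list[tuple[int, int]] = []
            if n_breaks == 0:
                pieces.append((0, L))
            else:
                breaks = np.sort(rng.integers(1, L, size=n_breaks))
                total_gap = int(gap_frac * L * rng.uniform(0.5, 1.0))
                gaps = rng.multinomial(total_gap, np.ones(n_breaks) / n_breaks)
                cur = 0
                for b, g in zip(breaks, gaps):
                    if b <= cur:
                        continue
                    pieces.append((cur, int(b)))
                    cur = min(int(b) + int(g), L)
                if cur < L:
                    pieces.append((cur, L))
            for s, e in pieces:
                if e - s < 1:
                    continue
                ts, te = tmap(s), tmap(e)
                dt = (te - ts) - (e - s)
                if dt > 0:
                    h1 = (e - s) // 2
                    h2 = (e - s) - h1
                    if h1 == 0:
                        blocks = ((h2, 0, 0),)
                        te = ts + h2
                        dt = 0
                    else:
                        blocks = ((h1, dt, 0), (h2, 0, 0))
                else:
                    te = ts + (e - s)
                    blocks = ((e - s, 0, 0),)
                if seg.orientation == "+":
                    qs, qe = seg.start + s, seg.start + e
                    strand = "+"
                else:
                    qsize = anc_len[seg.ancestor]
                    qs = (qsize - seg.end) + s
                    qe = (qsize - seg.end) + e
                    strand = "-"
                chain = AlignmentChain(
                    score=float(e - s),
                    target=ChainSide(dname, der_len[dname], "+", ts, te),
                    query=ChainSide(seg.ancestor, anc_len[seg.ancestor],
                                    strand, qs, qe),
                    blocks=blocks,
                    chain_id=cid,
                )
                chains.append(chain)
                cid += 1
            t0 += tlen
    return chains


# ---------------------------------------------------------------------------
# Hi-C simulation


def simulate_hic(
    karyotype: Karyotype,
    alpha_macro: float = 1.5,
    alpha_micro: float = 1.0,
    intra_scale: float = 100.0,
    trans_base: float = 0.1,
    micro_trans_factor: float = 3.0,
    bin_size: int = 50_000,
    seed: int = 0,
) -> ContactMatrix:
    """Poisson contact matrix with power-law cis decay and uniform trans.

    Intra-chromosomal expectation at separation s is
    ``intra_scale * (s / bin_size) ** (-alpha_class)`` (the two class
    curves therefore coincide at s = bin_size and separate beyond it);
    trans expectation is ``trans_base`` scaled per micro participant:
    micro–micro pairs get the full ``micro_trans_factor`` k, mixed
    macro–micro pairs get sqrt(k) — each microchromosome individually
    engages in elevated trans contact, so mixed pairs sit strictly
    between the pure classes.  Counts are independent Poisson draws; the
    output is symmetric.
    """
    if alpha_macro <= 0 or alpha_micro <= 0:
        raise ConfigurationError("decay exponents must be > 0")
    if micro_trans_factor < 1:
        raise ConfigurationError("micro_trans_factor must be >= 1")
    lengths = karyotype.lengths()
    if min(lengths.values()) < bin_size:
        raise ConfigurationError("bin_size larger than the smallest chromosome")
    classes = karyotype.classes()
    rng = np.random.default_rng(seed)
    bins = _bin_table(lengths, bin_size)
    offsets: dict[str, int] = {}
    nbins: dict[str, int] = {}
    pos = 0
    for scaf in lengths:
        n = int(np.ceil(lengths[scaf] / bin_size))
        offsets[scaf] = pos
        nbins[scaf] = n
        pos += n
    N = pos
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    vv: list[np.ndarray] = []

    def add(i_arr, j_arr):
        if len(i_arr) == 0:
            return
        key = i_arr.astype(np.int64) * N + j_arr.astype(np.int64)
        uniq, cnt = np.unique(key, return_counts=True)
        ii.append((uniq // N).astype(np.int64))
        jj.append((uniq % N).astype(np.int64))
        vv.append(cnt.astype(float))

    scafs = list(lengths)
    for scaf in scafs:
        n = nbins[scaf]
        if n < 2:
            continue
        alpha = alpha_micro if classes[scaf] == MICRO else alpha_macro
        d = np.arange(1, n)
        mu = intra_scale * d.astype(float) ** (-alpha)
        totals = rng.poisson((n - d) * mu)
        for dk, tot in zip(d, totals):
            if tot == 0:
                continue
            p = rng.integers(0, n - dk, size=int(tot))
            add(offsets[scaf] + p, offsets[scaf] + p + dk)
    for a_idx, a in enumerate(scafs):
        for b in scafs[a_idx + 1:]:
            n_micro_side = (classes[a] == MICRO) + (classes[b] == MICRO)
            mu = trans_base * micro_trans_factor ** (n_micro_side / 2)
            tot = rng.poisson(nbins[a] * nbins[b] * mu)
            if tot == 0:
                continue
            pa = rng.integers(0, nbins[a], size=int(tot))
            pb = rng.integers(0, nbins[b], size=int(tot))
            add(offsets[a] + pa, offsets[b] + pb)
    if ii:
        i_all = np.concatenate(ii)
        j_all = np.concatenate(jj)
        v_all = np.concatenate(vv)
    else:
        i_all = j_all = np.array([], dtype=np.int64)
        v_all = np.array([], dtype=float)
    m = sp.coo_matrix((v_all, (i_all, j_all)), shape=(N, N)).tocsr()
    sym = m + m.T
    sym.setdiag(sym.diagonal() - m.diagonal())
    sym.eliminate_zeros()
    return ContactMatrix(bin_size=bin_size, bins=bins, counts=sym.tocsr())


# ---------------------------------------------------------------------------
# Recovery scoring


_CALL_EVENT_KEYS = {
    "micro_micro_fusion": "micro_micro_fusion",
    "macro_micro_fusion_terminal": "macro_micro_fusion_terminal",
    "macro_micro_fusion_centric": "macro_micro_fusion_centric",
    "macro_macro_fusion": "macro_macro_fusion",
    "fission_new_micro": "fission",
    "fission_new_macro": "fission",
}


def _truth_keys(history: SimulatedHistory) -> set[tuple]:
    keys = set()
    for ev in history.events:
        t = ev["type"]
        if t == "expansion":
            continue
        if t == "fission":
            keys.add(("fission", ev["participants"][0]))
        else:
            keys.add((t, frozenset(ev["participants"])))
    return keys


def _predicted_keys(calls) -> set[tuple]:
    keys = set()
    for c in calls:
        mapped = _CALL_EVENT_KEYS.get(c.event)
        if mapped is None:
            continue
        if mapped == "fission":
            # both fission products trace to the same ancestor macro
            keys.add(("fission", c.ancestors[0].query_chrom))
        else:
            keys.add((mapped, frozenset(a.query_chrom for a in c.ancestors)))
    return keys


def score_event_recovery(history: SimulatedHistory, calls) -> tuple[float, float]:
    """Exact-type recall and precision of called events against the log.

    Events are keyed by (type, ancestor participants); fission is keyed by
    the fissioned macrochromosome alone, so the two products of one
    fission count as a single prediction.  Expansion events are not
    callable from chains and are excluded from the truth set.
    """
    truth = _truth_keys(history)
    pred = _predicted_keys(calls)
    hit = len(truth & pred)
    recall = hit / len(truth) if truth else 1.0
    precision = hit / len(pred) if pred else (1.0 if not truth else 0.0)
    return recall, precision


def write_ground_truth(history: SimulatedHistory, path) -> None:
    history.to_json(path)
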