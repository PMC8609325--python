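"""Fusion/fission event calling from syntenic-block composition.

Microchromosome loss in reptiles proceeds almost entirely by fusion:
micro–micro fusions, fusions of micros to the termini of macrochromosomes,
and Robertsonian (centric) fusions in which a micro becomes a whole
chromosome arm.  Rarely, fission of a macrochromosome creates a new
chromosome in the micro size range.  Given syntenic blocks between an
ancestor-like query genome and a derived target genome, this module
reconstructs, for each target chromosome, which query chromosomes compose
it and classifies the history as one of those event types.

The decision cascade (per target chromosome):

1. a single same-class ancestor with reciprocal coverage ≥ ``f_intact``
   → conserved;
2. two or more micro ancestors and no macro ancestor → micro–micro fusion;
3. micro plus macro ancestors → macro–micro fusion; with a centromere
   position, a micro constituting a whole arm is *centric*, otherwise a
   micro whose span abuts a chromosome end (within ``d_term``) is
   *terminal* (without centromere data the terminal label covers both,
   since a fused arm also reaches an end);
   two or more macro ancestors only → macro–macro fusion;
4. all ancestry from one query macrochromosome without reciprocal
   coverage → fission (new micro or new macro by the target's class);
5. anything else → unresolved.

A separate four-way map labels each aligned target interval by ancestral
state: macro (macro in both species), micro (micro in both), new_macro
(micro in query but macro in target), new_micro (macro in query but micro
in target).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from microchrom.chain_io import SyntenyBlock
from microchrom.errors import ConfigurationError
from microchrom.karyo import Karyotype, MACRO, MICRO

EVENT_TYPES = (
    "conserved_micro",
    "conserved_macro",
    "micro_micro_fusion",
    "macro_micro_fusion_terminal",
    "macro_micro_fusion_centric",
    "macro_macro_fusion",
    "fission_new_micro",
    "fission_new_macro",
    "unresolved",
)

FOUR_WAY_STATES = ("macro", "micro", "new_macro", "new_micro")


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total, prev_end = 0, None
    for s, e in sorted(intervals):
        if prev_end is None or s >= prev_end:
            total += e - s
            prev_end = e
        elif e > prev_end:
            total += e - prev_end
            prev_end = e
    return total


@dataclass(frozen=True)
class Ancestor:
    """One query chromosome contributing to a target chromosome."""

    query_chrom: str
    chrom_class: str
    aligned_bp: int
    t_start: int
    t_end: int
    query_coverage: float  # fraction of the query chromosome covered


@dataclass(frozen=True)
class Composition:
    target_chrom: str
    target_length: int
    ancestors: tuple[Ancestor, ...]  # ordered by target-side position
    covered_fraction: float  # of the target chromosome


@dataclass(frozen=True)
class RearrangementCall:
    target_chrom: str
    event: str
    ancestors: tuple[Ancestor, ...]
    notes: str = ""

    def __post_init__(self):
        if self.event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event!r}")
        if self.event != "unresolved" and not self.ancestors:
            raise ValueError("non-unresolved call requires ancestors")


def compose(
    target_chrom: str,
    blocks: Sequence[SyntenyBlock],
    query_karyotype: Karyotype,
    target_karyotype: Karyotype,
    min_support: int = 100_000,
) -> Composition:
    """Aggregate blocks landing on one target chromosome by query ancestor.

    Ancestors with total aligned bp below ``min_support`` are dropped;
    survivors are ordered by their position along the target chromosome.
    """
    tlen = target_karyotype[target_chrom].length
    qcls = query_karyotype.classes()
    qlen = query_karyotype.lengths()
    per_q: dict[str, dict] = {}
    t_intervals: list[tuple[int, int]] = []
    for b in blocks:
        if b.t_chrom != target_chrom:
            continue
        if b.q_chrom not in qcls:
            raise KeyError(f"block query chromosome {b.q_chrom!r} not in karyotype")
        d = per_q.setdefault(b.q_chrom, {"bp": 0, "t": [], "q": []})
        d["bp"] += b.aligned_bp
        d["t"].append((b.t_start, b.t_end))
        d["q"].append((b.q_start, b.q_end))
    ancestors = []
    for qc, d in per_q.items():
        if d["bp"] < min_support:
            continue
        t_intervals.extend(d["t"])
        ancestors.append(
            Ancestor(
                query_chrom=qc,
                chrom_class=qcls[qc],
                aligned_bp=d["bp"],
                t_start=min(s for s, _ in d["t"]),
                t_end=max(e for _, e in d["t"]),
                query_coverage=_union_length(d["q"]) / qlen[qc],
            )
        )
    ancestors.sort(key=lambda a: (a.t_start, a.t_end, a.query_chrom))
    return Composition(
        target_chrom=target_chrom,
        target_length=tlen,
        ancestors=tuple(ancestors),
        covered_fraction=_union_length(t_intervals) / tlen,
    )


def default_d_term(target_length: int) -> int:
    """Terminal-zone width: min(5 Mb, 10 % of the chromosome length)."""
    return int(min(5_000_000, 0.10 * target_length))


def _is_terminal(a: Ancestor, length: int, d_term: int) -> bool:
    # the span's outer edge must abut a chromosome end
    return min(a.t_start, length - a.t_end) <= d_term


def _covers_arm(a: Ancestor, centromere: int, length: int, f_intact: float) -> bool:
    span = a.t_end - a.t_start
    for arm_s, arm_e in ((0, centromere), (centromere, length)):
        arm = arm_e - arm_s
        if arm <= 0:
            continue
        ov = min(a.t_end, arm_e) - max(a.t_start, arm_s)
        # the micro must fill the arm and lie (almost) wholly within it
        if ov >= f_intact * arm and ov >= f_intact * span:
            return True
    return False


def call_event(
    composition: Composition,
    target_class: str,
    d_term: int | float | None = None,
    centromere: int | None = None,
    f_intact: float = 0.8,
) -> RearrangementCall:
    """Classify one target chromosome's history (cascade in module docstring).

    ``d_term`` may be bp (int) or a fraction of the target length (float
    < 1); default ``min(5 Mb, 10 %)``.  ``f_intact`` is reciprocal: a
    conserved chromosome must cover, and be covered by, its single
    ancestor at that fraction.
    """
    L = composition.target_length
    if d_term is None:
        d_term_bp = default_d_term(L)
    elif isinstance(d_term, float) and d_term < 1:
        d_term_bp = int(d_term * L)
    else:
        d_term_bp = int(d_term)
    if d_term_bp <= 0:
        raise ConfigurationError("d_term must be > 0")
    if not 0 < f_intact <= 1:
        raise ConfigurationError("f_intact must be in (0, 1]")

    anc = composition.ancestors
    micros = [a for a in anc if a.chrom_class == MICRO]
    macros = [a for a in anc if a.chrom_class == MACRO]

    if not anc:
        return RearrangementCall(composition.target_chrom, "unresolved", (),
                                 notes="no ancestry above min_support")

    # 1. conserved
    if (
        len(anc) == 1
        and anc[0].chrom_class == target_class
        and composition.covered_fraction >= f_intact
        and anc[0].query_coverage >= f_intact
    ):
        ev = "conserved_micro" if target_class == MICRO else "conserved_macro"
        return RearrangementCall(composition.target_chrom, ev, anc)

    # 2. pure micro–micro fusion
    if len(micros) >= 2 and not macros:
        return RearrangementCall(composition.target_chrom, "micro_micro_fusion", anc)

    # 3. fusions involving macro ancestors
    if micros and macros:
        if centromere is not None and any(
            _covers_arm(m, centromere, L, f_intact) for m in micros
        ):
            return RearrangementCall(
                composition.target_chrom, "macro_micro_fusion_centric", anc
            )
        if all(_is_terminal(m, L, d_term_bp) for m in micros):
            note = "" if centromere is not None else (
                "no centromere supplied: terminal label covers centric fusions"
            )
            return RearrangementCall(
                composition.target_chrom, "macro_micro_fusion_terminal", anc,
                notes=note,
            )
        return RearrangementCall(
            composition.target_chrom, "unresolved", anc,
            notes="macro+micro ancestry with interstitial micro placement",
        )
    if len(macros) >= 2 and not micros:
        return RearrangementCall(composition.target_chrom, "macro_macro_fusion", anc)

    # 4. fission: all ancestry from a single query macrochromosome
    if len(anc) == 1 and anc[0].chrom_class == MACRO:
        ev = "fission_new_micro" if target_class == MICRO else "fission_new_macro"
        return RearrangementCall(composition.target_chrom, ev, anc)

    return RearrangementCall(
        composition.target_chrom, "unresolved", anc,
        notes="ancestry pattern outside the event taxonomy",
    )


def call_events(
    blocks: Sequence[SyntenyBlock],
    query_karyotype: Karyotype,
    target_karyotype: Karyotype,
    min_support: int = 100_000,
    d_term: int | float | None = None,
    centromeres: Mapping[str, int] | None = None,
    f_intact: float = 0.8,
) -> list[RearrangementCall]:
    """Compose and classify every chromosome of the target karyotype."""
    centromeres = centromeres or {}
    calls = []
    for c in target_karyotype.chromosomes:
        comp = compose(c.name, blocks, query_karyotype, target_karyotype,
                       min_support=min_support)
        calls.append(
            call_event(
                comp,
                target_class=c.chrom_class,
                d_term=d_term,
                centromere=centromeres.get(c.name),
                f_intact=f_intact,
            )
        )
    return calls


def event_table(calls: Sequence[RearrangementCall]) -> pd.Series:
    """Counts per event type (all types present, zeros included)."""
    counts = Counter(c.event for c in calls)
    return pd.Series({ev: counts.get(ev, 0) for ev in EVENT_TYPES}, name="count")


def calls_to_json(calls: Sequence[RearrangementCall], path) -> None:
    payload = [
        {
            "target_chrom": c.target_chrom,
            "event": c.event,
            "notes": c.notes,
            "ancestors": [
                {
                    "query_chrom": a.query_chrom,
                    "class": a.chrom_class,
                    "aligned_bp": a.aligned_bp,
                    "t_start": a.t_start,
                    "t_end": a.t_end,
                    "query_coverage": round(a.query_coverage, 6),
                }
                for a in c.ancestors
            ],
        }
        for c in calls
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Four-way ancestral-state map


@dataclass(frozen=True)
class RegionClassMap:
    """Non-overlapping target intervals labelled by ancestral state."""

    intervals: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, state)

    def total_by_state(self) -> dict[str, int]:
        out = {s: 0 for s in FOUR_WAY_STATES}
        for _, s, e, state in self.intervals:
            out[state] += e - s
        return out

    @property
    def total_classified(self) -> int:
        return sum(e - s for _, s, e, _ in self.intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, state in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{state}\t0\t+\n")

    def state_at(self, chrom: str, pos: int) -> str | None:
        for c, s, e, state in self.intervals:
            if c == chrom and s <= pos < e:
                return state
        return None


_STATE_FROM_CLASSES = {
    (MACRO, MACRO): "macro",
    (MICRO, MICRO): "micro",
    (MICRO, MACRO): "new_macro",
    (MACRO, MICRO): "new_micro",
}


def classify_regions_four_way(
    blocks: Sequence[SyntenyBlock],
    query_karyotype: Karyotype,
    target_karyotype: Karyotype,
) -> RegionClassMap:
    """Label each aligned target interval by (query class, target class).

    Overlapping blocks are resolved in favour of the higher score, then the
    longer block; the losing block keeps its non-overlapped parts.
    Unaligned target regions are left unlabelled.
    """
    qcls = query_karyotype.classes()
    tcls = target_karyotype.classes()
    order = sorted(
        blocks, key=lambda b: (-b.score, -(b.t_end - b.t_start), b.t_chrom, b.t_start)
    )
    covered: dict[str, list[tuple[int, int]]] = {}
    out: list[tuple[str, int, int, str]] = []
    for b in order:
        state = _STATE_FROM_CLASSES.get((qcls.get(b.q_chrom), tcls.get(b.t_chrom)))
        if state is None:
            raise KeyError(
                f"unclassified chromosome in block {b.q_chrom}->{b.t_chrom}"
            )
        pieces = [(b.t_start, b.t_end)]
        for cs, ce in covered.get(b.t_chrom, []):
            nxt = []
            for s, e in pieces:
                if ce <= s or cs >= e:
                    nxt.append((s, e))
                    continue
                if s < cs:
                    nxt.append((s, cs))
                if ce < e:
                    nxt.append((ce, e))
            pieces = nxt
            if not pieces:
                break
        for s, e in pieces:
            out.append((b.t_chrom, s, e, state))
        covered.setdefault(b.t_chrom, []).extend(pieces)
    out.sort()
    return RegionClassMap(intervals=tuple(out))
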