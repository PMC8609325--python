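"""Homology summaries over syntenic blocks.

The central statistic is the *micro-fraction*: the length-weighted
proportion of a query species' microchromosome alignment that lands on
microchromosomes of a target species.  Arranged over all ordered species
pairs it forms a query×target heat map whose asymmetry exposes lineages
that fused microchromosomes into macrochromosomes (when such a lineage is
the query, most of its surviving micro alignment still hits ancestral
micros; when it is the target, much of the ancestral micro alignment lands
on its fused macros).

Weighting blocks by aligned length (rather than counting chains) makes the
statistic invariant to alignment fragmentation: splitting a chain in two
leaves every fraction unchanged.  A count mode is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from microchrom.chain_io import SyntenyBlock
from microchrom.errors import UndefinedValueError
from microchrom.karyo import Karyotype, MICRO


@dataclass(frozen=True)
class ProfileRow:
    partner: str
    aligned_bp: int
    n_blocks: int
    focal_spans: tuple[tuple[int, int], ...]
    partner_spans: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class HomologyProfile:
    """Partners of one focal chromosome, sorted by descending aligned bp."""

    chrom: str
    rows: tuple[ProfileRow, ...]

    @property
    def partners(self) -> list[str]:
        return [r.partner for r in self.rows]

    @property
    def total_aligned_bp(self) -> int:
        return sum(r.aligned_bp for r in self.rows)


def homology_profile(
    chrom: str,
    blocks: Sequence[SyntenyBlock],
    min_support: int = 100_000,
    karyotype: Karyotype | None = None,
    side: str = "query",
) -> HomologyProfile:
    """Partner chromosomes of ``chrom`` with at least ``min_support`` aligned bp.

    ``side`` selects whether the focal chromosome is read from the query or
    the target side of the blocks.  Partners below ``min_support`` total
    aligned length are dropped — the operational meaning of "sufficient
    homology".  When a ``karyotype`` is supplied, an unknown focal name
    raises ``KeyError`` instead of silently returning an empty profile.
    """
    if side not in ("query", "target"):
        raise ValueError("side must be 'query' or 'target'")
    if karyotype is not None and chrom not in karyotype:
        raise KeyError(f"unknown chromosome {chrom!r} in {karyotype.species}")
    acc: dict[str, dict] = {}
    for b in blocks:
        if side == "query":
            focal, partner = b.q_chrom, b.t_chrom
            fspan, pspan = (b.q_start, b.q_end), (b.t_start, b.t_end)
        else:
            focal, partner = b.t_chrom, b.q_chrom
            fspan, pspan = (b.t_start, b.t_end), (b.q_start, b.q_end)
        if focal != chrom:
            continue
        d = acc.setdefault(partner, {"bp": 0, "n": 0, "fs": [], "ps": []})
        d["bp"] += b.aligned_bp
        d["n"] += 1
        d["fs"].append(fspan)
        d["ps"].append(pspan)
    rows = [
        ProfileRow(
            partner=p,
            aligned_bp=d["bp"],
            n_blocks=d["n"],
            focal_spans=tuple(sorted(d["fs"])),
            partner_spans=tuple(sorted(d["ps"])),
        )
        for p, d in acc.items()
        if d["bp"] >= min_support
    ]
    rows.sort(key=lambda r: (-r.aligned_bp, r.partner))
    return HomologyProfile(chrom=chrom, rows=tuple(rows))


def micro_fraction(
    blocks: Sequence[SyntenyBlock],
    query_karyotype: Karyotype,
    target_karyotype: Karyotype,
    weight: str = "length",
) -> float:
    """Fraction of query-micro alignment that lands on target micros.

    Length mode (default): each block contributes its aligned bp.  Count
    mode: each block contributes 1.  Blocks whose query chromosome is not a
    microchromosome are ignored.  Raises :class:`UndefinedValueError` when
    no query-micro alignment exists.
    """
    if weight not in ("length", "count"):
        raise ValueError("weight must be 'length' or 'count'")
    qcls = query_karyotype.classes()
    tcls = target_karyotype.classes()
    num = 0.0
    den = 0.0
    for b in blocks:
        if qcls.get(b.q_chrom) != MICRO:
            continue
        w = b.aligned_bp if weight == "length" else 1
        den += w
        if tcls.get(b.t_chrom) == MICRO:
            num += w
    if den == 0:
        raise UndefinedValueError(
            f"no microchromosome alignment from {query_karyotype.species} "
            f"to {target_karyotype.species}"
        )
    return num / den


@dataclass(frozen=True)
class MicroFractionMatrix:
    """Query×target grid of micro-to-micro fractions plus per-cell weight.

    ``fractions`` holds NaN for species pairs with no alignment data
    (absent, not zero); the diagonal is 1.0 by convention.  ``weights`` is
    the total query-micro aligned bp entering each cell.
    """

    fractions: pd.DataFrame
    weights: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.fractions.index)

    def to_tsv(self, path) -> None:
        self.fractions.to_csv(path, sep="\t", index_label="query\\target")


def micro_fraction_matrix(
    all_pairwise_blocks: Mapping[tuple[str, str], Sequence[SyntenyBlock]],
    karyotypes: Mapping[str, Karyotype],
    weight: str = "length",
) -> MicroFractionMatrix:
    """Micro-fraction for every ordered species pair with alignment data."""
    species = list(karyotypes)
    frac = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    wts = pd.DataFrame(0.0, index=species, columns=species, dtype=float)
    for s in species:
        frac.loc[s, s] = 1.0
    for (q, t), blocks in all_pairwise_blocks.items():
        if q not in karyotypes or t not in karyotypes:
            raise KeyError(f"no karyotype for pair ({q}, {t})")
        qcls = karyotypes[q].classes()
        total = sum(
            b.aligned_bp for b in blocks if qcls.get(b.q_chrom) == MICRO
        )
        wts.loc[q, t] = float(total)
        if total > 0:
            frac.loc[q, t] = micro_fraction(
                blocks, karyotypes[q], karyotypes[t], weight=weight
            )
    return MicroFractionMatrix(fractions=frac, weights=wts)


def resize_for_plot(
    query_karyotype: Karyotype,
    target_karyotype: Karyotype,
    blocks: Sequence[SyntenyBlock],
    query_order: Sequence[str] | None = None,
    target_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale both genomes to [0, 1] and map blocks into the shared axis.

    Chromosome sizes are depicted as a proportion of genome length;
    an explicit order list supports the customary reordering of
    chromosomes to bring homologies together.  Returns ``(chrom_table,
    block_table)``: per-chromosome scaled offsets, and blocks with
    ``q_scaled_start``-style columns.
    """

    def offsets(k: Karyotype, order):
        names = list(order) if order is not None else k.names
        unknown = set(names) - set(k.names)
        if unknown:
            raise KeyError(f"{k.species}: unknown chromosomes in order: {sorted(unknown)}")
        if set(names) != set(k.names):
            raise ValueError(f"{k.species}: order list must name every chromosome")
        total = k.genome_length
        off, pos = {}, 0
        rows = []
        for n in names:
            c = k[n]
            off[n] = pos / total
            rows.append({
                "species": k.species, "chrom": n,
                "offset": pos / total, "scaled_length": c.length / total,
                "chrom_class": c.chrom_class,
            })
            pos += c.length
        return off, {n: k[n].length for n in names}, total, rows

    qoff, qlen, qtotal, qrows = offsets(query_karyotype, query_order)
    toff, tlen, ttotal, trows = offsets(target_karyotype, target_order)
    chrom_table = pd.DataFrame(qrows + trows)
    brows = []
    for b in blocks:
        brows.append({
            "q_chrom": b.q_chrom,
            "q_scaled_start": qoff[b.q_chrom] + b.q_start / qtotal,
            "q_scaled_end": qoff[b.q_chrom] + b.q_end / qtotal,
            "t_chrom": b.t_chrom,
            "t_scaled_start": toff[b.t_chrom] + b.t_start / ttotal,
            "t_scaled_end": toff[b.t_chrom] + b.t_end / ttotal,
            "orientation": b.orientation,
            "aligned_bp": b.aligned_bp,
        })
    block_table = pd.DataFrame(
        brows,
        columns=["q_chrom", "q_scaled_start", "q_scaled_end", "t_chrom",
                 "t_scaled_start", "t_scaled_end", "orientation", "aligned_bp"],
    )
    return chrom_table, block_table
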