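"""UCSC chain files: parsing, filtering, and reduction to syntenic blocks.

A chain is a scored, gapped pairwise alignment between a *target* and a
*query* assembly, written as a header line::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by alignment-block lines ``size dt dq`` (ungapped block length,
gap on target, gap on query) and a final bare ``size``.  Coordinates are
0-based half-open; on the ``-`` strand they refer to the reverse-complemented
sequence.  The target strand is always ``+``.

"Reciprocally best aligned chains" are recovered here by single-level
greedy netting: chains are accepted in descending score order when their
spans do not overlap previously accepted spans on *either* genome.  The
accepted chains are the syntenic blocks all downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from microchrom.errors import ChainParseError, InputFormatError


@dataclass(frozen=True)
class ChainSide:
    """One side (target or query) of a chain header."""

    name: str
    size: int
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end <= self.size):
            raise ValueError(
                f"{self.name}: need 0 <= start < end <= size, "
                f"got {self.start}..{self.end} of {self.size}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def forward_interval(self) -> tuple[int, int]:
        """Start/end on the forward strand regardless of alignment strand."""
        if self.strand == "+":
            return self.start, self.end
        return self.size - self.end, self.size - self.start


@dataclass(frozen=True)
class AlignmentChain:
    score: float
    target: ChainSide
    query: ChainSide
    blocks: tuple[tuple[int, int, int], ...]  # (size, dt, dq); last has dt=dq=0
    chain_id: int

    def __post_init__(self):
        sizes = sum(b[0] for b in self.blocks)
        dt = sum(b[1] for b in self.blocks)
        dq = sum(b[2] for b in self.blocks)
        if sizes + dt != self.target.span:
            raise ValueError(
                f"chain {self.chain_id}: block sizes + target gaps "
                f"({sizes}+{dt}) != target span ({self.target.span})"
            )
        if sizes + dq != self.query.span:
            raise ValueError(
                f"chain {self.chain_id}: block sizes + query gaps "
                f"({sizes}+{dq}) != query span ({self.query.span})"
            )

    @property
    def aligned_bp(self) -> int:
        return sum(b[0] for b in self.blocks)


@dataclass(frozen=True)
class SyntenyBlock:
    """A reciprocal-best chain treated as a unit of conserved homology.

    Intervals are forward-strand, 0-based half-open on both genomes.
    """

    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    orientation: str  # "same" | "inverted"
    aligned_bp: int
    score: float

    def __post_init__(self):
        if self.aligned_bp <= 0:
            raise ValueError("aligned_bp must be > 0")
        if self.aligned_bp > min(self.q_end - self.q_start, self.t_end - self.t_start):
            raise ValueError("aligned_bp exceeds interval span")
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")


# ---------------------------------------------------------------------------
# Parsing / writing


def read_chain(path) -> list[AlignmentChain]:
    """Parse a UCSC chain file; raises :class:`ChainParseError` with the line."""
    chains: list[AlignmentChain] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[tuple[int, int, int]] = []

    def finish(lineno: int):
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ChainParseError("chain does not end with a bare block size", lineno)
        try:
            chain = AlignmentChain(
                score=float(header[1]),
                target=ChainSide(header[2], int(header[3]), header[4],
                                 int(header[5]), int(header[6])),
                query=ChainSide(header[7], int(header[8]), header[9],
                                int(header[10]), int(header[11])),
                blocks=tuple(blocks),
                chain_id=int(header[12]),
            )
        except ValueError as exc:
            raise ChainParseError(str(exc), header_line) from exc
        chains.append(chain)
        header, blocks = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "chain":
                finish(lineno)
                if len(fields) != 13:
                    raise ChainParseError(
                        f"chain header has {len(fields)} fields, expected 13", lineno
                    )
                header, header_line = fields, lineno
            else:
                if header is None:
                    raise ChainParseError("alignment block outside a chain", lineno)
                try:
                    nums = [int(x) for x in fields]
                except ValueError:
                    raise ChainParseError(f"non-integer block line {line!r}", lineno)
                if len(nums) == 3:
                    blocks.append((nums[0], nums[1], nums[2]))
                elif len(nums) == 1:
                    blocks.append((nums[0], 0, 0))
                else:
                    raise ChainParseError(
                        f"block line has {len(nums)} fields, expected 1 or 3", lineno
                    )
        finish(lineno)
    return chains


def write_chain(chains: Iterable[AlignmentChain], path) -> None:
    """Write chains in the canonical UCSC dialect (round-trips byte-exactly)."""
    with open(path, "w") as fh:
        for c in chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            t, q = c.target, c.query
            fh.write(
                f"chain {score} {t.name} {t.size} {t.strand} {t.start} {t.end} "
                f"{q.name} {q.size} {q.strand} {q.start} {q.end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


def filter_chains(
    chains: Sequence[AlignmentChain], min_len: int
) -> list[AlignmentChain]:
    """Keep chains with ``aligned_bp >= min_len`` (order preserved).

    The published filters are 100 kb for vertebrate pairs and 5 kb for
    comparisons against amphioxus.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [c for c in chains if c.aligned_bp >= min_len]


#: Chain-length filters by pair class (bp).
MIN_LEN_VERTEBRATE = 100_000
MIN_LEN_AMPHIOXUS = 5_000


# ---------------------------------------------------------------------------
# Netting


def chain_to_block(chain: AlignmentChain) -> SyntenyBlock:
    qs, qe = chain.query.forward_interval()
    return SyntenyBlock(
        q_chrom=chain.query.name,
        q_start=qs,
        q_end=qe,
        t_chrom=chain.target.name,
        t_start=chain.target.start,
        t_end=chain.target.end,
        orientation="same" if chain.query.strand == chain.target.strand else "inverted",
        aligned_bp=chain.aligned_bp,
        score=chain.score,
    )


def chains_to_blocks(chains: Iterable[AlignmentChain]) -> list[SyntenyBlock]:
    """Convert chains directly to blocks (no overlap resolution)."""
    return [chain_to_block(c) for c in chains]


def _check_consistent_sizes(chains: Sequence[AlignmentChain]) -> None:
    sizes: dict[tuple[str, str], int] = {}
    for c in chains:
        for side, tag in ((c.target, "target"), (c.query, "query")):
            key = (tag, side.name)
            if sizes.setdefault(key, side.size) != side.size:
                raise InputFormatError(
                    f"inconsistent {tag} size for {side.name}: "
                    f"{sizes[key]} vs {side.size}"
                )


def _max_overlap(start: int, end: int, accepted: list[tuple[int, int]]) -> int:
    best = 0
    for s, e in accepted:
        ov = min(end, e) - max(start, s)
        if ov > best:
            best = ov
    return best


def reciprocal_best(
    chains: Sequence[AlignmentChain],
    overlap_tol: int = 0,
    min_len: int = 0,
) -> list[SyntenyBlock]:
    """Single-level greedy net: highest-scoring mutually non-overlapping chains.

    Chains are processed in descending score (ties broken by ascending
    chain id) and accepted when their forward-strand span overlaps every
    previously accepted span by at most ``overlap_tol`` bp on both the
    query and the target genome.  Accepted chains become
    :class:`SyntenyBlock` records, emitted in acceptance order.
    """
    if overlap_tol < 0:
        raise ValueError("overlap_tol must be >= 0")
    _check_consistent_sizes(chains)
    pool = filter_chains(chains, min_len) if min_len else list(chains)
    order = sorted(pool, key=lambda c: (-c.score, c.chain_id))
    taken_q: dict[str, list[tuple[int, int]]] = {}
    taken_t: dict[str, list[tuple[int, int]]] = {}
    out: list[SyntenyBlock] = []
    for c in order:
        qs, qe = c.query.forward_interval()
        ts, te = c.target.start, c.target.end
        if _max_overlap(qs, qe, taken_q.get(c.query.name, [])) > overlap_tol:
            continue
        if _max_overlap(ts, te, taken_t.get(c.target.name, [])) > overlap_tol:
            continue
        taken_q.setdefault(c.query.name, []).append((qs, qe))
        taken_t.setdefault(c.target.name, []).append((ts, te))
        out.append(chain_to_block(c))
    return out


def invert_blocks(blocks: Iterable[SyntenyBlock]) -> list[SyntenyBlock]:
    """Swap query and target sides (view the same homology from the other genome)."""
    return [
        SyntenyBlock(
            q_chrom=b.t_chrom, q_start=b.t_start, q_end=b.t_end,
            t_chrom=b.q_chrom, t_start=b.q_start, t_end=b.q_end,
            orientation=b.orientation, aligned_bp=b.aligned_bp, score=b.score,
        )
        for b in blocks
    ]


def blocks_to_bed(blocks: Iterable[SyntenyBlock], path, side: str = "target") -> None:
    """Export block intervals on one genome as BED4 (partner in the name column)."""
    if side not in ("target", "query"):
        raise ValueError("side must be 'target' or 'query'")
    with open(path, "w") as fh:
        for b in blocks:
            if side == "target":
                fh.write(f"{b.t_chrom}\t{b.t_start}\t{b.t_end}\t{b.q_chrom}\n")
            else:
                fh.write(f"{b.q_chrom}\t{b.q_start}\t{b.q_end}\t{b.t_chrom}\n")
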