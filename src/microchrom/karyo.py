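"""Chromosome metadata: macro/micro classification, GC content, gene density.

Bird and reptile karyotypes are bimodal: a handful of large macrochromosomes
and many tiny, GC-rich, gene-dense microchromosomes.  The boundary between
the two classes is a clade-specific size threshold (35 Mb in birds and
snakes; larger in turtles, rearranged lizards, tegu and alligator, up to
96 Mb).  A chromosome is a microchromosome iff its length is strictly below
the clade threshold; an explicit class label taken from published karyotype
data overrides the size rule.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from microchrom.errors import ConfigurationError, InputFormatError, UndefinedValueError

MACRO = "macro"
MICRO = "micro"
UNASSIGNED = "unassigned"

#: Clade-specific micro/macro size thresholds (bp): the size of the largest
#: microchromosome in each clade.  Birds and snakes share the 35-Mb boundary.
CLADE_THRESHOLDS = {
    "bird": 35_000_000,
    "snake": 35_000_000,
    "turtle": 45_000_000,
    "rearranged_lizard": 50_000_000,
    "tegu": 75_000_000,
    "alligator": 96_000_000,
}


@dataclass(frozen=True)
class ChromosomeRecord:
    """One assembled chromosome (or chromosome-scale scaffold)."""

    name: str
    length: int
    gc: float | None = None
    n_genes: int | None = None
    chrom_class: str = UNASSIGNED

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"chromosome {self.name}: gc must be in [0,1]")
        if self.n_genes is not None and self.n_genes < 0:
            raise ValueError(f"chromosome {self.name}: n_genes must be >= 0")
        if self.chrom_class not in (MACRO, MICRO, UNASSIGNED):
            raise ValueError(f"unknown chromosome class {self.chrom_class!r}")


@dataclass(frozen=True)
class Karyotype:
    """A species' chromosome complement plus its clade micro-size threshold.

    Parameters
    ----------
    species:
        Species identifier.
    chromosomes:
        Ordered chromosome records; names must be unique.
    micro_threshold:
        Clade-specific boundary in bp; chromosomes strictly below it are
        microchromosomes.  May be ``None`` only when every chromosome
        carries an explicit class label.
    expected_n:
        Haploid chromosome number from cytology; used to pick the largest
        Hi-C scaffolds.  Defaults to the number of records.
    """

    species: str
    chromosomes: tuple[ChromosomeRecord, ...]
    micro_threshold: int | None = None
    expected_n: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.species}: duplicate chromosome names")
        if self.micro_threshold is not None and self.micro_threshold <= 0:
            raise ValueError("micro_threshold must be > 0")
        if self.expected_n is None:
            object.__setattr__(self, "expected_n", len(self.chromosomes))
        if self.expected_n < 1 and self.chromosomes:
            raise ValueError("expected_n must be >= 1")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def classes(self) -> dict[str, str]:
        return {c.name: c.chrom_class for c in self.chromosomes}

    def class_of(self, name: str) -> str:
        return self[name].chrom_class

    def micros(self) -> list[ChromosomeRecord]:
        return [c for c in self.chromosomes if c.chrom_class == MICRO]

    def macros(self) -> list[ChromosomeRecord]:
        return [c for c in self.chromosomes if c.chrom_class == MACRO]

    @property
    def genome_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def classify_chromosomes(
    karyotype: Karyotype,
    explicit: Mapping[str, str] | None = None,
    boundary_is_macro: bool = True,
) -> Karyotype:
    """Label every chromosome macro or micro.

    The size rule is ``micro iff length < micro_threshold``; a chromosome
    exactly at the threshold is a macrochromosome (strict inequality,
    flip with ``boundary_is_macro=False``).  Explicit labels — either
    already present on the records or supplied via ``explicit`` — win over
    the size rule, mirroring assignments "based on published karyotype
    data" when assembly sizes are ambiguous.
    """
    explicit = dict(explicit or {})
    needs_rule = [
        c for c in karyotype.chromosomes
        if c.name not in explicit and c.chrom_class == UNASSIGNED
    ]
    if needs_rule and karyotype.micro_threshold is None:
        raise ConfigurationError(
            f"{karyotype.species}: no micro_threshold and no explicit class "
            f"labels for {needs_rule[0].name} (and possibly others)"
        )
    thr = karyotype.micro_threshold
    out = []
    for c in karyotype.chromosomes:
        if c.name in explicit:
            label = explicit[c.name]
            if label not in (MACRO, MICRO):
                raise ConfigurationError(f"bad explicit class {label!r} for {c.name}")
        elif c.chrom_class != UNASSIGNED:
            label = c.chrom_class
        elif boundary_is_macro:
            label = MICRO if c.length < thr else MACRO
        else:
            label = MICRO if c.length <= thr else MACRO
        out.append(replace(c, chrom_class=label))
    return replace(karyotype, chromosomes=tuple(out))


_GC_BASES = frozenset("GCgc")
_UNAMBIGUOUS = frozenset("ACGTacgt")


def gc_content(sequence: str) -> float:
    """G+C fraction of a nucleotide sequence.

    Case-insensitive (soft-masked lowercase counts normally); N and IUPAC
    ambiguity codes are excluded from both numerator and denominator.
    Raises :class:`UndefinedValueError` when no unambiguous base remains.
    """
    seq = str(sequence)
    denom = sum(1 for b in seq if b in _UNAMBIGUOUS)
    if denom == 0:
        raise UndefinedValueError("sequence has no unambiguous A/C/G/T bases")
    gc = sum(1 for b in seq if b in _GC_BASES)
    return gc / denom


def gene_density(n_genes: int, length: int) -> float:
    """Genes per megabase: ``n_genes / (length / 1e6)``."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    return n_genes / (length / 1e6)


def gc_vs_size_table(karyotype: Karyotype) -> pd.DataFrame:
    """Per-chromosome (name, length, gc, class) table, largest first.

    The GC-versus-size scatter is the standard visual of the macro/micro
    GC contrast (microchromosomes are GC-rich).
    """
    rows = [
        {"name": c.name, "length": c.length, "gc": c.gc, "chrom_class": c.chrom_class}
        for c in karyotype.chromosomes
    ]
    df = pd.DataFrame(rows, columns=["name", "length", "gc", "chrom_class"])
    if not df.empty:
        df = df.sort_values("length", ascending=False, kind="mergesort")
        df = df.reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# I/O


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def fasta_gc(path) -> dict[str, float]:
    """GC content per record of a (possibly gzipped) multi-FASTA."""
    with _open_text(path) as fh:
        return {rec.id: gc_content(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}


def attach_gc(karyotype: Karyotype, gc_by_name: Mapping[str, float]) -> Karyotype:
    """Return a karyotype with GC values filled in from a name→gc map."""
    chroms = tuple(
        replace(c, gc=float(gc_by_name[c.name])) if c.name in gc_by_name else c
        for c in karyotype.chromosomes
    )
    return replace(karyotype, chromosomes=chroms)


def read_karyotype_table(
    path,
    micro_threshold: int | None = None,
    expected_n: int | None = None,
) -> Karyotype:
    """Read a tab-separated karyotype table.

    Required columns: ``species``, ``chrom``, ``length``.  Optional:
    ``class`` (macro/micro), ``n_genes``, ``gc``.  Metadata comment lines
    ``#micro_threshold=<bp>`` and ``#expected_n=<int>`` are honoured;
    function arguments override them.
    """
    meta: dict[str, int] = {}
    with _open_text(path) as fh:
        lines = fh.readlines()
    for ln in lines:
        if ln.startswith("#") and "=" in ln:
            key, _, val = ln[1:].strip().partition("=")
            if key in ("micro_threshold", "expected_n"):
                meta[key] = int(val)
    body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    if not body:
        raise InputFormatError(f"{path}: empty karyotype table")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    required = {"species", "chrom", "length"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: karyotype table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    species = df["species"].iloc[0]
    chroms = []
    for _, row in df.iterrows():
        cls = row.get("class", UNASSIGNED)
        if pd.isna(cls):
            cls = UNASSIGNED
        ng = row.get("n_genes")
        gc = row.get("gc")
        chroms.append(
            ChromosomeRecord(
                name=str(row["chrom"]),
                length=int(row["length"]),
                gc=None if gc is None or pd.isna(gc) else float(gc),
                n_genes=None if ng is None or pd.isna(ng) else int(ng),
                chrom_class=str(cls),
            )
        )
    return Karyotype(
        species=str(species),
        chromosomes=tuple(chroms),
        micro_threshold=micro_threshold or meta.get("micro_threshold"),
        expected_n=expected_n or meta.get("expected_n"),
    )


def write_karyotype_table(karyotype: Karyotype, path) -> None:
    """Write the tab-separated karyotype table (round-trips with the reader)."""
    with open(path, "w") as fh:
        if karyotype.micro_threshold is not None:
            fh.write(f"#micro_threshold={karyotype.micro_threshold}\n")
        if karyotype.expected_n is not None:
            fh.write(f"#expected_n={karyotype.expected_n}\n")
        fh.write("species\tchrom\tlength\tclass\tn_genes\tgc\n")
        for c in karyotype.chromosomes:
            ng = "" if c.n_genes is None else c.n_genes
            gc = "" if c.gc is None else f"{c.gc:.6f}"
            fh.write(
                f"{karyotype.species}\t{c.name}\t{c.length}\t{c.chrom_class}\t{ng}\t{gc}\n"
            )
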