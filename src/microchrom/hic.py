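"""Binned Hi-C contact matrices and class-resolved contact statistics.

Inputs are 7-column GInteractions text at a fixed bin size (50 kb by
default): origin scaffold, origin start, origin end, target scaffold,
target start, target end, interaction count.  Matrices are assumed to be
pre-normalized exports; no balancing is applied here.

Two statistics mirror the standard comparative analysis of micro- versus
macrochromosome chromatin:

* the inter-scaffold heat map — mean interaction value between every pair
  of the N largest scaffolds (N = expected chromosome number), which
  exposes the elevated trans contacts among microchromosomes;
* the distance-dependent contact probability P(s) — mean contact intensity
  per bin pair as a function of genomic separation s, computed separately
  per chromosome class (and plotted to a maximum distance of 1e8 bp).
  Microchromosomes show a shallower decay (higher P at large s),
  reflecting their greater compaction and interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from microchrom.errors import InputFormatError, UndefinedValueError
from microchrom.karyo import Karyotype

DEFAULT_BIN_SIZE = 50_000
DEFAULT_MAX_DIST = 100_000_000  # 1e8 bp plotting limit
DEFAULT_N_DIST_BINS = 30


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix over one or more scaffolds.

    ``bins`` rows are ordered by scaffold (insertion order) then start;
    ``counts`` is a symmetric sparse matrix over those bins.
    """

    bin_size: int
    bins: pd.DataFrame  # columns: scaffold, start, end
    counts: sp.csr_matrix

    def __post_init__(self):
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin table")
        if (self.counts.data < 0).any():
            raise ValueError("negative contact values")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.bins["scaffold"]))

    def scaffold_lengths(self) -> dict[str, int]:
        return self.bins.groupby("scaffold", sort=False)["end"].max().to_dict()

    def bin_indices(self, scaffold: str) -> np.ndarray:
        return np.flatnonzero((self.bins["scaffold"] == scaffold).to_numpy())

    def restrict(self, idx: np.ndarray) -> "ContactMatrix":
        """Sub-matrix over the given bin indices (order preserved)."""
        sub = self.counts[idx][:, idx].tocsr()
        bins = self.bins.iloc[idx].reset_index(drop=True)
        return ContactMatrix(bin_size=self.bin_size, bins=bins, counts=sub)

    @property
    def total(self) -> float:
        return float(sp.triu(self.counts).sum())


def _bin_table(scaffold_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for scaf, length in scaffold_lengths.items():
        for start in range(0, length, bin_size):
            rows.append((scaf, start, min(start + bin_size, length)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def _symmetrize(m: sp.spmatrix) -> sp.csr_matrix:
    sym = (m + m.T).tolil()
    sym.setdiag(sym.diagonal() - m.diagonal())
    sym = sym.tocsr()
    sym.eliminate_zeros()
    return sym


def build_matrix(
    scaffold_lengths: Mapping[str, int],
    entries: Iterable[tuple[str, int, str, int, float]],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> ContactMatrix:
    """Assemble a symmetric matrix from (scaf1, start1, scaf2, start2, value).

    Duplicate and transposed entries are merged by summation.
    """
    bins = _bin_table(scaffold_lengths, bin_size)
    index: dict[tuple[str, int], int] = {
        (r.scaffold, r.start): i for i, r in enumerate(bins.itertuples())
    }
    ii, jj, vv = [], [], []
    for s1, p1, s2, p2, v in entries:
        try:
            i, j = index[(s1, p1)], index[(s2, p2)]
        except KeyError as exc:
            raise InputFormatError(f"coordinate outside scaffold bins: {exc}") from exc
        ii.append(i)
        jj.append(j)
        vv.append(v)
    n = len(bins)
    m = sp.coo_matrix((vv, (ii, jj)), shape=(n, n)).tocsr()
    return ContactMatrix(bin_size=bin_size, bins=bins, counts=_symmetrize(m))


def read_ginteractions(
    path,
    bin_size: int = DEFAULT_BIN_SIZE,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> ContactMatrix:
    """Read a 7-column GInteractions file into a symmetric matrix.

    Lines with the same unordered bin pair are merged by sum.  Scaffold
    lengths default to the largest end coordinate seen per scaffold (tail
    bins may be shorter than ``bin_size``).
    """
    # validate the 7-column contract line-by-line (cheap), then parse in bulk
    kept: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 6 and len(line.split()) != 7:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 7 columns, "
                    f"got {len(line.split())}"
                )
            kept.append(line)
    if not kept:
        return build_matrix(dict(scaffold_lengths or {}), [], bin_size=bin_size)
    from io import StringIO

    df = pd.read_csv(
        StringIO("\n".join(kept)), sep=r"\s+", header=None,
        names=["s1", "a1", "e1", "s2", "a2", "e2", "v"],
        dtype={"s1": str, "s2": str},
    )
    if (df["v"] < 0).any():
        bad = df.index[df["v"] < 0][0]
        raise InputFormatError(f"{path}: negative count on data line {bad + 1}")
    for side in ("1", "2"):
        a, e = df[f"a{side}"], df[f"e{side}"]
        ok = (a % bin_size == 0) & (e - a <= bin_size) & (e > a)
        if not ok.all():
            bad = df.index[~ok][0]
            raise InputFormatError(
                f"{path}: interval on data line {bad + 1} does not fit the "
                f"{bin_size}-bp binning"
            )
    if scaffold_lengths:
        lengths = dict(scaffold_lengths)
    else:
        ends = pd.concat([
            df.groupby("s1")["e1"].max(), df.groupby("s2")["e2"].max()
        ])
        lengths = ends.groupby(level=0).max().to_dict()
    bins = _bin_table(lengths, bin_size)
    offsets: dict[str, int] = {}
    pos = 0
    for scaf, length in lengths.items():
        offsets[scaf] = pos
        pos += -(-length // bin_size)
    try:
        i = (df["s1"].map(offsets) + df["a1"] // bin_size).to_numpy()
        j = (df["s2"].map(offsets) + df["a2"] // bin_size).to_numpy()
    except TypeError:
        raise InputFormatError(f"{path}: scaffold not present in supplied lengths")
    if np.isnan(i).any() or np.isnan(j).any():
        raise InputFormatError(f"{path}: scaffold not present in supplied lengths")
    n = pos
    m = sp.coo_matrix(
        (df["v"].to_numpy(float), (i.astype(np.int64), j.astype(np.int64))),
        shape=(n, n),
    ).tocsr()
    return ContactMatrix(bin_size=bin_size, bins=bins, counts=_symmetrize(m))


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_ginteractions(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle as canonical 7-column GInteractions TSV."""
    bins = matrix.bins
    coo = sp.triu(matrix.counts).tocoo()
    order = np.lexsort((coo.col, coo.row))
    row, col, data = coo.row[order], coo.col[order], coo.data[order]
    scaf = bins["scaffold"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    out = pd.DataFrame({
        "s1": scaf[row], "a1": start[row], "e1": end[row],
        "s2": scaf[col], "a2": start[col], "e2": end[col],
        "v": [_fmt_value(v) for v in data],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def select_top_scaffolds(matrix: ContactMatrix, karyotype: Karyotype) -> ContactMatrix:
    """Restrict to the ``expected_n`` largest scaffolds (ties by name)."""
    lengths = matrix.scaffold_lengths()
    n = karyotype.expected_n
    if n > len(lengths):
        raise ValueError(
            f"expected_n={n} but the matrix has only {len(lengths)} scaffolds"
        )
    keep = sorted(lengths, key=lambda s: (-lengths[s], s))[:n]
    keep_set = set(keep)
    order = {s: k for k, s in enumerate(keep)}
    mask = matrix.bins["scaffold"].isin(keep_set).to_numpy()
    idx = np.flatnonzero(mask)
    # reorder largest -> smallest
    idx = idx[np.argsort([order[s] for s in matrix.bins["scaffold"].iloc[idx]],
                         kind="stable")]
    return matrix.restrict(idx)


def interaction_heatmap(matrix: ContactMatrix) -> pd.DataFrame:
    """Scaffold×scaffold table of mean interaction per bin pair.

    Cell (A, B) is the mean of the symmetric matrix over all ordered bin
    pairs a∈A, b∈B (absent pairs count as zero); scaffolds are ordered
    largest to smallest.
    """
    lengths = matrix.scaffold_lengths()
    scafs = sorted(lengths, key=lambda s: (-lengths[s], s))
    table = pd.DataFrame(0.0, index=scafs, columns=scafs)
    idx = {s: matrix.bin_indices(s) for s in scafs}
    for a in scafs:
        for b in scafs:
            block = matrix.counts[idx[a]][:, idx[b]]
            table.loc[a, b] = block.sum() / (len(idx[a]) * len(idx[b]))
    return table


@dataclass(frozen=True)
class PsCurve:
    """Distance-dependent contact probability for one chromosome class."""

    label: str
    edges: np.ndarray  # distance-bin edges, bp (len = n_bins + 1)
    p: np.ndarray  # mean counts per valid bin pair, per distance bin
    n_pairs: np.ndarray  # valid bin pairs per distance bin
    total_counts: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def as_probability(self) -> "PsCurve":
        """Unit-sum normalization of the curve."""
        s = self.p.sum()
        if s == 0:
            raise UndefinedValueError(f"P(s) for {self.label} is identically zero")
        return replace(self, p=self.p / s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.label,
            "s_lo": self.edges[:-1].astype(int),
            "s_hi": self.edges[1:].astype(int),
            "s_mid": self.midpoints,
            "p": self.p,
            "n_pairs": self.n_pairs,
        })


def distance_bin_edges(
    bin_size: int,
    max_dist: int = DEFAULT_MAX_DIST,
    n_dist_bins: int = DEFAULT_N_DIST_BINS,
    spacing: str = "log",
) -> np.ndarray:
    if spacing == "log":
        return np.geomspace(bin_size, max_dist, n_dist_bins + 1)
    if spacing == "linear":
        return np.linspace(bin_size, max_dist, n_dist_bins + 1)
    raise ValueError("spacing must be 'log' or 'linear'")


def _scaffold_ps_arrays(
    matrix: ContactMatrix, scaffold: str
) -> tuple[np.ndarray, np.ndarray]:
    """(pairs_at_sep, counts_at_sep) indexed by separation in bins (0..n-1)."""
    idx = matrix.bin_indices(scaffold)
    n = len(idx)
    starts = matrix.bins["start"].iloc[idx].to_numpy() // matrix.bin_size
    span = int(starts.max()) + 1
    ind = np.zeros(span)
    ind[starts] = 1.0
    full = np.correlate(ind, ind, mode="full")
    pairs = np.rint(full[span:]).astype(np.int64)  # separations 1..span-1
    pairs = np.concatenate(([0], pairs))
    counts = np.zeros(span)
    sub = sp.triu(matrix.counts[idx][:, idx], k=1).tocoo()
    if sub.nnz:
        seps = starts[sub.col] - starts[sub.row]
        np.add.at(counts, seps, sub.data)
    return pairs, counts


def ps_curve(
    matrix: ContactMatrix,
    classes: Mapping[str, str] | Karyotype | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    n_dist_bins: int = DEFAULT_N_DIST_BINS,
    spacing: str = "log",
    mode: str = "mean",
) -> dict[str, PsCurve]:
    """P(s) per chromosome class from intra-scaffold contacts.

    For each logarithmic distance bin, P is the summed contact count over
    all intra-scaffold bin pairs at separations in the bin, divided by the
    number of such pairs (zero-count pairs included in the denominator).
    ``classes`` maps scaffold → class label (a classified
    :class:`~microchrom.karyo.Karyotype` also works); ``None`` pools every
    scaffold under the label ``"all"``.  ``mode="probability"`` rescales
    each curve to unit sum.
    """
    if isinstance(classes, Karyotype):
        classes = classes.classes()
    if classes is None:
        classes = {s: "all" for s in matrix.scaffolds}
    if mode not in ("mean", "probability"):
        raise ValueError("mode must be 'mean' or 'probability'")
    edges = distance_bin_edges(matrix.bin_size, max_dist, n_dist_bins, spacing)
    labels = sorted(set(classes.get(s) for s in matrix.scaffolds) - {None})
    curves: dict[str, PsCurve] = {}
    for label in labels:
        scafs = [s for s in matrix.scaffolds if classes.get(s) == label]
        tot_pairs = np.zeros(n_dist_bins, dtype=np.int64)
        tot_counts = np.zeros(n_dist_bins)
        usable = False
        for s in scafs:
            pairs, counts = _scaffold_ps_arrays(matrix, s)
            if len(pairs) < 2:
                continue
            usable = usable or pairs[1:].sum() > 0
            seps_bp = np.arange(len(pairs)) * matrix.bin_size
            which = np.digitize(seps_bp, edges) - 1
            ok = (which >= 0) & (which < n_dist_bins) & (seps_bp > 0)
            np.add.at(tot_pairs, which[ok], pairs[ok])
            np.add.at(tot_counts, which[ok], counts[ok])
        if not usable:
            raise UndefinedValueError(
                f"class {label!r}: no scaffold has two or more bins"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot_pairs > 0, tot_counts / np.maximum(tot_pairs, 1), np.nan)
        curve = PsCurve(label=label, edges=edges, p=p, n_pairs=tot_pairs,
                        total_counts=tot_counts)
        curves[label] = curve.as_probability() if mode == "probability" else curve
    return curves


def fit_decay_exponent(
    curve: PsCurve,
    s_min: float | None = None,
    s_max: float | None = None,
) -> float:
    """Power-law decay exponent α from a log-log linear fit (P ∝ s^−α)."""
    s = curve.midpoints
    p = curve.p
    ok = np.isfinite(p) & (p > 0) & (curve.n_pairs > 0)
    if s_min is not None:
        ok &= s >= s_min
    if s_max is not None:
        ok &= s <= s_max
    if ok.sum() < 2:
        raise UndefinedValueError("not enough positive P(s) points to fit")
    slope = np.polyfit(np.log(s[ok]), np.log(p[ok]), 1)[0]
    return float(-slope)


def partition_matrix_by_state(
    matrix: ContactMatrix, region_map
) -> dict[str, ContactMatrix]:
    """Split bins by ancestral-state region map; one sub-matrix per state.

    A bin takes the state covering the majority of it; on a tie the state
    of the earlier (left-most) interval wins.  Unclassified bins are
    dropped.  Counts between bins of the same state are preserved.
    """
    states = list(dict.fromkeys(st for _, _, _, st in region_map.intervals))
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, st in region_map.intervals:
        per_chrom.setdefault(chrom, []).append((s, e, st))
    assign: list[str | None] = []
    for row in matrix.bins.itertuples():
        best_state, best_ov = None, 0
        for s, e, st in per_chrom.get(row.scaffold, []):
            ov = min(row.end, e) - max(row.start, s)
            if ov > best_ov:  # strict: earlier interval wins ties
                best_state, best_ov = st, ov
        assign.append(best_state)
    assign_arr = np.array([a if a is not None else "" for a in assign])
    out: dict[str, ContactMatrix] = {}
    for st in states:
        idx = np.flatnonzero(assign_arr == st)
        if len(idx):
            out[st] = matrix.restrict(idx)
    return out


def mean_trans_by_class(
    matrix: ContactMatrix, classes: Mapping[str, str] | Karyotype
) -> pd.DataFrame:
    """Mean trans (inter-scaffold) contact per bin pair, by class pair.

    Rows/columns are class labels; cell (x, y) averages the heat-map cells
    of scaffold pairs with classes {x, y} (A ≠ B scaffold pairs only).
    """
    if isinstance(classes, Karyotype):
        classes = classes.classes()
    lengths = matrix.scaffold_lengths()
    scafs = list(lengths)
    labels = sorted(set(classes[s] for s in scafs))
    sums = {(a, b): 0.0 for a in labels for b in labels}
    npairs = {(a, b): 0 for a in labels for b in labels}
    idx = {s: matrix.bin_indices(s) for s in scafs}
    for i, a in enumerate(scafs):
        for b in scafs[i + 1:]:
            la, lb = classes[a], classes[b]
            block = matrix.counts[idx[a]][:, idx[b]]
            mean = block.sum() / (len(idx[a]) * len(idx[b]))
            for key in {(la, lb), (lb, la)}:
                sums[key] += mean
                npairs[key] += 1
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (a, b), s in sums.items():
        if npairs[(a, b)]:
            table.loc[a, b] = s / npairs[(a, b)]
    return table
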