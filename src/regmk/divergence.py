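"""Polarized X/Y divergence from three-way alignments.

Substitutions on a sex chromosome pair are assigned to the X or the Y
branch by comparing both gametolog sequences to an outgroup sequence that
stands in for the ancestral (pre-sex-chromosome) state: a column where X
differs from the outgroup while Y matches it is an X-specific
substitution, and vice versa.  Columns where X and Y agree with each
other but differ from the outgroup are fixed between species and predate
the sex chromosomes, so they are excluded from both branch rates; columns
with three distinct states are ambiguous and also excluded.  Columns with
a gap or N in any sequence are removed from the rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import Stratum

# Per-column classification codes.
INVARIANT = 0
X_SPECIFIC = 1
Y_SPECIFIC = 2
SPECIES_FIXED = 3
AMBIGUOUS = 4
EXCLUDED = 5

_VALID = frozenset(b"ACGT")


@dataclass
class AlignedTriplet:
    """One region as aligned X, Y and outgroup sequences of equal length.

    ``flank`` columns at each end are alignment anchors (the sequence
    extraction pads each region); they are excluded from rate denominators
    unless ``include_flanks`` is passed to :func:`polarize_sites`.
    """

    region_id: str
    x: str
    y: str
    outgroup: str
    stratum: Stratum = Stratum.NA
    flank: int = 0
    coords: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.outgroup)):
            raise ValueError(
                f"region {self.region_id}: aligned sequences differ in length "
                f"({len(self.x)}, {len(self.y)}, {len(self.outgroup)})"
            )
        if self.flank < 0 or 2 * self.flank >= len(self.x):
            if self.flank != 0:
                raise ValueError(f"region {self.region_id}: flank too large")


@dataclass
class PolarizedCounts:
    region_id: str
    n_x_specific: int
    n_y_specific: int
    n_species_fixed: int
    n_ambiguous: int
    n_invariant: int
    n_excluded: int
    aligned_length: int  # assayable columns (no gap/N in any sequence)
    stratum: Stratum = Stratum.NA

    @property
    def d_x(self) -> float:
        return self.n_x_specific / self.aligned_length if self.aligned_length else float("nan")

    @property
    def d_y(self) -> float:
        return self.n_y_specific / self.aligned_length if self.aligned_length else float("nan")

    @property
    def total_columns(self) -> int:
        return (
            self.n_x_specific
            + self.n_y_specific
            + self.n_species_fixed
            + self.n_ambiguous
            + self.n_invariant
            + self.n_excluded
        )


def _as_bytes(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def polarize_columns(
    x: str | np.ndarray, y: str | np.ndarray, outgroup: str | np.ndarray
) -> np.ndarray:
    """Classify every alignment column; returns an array of column codes."""
    xb, yb, ob = _as_bytes(x), _as_bytes(y), _as_bytes(outgroup)
    if not (xb.size == yb.size == ob.size):
        raise ValueError("aligned sequences differ in length")
    valid = np.isin(xb, list(_VALID)) & np.isin(yb, list(_VALID)) & np.isin(ob, list(_VALID))
    codes = np.full(xb.size, EXCLUDED, dtype=np.uint8)
    xo = xb == ob
    yo = yb == ob
    xy = xb == yb
    codes[valid & xo & yo] = INVARIANT
    codes[valid & ~xo & yo] = X_SPECIFIC
    codes[valid & xo & ~yo] = Y_SPECIFIC
    codes[valid & ~xo & ~yo & xy] = SPECIES_FIXED
    codes[valid & ~xo & ~yo & ~xy] = AMBIGUOUS
    return codes


def polarize_sites(triplet: AlignedTriplet, include_flanks: bool = False) -> PolarizedCounts:
    """Polarize all columns of a triplet and tally per-branch substitution counts.

    The rate denominator ``aligned_length`` counts only columns assayable in
    all three sequences (no gap, no N), within the core region unless
    ``include_flanks`` is set.
    """
    codes = polarize_columns(triplet.x, triplet.y, triplet.outgroup)
    if triplet.flank and not include_flanks:
        codes = codes[triplet.flank : len(codes) - triplet.flank]
    counts = np.bincount(codes, minlength=6)
    return PolarizedCounts(
        region_id=triplet.region_id,
        n_x_specific=int(counts[X_SPECIFIC]),
        n_y_specific=int(counts[Y_SPECIFIC]),
        n_species_fixed=int(counts[SPECIES_FIXED]),
        n_ambiguous=int(counts[AMBIGUOUS]),
        n_invariant=int(counts[INVARIANT]),
        n_excluded=int(counts[EXCLUDED]),
        aligned_length=int(codes.size - counts[EXCLUDED]),
        stratum=triplet.stratum,
    )


def pairwise_divergence(query: str | np.ndarray, target: str | np.ndarray) -> float:
    """Substitutions per assayable aligned column between two sequences.

    Columns with a gap or N in either sequence are excluded from both the
    numerator and the denominator.  Returns NaN when no column is assayable.
    """
    qb, tb = _as_bytes(query), _as_bytes(target)
    if qb.size != tb.size:
        raise ValueError("aligned sequences differ in length")
    valid = np.isin(qb, list(_VALID)) & np.isin(tb, list(_VALID))
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan")
    return int((qb[valid] != tb[valid]).sum()) / n_valid


# ---------------------------------------------------------------------------
# Homology-hit filtering (BLAST-style tabular hits)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    chrom: str
    start: int
    end: int
    bit_score: float
    percent_identity: float
    alignment_length: int
    query_length: int


def filter_homology_hits(
    hits: Sequence[HomologyHit],
    require_unique: bool = True,
    min_bit_score: float = 100.0,
    min_length_frac: float | None = 0.75,
) -> list[HomologyHit]:
    """Keep high-confidence single-copy homology hits.

    A hit survives iff it is the sole hit for its query (when
    ``require_unique``), its bit score exceeds ``min_bit_score`` (strict),
    and, when ``min_length_frac`` is set, its alignment covers at least that
    fraction of the query length.
    """
    n_hits: dict[str, int] = {}
    for hit in hits:
        n_hits[hit.query_id] = n_hits.get(hit.query_id, 0) + 1
    kept = []
    for hit in hits:
        if require_unique and n_hits[hit.query_id] > 1:
            continue
        if hit.bit_score <= min_bit_score:
            continue
        if min_length_frac is not None and hit.alignment_length < min_length_frac * hit.query_length:
            continue
        kept.append(hit)
    return kept


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column BLAST outfmt-6 style table plus a query-length column.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [qlen].  Subject coordinates are converted to
    0-based half-open.
    """
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns")
            sstart, send = int(f[8]), int(f[9])
            lo, hi = min(sstart, send), max(sstart, send)
            qlen = int(f[12]) if len(f) > 12 else abs(int(f[7]) - int(f[6])) + 1
            hits.append(
                HomologyHit(
                    query_id=f[0],
                    chrom=f[1],
                    start=lo - 1,
                    end=hi,
                    bit_score=float(f[11]),
                    percent_identity=float(f[2]),
                    alignment_length=int(f[3]),
                    query_length=qlen,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Triplet multi-FASTA I/O


def read_triplet_fasta(
    path: str | Path, stratum: Stratum = Stratum.NA, flank: int = 0
) -> AlignedTriplet:
    """Read one aligned triplet from a multi-FASTA with ids ``X|..``, ``Y|..``,
    ``OUT|..``."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    region_id = Path(path).stem
    for record in SeqIO.parse(str(path), "fasta"):
        role = record.id.split("|", 1)[0].upper()
        seqs[role] = str(record.seq).upper()
        if "|" in record.id:
            region_id = record.id.split("|", 1)[1]
    missing = {"X", "Y", "OUT"} - set(seqs)
    if missing:
        raise ValueError(f"{path}: missing sequences for roles {sorted(missing)}")
    return AlignedTriplet(
        region_id=region_id, x=seqs["X"], y=seqs["Y"], outgroup=seqs["OUT"],
        stratum=stratum, flank=flank,
    )


def write_triplet_fasta(triplet: AlignedTriplet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for role, seq in (("X", triplet.x), ("Y", triplet.y), ("OUT", triplet.outgroup)):
            handle.write(f">{role}|{triplet.region_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# Class comparison: Kruskal-Wallis omnibus + Dunn's post hoc with Bonferroni


@dataclass
class ClassComparison:
    statistic: float
    pvalue: float
    pairwise: "dict[tuple[str, str], tuple[float, float]]"  # (z, adjusted p)
    letters: dict[str, str]
    excluded: list[str]


def _dunn_pairwise(values_by_class: Mapping[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's test: normal approximation on mean rank differences with tie
    correction; p-values Bonferroni-adjusted over all pairs."""
    names = list(values_by_class)
    pooled = np.concatenate([values_by_class[c] for c in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    offset = 0
    for name in names:
        size = values_by_class[name].size
        mean_ranks[name] = float(ranks[offset : offset + size].mean())
        sizes[name] = size
        offset += size
    n_pairs = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in combinations(names, 2):
        se = np.sqrt((n_total * (n_total + 1) / 12 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2 * stats.norm.sf(abs(z)) * n_pairs)
        out[(a, b)] = (float(z), float(p))
    return out


def _compact_letters(
    names: Sequence[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different from each other.
    """
    groups: list[set[str]] = [set(names)]
    for a, b in significant:
        next_groups: list[set[str]] = []
        for grp in groups:
            if a in grp and b in grp:
                next_groups.append(grp - {a})
                next_groups.append(grp - {b})
            else:
                next_groups.append(grp)
        # absorb subsets
        groups = []
        for grp in sorted(next_groups, key=len, reverse=True):
            if grp and not any(grp <= other for other in groups):
                groups.append(grp)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {name: [] for name in names}
    for letter, grp in zip(alphabet, groups):
        for name in grp:
            letters[name].append(letter)
    return {name: "".join(sorted(ls)) or "-" for name, ls in letters.items()}


def compare_divergence_classes(
    values_by_class: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ClassComparison:
    """Kruskal-Wallis omnibus over site classes, Dunn's pairwise post hoc
    with Bonferroni adjustment, and compact-letter groupings.

    Classes with fewer than 2 observations are excluded with a warning entry.
    """
    import warnings

    arrays: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, values in values_by_class.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            excluded.append(name)
            warnings.warn(f"class {name!r} has < 2 observations; excluded")
        else:
            arrays[name] = arr
    if len(arrays) < 2:
        raise ValueError("need at least 2 classes with >= 2 observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        # all values identical: no evidence of any difference
        stat, pval = 0.0, 1.0
        pairwise = {
            (a, b): (0.0, 1.0) for a, b in combinations(arrays, 2)
        }
    else:
        stat, pval = stats.kruskal(*arrays.values())
        pairwise = _dunn_pairwise(arrays)
    significant = {pair for pair, (_, p) in pairwise.items() if p < alpha}
    letters = _compact_letters(list(arrays), significant)
    return ClassComparison(
        statistic=float(stat), pvalue=float(pval), pairwise=pairwise,
        letters=letters, excluded=excluded,
    )
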