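"""McDonald-Kreitman tests for noncoding and coding sequence.

The MK test compares divergence (D, fixed differences against a reference
lineage) to polymorphism (P, sites segregating within a population)
between a putatively selected class of sites and a neutral reference
class.  For noncoding tests the focal class is ACR sequence and the
neutral class is GC-matched intergenic sequence; for coding tests the
focal class is nonsynonymous sites and the neutral class synonymous
sites.  The neutrality index NI = (P_focal/P_neutral)/(D_focal/D_neutral)
is the odds ratio of the 2x2 table; alpha = 1 - NI estimates the fraction
of focal-class divergence fixed by positive selection.  NI < 1 indicates
an excess of focal divergence between lineages (positive selection),
NI > 1 an excess of focal polymorphism (purifying selection or
segregating deleterious variants).

For gene-level tables where zero counts are common, NI_Haldane is the
natural log of the odds ratio after adding 0.5 to each cell, which is
finite for every count pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq


def neutrality_index(
    d_focal: float, d_neutral: float, p_focal: float, p_neutral: float
) -> tuple[float, float]:
    """Neutrality index and alpha from pooled 2x2 MK counts.

    NI = (P_focal/P_neutral) / (D_focal/D_neutral); alpha = 1 - NI.
    Negative alpha is reported as-is (adaptive fixation rate near zero).
    Raises ``ZeroDivisionError`` when any required denominator is zero;
    use :func:`ni_haldane` for sparse gene-level tables.
    """
    if d_neutral == 0 or p_neutral == 0 or d_focal == 0:
        raise ZeroDivisionError(
            "NI undefined with a zero denominator count; use ni_haldane for "
            "zero-count-safe gene-level tables"
        )
    ni = (p_focal / p_neutral) / (d_focal / d_neutral)
    return ni, 1.0 - ni


def mk_chi_square(
    d_focal: float, d_neutral: float, p_focal: float, p_neutral: float,
    correction: str = "none",
) -> tuple[float, float]:
    """Chi-square test of independence on the 2x2 MK table.

    Rows are (D_focal, D_neutral) and (P_focal, P_neutral).  With
    ``correction="none"`` this is the Pearson statistic
    N(ad - bc)^2 / (row x column products); ``"yates"`` applies the
    continuity correction N(|ad - bc| - N/2)^2 / (...).  Both variants are
    provided because published tables mix them.  Returns (statistic,
    df = 1 p-value).
    """
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    a, b, c, d = d_focal, d_neutral, p_focal, p_neutral
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    num = abs(a * d - b * c)
    if correction == "yates":
        num = max(num - n / 2, 0.0)
    statistic = n * num * num / margins
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass
class MKTable:
    """Pooled MK table with derived statistics (both chi-square variants)."""

    d_focal: int
    d_neutral: int
    p_focal: int
    p_neutral: int
    label: str = ""

    ni: float = field(init=False)
    alpha: float = field(init=False)
    chi2: float = field(init=False)
    chi2_p: float = field(init=False)
    chi2_yates: float = field(init=False)
    chi2_yates_p: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.d_focal, self.d_neutral, self.p_focal, self.p_neutral) < 0:
            raise ValueError("MK counts must be non-negative")
        try:
            self.ni, self.alpha = neutrality_index(
                self.d_focal, self.d_neutral, self.p_focal, self.p_neutral
            )
        except ZeroDivisionError:
            self.ni = self.alpha = float("nan")
        try:
            self.chi2, self.chi2_p = mk_chi_square(
                self.d_focal, self.d_neutral, self.p_focal, self.p_neutral, "none"
            )
            self.chi2_yates, self.chi2_yates_p = mk_chi_square(
                self.d_focal, self.d_neutral, self.p_focal, self.p_neutral, "yates"
            )
        except ValueError:
            self.chi2 = self.chi2_p = self.chi2_yates = self.chi2_yates_p = float("nan")


def ni_haldane(dn: float, ds: float, pn: float, ps: float) -> float:
    """Zero-count-safe log neutrality index (natural log).

    Adds 0.5 to each cell of the 2x2 table before taking the log odds
    ratio, so the value is finite for every count pattern, including the
    all-zero table (which gives exactly 0).
    """
    if min(dn, ds, pn, ps) < 0:
        raise ValueError("counts must be non-negative")
    return float(np.log(((pn + 0.5) / (ps + 0.5)) / ((dn + 0.5) / (ds + 0.5))))


class SelectionClass(str, Enum):
    PURIFYING = "purifying"
    POSITIVE = "positive"
    RELAXED = "relaxed"


def classify_gene(ni_h: float, threshold: float = 0.25) -> SelectionClass:
    """Classify a gene from NI_Haldane: > +threshold purifying, < -threshold
    positive, otherwise (boundary included) relaxed purifying selection."""
    if not np.isfinite(ni_h):
        raise ValueError("NI_Haldane must be finite")
    if ni_h > threshold:
        return SelectionClass.PURIFYING
    if ni_h < -threshold:
        return SelectionClass.POSITIVE
    return SelectionClass.RELAXED


@dataclass
class GeneMKResult:
    gene_id: str
    dn: int
    ds: int
    pn: int
    ps: int
    ni_haldane: float = field(init=False)
    selection_class: SelectionClass = field(init=False)

    def __post_init__(self) -> None:
        self.ni_haldane = ni_haldane(self.dn, self.ds, self.pn, self.ps)
        self.selection_class = classify_gene(self.ni_haldane)


# ---------------------------------------------------------------------------
# Pooled noncoding MK from polarized column codes and polymorphic positions


def region_counts(
    regions: Sequence, codes: np.ndarray, poly_positions: Sequence[int], lineage: str = "Y",
    factor: str = "focal",
) -> pd.DataFrame:
    """Per-region divergence (lineage-specific substitutions) and
    polymorphism (segregating sites) counts for MK pooling.

    ``codes`` are per-column classifications from
    :func:`regmk.divergence.polarize_columns` over the shared coordinate
    system; ``poly_positions`` are the positions of segregating sites on
    the focal chromosome.
    """
    from . import divergence as _dv

    target = _dv.Y_SPECIFIC if lineage.upper() == "Y" else _dv.X_SPECIFIC
    d_cum = np.concatenate([[0], np.cumsum(codes == target)])
    poly = np.zeros(codes.size, dtype=bool)
    pos = np.asarray(list(poly_positions), dtype=int)
    poly[pos[pos < codes.size]] = True
    p_cum = np.concatenate([[0], np.cumsum(poly)])
    rows = []
    for region in regions:
        rows.append(
            {
                "region_id": region.label or f"{region.start}-{region.end}",
                "factor": factor,
                "D": int(d_cum[region.end] - d_cum[region.start]),
                "P": int(p_cum[region.end] - p_cum[region.start]),
            }
        )
    return pd.DataFrame(rows)


def pooled_noncoding_mk(
    acr_regions: Sequence,
    control_regions: Sequence,
    codes: np.ndarray,
    poly_positions: Sequence[int],
    lineage: str = "Y",
    label: str = "",
) -> tuple[MKTable, pd.DataFrame]:
    """Pooled noncoding MK test: ACRs as the focal factor, matched
    intergenic controls as the neutral factor.

    Returns the pooled :class:`MKTable` and the per-region count records
    (suitable for :func:`bootstrap_mk`).
    """
    focal = region_counts(acr_regions, codes, poly_positions, lineage, "focal")
    neutral = region_counts(control_regions, codes, poly_positions, lineage, "neutral")
    records = pd.concat([focal, neutral], ignore_index=True)
    table = MKTable(
        d_focal=int(focal["D"].sum()),
        d_neutral=int(neutral["D"].sum()),
        p_focal=int(focal["P"].sum()),
        p_neutral=int(neutral["P"].sum()),
        label=label,
    )
    return table, records


# ---------------------------------------------------------------------------
# Codon-context site classification against the outgroup


class SiteCall(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    OMITTED = "omitted"


class OmitReason(str, Enum):
    N_BASE = "N_base"
    CODON_GAP = "codon_gap"
    MISSING_GENOTYPE = "missing_genotype"
    NOT_BIALLELIC = "not_biallelic"
    PREMATURE_STOP = "premature_stop"
    NONE = "none"


@dataclass(frozen=True)
class CodonSiteCall:
    gene_id: str
    codon_index: int
    position_in_codon: int
    alleles: tuple[str, ...]
    call: SiteCall
    kind: str  # "divergence", "polymorphism" or "" for omitted/invariant
    reason_omitted: OmitReason = OmitReason.NONE


@dataclass
class CodingMKCounts:
    gene_id: str
    dn: int
    ds: int
    pn: int
    ps: int
    calls: list[CodonSiteCall]
    premature_stop: bool = False


def _is_synonymous(outgroup_codon: str, pos: int, allele: str) -> bool:
    mutated = outgroup_codon[:pos] + allele + outgroup_codon[pos + 1 :]
    return str(Seq(outgroup_codon).translate()) == str(Seq(mutated).translate())


def classify_coding_sites(
    focal: str,
    outgroup: str,
    pop_alleles: Mapping[int, Sequence[str | None]] | None = None,
    gene_id: str = "",
) -> CodingMKCounts:
    """Classify every variable coding site as synonymous or nonsynonymous
    in the outgroup codon context and pool (DN, DS, PN, PS).

    ``focal`` and ``outgroup`` are aligned coding sequences (same frame,
    length divisible by 3).  ``pop_alleles`` maps alignment positions to
    the alleles observed among population samples at that site (``None``
    marks a missing genotype); positions absent from the map are taken as
    monomorphic for the focal base.

    Site handling: whole codons containing an alignment gap are omitted;
    sites containing an N, a missing genotype, or more than two alleles
    are omitted with the matching reason.  A site monomorphic for an
    allele that differs from the outgroup base counts as divergence; a
    biallelic segregating site counts as polymorphism.  Each counted site
    is classified by substituting the focal allele into the outgroup
    codon and comparing the translated amino acids.  A premature stop
    codon in the outgroup frame flags the gene and omits that codon.
    """
    focal = focal.upper()
    outgroup = outgroup.upper()
    if len(focal) != len(outgroup):
        raise ValueError("focal and outgroup alignments differ in length")
    if len(focal) % 3 != 0:
        raise ValueError("coding alignment length must be divisible by 3")
    pop_alleles = pop_alleles or {}

    dn = ds = pn = ps = 0
    calls: list[CodonSiteCall] = []
    premature_stop = False
    n_codons = len(focal) // 3

    def omit(codon_idx: int, pos: int, alleles: tuple[str, ...], reason: OmitReason) -> None:
        calls.append(
            CodonSiteCall(gene_id, codon_idx, pos, alleles, SiteCall.OMITTED, "", reason)
        )

    for codon_idx in range(n_codons):
        f_codon = focal[3 * codon_idx : 3 * codon_idx + 3]
        o_codon = outgroup[3 * codon_idx : 3 * codon_idx + 3]
        if "-" in f_codon or "-" in o_codon:
            for pos in range(3):
                omit(codon_idx, pos, (), OmitReason.CODON_GAP)
            continue
        if "N" not in o_codon and str(Seq(o_codon).translate()) == "*" and codon_idx < n_codons - 1:
            premature_stop = True
            for pos in range(3):
                omit(codon_idx, pos, (), OmitReason.PREMATURE_STOP)
            continue
        for pos in range(3):
            aln_pos = 3 * codon_idx + pos
            site_alleles = pop_alleles.get(aln_pos)
            if site_alleles is None:
                alleles = (f_codon[pos],)
            else:
                if any(a is None for a in site_alleles):
                    omit(codon_idx, pos, (), OmitReason.MISSING_GENOTYPE)
                    continue
                alleles = tuple(sorted({str(a).upper() for a in site_alleles}))
            if "N" in alleles or f_codon[pos] == "N" or o_codon[pos] == "N":
                omit(codon_idx, pos, alleles, OmitReason.N_BASE)
                continue
            if len(alleles) > 2:
                omit(codon_idx, pos, alleles, OmitReason.NOT_BIALLELIC)
                continue
            derived = [a for a in alleles if a != o_codon[pos]]
            if not derived:
                continue  # invariant site
            syn = all(_is_synonymous(o_codon, pos, a) for a in derived)
            call = SiteCall.SYNONYMOUS if syn else SiteCall.NONSYNONYMOUS
            if len(alleles) == 1:
                kind = "divergence"
                if syn:
                    ds += 1
                else:
                    dn += 1
            else:
                kind = "polymorphism"
                if syn:
                    ps += 1
                else:
                    pn += 1
            calls.append(CodonSiteCall(gene_id, codon_idx, pos, alleles, call, kind))
    return CodingMKCounts(gene_id, dn, ds, pn, ps, calls, premature_stop)


# ---------------------------------------------------------------------------
# Bootstrap over resampling units (regions or genes)


@dataclass
class BootstrapMK:
    ni_mean: float
    ni_sd: float
    ni_low: float   # mean - 2 SD
    ni_high: float  # mean + 2 SD
    alpha_mean: float
    alpha_sd: float
    n_reps: int
    n_dropped: int  # replicates with undefined NI
    unstable: bool  # > 50% of replicates undefined


def bootstrap_mk(
    records: pd.DataFrame, n_reps: int = 10_000, seed: int | np.random.Generator | None = None
) -> BootstrapMK:
    """Bootstrap SD (and mean +/- 2 SD interval) for pooled NI and alpha.

    ``records`` carries one row per resampling unit (ACR/control region,
    or gene) with columns ``factor`` ("focal" or "neutral"), ``D`` and
    ``P``.  Units are resampled with replacement within each factor, the
    counts re-pooled, and NI/alpha recomputed per replicate; replicates
    with an undefined NI (a zero pooled denominator) are dropped and
    counted.  Resampling whole regions preserves within-region correlation
    of the counts.
    """
    import warnings

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    focal = records[records["factor"] == "focal"]
    neutral = records[records["factor"] == "neutral"]
    if len(focal) < 2 or len(neutral) < 2:
        raise ValueError("need >= 2 resampling units per factor")

    def pooled(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        d = sub["D"].to_numpy(dtype=float)
        p = sub["P"].to_numpy(dtype=float)
        idx = rng.integers(0, len(sub), size=(n_reps, len(sub)))
        return d[idx].sum(axis=1), p[idx].sum(axis=1)

    d_f, p_f = pooled(focal)
    d_n, p_n = pooled(neutral)
    valid = (d_f > 0) & (d_n > 0) & (p_n > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ni = np.where(valid, (p_f / np.maximum(p_n, 1)) / (d_f / np.maximum(d_n, 1)), np.nan)
    ni = ni[valid]
    n_dropped = int(n_reps - ni.size)
    unstable = n_dropped > n_reps / 2
    if unstable:
        warnings.warn(
            f"{n_dropped}/{n_reps} bootstrap replicates had undefined NI; "
            "interval flagged unstable"
        )
    if ni.size == 0:
        nan = float("nan")
        return BootstrapMK(nan, nan, nan, nan, nan, nan, n_reps, n_dropped, True)
    ni_mean = float(ni.mean())
    ni_sd = float(ni.std(ddof=1)) if ni.size > 1 else 0.0
    return BootstrapMK(
        ni_mean=ni_mean,
        ni_sd=ni_sd,
        ni_low=ni_mean - 2 * ni_sd,
        ni_high=ni_mean + 2 * ni_sd,
        alpha_mean=1.0 - ni_mean,
        alpha_sd=ni_sd,
        n_reps=n_reps,
        n_dropped=n_dropped,
        unstable=unstable,
    )
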