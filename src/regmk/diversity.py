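"""Nucleotide diversity from population genotypes with hemizygosity-aware
filters.

On the noncrossover regions of the sex chromosomes, males carry a single
copy, so a heterozygous genotype there can only come from misaligned
reads and is discarded.  Read-depth outliers (below half or above double
the per-chromosome median) are likewise discarded as alignment
artifacts.  Per-site pi is the mean pairwise difference among the called
alleles; sites are then averaged within fixed nonoverlapping windows,
and region-to-autosome ratios are compared against the neutral
expectations for hemizygous compartments (Y: 25% of autosomal diversity,
X: 75%, given equal sex ratios).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class RegionClass(str, Enum):
    Y_NONCROSSOVER = "Y_noncrossover"
    X_NONCROSSOVER = "X_noncrossover"
    PAR = "PAR"
    AUTOSOME = "AUTOSOME"


#: hemizygous compartments where heterozygous calls are impossible in males
_HEMIZYGOUS = {RegionClass.Y_NONCROSSOVER, RegionClass.X_NONCROSSOVER}

#: neutral expectation for diversity relative to autosomes
NEUTRAL_EXPECTATION = {"Y": 0.25, "X": 0.75}

#: depth windows (half to double the per-chromosome median read depth)
DEFAULT_DEPTH_BOUNDS: dict[RegionClass, tuple[float, float]] = {
    RegionClass.Y_NONCROSSOVER: (3.5, 14.0),
    RegionClass.X_NONCROSSOVER: (3.5, 14.0),
    RegionClass.PAR: (3.5, 14.0),
    RegionClass.AUTOSOME: (6.5, 26.0),
}


@dataclass(frozen=True)
class SiteGenotypes:
    """One population genotype record.

    ``genotypes`` holds one tuple of allele indices per sample: length-1
    tuples are haploid (hemizygous) calls, length-2 diploid calls, and
    ``None`` a missing genotype.  ``alts`` may list more than one
    alternate allele; such sites are removed by the biallelic filter.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[tuple[int, ...] | None, ...]
    depths: tuple[int, ...]
    region_class: RegionClass

    def allele_counts(self) -> tuple[int, int]:
        """(reference, alternate) allele counts over called samples."""
        c_ref = c_alt = 0
        for gt in self.genotypes:
            if gt is None:
                continue
            for allele in gt:
                if allele == 0:
                    c_ref += 1
                else:
                    c_alt += 1
        return c_ref, c_alt

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.depths)) if self.depths else 0.0


def filter_genotypes(
    sites: Iterable[SiteGenotypes],
    depth_bounds: Mapping[RegionClass, tuple[float, float]] | None = None,
) -> tuple[list[SiteGenotypes], Counter]:
    """Apply the biallelic, hemizygosity and depth filters.

    Filters (order-independent; a site is dropped if any filter fails):
      * not biallelic (more than one alternate allele);
      * any heterozygous call at a site in a hemizygous (noncrossover)
        compartment;
      * mixed ploidy among called genotypes at one site;
      * mean read depth across called samples outside the per-region
        bounds (default: half to double the median depth, i.e. 3.5-14 on
        the sex chromosomes and 6.5-26 on the autosome).

    Returns the kept sites and a tally of dropped sites by reason.
    """
    bounds = dict(DEFAULT_DEPTH_BOUNDS)
    if depth_bounds:
        bounds.update(depth_bounds)
    kept: list[SiteGenotypes] = []
    tallies: Counter = Counter()
    for site in sites:
        if not isinstance(site.region_class, RegionClass):
            raise ValueError(f"unknown region class: {site.region_class!r}")
        reasons = []
        if len(site.alts) != 1:
            reasons.append("not_biallelic")
        called = [gt for gt in site.genotypes if gt is not None]
        ploidies = {len(gt) for gt in called}
        if len(ploidies) > 1:
            reasons.append("mixed_ploidy")
        if site.region_class in _HEMIZYGOUS and any(
            len(gt) > 1 and len(set(gt)) > 1 for gt in called
        ):
            reasons.append("heterozygous_hemizygous")
        lo, hi = bounds[site.region_class]
        if not (lo <= site.mean_depth <= hi):
            reasons.append("depth")
        if reasons:
            for reason in reasons:
                tallies[reason] += 1
        else:
            kept.append(site)
    return kept, tallies


def per_site_pi(c_ref: int, c_alt: int) -> float:
    """Per-site nucleotide diversity: mean pairwise difference.

    With c_ref + c_alt = n called alleles, pi = c_ref * c_alt / C(n, 2).
    Raises ``ValueError`` for n < 2 (the site is not assayable).
    """
    n = c_ref + c_alt
    if n < 2:
        raise ValueError("per-site pi requires at least 2 called alleles")
    return c_ref * c_alt / comb(n, 2)


def windowed_pi(
    sites: Sequence[SiteGenotypes],
    chrom_length: int,
    window: int = 10_000,
    denominator: str = "sites",
) -> pd.DataFrame:
    """Average per-site pi within fixed nonoverlapping windows.

    Windows tile [0, chrom_length).  With ``denominator="sites"`` the
    window value is the mean of per-site pi over retained variant sites
    in the window (pi per segregating site); with ``"length"`` the summed
    site pi is divided by the window's bp span, giving pi per bp --
    invariant sites contribute zero, which is the scale on which
    chromosome-level diversity and region/autosome ratios are quoted.
    Windows with no retained site are flagged empty; under the "sites"
    denominator their pi is NaN and they are excluded from summaries,
    under "length" their pi is 0.
    """
    if denominator not in ("sites", "length"):
        raise ValueError("denominator must be 'sites' or 'length'")
    n_windows = (chrom_length + window - 1) // window
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=int)
    for site in sites:
        if not 0 <= site.pos < chrom_length:
            raise ValueError(f"site position {site.pos} outside [0, {chrom_length})")
        c_ref, c_alt = site.allele_counts()
        if c_ref + c_alt < 2:
            continue
        idx = site.pos // window
        sums[idx] += per_site_pi(c_ref, c_alt)
        counts[idx] += 1
    starts = np.arange(n_windows) * window
    ends = np.minimum(starts + window, chrom_length)
    if denominator == "sites":
        with np.errstate(invalid="ignore"):
            pi = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        pi = sums / (ends - starts)
    return pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "n_sites": counts,
            "pi": pi,
            "empty": counts == 0,
        }
    )


def chromosome_pi(windows: pd.DataFrame, include_empty: bool = False) -> float:
    """Chromosome summary: mean of window pi over nonempty windows.

    With ``include_empty`` set, empty windows contribute pi = 0 instead of
    being excluded.
    """
    if include_empty:
        return float(windows["pi"].fillna(0.0).mean())
    nonempty = windows.loc[~windows["empty"], "pi"]
    return float(nonempty.mean()) if len(nonempty) else float("nan")


def diversity_ratio(
    pi_region: float, pi_autosome: float, expectation: str | float = "Y"
) -> tuple[float, float]:
    """Region/autosome diversity ratio and its deviation from the neutral
    expectation (Y: 0.25, X: 0.75, or any numeric expectation)."""
    if pi_autosome <= 0:
        raise ValueError("autosomal pi must be positive")
    expected = NEUTRAL_EXPECTATION[expectation] if isinstance(expectation, str) else expectation
    ratio = pi_region / pi_autosome
    return ratio, ratio - expected


def read_vcf_sites(
    path: str | Path,
    region_classes: Mapping[str, RegionClass],
) -> list[SiteGenotypes]:
    """Read SiteGenotypes from a VCF with GT and DP FORMAT fields.

    ``region_classes`` maps chromosome name to its region class.  Haploid
    GT entries become length-1 tuples, diploid length-2; missing calls
    become ``None``.
    """
    from cyvcf2 import VCF

    sites: list[SiteGenotypes] = []
    vcf = VCF(str(path))
    for variant in vcf:
        if variant.CHROM not in region_classes:
            raise KeyError(f"no region class for chromosome {variant.CHROM}")
        genotypes = []
        for gt in variant.genotypes:  # [allele1, allele2, phased] or [allele, phased]
            alleles = tuple(a for a in gt[:-1] if a != -1)
            genotypes.append(alleles if alleles else None)
        depths = variant.format("DP")
        depths = tuple(int(d) for d in np.ravel(depths)) if depths is not None else ()
        sites.append(
            SiteGenotypes(
                chrom=variant.CHROM,
                pos=variant.POS - 1,
                ref=variant.REF,
                alts=tuple(variant.ALT),
                genotypes=tuple(genotypes),
                depths=depths,
                region_class=region_classes[variant.CHROM],
            )
        )
    return sites
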