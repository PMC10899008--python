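"""Synthetic sex-chromosome data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised and checked
against bookkept truth without any sequencing data:

* an ancestral sequence drawn with a smoothly varying (piecewise-linear
  per kb) GC field, which doubles as the outgroup;
* X and Y copies derived by independent per-site substitution at
  stratum-specific rates (three evolutionary strata of decreasing age),
  multiplied inside ACR intervals by per-chromosome factors -- an
  elevated Y-side multiplier phenomenologically emulates positive
  selection on Y-linked regulatory sequence;
* population polymorphism at per-site rates theta, hemizygous in all
  males over the noncrossover regions, with read depths drawn around a
  configurable median so the depth filters bite;
* per-gametolog expression whose log2(X/Y) ratio tracks the (bookkept)
  Y ACR divergence of the assigned gene with a configurable slope, with
  replicate counts drawn from a negative binomial.

Alignments are substitution-only (no indels), so the truth table of
injected lineage-specific substitutions is exact and the polarization
stage can be verified to the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import RegionClass, SiteGenotypes
from .divergence import AlignedTriplet
from .expression_assoc import ExpressionRecord
from .genome_io import AnnotationSet, Gene, GenomicInterval, Stratum, assign_acr_to_gene

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate(b"ACGT")}


@dataclass
class SimParams:
    """Study conditions for one synthetic cohort.

    Defaults follow the structure of the system under study: three
    evolutionary strata with distinct X-Y divergence (oldest stratum
    most diverged), Y substitution rates elevated inside ACRs, strongly
    reduced Y polymorphism (pi roughly 0.0001 against 0.0043 on the
    autosome and 0.0019 on X), 12 hemizygous males, and 3 RNA replicates
    per allele.
    """

    seed: int = 0
    chrom_length: int = 300_000
    auto_length: int = 120_000
    # per-stratum substitution rates (substitutions/bp since divergence)
    d_x: dict = dc_field(default_factory=lambda: {Stratum.S1: 0.010, Stratum.S2: 0.006, Stratum.S3: 0.004})
    d_y: dict = dc_field(default_factory=lambda: {Stratum.S1: 0.040, Stratum.S2: 0.020, Stratum.S3: 0.010})
    d_auto: float = 0.020
    acr_rate_multiplier_y: float = 3.0
    acr_rate_multiplier_x: float = 1.0
    n_acrs: int = 60
    acr_length: int = 300
    n_genes: int = 60
    gene_length: int = 2_000
    n_repeats: int = 40
    repeat_length: int = 400
    gc_low: float = 0.35
    gc_high: float = 0.55
    # per-site polymorphism rates (theta)
    theta_x: float = 0.0019
    theta_y: float = 0.0001
    theta_auto: float = 0.0043
    acr_theta_multiplier: float = 1.0  # < 1: polymorphism deficit inside ACRs
    n_males: int = 12
    median_depth_sex: float = 7.0
    median_depth_auto: float = 13.0
    depth_outlier_frac: float = 0.02
    # expression model
    expression_slope: float = 0.457
    expression_noise_sd: float = 0.98
    baseline_mean: float = 200.0
    dispersion: float = 50.0
    n_replicates: int = 3
    zero_gene_frac: float = 0.02
    strata_bounds: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        rates = (
            list(self.d_x.values()) + list(self.d_y.values())
            + [self.d_auto, self.theta_x, self.theta_y, self.theta_auto]
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("substitution and polymorphism rates must lie in [0, 1]")
        if self.acr_rate_multiplier_x < 0 or self.acr_rate_multiplier_y < 0:
            raise ValueError("ACR rate multipliers must be >= 0")

    def resolved_strata(self) -> list[GenomicInterval]:
        """Strata boundary table; default splits the chromosome in thirds
        (S1 oldest first)."""
        if self.strata_bounds is not None:
            return self.strata_bounds
        third = self.chrom_length // 3
        return [
            GenomicInterval("chrXY", 0, third, stratum=Stratum.S1),
            GenomicInterval("chrXY", third, 2 * third, stratum=Stratum.S2),
            GenomicInterval("chrXY", 2 * third, self.chrom_length, stratum=Stratum.S3),
        ]


@dataclass
class SimBundle:
    """One simulated cohort: sequences, annotations, truth bookkeeping."""

    params: SimParams
    chrom: str
    x: np.ndarray          # uint8 base codes, gap-free, shared coordinates
    y: np.ndarray
    outgroup: np.ndarray   # the ancestor
    auto: np.ndarray
    auto_outgroup: np.ndarray
    annotations: AnnotationSet
    strata_bounds: list[GenomicInterval]
    truth: pd.DataFrame    # per-ACR injected substitution counts
    x_mut: np.ndarray      # boolean masks of injected substitutions
    y_mut: np.ndarray
    auto_mut: np.ndarray
    gc_profile: np.ndarray  # per-site target GC

    def seq_str(self, which: str) -> str:
        arr = getattr(self, which)
        return arr.tobytes().decode("ascii")

    def triplet(self, region: GenomicInterval, flank: int = 50) -> AlignedTriplet:
        """Extract the aligned (gap-free) triplet for a region, padded with
        ``flank`` anchor columns on each side where the chromosome allows."""
        lo = max(0, region.start - flank)
        hi = min(len(self.x), region.end + flank)
        left = region.start - lo
        if left != min(flank, region.start) or hi - region.end != left:
            # keep flanks symmetric so flank-stripping recovers the core
            pad = min(left, hi - region.end)
            lo, hi = region.start - pad, region.end + pad
            left = pad
        return AlignedTriplet(
            region_id=region.label or f"{region.chrom}:{region.start}-{region.end}",
            x=self.x[lo:hi].tobytes().decode(),
            y=self.y[lo:hi].tobytes().decode(),
            outgroup=self.outgroup[lo:hi].tobytes().decode(),
            stratum=region.stratum,
            flank=left,
            coords={"chrom": region.chrom, "start": lo, "end": hi},
        )


def _draw_sequence(rng: np.random.Generator, gc_site: np.ndarray) -> np.ndarray:
    """Draw bases with per-site P(G or C) = gc_site, split evenly G/C, A/T."""
    is_gc = rng.random(gc_site.size) < gc_site
    second = rng.random(gc_site.size) < 0.5
    out = np.empty(gc_site.size, dtype=np.uint8)
    out[is_gc & second] = ord("G")
    out[is_gc & ~second] = ord("C")
    out[~is_gc & second] = ord("A")
    out[~is_gc & ~second] = ord("T")
    return out


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site with its per-site probability; substituted sites
    always change to one of the three other bases.  Returns (sequence, mask)."""
    mask = rng.random(seq.size) < rate
    n = int(mask.sum())
    out = seq.copy()
    if n:
        idx = np.array([_IDX[b] for b in seq[mask]])
        shift = rng.integers(1, 4, size=n)
        out[mask] = _BASES[(idx + shift) % 4]
    return out, mask


def _gc_field(rng: np.random.Generator, length: int, low: float, high: float) -> np.ndarray:
    """Piecewise-linear target GC: control points every 10 kb, linear in
    between, constant within each kb."""
    n_kb = max(length // 1_000, 1)
    n_nodes = max(n_kb // 10 + 2, 2)
    nodes = rng.uniform(low, high, size=n_nodes)
    kb_gc = np.interp(np.arange(n_kb), np.linspace(0, n_kb - 1, n_nodes), nodes)
    per_site = np.repeat(kb_gc, 1_000)[:length]
    if per_site.size < length:  # remainder kb
        per_site = np.concatenate([per_site, np.full(length - per_site.size, kb_gc[-1])])
    return per_site


def _layout_annotations(params: SimParams) -> AnnotationSet:
    """Deterministic slot layout: one ACR upstream of each gene's TSS, with
    repeats in the slack space.  ACRs never overlap genes."""
    n_slots = max(params.n_acrs, params.n_genes, 1)
    slot = params.chrom_length // n_slots
    needed = (
        400
        + (params.acr_length if params.n_acrs else 0)
        + (300 + params.gene_length if params.n_genes else 0)
        + (200 + params.repeat_length if params.n_repeats else 0)
    )
    if slot < needed:
        raise ValueError(
            f"chromosome too short: slot {slot} bp cannot hold an ACR "
            f"({params.acr_length}), gene ({params.gene_length}) and repeat "
            f"({params.repeat_length}) with margins ({needed} bp needed)"
        )
    acrs, genes, repeats = [], [], []
    for i in range(n_slots):
        base = i * slot
        if i < params.n_acrs:
            acrs.append(
                GenomicInterval("chrXY", base + 200, base + 200 + params.acr_length, f"acr{i:04d}")
            )
        if i < params.n_genes:
            gstart = base + 200 + params.acr_length + 300
            genes.append(Gene("chrXY", gstart, gstart + params.gene_length, f"gene{i:04d}", "+"))
        if i < params.n_repeats:
            rstart = base + 200 + params.acr_length + 300 + params.gene_length + 200
            repeats.append(
                GenomicInterval("chrXY", rstart, rstart + params.repeat_length, f"rep{i:04d}")
            )
    return AnnotationSet(
        genes=genes, repeats=repeats, acrs=acrs,
        chrom_lengths={"chrXY": params.chrom_length, "chrA": params.auto_length},
    )


def _site_rates(
    params: SimParams, strata: Sequence[GenomicInterval], acrs: Sequence[GenomicInterval],
    rates: dict, multiplier: float,
) -> np.ndarray:
    out = np.zeros(params.chrom_length)
    for bound in strata:
        out[bound.start : bound.end] = rates.get(bound.stratum, 0.0)
    for acr in acrs:
        out[acr.start : acr.end] *= multiplier
    return np.clip(out, 0.0, 1.0)


def simulate_sequences(params: SimParams) -> SimBundle:
    """Generate the cohort's sequences, annotations and truth table.

    The outgroup is the ancestor itself; X and Y are derived from it by
    independent per-site substitution, so every lineage-specific
    substitution is known.  The truth table records, per ACR, the number
    of sites substituted only on X and only on Y (sites hit on both
    lineages are species-fixed or ambiguous after alignment and are
    bookkept separately).
    """
    rng = np.random.default_rng([params.seed, 0])
    strata = params.resolved_strata()
    annotations = _layout_annotations(params)
    gc_site = _gc_field(rng, params.chrom_length, params.gc_low, params.gc_high)
    ancestor = _draw_sequence(rng, gc_site)

    rate_x = _site_rates(params, strata, annotations.acrs, params.d_x, params.acr_rate_multiplier_x)
    rate_y = _site_rates(params, strata, annotations.acrs, params.d_y, params.acr_rate_multiplier_y)
    x_seq, x_mut = _mutate(rng, ancestor, rate_x)
    y_seq, y_mut = _mutate(rng, ancestor, rate_y)

    auto_gc = _gc_field(rng, params.auto_length, params.gc_low, params.gc_high)
    auto_ancestor = _draw_sequence(rng, auto_gc)
    auto_seq, auto_mut = _mutate(rng, auto_ancestor, np.full(params.auto_length, params.d_auto))

    # stratum labels on ACRs from their midpoints
    labelled_acrs = []
    rows = []
    for acr in annotations.acrs:
        stratum = Stratum.NA
        for bound in strata:
            if bound.start <= acr.midpoint < bound.end:
                stratum = bound.stratum
                break
        acr = GenomicInterval(acr.chrom, acr.start, acr.end, acr.label, stratum)
        labelled_acrs.append(acr)
        sl = slice(acr.start, acr.end)
        x_only = int((x_mut[sl] & ~y_mut[sl]).sum())
        y_only = int((y_mut[sl] & ~x_mut[sl]).sum())
        both = x_mut[sl] & y_mut[sl]
        same = x_seq[sl][both] == y_seq[sl][both]
        rows.append(
            {
                "region_id": acr.label,
                "stratum": stratum.value,
                "start": acr.start,
                "end": acr.end,
                "length": len(acr),
                "n_x_specific": x_only,
                "n_y_specific": y_only,
                "n_species_fixed": int(same.sum()),
                "n_ambiguous": int((~same).sum()),
                "d_x": x_only / len(acr),
                "d_y": y_only / len(acr),
            }
        )
    annotations.acrs = labelled_acrs
    truth = pd.DataFrame(rows)
    return SimBundle(
        params=params,
        chrom="chrXY",
        x=x_seq, y=y_seq, outgroup=ancestor,
        auto=auto_seq, auto_outgroup=auto_ancestor,
        annotations=annotations,
        strata_bounds=strata,
        truth=truth,
        x_mut=x_mut, y_mut=y_mut, auto_mut=auto_mut,
        gc_profile=gc_site,
    )


# ---------------------------------------------------------------------------
# Population polymorphism


def _sfs_counts(rng: np.random.Generator, n_sites: int, n_alleles: int) -> np.ndarray:
    """Derived-allele counts drawn from the standard neutral frequency
    spectrum, P(k) proportional to 1/k for k = 1..n-1."""
    k = np.arange(1, n_alleles)
    weights = 1.0 / k
    return rng.choice(k, size=n_sites, p=weights / weights.sum())


def _depths(
    rng: np.random.Generator, n_sites: int, n_samples: int, median: float, outlier_frac: float
) -> np.ndarray:
    depth = rng.poisson(median, size=(n_sites, n_samples))
    out = rng.random(n_sites) < outlier_frac
    factor = np.where(rng.random(n_sites) < 0.5, 3.0, 0.2)
    depth[out] = np.maximum((depth[out] * factor[out, None]).astype(int), 0)
    return depth


def simulate_polymorphism(bundle: SimBundle, params: SimParams | None = None) -> list[SiteGenotypes]:
    """Place segregating sites on X, Y and the autosome.

    Sites arise per bp at the compartment's theta (modulated inside ACRs
    by ``acr_theta_multiplier``); derived-allele counts follow the
    neutral frequency spectrum.  Noncrossover X/Y sites carry one haploid
    call per male (no heterozygotes by construction); autosomal sites are
    diploid.  Read depths are Poisson around the compartment median with
    a small fraction of 3x / 0.2x outlier sites so depth filters are
    exercised.
    """
    params = params or bundle.params
    rng = np.random.default_rng([params.seed, 1])
    sites: list[SiteGenotypes] = []

    def theta_track(base_theta: float) -> np.ndarray:
        track = np.full(params.chrom_length, base_theta)
        for acr in bundle.annotations.acrs:
            track[acr.start : acr.end] *= params.acr_theta_multiplier
        return track

    specs = [
        ("chrX", bundle.x, theta_track(params.theta_x), RegionClass.X_NONCROSSOVER, 1,
         params.median_depth_sex),
        ("chrY", bundle.y, theta_track(params.theta_y), RegionClass.Y_NONCROSSOVER, 1,
         params.median_depth_sex),
        ("chrA", bundle.auto, np.full(params.auto_length, params.theta_auto), RegionClass.AUTOSOME, 2,
         params.median_depth_auto),
    ]
    for chrom, seq, theta, region_class, ploidy, median_depth in specs:
        hit = rng.random(seq.size) < theta
        positions = np.flatnonzero(hit)
        n_alleles = params.n_males * ploidy
        derived_counts = _sfs_counts(rng, positions.size, n_alleles)
        depth = _depths(rng, positions.size, params.n_males, median_depth, params.depth_outlier_frac)
        for j, pos in enumerate(positions):
            ref = chr(seq[pos])
            alt_idx = (_IDX[seq[pos]] + int(rng.integers(1, 4))) % 4
            alt = chr(_BASES[alt_idx])
            carriers = rng.choice(n_alleles, size=int(derived_counts[j]), replace=False)
            carrier_set = set(int(c) for c in carriers)
            genotypes = []
            for s in range(params.n_males):
                alleles = tuple(
                    1 if (s * ploidy + a) in carrier_set else 0 for a in range(ploidy)
                )
                genotypes.append(alleles)
            sites.append(
                SiteGenotypes(
                    chrom=chrom, pos=int(pos), ref=ref, alts=(alt,),
                    genotypes=tuple(genotypes),
                    depths=tuple(int(d) for d in depth[j]),
                    region_class=region_class,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    bundle: SimBundle, params: SimParams | None = None
) -> tuple[list[ExpressionRecord], pd.DataFrame]:
    """Per-gametolog replicate counts whose log2(X/Y) tracks Y ACR divergence.

    Each gene's assigned Y ACR divergence (mean over ACRs within 50 kb of
    its TSS, from the truth table) is standardized across genes; the true
    log2 ratio is ``expression_slope`` times that z-score plus Gaussian
    noise, and replicate counts are negative binomial around the implied
    allele means.  A small fraction of genes is silent in both alleles
    (all-zero counts) to exercise the downstream filter.
    """
    params = params or bundle.params
    rng = np.random.default_rng([params.seed, 2])
    assignment = assign_acr_to_gene(bundle.annotations.acrs, bundle.annotations.genes)
    truth = bundle.truth.set_index("region_id")
    per_gene_div: dict[str, list[float]] = {}
    for acr_key, gene_id in assignment.items():
        if gene_id is not None and acr_key in truth.index:
            per_gene_div.setdefault(gene_id, []).append(float(truth.loc[acr_key, "d_y"]))
    gene_ids = sorted(per_gene_div)
    if not gene_ids:
        return [], pd.DataFrame(columns=["gene_id", "y_acr_divergence", "true_log2"])
    div = np.array([np.mean(per_gene_div[g]) for g in gene_ids])
    sd = div.std()
    z = (div - div.mean()) / sd if sd > 0 else np.zeros_like(div)
    true_log2 = params.expression_slope * z + rng.normal(0.0, params.expression_noise_sd, div.size)

    silent = rng.random(div.size) < params.zero_gene_frac
    records: list[ExpressionRecord] = []
    size = params.dispersion
    for i, gene_id in enumerate(gene_ids):
        if silent[i]:
            zeros = tuple(0.0 for _ in range(params.n_replicates))
            records.append(ExpressionRecord(gene_id, zeros, zeros))
            continue
        mean_y = params.baseline_mean
        mean_x = params.baseline_mean * 2.0 ** true_log2[i]
        x_counts = rng.negative_binomial(size, size / (size + mean_x), params.n_replicates)
        y_counts = rng.negative_binomial(size, size / (size + mean_y), params.n_replicates)
        records.append(
            ExpressionRecord(gene_id, tuple(float(c) for c in x_counts), tuple(float(c) for c in y_counts))
        )
    truth_df = pd.DataFrame(
        {"gene_id": gene_ids, "y_acr_divergence": div, "true_log2": true_log2, "silent": silent}
    )
    return records, truth_df


# ---------------------------------------------------------------------------
# On-disk bundle (all plain text)


def write_bundle(
    bundle: SimBundle,
    outdir: str | Path,
    sites: Sequence[SiteGenotypes] | None = None,
    expression: Sequence[ExpressionRecord] | None = None,
) -> None:
    """Write the cohort as FASTA / BED / TSV / VCF files.

    Output is byte-deterministic for fixed SimParams.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(bundle.seq_str("x")), id="chrX", description=""),
        SeqRecord(Seq(bundle.seq_str("y")), id="chrY", description=""),
        SeqRecord(Seq(bundle.seq_str("outgroup")), id="outgroup", description=""),
        SeqRecord(Seq(bundle.seq_str("auto")), id="chrA", description=""),
        SeqRecord(Seq(bundle.seq_str("auto_outgroup")), id="chrA_outgroup", description=""),
    ]
    SeqIO.write(records, str(outdir / "sequences.fasta"), "fasta")

    from .genome_io import write_bed, write_strata_table

    write_bed(bundle.annotations.acrs, outdir / "acrs.bed")
    write_bed([g.interval for g in bundle.annotations.genes], outdir / "genes.bed")
    write_bed(bundle.annotations.repeats, outdir / "repeats.bed")
    write_strata_table(bundle.strata_bounds, outdir / "strata.tsv")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    if sites is not None:
        write_vcf(sites, outdir / "genotypes.vcf", n_samples=bundle.params.n_males)
    if expression is not None:
        rows = []
        for rec in expression:
            for rep, (xc, yc) in enumerate(zip(rec.x_counts, rec.y_counts), start=1):
                rows.append((rec.gene_id, "X", rep, xc))
                rows.append((rec.gene_id, "Y", rep, yc))
        pd.DataFrame(rows, columns=["gene", "allele", "replicate", "count"]).to_csv(
            outdir / "expression_counts.tsv", sep="\t", index=False
        )


def write_vcf(sites: Sequence[SiteGenotypes], path: str | Path, n_samples: int = 12) -> None:
    """Write sites as a minimal VCF 4.2 with GT and DP per sample."""
    sample_names = [f"male{i + 1:02d}" for i in range(n_samples)]
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s.chrom for s in sites})
        for chrom in chroms:
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names) + "\n")
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            fields = []
            for gt, dp in zip(site.genotypes, site.depths):
                if gt is None:
                    gt_str = "./."
                else:
                    gt_str = "/".join(str(a) for a in gt)
                fields.append(f"{gt_str}:{dp}")
            handle.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t{','.join(site.alts)}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(fields) + "\n"
            )
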