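"""GC- and length-matched intergenic permutation null for ACR divergence.

Regulatory regions tend to be GC-rich, and GC-rich sequence can mutate
faster (biased gene conversion, CpG deamination), so a fair null for
"is divergence inside ACRs elevated?" draws random intergenic regions
matched to each ACR for length and GC content (within an absolute
tolerance, default 2 percentage points).  Repeating the draw gives a
null distribution of mean divergence; the observed mean ACR divergence
is ranked against it with the add-one empirical p-value estimator
p = (r + 1) / (n + 1), which never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import divergence as dv
from .genome_io import GenomicInterval

_GC_BYTES = (ord("G"), ord("C"), ord("g"), ord("c"))
_BASE_BYTES = tuple(ord(c) for c in "ACGTacgt")


def gc_content(sequence: str | np.ndarray) -> float:
    """GC fraction over unambiguous bases; N bases are excluded entirely.

    Returns NaN when the sequence contains no A/C/G/T base.
    """
    arr = sequence if isinstance(sequence, np.ndarray) else np.frombuffer(
        sequence.encode("ascii"), dtype=np.uint8
    )
    is_base = np.isin(arr, _BASE_BYTES)
    n_base = int(is_base.sum())
    if n_base == 0:
        return float("nan")
    n_gc = int(np.isin(arr, _GC_BYTES).sum())
    return n_gc / n_base


@dataclass
class ControlSets:
    """Matched control draws: one interval per (set, unflagged ACR)."""

    sets: list[list[GenomicInterval]]
    acr_keys: list[str]           # ACR keys included in every set, ACR order
    flagged: list[str] = field(default_factory=list)  # ACRs with no match


class _GCIndex:
    """O(1) window GC via prefix sums over one chromosome sequence."""

    def __init__(self, sequence: str | np.ndarray):
        arr = sequence if isinstance(sequence, np.ndarray) else np.frombuffer(
            sequence.encode("ascii"), dtype=np.uint8
        )
        self.length = arr.size
        self._gc = np.concatenate([[0], np.cumsum(np.isin(arr, _GC_BYTES))])
        self._base = np.concatenate([[0], np.cumsum(np.isin(arr, _BASE_BYTES))])

    def window_gc(self, starts: np.ndarray, length: int) -> np.ndarray:
        gc = self._gc[starts + length] - self._gc[starts]
        base = self._base[starts + length] - self._base[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(base > 0, gc / np.maximum(base, 1), np.nan)


def sample_matched_controls(
    acrs: Sequence[GenomicInterval],
    intergenic: Sequence[GenomicInterval],
    sequence: str | np.ndarray,
    n_sets: int = 10_000,
    gc_tol: float = 0.02,
    with_replacement: bool = True,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 1_000,
    non_overlapping: bool = False,
) -> ControlSets:
    """Draw ``n_sets`` sets of length- and GC-matched intergenic controls.

    For each ACR and each set, a start is drawn uniformly over all
    intergenic placements that can hold the ACR's length, and accepted if
    the control window's GC content is within ``gc_tol`` (absolute) of the
    ACR's.  The retry budget is ``max_tries`` candidate draws per ACR per
    set; an ACR that cannot be matched within budget is flagged and
    excluded from every set, so set sizes stay equal.

    With ``with_replacement=False`` the same start may not be used twice
    within one set (re-use across sets remains allowed).  With
    ``non_overlapping=True`` control regions within one set may not
    overlap each other at all -- overlapping windows double-count sites,
    which overdisperses pooled counts in downstream MK tables; if the
    surplus of accepted candidates runs out, the last accepted candidate
    is used even if it overlaps, with a warning.
    """
    import warnings

    if not intergenic:
        raise ValueError("intergenic space is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _GCIndex(sequence)

    acr_keys = [a.label or f"{a.chrom}:{a.start}-{a.end}" for a in acrs]
    accepted: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    chrom = acrs[0].chrom if acrs else (intergenic[0].chrom if intergenic else "chr")

    for acr, key in zip(acrs, acr_keys):
        length = len(acr)
        target = index.window_gc(np.array([acr.start]), length)[0]
        # eligible placements: per intergenic interval long enough
        ivls = [iv for iv in intergenic if len(iv) >= length]
        if not ivls or np.isnan(target):
            flagged.append(key)
            continue
        counts = np.array([len(iv) - length + 1 for iv in ivls])
        offsets = np.concatenate([[0], np.cumsum(counts)])
        starts0 = np.array([iv.start for iv in ivls])
        total_eligible = int(offsets[-1])

        hits: list[np.ndarray] = []
        n_hit = 0
        budget = max_tries * n_sets
        drawn = 0
        while n_hit < n_sets and drawn < budget:
            batch = min(max(4 * (n_sets - n_hit), 1024), budget - drawn)
            idx = rng.integers(0, total_eligible, size=batch)
            which = np.searchsorted(offsets, idx, side="right") - 1
            cand = starts0[which] + (idx - offsets[which])
            gc = index.window_gc(cand, length)
            ok = np.abs(gc - target) <= gc_tol + 1e-12
            hits.append(cand[ok])
            n_hit += int(ok.sum())
            drawn += batch
        pool = np.concatenate(hits) if hits else np.empty(0, dtype=int)
        if pool.size < n_sets:
            flagged.append(key)
            continue
        accepted[key] = pool

    if flagged:
        warnings.warn(
            f"{len(flagged)} ACR(s) had no GC-matched intergenic candidate "
            f"within budget and were excluded from every control set: {flagged[:5]}"
        )

    kept_keys = [k for k in acr_keys if k in accepted]
    kept_lengths = {k: len(a) for a, k in zip(acrs, acr_keys) if k in accepted}
    n_overlap_fallback = 0
    sets: list[list[GenomicInterval]] = []
    for set_idx in range(n_sets):
        regions: list[GenomicInterval] = []
        used: set[int] = set()
        taken: list[tuple[int, int]] = []
        for key in kept_keys:
            pool = accepted[key]
            length = kept_lengths[key]

            def rejected(start: int) -> bool:
                if not with_replacement and start in used:
                    return True
                if non_overlapping and any(
                    start < e and s < start + length for s, e in taken
                ):
                    return True
                return False

            start = int(pool[set_idx])
            probe = set_idx
            while rejected(start) and probe + n_sets < pool.size:
                probe += n_sets
                start = int(pool[probe])
            if rejected(start):
                n_overlap_fallback += 1
            used.add(start)
            taken.append((start, start + length))
            regions.append(
                GenomicInterval(chrom, start, start + length, f"{key}|set{set_idx}")
            )
        sets.append(regions)
    if n_overlap_fallback:
        warnings.warn(
            f"{n_overlap_fallback} control draw(s) exhausted the candidate surplus "
            "and violate the replacement/overlap constraint"
        )
    return ControlSets(sets=sets, acr_keys=kept_keys, flagged=flagged)


def mean_rates(
    regions: Sequence[GenomicInterval], codes: np.ndarray
) -> tuple[float, float]:
    """Mean per-region polarized rates (d_X, d_Y) over intervals of a
    chromosome whose columns were classified with
    :func:`regmk.divergence.polarize_columns`."""
    x_cum = np.concatenate([[0], np.cumsum(codes == dv.X_SPECIFIC)])
    y_cum = np.concatenate([[0], np.cumsum(codes == dv.Y_SPECIFIC)])
    ok_cum = np.concatenate([[0], np.cumsum(codes != dv.EXCLUDED)])
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    lengths = ok_cum[ends] - ok_cum[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        d_x = (x_cum[ends] - x_cum[starts]) / lengths
        d_y = (y_cum[ends] - y_cum[starts]) / lengths
    return float(np.nanmean(d_x)), float(np.nanmean(d_y))


def null_distribution(control_sets: ControlSets, codes: np.ndarray) -> pd.DataFrame:
    """Per-set mean polarized rates over the matched control regions."""
    x_cum = np.concatenate([[0], np.cumsum(codes == dv.X_SPECIFIC)])
    y_cum = np.concatenate([[0], np.cumsum(codes == dv.Y_SPECIFIC)])
    ok_cum = np.concatenate([[0], np.cumsum(codes != dv.EXCLUDED)])
    rows = []
    for set_idx, regions in enumerate(control_sets.sets):
        starts = np.array([r.start for r in regions])
        ends = np.array([r.end for r in regions])
        lengths = ok_cum[ends] - ok_cum[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            d_x = (x_cum[ends] - x_cum[starts]) / lengths
            d_y = (y_cum[ends] - y_cum[starts]) / lengths
        rows.append((set_idx, float(np.nanmean(d_x)), float(np.nanmean(d_y))))
    return pd.DataFrame(rows, columns=["set_id", "mean_d_x", "mean_d_y"])


def empirical_pvalue(
    observed: float, null: Sequence[float], tail: str = "two_sided"
) -> float:
    """Empirical p-value of ``observed`` against a permutation null.

    Uses the add-one estimator p = (r + 1)/(n + 1), where r counts null
    values at least as extreme as the observation in the stated tail;
    ``two_sided`` doubles the smaller one-sided value, capped at 1.
    """
    arr = np.asarray(null, dtype=float)
    if arr.size == 0:
        raise ValueError("null distribution is empty")
    n = arr.size
    p_greater = (int((arr >= observed).sum()) + 1) / (n + 1)
    p_less = (int((arr <= observed).sum()) + 1) / (n + 1)
    if tail == "greater":
        return p_greater
    if tail == "less":
        return p_less
    if tail == "two_sided":
        return min(1.0, 2 * min(p_greater, p_less))
    raise ValueError(f"unknown tail: {tail!r}")
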