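"""Binding-site statistics: DHS overlap, phased-nucleosome flanking, and a
one-sided binomial enrichment test against matched random regions.

A site is DHS-associated when it overlaps any DHS by at least 1 bp, and
"flanked by a phased nucleosome" when the site extended by ±50 bp overlaps
at least one phased nucleosome call. The background rate is the flanked
fraction of randomly placed regions with lengths resampled from the sites,
and the reported p-value is the exact upper-tail binomial probability of
observing at least the real hit count at that background rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .detect import DHS
from .intervals import IntervalIndex
from .nucleosomes import NucleosomeCall
from .types import ChromSizes, GenomicInterval


@dataclass
class OverlapResult:
    n_sites: int
    n_hits: int
    percent: float  # rounded to 1 decimal
    background_percent: Optional[float] = None
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_hits <= self.n_sites):
            raise ValueError("need 0 <= n_hits <= n_sites")


def _percent(k: int, n: int) -> float:
    return round(100.0 * k / n, 1)


def fraction_overlapping(
    sites: Sequence[GenomicInterval], dhss: Sequence[DHS] | Sequence[GenomicInterval]
) -> OverlapResult:
    """Fraction of sites overlapping any DHS by >= 1 bp."""
    if not sites:
        raise ValueError("empty site set")
    intervals = [d.interval if isinstance(d, DHS) else d for d in dhss]
    index = IntervalIndex(intervals)
    hits = sum(1 for s in sites if index.overlaps(s.chrom, s.start, s.end))
    return OverlapResult(len(sites), hits, _percent(hits, len(sites)))


def is_flanked(
    site: GenomicInterval, calls: Sequence[NucleosomeCall] | IntervalIndex, flank: int = 50
) -> bool:
    """True iff the site extended by ±flank overlaps a phased nucleosome."""
    index = (
        calls
        if isinstance(calls, IntervalIndex)
        else phased_call_index(calls)
    )
    return index.overlaps(site.chrom, max(0, site.start - flank), site.end + flank)


def phased_call_index(calls: Sequence[NucleosomeCall]) -> IntervalIndex:
    return IntervalIndex([c.interval for c in calls if c.phased])


def flanked_fraction(
    sites: Sequence[GenomicInterval],
    calls: Sequence[NucleosomeCall] | IntervalIndex,
    flank: int = 50,
) -> OverlapResult:
    if not sites:
        raise ValueError("empty site set")
    index = calls if isinstance(calls, IntervalIndex) else phased_call_index(calls)
    hits = sum(1 for s in sites if is_flanked(s, index, flank))
    return OverlapResult(len(sites), hits, _percent(hits, len(sites)))


def random_background(
    n: int,
    lengths: Sequence[int],
    sizes: ChromSizes,
    seed: int | np.random.Generator,
) -> List[GenomicInterval]:
    """n random regions, lengths resampled from ``lengths``, placed uniformly
    and fully inside chromosomes. Deterministic per seed."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not lengths:
        raise ValueError("need a non-empty length distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    chroms = [c for c in sizes if sizes[c] > int(lengths_arr.max())]
    if not chroms:
        raise ValueError("no chromosome can hold the longest site")
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: List[GenomicInterval] = []
    picks = rng.choice(len(chroms), size=n, p=weights)
    sampled = rng.choice(lengths_arr, size=n, replace=True)
    for i in range(n):
        chrom = chroms[picks[i]]
        length = int(sampled[i])
        start = int(rng.integers(0, sizes[chrom] - length + 1))
        out.append(GenomicInterval(chrom, start, start + length, name=f"rand{i}"))
    return out


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper tail P(X >= k), X ~ Binomial(n, p0).

    Summed in log space (log-gamma binomial coefficients + logsumexp), so it
    stays accurate deep into the tail.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("need 0 < p0 < 1")
    if k == 0:
        return 1.0
    ks = np.arange(k, n + 1, dtype=float)
    log_pmf = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p0)
        + (n - ks) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def analyze_sites(
    sites: Sequence[GenomicInterval],
    dhss: Sequence[DHS] | Sequence[GenomicInterval],
    calls: Sequence[NucleosomeCall],
    sizes: ChromSizes,
    flank: int = 50,
    n_random: Optional[int] = None,
    seed: int = 0,
) -> dict:
    """Full binding-site analysis.

    Reports the DHS-associated fraction of the sites, the phased-flanked
    fraction of the DHS-associated subset, the flanked fraction of an
    equally sized random background (site lengths resampled), and the
    one-sided binomial p-value of the enrichment.
    """
    overlap = fraction_overlapping(sites, dhss)
    intervals = [d.interval if isinstance(d, DHS) else d for d in dhss]
    index = IntervalIndex(intervals)
    associated = [s for s in sites if index.overlaps(s.chrom, s.start, s.end)]
    call_index = phased_call_index(calls)

    result = {
        "n_sites": overlap.n_sites,
        "n_dhs_associated": overlap.n_hits,
        "dhs_overlap_percent": overlap.percent,
    }
    if not associated:
        result.update(flanked_percent=None, background_percent=None, binomial_p=None)
        return result

    flanked = flanked_fraction(associated, call_index, flank)
    n_rand = n_random if n_random is not None else len(associated)
    randoms = random_background(
        n_rand, [s.length for s in associated], sizes, seed
    )
    background = flanked_fraction(randoms, call_index, flank)
    p0 = max(background.n_hits, 1) / background.n_sites  # guard degenerate 0 rate
    result.update(
        n_flanked=flanked.n_hits,
        flanked_percent=flanked.percent,
        background_percent=background.percent,
        binomial_p=binomial_pvalue(flanked.n_hits, flanked.n_sites, min(p0, 1 - 1e-12)),
    )
    return result
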