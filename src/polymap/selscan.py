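"""Divergent-panel comparison: per-site Weir-Cockerham F_st variance
components, sliding-window aggregation (ratio of sums), empirical top-0.1%
outlier threshold, outlier-region merging, opposite-homozygote scanning and
per-chromosome count/density tables.

The F_st estimator is the two-population Weir & Cockerham form computed from
genotype counts (it uses observed heterozygosity and carries the small-sample
correction that matters at three diploids per group). A Hudson-style
frequency-only estimator is available behind a flag for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeMatrix, VariantSite


@dataclass
class FstWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps: int
    fst: float  # clipped to [0, 1] for reporting
    fst_raw: float
    qualifies: bool  # enters the empirical distribution (n_snps >= min_snps)


@dataclass
class OutlierRegion:
    chrom: str
    start: int
    end: int
    peak_fst: float
    n_windows: int


@dataclass(frozen=True)
class OppositeHomSite:
    site: VariantSite
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("opposite homozygotes require different alleles")


# ---------------------------------------------------------------------------
# Weir-Cockerham per-site components
# ---------------------------------------------------------------------------

def _group_stats(codes: np.ndarray):
    """Per-site sample size, alt frequency, observed het frequency."""
    called = codes != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = np.where(called, codes == 1, False).sum(axis=0) / n
    return n, p, h


def wc_components(matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir-Cockerham (a, b, c) per site for two populations.

    Sites where either group has no called genotype get nan components.
    Monomorphic-across-both sites get (0, 0, 0).
    """
    if [s.pos for s in matrix_a.sites] != [s.pos for s in matrix_b.sites] or \
       [s.chrom for s in matrix_a.sites] != [s.chrom for s in matrix_b.sites]:
        raise ValueError("the two matrices must carry the same site list")
    n1, p1, h1 = _group_stats(matrix_a.codes)
    n2, p2, h2 = _group_stats(matrix_b.codes)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    invalid = (n1 == 0) | (n2 == 0) | (nbar <= 1.0)
    mono = ~invalid & ((pbar == 0.0) | (pbar == 1.0))
    for arr in (a, b, c):
        arr[invalid] = np.nan
        arr[mono] = 0.0
    return a, b, c


def wc_fst_site(counts_a: Sequence[int], counts_b: Sequence[int]
                ) -> tuple[float, float, float, float]:
    """Weir-Cockerham components and per-site ratio from genotype-count
    triples (hom-ref, het, hom-alt) of the two groups.

    The ratio a/(a+b+c) is nan when a+b+c = 0 (such sites are excluded from
    windows).
    """
    def _matrix(counts):
        codes = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        if not codes:
            codes = [MISSING]
        site = [VariantSite("0", 1, "A", "G")]
        return GenotypeMatrix(site, [f"s{i}" for i in range(len(codes))],
                              np.array(codes, dtype=np.int8)[:, None])

    a, b, c = wc_components(_matrix(list(counts_a)), _matrix(list(counts_b)))
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    ratio = a / denom if denom != 0 and np.isfinite(denom) else float("nan")
    return a, b, c, ratio


def hudson_fst_site(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Hudson-style estimator from allele frequencies only (for comparison)."""
    def _freq(counts):
        n = sum(counts)
        return (counts[1] + 2 * counts[2]) / (2 * n), n
    p1, n1 = _freq(counts_a)
    p2, n2 = _freq(counts_b)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# sliding windows and outlier regions
# ---------------------------------------------------------------------------

def window_fst(sites: Sequence[VariantSite], a: np.ndarray, b: np.ndarray,
               c: np.ndarray, chrom_lengths: Mapping[str, int],
               window: int = 100_000, step: int = 10_000,
               min_snps: int = 5) -> list[FstWindow]:
    """Sliding-window F_st as ratio of sums, windows anchored at position 0.

    Window starts run 0, step, 2*step, ... while start < chromosome length;
    trailing windows are truncated at the chromosome end. Sites with
    undefined per-site ratio (a+b+c = 0 or nan) do not contribute. Windows
    with fewer than ``min_snps`` contributing sites are reported but flagged
    as not qualifying for the empirical distribution.
    """
    chroms = np.array([s.chrom for s in sites], dtype=object)
    pos0 = np.array([s.pos - 1 for s in sites], dtype=np.int64)
    unknown = set(np.unique(chroms)) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosomes without a length: {sorted(unknown)}")
    denom_site = a + b + c
    usable = np.isfinite(denom_site) & (denom_site != 0.0)
    windows: list[FstWindow] = []
    for chrom, length in chrom_lengths.items():
        on = (chroms == chrom) & usable
        p = pos0[on]
        order = np.argsort(p, kind="stable")
        p = p[order]
        ca = np.concatenate([[0.0], np.cumsum(a[on][order])])
        cd = np.concatenate([[0.0], np.cumsum(denom_site[on][order])])
        for start in range(0, length, step):
            end = min(start + window, length)
            lo = int(np.searchsorted(p, start, side="left"))
            hi = int(np.searchsorted(p, end, side="left"))
            n_snps = hi - lo
            if n_snps > 0:
                num = ca[hi] - ca[lo]
                den = cd[hi] - cd[lo]
                raw = num / den if den != 0 else float("nan")
            else:
                raw = float("nan")
            clipped = float(min(1.0, max(0.0, raw))) if math.isfinite(raw) \
                else float("nan")
            windows.append(FstWindow(
                chrom=chrom, start=start, end=end, n_snps=n_snps,
                fst=clipped, fst_raw=float(raw),
                qualifies=n_snps >= min_snps and math.isfinite(raw)))
    return windows


def outlier_threshold(window_fsts: Sequence[float],
                      top_fraction: float = 0.001) -> float:
    """Lower bound of the highest ``top_fraction`` of window F_st values:
    the minimum among the top ceil(top_fraction * N) windows."""
    vals = np.asarray(window_fsts, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no qualifying windows")
    k = max(1, math.ceil(top_fraction * vals.size))
    top = np.sort(vals)[-k:]
    thr = float(top.min())
    if np.all(vals == vals[0]):
        warnings.warn("degenerate empirical distribution: all window F_st "
                      "values are equal; every window is an outlier")
    return thr


def outlier_windows(windows: Sequence[FstWindow],
                    top_fraction: float = 0.001
                    ) -> tuple[float, list[FstWindow]]:
    """Threshold from qualifying windows plus the windows at or above it."""
    qualifying = [w for w in windows if w.qualifies]
    thr = outlier_threshold([w.fst for w in qualifying], top_fraction)
    return thr, [w for w in qualifying if w.fst >= thr]


def merge_outliers(windows: Sequence[FstWindow]) -> list[OutlierRegion]:
    """Merge overlapping or bookended outlier windows into maximal regions."""
    regions: list[OutlierRegion] = []
    by_chrom: dict[str, list[FstWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in by_chrom:
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cur: OutlierRegion | None = None
        for w in ws:
            if cur is not None and w.start <= cur.end:
                cur.end = max(cur.end, w.end)
                cur.peak_fst = max(cur.peak_fst, w.fst)
                cur.n_windows += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = OutlierRegion(chrom=chrom, start=w.start, end=w.end,
                                    peak_fst=w.fst, n_windows=1)
        if cur is not None:
            regions.append(cur)
    return regions


def top_outlier_region(regions: Sequence[OutlierRegion]) -> OutlierRegion:
    """Region with the highest peak F_st; ties prefer more merged windows,
    then the wider span, then input order."""
    if not regions:
        raise ValueError("no outlier regions")
    return max(enumerate(regions),
               key=lambda t: (t[1].peak_fst, t[1].n_windows,
                              t[1].end - t[1].start, -t[0]))[1]


# ---------------------------------------------------------------------------
# opposite homozygotes
# ---------------------------------------------------------------------------

def opposite_homozygotes(matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix,
                         require_complete: bool = True
                         ) -> list[OppositeHomSite]:
    """Sites where every individual of each group is homozygous, for
    different alleles between the groups.

    With ``require_complete`` any missing call disqualifies the site;
    otherwise missing calls are ignored but each group still needs at least
    one call. SNPs and InDels travel through the same scan and are told
    apart downstream via ``site.vtype``.
    """
    if [s.pos for s in matrix_a.sites] != [s.pos for s in matrix_b.sites] or \
       [s.chrom for s in matrix_a.sites] != [s.chrom for s in matrix_b.sites]:
        raise ValueError("the two matrices must carry the same site list")
    ca, cb = matrix_a.codes, matrix_b.codes

    def _fixed(codes, value):
        hom = np.all((codes == value) | (codes == MISSING), axis=0)
        some = (codes == value).any(axis=0)
        if require_complete:
            hom &= ~(codes == MISSING).any(axis=0)
        return hom & some

    a_ref, a_alt = _fixed(ca, 0), _fixed(ca, 2)
    b_ref, b_alt = _fixed(cb, 0), _fixed(cb, 2)
    qualifies = (a_ref & b_alt) | (a_alt & b_ref)
    out = []
    for i in np.flatnonzero(qualifies):
        site = matrix_a.sites[i]
        if a_alt[i]:
            out.append(OppositeHomSite(site, allele_a=site.alt, allele_b=site.ref))
        else:
            out.append(OppositeHomSite(site, allele_a=site.ref, allele_b=site.alt))
    return out


def chrom_density(counts: Mapping[str, int],
                  chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-chromosome count and count-per-Mb, sorted by density descending."""
    missing = set(counts) - set(chrom_lengths)
    if missing:
        raise ValueError(f"no length for chromosomes: {sorted(missing)}")
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int(counts.get(chrom, 0))
        rows.append({"chrom": chrom, "count": n,
                     "density_per_mb": n / (length / 1e6)})
    df = pd.DataFrame(rows)
    return df.sort_values("density_per_mb", ascending=False,
                          kind="stable").reset_index(drop=True)


def opposite_homozygote_counts(sites: Sequence[OppositeHomSite],
                               vtype: str | None = None) -> dict[str, int]:
    """Per-chromosome counts, optionally restricted to 'SNP' or 'INDEL'."""
    counts: dict[str, int] = {}
    for s in sites:
        if vtype is not None and s.site.vtype != vtype:
            continue
        counts[s.site.chrom] = counts.get(s.site.chrom, 0) + 1
    return counts
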