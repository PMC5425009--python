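"""Site-level quality control: MAF / missingness / Hardy-Weinberg filters and
greedy LD pruning to form an 'independent markers' subset.

The HWE test is the exact conditional test (two-sided sum of genotype-table
probabilities no larger than the observed one); a chi-square variant is kept
behind a flag. MAF is computed on non-missing alleles only, r^2 on dosage
correlation with pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .gio import MISSING, GenotypeMatrix

FAIL_MAF = "MAF"
FAIL_MISS = "MISS"
FAIL_HWE = "HWE"


@dataclass(frozen=True)
class SiteQC:
    """Per-site QC statistics; ``passed`` is True iff no fail reason is set."""

    maf: float
    missing_rate: float
    hwe_p: float
    fail_reasons: frozenset = frozenset()

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_fail: dict[str, int]
    table: pd.DataFrame = field(repr=False)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test on one genotype-count triple.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of tables no more probable than the
    observed one (two-sided convention).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        return float("nan")
    n_alt = n_het + 2 * n_hom_alt
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # multinomial probability conditional on allele counts, up to a constant
    logp = (hets * np.log(2.0) - gammaln(hom_rare + 1) - gammaln(hets + 1)
            - gammaln(hom_common + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-d.f. chi-square HWE test (no continuity correction)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    p = (n_het + 2 * n_hom_alt) / (2 * n)
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * n
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(exp == 0):
        return 1.0
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(chi2.sf(stat, df=1))


def _genotype_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    c = matrix.codes
    return ((c == 0).sum(axis=0), (c == 1).sum(axis=0), (c == 2).sum(axis=0),
            (c == MISSING).sum(axis=0))


def _site_arrays(matrix: GenotypeMatrix,
                 hwe_method: str = "exact") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n0, n1, n2, nmiss = _genotype_counts(matrix)
    called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (n1 + 2 * n2) / (2 * called)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    maf[called == 0] = np.nan
    missing_rate = nmiss / matrix.n_samples
    hwe_fn = hwe_exact_p if hwe_method == "exact" else hwe_chisq_p
    hwe_p = np.array([hwe_fn(int(a), int(b), int(c))
                      for a, b, c in zip(n0, n1, n2)])
    return maf, missing_rate, hwe_p


def site_stats(matrix: GenotypeMatrix, site_index: int,
               hwe_method: str = "exact") -> SiteQC:
    """QC statistics for one site (no pass/fail classification applied)."""
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    single = matrix.take_sites([site_index])
    maf, miss, hwe = _site_arrays(single, hwe_method)
    return SiteQC(maf=float(maf[0]), missing_rate=float(miss[0]),
                  hwe_p=float(hwe[0]))


def filter_sites(matrix: GenotypeMatrix, maf_min: float = 0.05,
                 miss_max: float = 0.5, hwe_min: float = 1e-6,
                 hwe_method: str = "exact") -> tuple[GenotypeMatrix, QCReport]:
    """Retain sites with maf >= maf_min, missing rate <= miss_max and
    HWE p >= hwe_min; fully missing sites always fail with reason MISS.

    Fail reasons are non-exclusive: a site can be counted under several
    reasons but is removed once.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= miss_max <= 1 and 0 <= hwe_min <= 1):
        raise ValueError("QC thresholds out of range")
    maf, miss, hwe = _site_arrays(matrix, hwe_method)
    fail_maf = ~(maf >= maf_min)  # nan maf (all missing) handled below
    fail_miss = miss > miss_max
    fail_hwe = ~(hwe >= hwe_min)
    all_missing = np.isnan(maf)
    fail_maf = np.where(all_missing, False, fail_maf)
    fail_hwe = np.where(all_missing, False, fail_hwe)
    fail_miss = fail_miss | all_missing
    keep = ~(fail_maf | fail_miss | fail_hwe)

    reasons = []
    for i in range(matrix.n_sites):
        r = []
        if fail_maf[i]:
            r.append(FAIL_MAF)
        if fail_miss[i]:
            r.append(FAIL_MISS)
        if fail_hwe[i]:
            r.append(FAIL_HWE)
        reasons.append(",".join(r))
    table = pd.DataFrame({
        "chrom": matrix.chromosomes(), "pos": matrix.positions(),
        "maf": maf, "missing_rate": miss, "hwe_p": hwe,
        "pass": keep, "fail_reasons": reasons})
    report = QCReport(
        n_input=matrix.n_sites, n_retained=int(keep.sum()),
        n_fail={FAIL_MAF: int(fail_maf.sum()), FAIL_MISS: int(fail_miss.sum()),
                FAIL_HWE: int(fail_hwe.sum())},
        table=table)
    return matrix.take_sites(np.flatnonzero(keep)), report


def pairwise_r2(matrix: GenotypeMatrix,
                indices: Sequence[int] | None = None) -> np.ndarray:
    """Squared dosage correlation, pairwise-complete over non-missing calls."""
    sub = matrix if indices is None else matrix.take_sites(indices)
    df = pd.DataFrame(sub.dosages())
    r = df.corr(min_periods=1).to_numpy()
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(matrix: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained site indices.

    Within each sliding window of ``window_snps`` sites, while any retained
    pair has r^2 > ``r2_max`` the pair with the largest r^2 is resolved by
    dropping its lower-MAF member (ties drop the larger site index); the
    window then advances by ``step_snps``.
    """
    if window_snps < 2 or step_snps < 1:
        raise ValueError("window_snps must be >= 2 and step_snps >= 1")
    maf, _, _ = _site_arrays(matrix, hwe_method="chisq")
    maf = np.nan_to_num(maf, nan=-1.0)
    kept = np.ones(matrix.n_sites, dtype=bool)
    n = matrix.n_sites
    start = 0
    while start < n:
        win = np.flatnonzero(kept[start:start + window_snps]) + start
        if win.size >= 2:
            r2 = pairwise_r2(matrix, win)
            active = np.ones(win.size, dtype=bool)
            while True:
                m = r2.copy()
                m[~active, :] = 0.0
                m[:, ~active] = 0.0
                np.fill_diagonal(m, 0.0)
                i, j = np.unravel_index(np.argmax(m), m.shape)
                if m[i, j] <= r2_max:
                    break
                gi, gj = win[i], win[j]
                if maf[gi] < maf[gj]:
                    drop = i
                elif maf[gj] < maf[gi]:
                    drop = j
                else:
                    drop = i if gi > gj else j
                active[drop] = False
                kept[win[drop]] = False
        if start + window_snps >= n:
            break
        start += step_snps
    return np.flatnonzero(kept)
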