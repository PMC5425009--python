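"""Breeding-experiment analytics for a dominant binary trait: per-mating
penetrance, the reciprocal-cross sex-linkage check, Mendelian dominance
expectations with exact segregation tests, and genotype-by-phenotype
contingency analysis of a single candidate site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

from .gio import MISSING, GenotypeMatrix, SampleRecord


@dataclass
class MatingSummary:
    """Offspring counts of one mating group; ``penetrance`` is the affected
    fraction among scored offspring."""

    sire: str | None
    dam: str | None
    n_wild: int
    n_poly: int

    @property
    def total(self) -> int:
        return self.n_wild + self.n_poly

    @property
    def penetrance(self) -> float:
        return self.n_poly / self.total if self.total else float("nan")


@dataclass
class ReciprocalCrossResult:
    table: np.ndarray  # 2x2: orientation x (affected, unaffected)
    odds_ratio: float
    p_value: float


@dataclass
class ContingencyTable:
    """Phenotype x genotype counts at one biallelic site plus the
    dominant-model (carrier versus non-carrier) collapse."""

    table: pd.DataFrame  # rows case/control, columns hom-ref/het/hom-alt
    dominant_table: np.ndarray  # 2x2: (case, control) x (carrier, non-carrier)
    carrier_penetrance: float
    p_dominant: float


def penetrance_by_mating(pedigree: Sequence[SampleRecord],
                         group_by: str = "sire") -> list[MatingSummary]:
    """Offspring counts and penetrance per sire, dam or (sire, dam) pair.

    Only offspring with a recorded relevant parent and a non-missing
    phenotype are counted; groups with zero scored offspring are omitted.
    """
    if group_by not in ("sire", "dam", "pair"):
        raise ValueError("group_by must be 'sire', 'dam' or 'pair'")
    groups: dict[tuple[str | None, str | None], list[str]] = {}
    for rec in pedigree:
        if rec.phenotype is None:
            continue
        if group_by == "sire":
            key = (rec.sire, None)
        elif group_by == "dam":
            key = (None, rec.dam)
        else:
            key = (rec.sire, rec.dam)
        if (group_by in ("sire", "pair") and rec.sire is None) or \
           (group_by in ("dam", "pair") and rec.dam is None):
            continue
        groups.setdefault(key, []).append(rec.phenotype)
    out = []
    for (sire, dam), phenos in groups.items():
        out.append(MatingSummary(sire=sire, dam=dam,
                                 n_poly=sum(p == "case" for p in phenos),
                                 n_wild=sum(p == "control" for p in phenos)))
    return out


def select_matings(summaries: Sequence[MatingSummary],
                   min_penetrance: float) -> list[MatingSummary]:
    """Matings whose penetrance is strictly above the threshold ('above 90%'
    reads as a strict inequality)."""
    return [s for s in summaries if s.total and s.penetrance > min_penetrance]


def reciprocal_cross_test(sire_carrier: Sequence[MatingSummary],
                          dam_carrier: Sequence[MatingSummary]
                          ) -> ReciprocalCrossResult:
    """Fisher's exact test of affected fraction by carrier-parent sex.

    Pools offspring counts over matings within each orientation; a trait
    transmitted autosomally shows no orientation effect.
    """
    if not sire_carrier or not dam_carrier:
        raise ValueError("both cross orientations must be present")
    table = np.array([
        [sum(s.n_poly for s in sire_carrier), sum(s.n_wild for s in sire_carrier)],
        [sum(s.n_poly for s in dam_carrier), sum(s.n_wild for s in dam_carrier)],
    ], dtype=np.int64)
    odds, p = fisher_exact(table, alternative="two-sided")
    return ReciprocalCrossResult(table=table, odds_ratio=float(odds),
                                 p_value=float(p))


def dominance_expectation(sire_genotype: int, dam_genotype: int,
                          penetrance: float = 1.0) -> float:
    """Expected affected fraction among offspring of the given parental
    dosages of a completely dominant allele, times the penetrance."""
    for g in (sire_genotype, dam_genotype):
        if g not in (0, 1, 2):
            raise ValueError("parental genotypes must be dosages in {0,1,2}")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    p_carrier = 1.0 - (1.0 - sire_genotype / 2.0) * (1.0 - dam_genotype / 2.0)
    return p_carrier * penetrance


def segregation_fit(n_poly: int, n_wild: int, expected: float) -> float:
    """Two-sided exact binomial p for the observed affected count against a
    Mendelian expectation."""
    if not 0.0 <= expected <= 1.0:
        raise ValueError("expected fraction must be in [0, 1]")
    n = n_poly + n_wild
    if n == 0:
        raise ValueError("no offspring to test")
    return float(binomtest(n_poly, n, expected, alternative="two-sided").pvalue)


def genotype_phenotype_table(matrix: GenotypeMatrix, phenotypes: np.ndarray,
                             site_index: int = 0) -> ContingencyTable:
    """2x3 phenotype-by-genotype table at one biallelic site.

    Columns are labelled by allele pairs (e.g. GG/GT/TT for ref G, alt T).
    The dominant-model collapse pools het and hom-alt carriers; the Fisher
    exact p tests carrier status against phenotype on the collapsed 2x2.
    """
    site = matrix.sites[site_index]
    codes = matrix.codes[:, site_index]
    y = np.asarray(phenotypes, dtype=float)
    ok = (codes != MISSING) & np.isfinite(y)
    codes, y = codes[ok], y[ok]
    labels = [site.ref + site.ref, site.ref + site.alt, site.alt + site.alt]
    counts = np.array([[np.sum((y == cls) & (codes == g)) for g in (0, 1, 2)]
                       for cls in (1.0, 0.0)], dtype=np.int64)
    table = pd.DataFrame(counts, index=["case", "control"], columns=labels)
    carrier = codes >= 1
    dom = np.array([[np.sum((y == 1) & carrier), np.sum((y == 1) & ~carrier)],
                    [np.sum((y == 0) & carrier), np.sum((y == 0) & ~carrier)]],
                   dtype=np.int64)
    n_carriers = dom[:, 0].sum()
    pen = float(dom[0, 0] / n_carriers) if n_carriers else float("nan")
    _, p = fisher_exact(dom, alternative="two-sided")
    return ContingencyTable(table=table, dominant_table=dom,
                            carrier_penetrance=pen, p_dominant=float(p))
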