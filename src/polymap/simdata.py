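"""Synthetic cohorts with the statistical structure the mapping pipeline
assumes: a three-generation backcross segregating a completely dominant
causal locus, small divergent resequencing panels with a fixed-difference
sweep around that locus, single-mating breeding programs, and the published
validation-panel genotype counts.

Founder allele frequencies follow a Balding-Nichols model around a shared
ancestral frequency; the polydactylous donor line is modelled as fully
inbred (a closed purebred line), the recipient breed as an outbred
Hardy-Weinberg population. Meiosis uses a Haldane map (Poisson crossovers,
no interference). Random streams are split per stage, so e.g. adding sites
does not perturb phenotype draws for a fixed seed, and a seed fully
determines every output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gio import (GenotypeMatrix, SampleRecord, VariantSite, write_samples,
                  write_vcf)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_chrom_lengths() -> dict[str, int]:
    # miniature three-chromosome genome: two macro analogs and one micro,
    # so per-chromosome density comparisons are exercisable at desk scale
    return {"1": 20_000_000, "2": 15_000_000, "9": 5_000_000}


@dataclass
class SimConfig:
    """Design constants of the simulated mapping study.

    Defaults mirror the breeding design being emulated: a backcross cohort
    of 112 birds (two progenitors, one F1 sire, 11 recipient-breed dams and
    98 F2 offspring in 11 families), a completely dominant causal allele at
    8.46 Mb of chromosome "2", and a 400 kb fixed-difference sweep around it.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    recomb_rate: float = 3.0  # cM per Mb
    founder_fst: float = 0.10  # Balding-Nichols divergence of the two breeds
    n_sites_per_chrom: int = 1666
    causal_chrom: str = "2"
    causal_pos: int = 8_460_000
    penetrance: float = 1.0
    sweep_halfwidth: int = 200_000
    n_f2: int = 98
    n_families: int = 11
    indel_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must be non-empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigError(f"non-positive length for chromosome {chrom}")
        if self.n_sites_per_chrom < 1:
            raise ConfigError("need at least one site per chromosome")
        if self.causal_chrom not in self.chrom_lengths:
            raise ConfigError(f"causal chromosome {self.causal_chrom!r} unknown")
        if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
            raise ConfigError("causal_pos outside its chromosome")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must be in [0, 1]")
        if not 0.0 <= self.founder_fst < 1.0:
            raise ConfigError("founder_fst must be in [0, 1)")
        if self.n_families < 1 or self.n_f2 < 1:
            raise ConfigError("n_families and n_f2 must be positive")
        if self.n_families > self.n_f2:
            raise ConfigError("more families than F2 offspring")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ConfigError("indel_fraction must be in [0, 1]")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    pedigree: list[SampleRecord]
    causal_site_index: int
    config: SimConfig
    #: fraction of each genome inherited from the donor (BF) founder;
    #: tracked through meiosis, None for cohorts without transmission
    bf_fraction: np.ndarray | None = None


@dataclass
class _FounderModel:
    sites: list[VariantSite]
    p_bf: np.ndarray
    p_sz: np.ndarray
    causal_index: int
    sweep_mask: np.ndarray
    chrom_slices: dict[str, slice]


_STREAMS = ("model", "founders", "meiosis", "phenotype", "panels", "extra")


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s)
            for name, s in zip(_STREAMS, children)}


def _founder_model(config: SimConfig,
                   rng: np.random.Generator) -> _FounderModel:
    """Sites, per-breed allele frequencies and the sweep layout (seeded)."""
    sites: list[VariantSite] = []
    chrom_slices: dict[str, slice] = {}
    positions_all: list[np.ndarray] = []
    offset = 0
    for chrom, length in config.chrom_lengths.items():
        n = config.n_sites_per_chrom
        want = n - 1 if chrom == config.causal_chrom else n
        pos = np.array([], dtype=np.int64)
        while pos.size < want:
            draw = rng.integers(1, length + 1, size=2 * (want - pos.size) + 16)
            pos = np.unique(np.concatenate([pos, draw]))
            pos = pos[pos != config.causal_pos] if chrom == config.causal_chrom else pos
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        if chrom == config.causal_chrom:
            pos = np.sort(np.append(pos, config.causal_pos))
        positions_all.append(pos)
        chrom_slices[chrom] = slice(offset, offset + pos.size)
        offset += pos.size
        for p in pos:
            sites.append(None)  # placeholder; alleles drawn below
        # placeholder list filled after frequency draws (keeps stream order simple)
        sites[chrom_slices[chrom]] = [
            VariantSite(chrom=chrom, pos=int(p), ref="N", alt="N")
            for p in pos]
    total = offset
    pi = rng.uniform(0.05, 0.95, size=total)
    fst = config.founder_fst
    if fst > 0.0:
        alpha = pi * (1.0 - fst) / fst
        beta = (1.0 - pi) * (1.0 - fst) / fst
        p_bf = rng.beta(alpha, beta)
        p_sz = rng.beta(alpha, beta)
    else:
        p_bf = pi.copy()
        p_sz = pi.copy()

    chroms = np.array([s.chrom for s in sites], dtype=object)
    pos = np.array([s.pos for s in sites], dtype=np.int64)
    causal_index = int(np.flatnonzero(
        (chroms == config.causal_chrom) & (pos == config.causal_pos))[0])
    lo = config.causal_pos - config.sweep_halfwidth
    hi = config.causal_pos + config.sweep_halfwidth
    length = config.chrom_lengths[config.causal_chrom]
    if lo < 1 or hi > length:
        warnings.warn("sweep region exceeds chromosome bounds; clipping")
        lo, hi = max(lo, 1), min(hi, length)
    sweep = (chroms == config.causal_chrom) & (pos >= lo) & (pos <= hi)
    p_bf[sweep] = 1.0  # donor line fixed for the swept haplotype
    p_sz[causal_index] = 0.0  # recipient breed carries no causal allele

    is_indel = rng.random(total) < config.indel_fraction
    is_indel[causal_index] = False
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=total)
    alt_shift = rng.integers(1, 4, size=total)
    ins = bases[rng.integers(0, 4, size=total)]
    final_sites = []
    for i, s in enumerate(sites):
        ref = bases[ref_idx[i]]
        if is_indel[i]:
            alt = ref + ins[i]
        else:
            alt = bases[(ref_idx[i] + alt_shift[i]) % 4]
        sid = "rs_causal" if i == causal_index else None
        final_sites.append(VariantSite.from_alleles(s.chrom, s.pos, ref, alt, id=sid))
    return _FounderModel(sites=final_sites, p_bf=p_bf, p_sz=p_sz,
                         causal_index=causal_index, sweep_mask=sweep,
                         chrom_slices=chrom_slices)


def _hwe_genotypes(freqs: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def _inbred_haplotype(freqs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(1, freqs).astype(np.int8)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, model: _FounderModel,
            config: SimConfig, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete under the Haldane map; also returns the
    per-site indicator of descending from ``hap_a``."""
    from_a = np.empty(hap_a.size, dtype=bool)
    for chrom, sl in model.chrom_slices.items():
        length = config.chrom_lengths[chrom]
        morgans = (length / 1e6) * config.recomb_rate / 100.0
        k = rng.poisson(morgans)
        xo = np.sort(rng.uniform(0, length, size=k))
        start = rng.integers(0, 2)
        pos = np.array([s.pos for s in model.sites[sl]], dtype=float)
        phase = (start + np.searchsorted(xo, pos)) % 2
        from_a[sl] = phase == 0
    return np.where(from_a, hap_a, hap_b), from_a


def simulate_founders(config: SimConfig, n_bf: int = 1, n_sz: int = 1,
                      inbred_bf: bool = True) -> SimulatedCohort:
    """Founder individuals of the two breeds.

    Donor (BF) founders are drawn fully inbred by default (one haplotype
    from the breed frequencies, duplicated), so they are homozygous for the
    causal allele and the swept haplotype; recipient (SZ) founders are
    Hardy-Weinberg draws and carry zero causal copies.
    """
    rngs = _rngs(config)
    model = _founder_model(config, rngs["model"])
    rng = rngs["founders"]
    rows = []
    records = []
    for i in range(n_bf):
        if inbred_bf:
            hap = _inbred_haplotype(model.p_bf, rng)
            geno = (2 * hap).astype(np.int8)
        else:
            geno = _hwe_genotypes(model.p_bf, 1, rng)[0]
        rows.append(geno)
        records.append(SampleRecord(id=f"BF{i}", family="P0", sex="M",
                                    generation="G0", population="BF",
                                    phenotype="case"))
    for i in range(n_sz):
        rows.append(_hwe_genotypes(model.p_sz, 1, rng)[0])
        records.append(SampleRecord(id=f"SZ{i}", family="P0", sex="F",
                                    generation="G0", population="SZ",
                                    phenotype="control"))
    matrix = GenotypeMatrix(sites=model.sites,
                            samples=[r.id for r in records],
                            codes=np.stack(rows))
    return SimulatedCohort(genotypes=matrix, pedigree=records,
                           causal_site_index=model.causal_index, config=config)


def founder_frequencies(config: SimConfig
                        ) -> tuple[list[VariantSite], np.ndarray, np.ndarray]:
    """(sites, donor-breed freqs, recipient-breed freqs) for this seed."""
    model = _founder_model(config, _rngs(config)["model"])
    return model.sites, model.p_bf, model.p_sz


def sample_population(config: SimConfig, population: str, n: int,
                      seed: int | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg sample of ``n`` individuals from one breed's
    frequency model (used e.g. for divergence-recovery checks)."""
    if population not in ("BF", "SZ"):
        raise ValueError("population must be 'BF' or 'SZ'")
    rngs = _rngs(config)
    model = _founder_model(config, rngs["model"])
    rng = rngs["extra"] if seed is None else np.random.default_rng(seed)
    freqs = model.p_bf if population == "BF" else model.p_sz
    codes = _hwe_genotypes(freqs, n, rng)
    return GenotypeMatrix(sites=model.sites,
                          samples=[f"{population}_{i:03d}" for i in range(n)],
                          codes=codes)


def simulate_backcross(config: SimConfig) -> SimulatedCohort:
    """Three-generation backcross cohort.

    Structure: 1 inbred donor (BF) male x 1 recipient (SZ) female -> 1 F1
    sire, mated to ``n_families`` recipient-breed dams -> ``n_f2`` offspring
    assigned to dams round-robin. Gametes recombine under the Haldane map;
    an offspring carrying at least one causal allele is affected with
    probability ``penetrance``, non-carriers are never affected.
    """
    rngs = _rngs(config)
    model = _founder_model(config, rngs["model"])
    rng_f = rngs["founders"]
    rng_m = rngs["meiosis"]
    s = len(model.sites)

    bf_hap = _inbred_haplotype(model.p_bf, rng_f)
    sz_haps = rng_f.binomial(1, model.p_sz, size=(2, s)).astype(np.int8)
    dam_haps = rng_f.binomial(
        1, model.p_sz, size=(config.n_families, 2, s)).astype(np.int8)

    f1_bf, _ = _gamete(bf_hap, bf_hap, model, config, rng_m)
    f1_sz, _ = _gamete(sz_haps[0], sz_haps[1], model, config, rng_m)

    ids = ["BF0", "SZ0", "F1"]
    genos = [(2 * bf_hap).astype(np.int8), (sz_haps[0] + sz_haps[1]).astype(np.int8),
             (f1_bf + f1_sz).astype(np.int8)]
    bf_frac = [1.0, 0.0, 0.5]
    records = [
        SampleRecord(id="BF0", family="P0", sex="M", generation="G0",
                     population="BF"),
        SampleRecord(id="SZ0", family="P0", sex="F", generation="G0",
                     population="SZ"),
        SampleRecord(id="F1", family="P0", sire="BF0", dam="SZ0", sex="M",
                     generation="F1", population="BFxSZ"),
    ]
    for i in range(config.n_families):
        ids.append(f"DAM{i + 1:02d}")
        genos.append((dam_haps[i, 0] + dam_haps[i, 1]).astype(np.int8))
        bf_frac.append(0.0)
        records.append(SampleRecord(id=ids[-1], family=f"FAM{i + 1:02d}",
                                    sex="F", generation="G0", population="SZ"))
    for j in range(config.n_f2):
        fam = j % config.n_families
        gam_f1, from_bf = _gamete(f1_bf, f1_sz, model, config, rng_m)
        gam_dam, _ = _gamete(dam_haps[fam, 0], dam_haps[fam, 1], model,
                             config, rng_m)
        ids.append(f"F2_{j + 1:03d}")
        genos.append((gam_f1 + gam_dam).astype(np.int8))
        bf_frac.append(float(from_bf.mean()) / 2.0)
        records.append(SampleRecord(
            id=ids[-1], family=f"FAM{fam + 1:02d}", sire="F1",
            dam=f"DAM{fam + 1:02d}", sex="M" if j % 2 == 0 else "F",
            generation="F2", population="BFxSZ"))

    codes = np.stack(genos)
    carriers = codes[:, model.causal_index] >= 1
    rng_p = rngs["phenotype"]
    affected = carriers & (rng_p.random(len(ids)) < config.penetrance)
    for rec, aff in zip(records, affected):
        rec.phenotype = "case" if aff else "control"
    matrix = GenotypeMatrix(sites=model.sites, samples=ids, codes=codes)
    return SimulatedCohort(genotypes=matrix, pedigree=records,
                           causal_site_index=model.causal_index,
                           config=config, bf_fraction=np.array(bf_frac))


def simulate_divergent_panels(config: SimConfig, n_per_group: int = 3
                              ) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two small resequencing panels of the donor breed.

    Group A (trait-fixed) is homozygous for the swept haplotype across the
    sweep region, group B homozygous for the alternative there; at neutral
    sites both groups are Hardy-Weinberg draws from the donor-breed
    frequencies. Every sweep-region site is therefore an opposite
    homozygote between groups, with window F_st of 1 by construction.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rngs = _rngs(config)
    model = _founder_model(config, rngs["model"])
    rng = rngs["panels"]
    a = _hwe_genotypes(model.p_bf, n_per_group, rng)
    b = _hwe_genotypes(model.p_bf, n_per_group, rng)
    a[:, model.sweep_mask] = 2
    b[:, model.sweep_mask] = 0
    mat_a = GenotypeMatrix(sites=model.sites,
                           samples=[f"POLY_{i + 1}" for i in range(n_per_group)],
                           codes=a)
    mat_b = GenotypeMatrix(sites=model.sites,
                           samples=[f"NORM_{i + 1}" for i in range(n_per_group)],
                           codes=b)
    return mat_a, mat_b


def simulate_breeding_program(n_offspring: int, sire_genotype: int,
                              dam_genotype: int, penetrance: float = 1.0,
                              seed: int = 0) -> tuple[int, int]:
    """Offspring phenotype counts (affected, unaffected) of one mating under
    Mendelian transmission of a completely dominant allele with the given
    penetrance."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    for g in (sire_genotype, dam_genotype):
        if g not in (0, 1, 2):
            raise ValueError("parental genotypes must be dosages in {0,1,2}")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = (rng.binomial(1, sire_genotype / 2.0, size=n_offspring)
              + rng.binomial(1, dam_genotype / 2.0, size=n_offspring))
    affected = (dosage >= 1) & (rng.random(n_offspring) < penetrance)
    n_aff = int(affected.sum())
    return n_aff, n_offspring - n_aff


#: published validation-panel genotype counts at the candidate G/T site:
#: {phenotype: (hom-G, het, hom-T)}
VALIDATION_COUNTS = {"case": (0, 39, 52), "control": (45, 2, 0)}


def make_validation_fixture() -> tuple[GenotypeMatrix, np.ndarray]:
    """Validation panel reproducing the published genotype-by-phenotype
    counts at the candidate ZRS site (one biallelic G/T SNP, 138 birds).

    Returns the one-site genotype matrix and the binary phenotype vector
    (1 = polydactylous, 0 = normal).
    """
    site = VariantSite(chrom="2", pos=8_455_781, ref="G", alt="T",
                       id="rs80659072")
    codes = []
    phenos = []
    for label, cells in VALIDATION_COUNTS.items():
        for dosage, count in enumerate(cells):
            codes.extend([dosage] * count)
            phenos.extend([1.0 if label == "case" else 0.0] * count)
    samples = [f"V{i + 1:03d}" for i in range(len(codes))]
    matrix = GenotypeMatrix(sites=[site], samples=samples,
                            codes=np.array(codes, dtype=np.int8)[:, None])
    return matrix, np.array(phenos)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path,
                 prefix: str = "cohort") -> dict[str, Path]:
    """Write VCF + FAM + JSON config sidecar; byte-identical given a seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(cohort.genotypes, out_dir / f"{prefix}.vcf",
                         chrom_lengths=cohort.config.chrom_lengths),
        "fam": write_samples(cohort.pedigree, out_dir / f"{prefix}.fam"),
    }
    sidecar = out_dir / f"{prefix}.config.json"
    sidecar.write_text(json.dumps(dataclasses.asdict(cohort.config),
                                  indent=2, sort_keys=True) + "\n")
    paths["config"] = sidecar
    return paths
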