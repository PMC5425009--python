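"""End-to-end localization run on one simulated study: backcross GWAS
(QC -> LD pruning -> MDS covariates -> logistic + MLM association) plus the
divergent-panel F_st outlier scan, with bookkeeping about where the causal
site ends up in each ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, qc, selscan, simdata, structure
from .gio import phenotype_vector
from .qc import QCReport
from .selscan import FstWindow, OutlierRegion
from .structure import MdsResult


@dataclass
class LocalizationResult:
    cohort: simdata.SimulatedCohort
    qc_report: QCReport
    mds: MdsResult
    association: pd.DataFrame
    grm_model: assoc.GrmModel
    windows: list[FstWindow]
    fst_threshold: float
    outlier_regions: list[OutlierRegion]
    top_region: OutlierRegion | None
    causal: dict


def localize(config: simdata.SimConfig, n_per_panel: int = 3,
             window: int = 100_000, step: int = 10_000,
             min_snps: int = 5, top_fraction: float = 0.001
             ) -> LocalizationResult:
    """Simulate one study under ``config`` and run the full localization."""
    cohort = simdata.simulate_backcross(config)
    y = phenotype_vector(cohort.pedigree, cohort.genotypes.samples)

    filtered, report = qc.filter_sites(cohort.genotypes)
    pruned_idx = qc.ld_prune(filtered)
    mds = structure.classical_mds(
        structure.ibs_matrix(filtered.take_sites(pruned_idx)), k=2)
    covar = mds.coordinates

    logistic = assoc.logistic_assoc(filtered, y, covar)
    grm = assoc.compute_grm(filtered)
    model = assoc.reml_fit(y, grm, covar)
    mlm = assoc.mlm_assoc(filtered, y, covar, model)
    assoc.attach_mlm(logistic, mlm)
    table = assoc.association_table(logistic)

    panel_a, panel_b = simdata.simulate_divergent_panels(config, n_per_panel)
    a, b, c = selscan.wc_components(panel_a, panel_b)
    windows = selscan.window_fst(panel_a.sites, a, b, c,
                                 config.chrom_lengths, window=window,
                                 step=step, min_snps=min_snps)
    threshold, outliers = selscan.outlier_windows(windows, top_fraction)
    regions = selscan.merge_outliers(outliers)
    top = selscan.top_outlier_region(regions) if regions else None

    causal_site = cohort.genotypes.sites[cohort.causal_site_index]
    mask = (table["chrom"] == causal_site.chrom) & (table["pos"] == causal_site.pos)
    causal: dict = {"chrom": causal_site.chrom, "pos": causal_site.pos,
                    "retained": bool(mask.any())}
    if causal["retained"]:
        row = table[mask].iloc[0]
        p_log = table["p_logistic"].to_numpy(dtype=float)
        p_mlm = table["p_mlm"].to_numpy(dtype=float)
        # sites perfectly collinear with the causal genotype (e.g. an
        # allele-flipped fixed difference with no recombinant) are exact
        # statistical ties; a small relative tolerance absorbs solver-path
        # rounding, while genuinely distinct sites differ by orders of
        # magnitude in p
        causal.update({
            "p_logistic": float(row["p_logistic"]),
            "p_mlm": float(row["p_mlm"]),
            "logistic_is_min": bool(
                row["p_logistic"] <= 1.05 * np.nanmin(p_log)),
            "mlm_is_min": bool(row["p_mlm"] <= 1.05 * np.nanmin(p_mlm)),
            "bonferroni": assoc.bonferroni_threshold(len(table)),
        })
    if top is not None:
        causal["in_top_region"] = (
            top.chrom == causal_site.chrom
            and top.start <= causal_site.pos - 1 < top.end)
    return LocalizationResult(
        cohort=cohort, qc_report=report, mds=mds, association=table,
        grm_model=model, windows=windows, fst_threshold=threshold,
        outlier_regions=regions, top_region=top, causal=causal)
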