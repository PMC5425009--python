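"""Per-SNP case/control association.

Two models are fitted per site, mirroring the dual-model mapping design:

* a logistic model of case status on alt-allele dosage plus structure
  covariates (the two leading MDS components in the pipeline), and
* a mixed linear model treating the 0/1 phenotype as quantitative with a
  genomic-relationship random effect whose variance components are estimated
  once by REML on the null model and reused for every site.

Maximum-likelihood logistic estimates are reported when they exist; under
(quasi-)separation the Firth-penalized fit is reported instead. Logistic
p-values come from the penalized likelihood-ratio test for every site: with
near-complete separation everywhere in a fully penetrant cross, Wald
statistics collapse (Hauck-Donner effect) and would rank a perfectly
associated site below its almost-perfect neighbours, so the penalized LRT is
the one scale on which all sites are comparable. MLM p-values are Wald tests
from generalized least squares with the fitted covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import chi2

from .gio import GeneInterval, GenotypeMatrix, VariantSite

logger = logging.getLogger(__name__)

_SEPARATION_BETA = 10.0  # |log-odds| beyond which an ML fit is treated as separated


@dataclass
class AssociationResult:
    site: VariantSite
    beta: float
    or_: float
    se: float
    p_logistic: float
    p_mlm: float | None = None
    converged: bool = True
    firth_used: bool = False


# ---------------------------------------------------------------------------
# batched logistic engines (sites share the sample set; designs differ only
# in the genotype column, so Newton iterations vectorize across sites)
# ---------------------------------------------------------------------------

def _design(matrix: GenotypeMatrix, covariates: np.ndarray | None):
    dos = matrix.dosages()  # (n, S)
    n, s = dos.shape
    w = np.isfinite(dos).T.astype(float)  # (S, n)
    g = np.nan_to_num(dos, nan=0.0).T
    k = 0 if covariates is None else covariates.shape[1]
    x = np.empty((s, n, 2 + k))
    x[:, :, 0] = 1.0
    x[:, :, 1] = g
    if k:
        x[:, :, 2:] = covariates[None, :, :]
    return x, w


def _loglik(x, beta, y, w):
    eta = np.clip(np.einsum("snp,sp->sn", x, beta), -30.0, 30.0)
    mu = expit(eta)
    ll = np.einsum("sn->s", w * (y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return mu, ll


def _info(x, mu, w):
    m = w * mu * (1.0 - mu)
    return np.einsum("snp,sn,snq->spq", x, m, x), m


def _safe_solve(h, grad, dead):
    """Solve h @ d = grad per site, marking singular systems dead."""
    s, p, _ = h.shape
    sign, logdet = np.linalg.slogdet(h)
    bad = (sign <= 0) | ~np.isfinite(logdet)
    dead |= bad
    h = h.copy()
    h[dead] = np.eye(p)
    delta = np.linalg.solve(h, grad[..., None])[..., 0]
    delta[dead] = 0.0
    return delta, dead


def _ml_logistic(x, y, w, max_iter=40, tol=1e-10):
    s, n, p = x.shape
    beta = np.zeros((s, p))
    frac = np.clip((w * y).sum(1) / np.maximum(w.sum(1), 1.0), 0.01, 0.99)
    beta[:, 0] = np.log(frac / (1 - frac))
    dead = np.zeros(s, dtype=bool)
    converged = np.zeros(s, dtype=bool)
    idx = np.arange(s)
    _, ll = _loglik(x, beta, y, w)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        xa, wa, ba = x[idx], w[idx], beta[idx]
        mu, _ = _loglik(xa, ba, y, wa)
        grad = np.einsum("snp,sn->sp", xa, wa * (y - mu))
        h, _ = _info(xa, mu, wa)
        dead_a = dead[idx].copy()
        delta, dead_a = _safe_solve(h, grad, dead_a)
        delta = np.clip(delta, -5.0, 5.0)  # damp early blow-ups
        # step-halving: Newton for logistic likelihood can cycle on skewed
        # tables without an ascent guarantee
        step = np.where(dead_a, 0.0, 1.0)[:, None]
        ll_a = ll[idx]
        cand = ba + step * delta
        _, ll_new = _loglik(xa, cand, y, wa)
        for _half in range(12):
            worse = ~dead_a & (ll_new < ll_a - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            cand = ba + step * delta
            _, ll_new = _loglik(xa, cand, y, wa)
        beta[idx] = cand
        ll[idx] = ll_new
        conv_a = np.max(np.abs(grad), axis=1) < tol * np.maximum(1.0, wa.sum(1))
        converged[idx] |= conv_a
        dead[idx] = dead_a
        idx = idx[~(conv_a | dead_a)]
    mu, ll = _loglik(x, beta, y, w)
    h, _ = _info(x, mu, w)
    _, dead = _safe_solve(h, np.zeros_like(beta), dead)
    cov = np.full_like(h, np.nan)
    ok = ~dead
    if ok.any():
        cov[ok] = np.linalg.inv(h[ok])
    se = np.sqrt(np.maximum(np.einsum("spp->sp", cov), 0.0))
    return beta, se, converged & ~dead, ll


def _penalized_loglik(x, beta, y, w):
    mu, ll = _loglik(x, beta, y, w)
    h, _ = _info(x, mu, w)
    sign, logdet = np.linalg.slogdet(h)
    pl = ll + 0.5 * logdet
    pl[(sign <= 0) | ~np.isfinite(logdet)] = -np.inf
    return pl


def _firth_logistic(x, y, w, constrain: int | None = None,
                    max_iter=80, tol=1e-8, init: np.ndarray | None = None):
    """Firth-penalized fit; ``constrain`` fixes that coefficient at zero while
    keeping the full-design Jeffreys penalty (profile fit for the LRT)."""
    s, n, p = x.shape
    free = [j for j in range(p) if j != constrain]
    if init is not None:
        beta = np.where(np.all(np.isfinite(init), axis=1, keepdims=True)
                        & (np.max(np.abs(init), axis=1, keepdims=True) < 8.0),
                        init, 0.0)
        if constrain is not None:
            beta[:, constrain] = 0.0
    else:
        beta = np.zeros((s, p))
    dead = np.zeros(s, dtype=bool)
    pl = _penalized_loglik(x, beta, y, w)
    converged = np.zeros(s, dtype=bool)
    idx = np.arange(s)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        xa, wa, ba = x[idx], w[idx], beta[idx]
        mu, _ = _loglik(xa, ba, y, wa)
        h_full, m = _info(xa, mu, wa)
        sign, logdet = np.linalg.slogdet(h_full)
        bad = (sign <= 0) | ~np.isfinite(logdet)
        dead_a = dead[idx] | bad
        inv = np.empty_like(h_full)
        inv[~dead_a] = np.linalg.inv(h_full[~dead_a])
        inv[dead_a] = np.eye(p)
        q = np.einsum("snk,skj,snj->sn", xa, inv, xa)
        hat = m * q
        resid = wa * (y - mu) + hat * (0.5 - mu)
        grad = np.einsum("snp,sn->sp", xa[:, :, free], resid)
        h_free = h_full[:, free][:, :, free]
        delta_free, dead_a = _safe_solve(h_free, grad, dead_a)
        delta = np.zeros((idx.size, p))
        delta[:, free] = np.clip(delta_free, -5.0, 5.0)
        alive = ~dead_a
        # step-halving on the penalized likelihood
        step = np.where(alive, 1.0, 0.0)[:, None]
        pl_a = pl[idx]
        cand = ba + step * delta
        pl_new = _penalized_loglik(xa, cand, y, wa)
        for _half in range(12):
            worse = alive & (pl_new < pl_a - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            cand = ba + step * delta
            pl_new = _penalized_loglik(xa, cand, y, wa)
        improved = alive & (pl_new >= pl_a - 1e-9)
        ba = ba.copy()
        ba[improved] = cand[improved]
        beta[idx] = ba
        pl[idx] = np.where(improved, pl_new, pl_a)
        conv_a = np.max(np.abs(grad), axis=1) < tol * np.maximum(1.0, wa.sum(1))
        converged[idx] |= conv_a
        dead[idx] = dead_a
        idx = idx[~(conv_a | dead_a)]
    mu, _ = _loglik(x, beta, y, w)
    h_full, _ = _info(x, mu, w)
    cov = np.full_like(h_full, np.nan)
    ok = ~dead
    if ok.any():
        cov[ok] = np.linalg.inv(h_full[ok])
    se = np.sqrt(np.maximum(np.einsum("spp->sp", cov), 0.0))
    pl[dead] = np.nan
    return beta, se, pl, converged & ~dead


def logistic_assoc(matrix: GenotypeMatrix, phenotypes: np.ndarray,
                   covariates: np.ndarray | None = None
                   ) -> list[AssociationResult]:
    """Per-site logistic association of case status on alt dosage.

    Samples with a missing genotype are dropped for that site. Reported
    effect sizes are maximum-likelihood estimates where the ML fit converges
    to a finite interior optimum, otherwise the Firth-penalized estimates
    (``firth_used``). P-values are penalized likelihood-ratio tests for every
    site (see module docstring).
    """
    y = np.asarray(phenotypes, dtype=float)
    if y.shape[0] != matrix.n_samples:
        raise ValueError("phenotype length does not match samples")
    vals = np.unique(y[np.isfinite(y)])
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("phenotypes must be coded 0/1")
    if vals.size < 2:
        raise ValueError("phenotype is constant; association is undefined")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != matrix.n_samples:
            raise ValueError("covariate rows do not align with samples")
    x, w = _design(matrix, covariates)
    w = w * np.isfinite(y)  # drop samples with missing phenotype
    y = np.nan_to_num(y, nan=0.0)

    beta_ml, se_ml, conv_ml, _ = _ml_logistic(x, y, w)
    beta_f, se_f, pl_full, conv_f = _firth_logistic(x, y, w, init=beta_ml)
    _, _, pl_null, conv_0 = _firth_logistic(x, y, w, constrain=1, init=beta_ml)
    lrt = np.clip(2.0 * (pl_full - pl_null), 0.0, None)
    p = chi2.sf(lrt, df=1)
    p = np.minimum(np.where(np.isfinite(lrt), p, np.nan), 1.0)
    p[~(conv_f & conv_0)] = np.nan

    use_firth = (~conv_ml) | (np.abs(beta_ml[:, 1]) > _SEPARATION_BETA) \
        | ~np.isfinite(se_ml[:, 1])
    results = []
    for i, site in enumerate(matrix.sites):
        firth = bool(use_firth[i])
        b = float(beta_f[i, 1] if firth else beta_ml[i, 1])
        se = float(se_f[i, 1] if firth else se_ml[i, 1])
        results.append(AssociationResult(
            site=site, beta=b, or_=float(np.exp(b)), se=se,
            p_logistic=float(p[i]),
            converged=bool(conv_f[i] if firth else conv_ml[i]),
            firth_used=firth))
    return results


# ---------------------------------------------------------------------------
# GRM / REML / mixed linear model
# ---------------------------------------------------------------------------

@dataclass
class GrmModel:
    grm: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik: float


def compute_grm(matrix: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix from standardized dosages.

    G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    over sites with 0 < p_i < 1; missing dosages are mean-imputed per site.
    """
    dos = matrix.dosages()
    p = np.nanmean(dos, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites; GRM is undefined")
    dos = dos[:, poly]
    p = p[poly]
    dos = np.where(np.isfinite(dos), dos, 2.0 * p)
    z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (z @ z.T) / z.shape[1]


def _reml_profile(h2: float, d: np.ndarray, ystar: np.ndarray,
                  xstar: np.ndarray) -> tuple[float, float]:
    """-2 restricted log-likelihood (up to a constant) profiled over the
    total variance, at heritability ratio h2; also returns sigma-total^2."""
    n, p = xstar.shape
    v = h2 * d + (1.0 - h2)
    v = np.maximum(v, 1e-12)
    xv = xstar / v[:, None]
    xtvx = xstar.T @ xv
    cf = cho_factor(xtvx)
    betahat = cho_solve(cf, xv.T @ ystar)
    r = ystar - xstar @ betahat
    q = float(np.sum(r * r / v))
    sigma2 = q / (n - p)
    val = ((n - p) * np.log(max(sigma2, 1e-300)) + float(np.sum(np.log(v)))
           + float(np.linalg.slogdet(xtvx)[1]))
    return val, sigma2


def reml_fit(phenotypes: np.ndarray, grm: np.ndarray,
             covariates: np.ndarray | None = None) -> GrmModel:
    """REML variance components for y = X b + g + e with g ~ N(0, G sigma_g^2).

    The GRM is eigendecomposed once, which reduces REML to a one-dimensional
    profile over the heritability ratio; that profile is scanned on a coarse
    grid and polished with bounded scalar minimization, so the optimum cannot
    fall into a local well. Components are clamped at zero by construction.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.shape[0]
    g = np.asarray(grm, dtype=float)
    if g.shape != (n, n):
        raise ValueError("GRM shape does not match phenotype length")
    g = (g + g.T) / 2.0
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    d, u = np.linalg.eigh(g)
    if d.min() < -1e-8:
        warnings.warn("GRM is not positive semidefinite; shifting spectrum")
        g = g + (-d.min() + 1e-8) * np.eye(n)
        d, u = np.linalg.eigh(g)
    d = np.maximum(d, 0.0)
    ystar = u.T @ y
    xstar = u.T @ x

    grid = np.linspace(0.0, 0.999, 41)
    vals = np.array([_reml_profile(h, d, ystar, xstar)[0] for h in grid])
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    if hi > lo:
        opt = minimize_scalar(lambda h: _reml_profile(h, d, ystar, xstar)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        h2 = float(opt.x)
        if opt.fun > vals[best]:
            h2 = float(grid[best])
    else:
        h2 = float(grid[best])
    val, sigma2 = _reml_profile(h2, d, ystar, xstar)
    p = x.shape[1]
    loglik = -0.5 * (val + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    return GrmModel(grm=g, sigma_g2=h2 * sigma2, sigma_e2=(1.0 - h2) * sigma2,
                    loglik=float(loglik))


def mlm_assoc(matrix: GenotypeMatrix, phenotypes: np.ndarray,
              covariates: np.ndarray | None, grm_model: GrmModel
              ) -> pd.DataFrame:
    """Per-site GLS effect and Wald p with V = G sigma_g^2 + I sigma_e^2.

    Variance components come from the null-model REML fit and are reused for
    every site (no per-SNP refit); missing dosages are mean-imputed.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.shape[0]
    v = grm_model.sigma_g2 * grm_model.grm + grm_model.sigma_e2 * np.eye(n)
    try:
        l = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phenotypic covariance V is singular") from exc
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    dos = matrix.dosages()
    p_site = np.nanmean(dos, axis=0) / 2.0
    dos = np.where(np.isfinite(dos), dos, 2.0 * p_site)

    yt = solve_triangular(l, y, lower=True)
    xt = solve_triangular(l, x, lower=True)
    gt = solve_triangular(l, dos, lower=True)
    # residualize whitened dosages and phenotype against whitened covariates
    qx, _ = np.linalg.qr(xt)
    gt = gt - qx @ (qx.T @ gt)
    yr = yt - qx @ (qx.T @ yt)
    gg = np.einsum("ns,ns->s", gt, gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (gt.T @ yr) / gg
        se = 1.0 / np.sqrt(gg)
        z = beta / se
    p = chi2.sf(z ** 2, df=1)
    p[~np.isfinite(z)] = np.nan
    return pd.DataFrame({
        "chrom": matrix.chromosomes(), "pos": matrix.positions(),
        "beta_mlm": beta, "se_mlm": se, "p_mlm": p})


def attach_mlm(results: list[AssociationResult], mlm: pd.DataFrame) -> None:
    """Fill ``p_mlm`` of logistic results from an ``mlm_assoc`` table in place."""
    lookup = {(c, int(p)): v for c, p, v in
              zip(mlm["chrom"], mlm["pos"], mlm["p_mlm"])}
    for r in results:
        r.p_mlm = lookup.get((r.site.chrom, r.site.pos))


# ---------------------------------------------------------------------------
# significance and annotation
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def significant(pvalues: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of tests with p strictly below the per-test threshold."""
    p = np.asarray(pvalues, dtype=float)
    return np.where(np.isfinite(p), p < threshold, False)


def nearest_gene(site: VariantSite, genes: list[GeneInterval]
                 ) -> tuple[str | None, int | None]:
    """Nearest gene and bp distance (0 when inside; ties keep input order)."""
    candidates = [g for g in genes if g.chrom == site.chrom]
    if not candidates:
        warnings.warn(f"no gene on chromosome {site.chrom}; "
                      f"distance for {site.chrom}:{site.pos} is missing")
        return None, None
    pos0 = site.pos - 1
    best: tuple[str, int] | None = None
    for g in candidates:
        if g.start <= pos0 < g.end:
            dist = 0
        elif pos0 < g.start:
            dist = g.start - pos0
        else:
            dist = pos0 - (g.end - 1)
        if best is None or dist < best[1]:
            best = (g.name, dist)
        elif dist == best[1] and g.name != best[0]:
            logger.info("site %s:%d equidistant from %s and %s; keeping %s",
                        site.chrom, site.pos, best[0], g.name, best[0])
    return best


def association_table(results: list[AssociationResult],
                      genes: list[GeneInterval] | None = None) -> pd.DataFrame:
    """Result table sorted by (chrom, pos), mirroring the significant-SNP
    report layout: chr, position, A1/A2, OR, mlm P, logistic P, nearest gene."""
    rows = []
    for r in results:
        row = {
            "chrom": r.site.chrom, "pos": r.site.pos,
            "A1": r.site.alt, "A2": r.site.ref,
            "beta": r.beta, "OR": r.or_, "se": r.se,
            "p_mlm": r.p_mlm, "p_logistic": r.p_logistic,
            "converged": r.converged, "firth_used": r.firth_used,
        }
        if genes is not None:
            name, dist = nearest_gene(r.site, genes)
            row["nearest_gene"] = name
            row["distance"] = dist
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def manhattan_plot(table: pd.DataFrame, path, p_column: str = "p_logistic",
                   threshold: float | None = None) -> None:
    """Minimal Manhattan-style plot of -log10 p by position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(table.groupby("chrom", sort=False)):
        with np.errstate(divide="ignore"):
            logp = -np.log10(sub[p_column].to_numpy(dtype=float))
        ax.scatter(sub["pos"].to_numpy() + offset, logp, s=4,
                   color=f"C{i % 10}", label=str(chrom))
        offset += sub["pos"].max() + 1
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="black", lw=1)
    ax.set_xlabel("genome position (concatenated chromosomes)")
    ax.set_ylabel(f"-log10 {p_column}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
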