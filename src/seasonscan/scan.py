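"""Per-SNP binomial GLM scans for seasonal and clinal allele-frequency change.

Each SNP is fit with a logit-link binomial GLM of allele frequency on a
single predictor (a spring/fall indicator, or latitude) with prior weights
equal to the effective pool-seq sample size n_eff, which folds the number of
pooled chromosomes and the read depth into one precision term.  The core is
an IRLS solver vectorised across SNPs, so genome scans and Monte-Carlo power
calculations run as array operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Role, SampleMeta, Season, SnpTable
from .fst import double_binomial_draw, effective_n

MAX_ITER = 50
TOL = 1e-8
SEPARATION_COEF = 30.0


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def invlogit(x):
    return _sigmoid(np.asarray(x, dtype=float))


def irls_many(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted binomial-logit IRLS for many SNPs at once.

    Parameters
    ----------
    y : (n_snps, m) observed frequencies
    x : (m,) predictor (shared design across SNPs)
    w : (n_snps, m) prior weights (effective sample sizes)

    Returns
    -------
    coef, se, p : (n_snps,) slope estimate, standard error, Wald z p-value
    ok : (n_snps,) bool — converged and not separated; failures carry NaN.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    n, m = y.shape
    if m < 3:
        raise ValueError("need at least 3 observations per SNP")

    # working response initialised from shrunk frequencies
    y_adj = (y * w + 0.5) / (w + 1.0)
    eta = logit(y_adj)
    b0 = np.zeros(n)
    b1 = np.zeros(n)
    active = np.ones(n, dtype=bool)
    for _ in range(MAX_ITER):
        mu = np.clip(_sigmoid(eta), 1e-10, 1.0 - 1e-10)
        v = mu * (1.0 - mu)
        wk = w * v
        z = eta + (y - mu) / v
        s00 = wk.sum(axis=1)
        s01 = wk @ x
        s11 = wk @ (x * x)
        r0 = (wk * z).sum(axis=1)
        r1 = (wk * z) @ x
        det = s00 * s11 - s01 * s01
        with np.errstate(invalid="ignore", divide="ignore"):
            nb1 = (s00 * r1 - s01 * r0) / det
            nb0 = (s11 * r0 - s01 * r1) / det
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1) | (det <= 0)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        moved = active & (step >= TOL)
        b0, b1 = nb0, nb1
        eta = b0[:, None] + b1[:, None] * x[None, :]
        active = moved & ~bad
        if not active.any():
            break
    converged = ~active
    separated = np.abs(b1) > SEPARATION_COEF

    mu = np.clip(_sigmoid(eta), 1e-10, 1.0 - 1e-10)
    wk = w * mu * (1.0 - mu)
    s00 = wk.sum(axis=1)
    s01 = wk @ x
    s11 = wk @ (x * x)
    det = s00 * s11 - s01 * s01
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s00 / det)
    ok = converged & ~separated & np.isfinite(se) & (se > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zscore = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(zscore))
    coef = np.where(ok, b1, np.nan)
    se = np.where(ok, se, np.nan)
    p = np.where(ok, p, np.nan)
    return coef, se, p, ok


def fit_binomial_glm(y, X, w):
    """Single weighted binomial GLM: frequencies ``y`` on a design matrix
    ``X`` (intercept column + one predictor) with prior weights ``w``.

    Returns (coefficient, se, p) for the predictor; a flagged fit
    (non-convergence or separation) returns NaNs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must have exactly an intercept and one predictor")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first column of X must be the intercept")
    coef, se, p, _ = irls_many(np.asarray(y)[None, :], X[:, 1],
                               np.asarray(w)[None, :])
    return float(coef[0]), float(se[0]), float(p[0])


# ---------------------------------------------------------------------------
# FDR and selection coefficients
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def cumulative_S(f_spring, f_fall):
    """Cumulative selection coefficient: total logit-scale displacement of
    the allele frequency over one seasonal episode.  NaN at fixed sites."""
    f_spring = np.asarray(f_spring, dtype=float)
    f_fall = np.asarray(f_fall, dtype=float)
    interior = (f_spring > 0) & (f_spring < 1) & (f_fall > 0) & (f_fall < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.abs(logit(f_fall) - logit(f_spring))
    return np.where(interior, s, np.nan)


def per_generation_s(S, h: float = 1.0, t: float = 10.0):
    """Per-generation selection coefficient from S = s*h*t under logistic
    allele-frequency growth."""
    if h <= 0 or t <= 0:
        raise ValueError("h and t must be positive")
    return np.asarray(S, dtype=float) / (h * t)


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------


def _scan(table: SnpTable, metas: list[SampleMeta], x: np.ndarray) -> dict:
    freqs = table.freq_matrix([m.sample_id for m in metas])
    depths = table.depth_matrix([m.sample_id for m in metas]).astype(float)
    chroms = table.df["chrom"].to_numpy()
    n_chr = np.column_stack(
        [np.fromiter((m.chromosomes(c) for c in chroms), dtype=float,
                     count=len(chroms)) for m in metas])
    usable = np.isfinite(freqs).all(axis=1) & (depths > 0).all(axis=1)
    coef = np.full(len(table), np.nan)
    se = np.full(len(table), np.nan)
    p = np.full(len(table), np.nan)
    if usable.any():
        w = effective_n(n_chr[usable], depths[usable])
        coef[usable], se[usable], p[usable], _ = irls_many(
            freqs[usable], x, w)
    return {"coef": coef, "se": se, "p": p,
            "n_skipped": int((~usable).sum()), "freqs": freqs}


def seasonal_scan(table: SnpTable, metas: list[SampleMeta]) -> pd.DataFrame:
    """Per-SNP GLM of allele frequency on season over the Pennsylvania
    spring/fall series.

    The predictor is 1 for spring, 0 for fall, so a positive coefficient
    means the alt allele is higher in spring.  Returns one record per SNP
    with coefficient, se, p, BH q, cumulative selection coefficient S and
    the winter-favoured allele (the allele higher in spring, winter
    selection preceding the spring sample).
    """
    pa = [m for m in metas if m.role is Role.PENNSYLVANIA_SERIES
          and m.season in (Season.SPRING, Season.FALL)]
    n_spring = sum(m.season is Season.SPRING for m in pa)
    n_fall = sum(m.season is Season.FALL for m in pa)
    if n_spring < 2 or n_fall < 2:
        raise ValueError("need >= 2 spring and >= 2 fall Pennsylvania samples")
    x = np.array([1.0 if m.season is Season.SPRING else 0.0 for m in pa])
    res = _scan(table, pa, x)
    f_spring = res["freqs"][:, x == 1.0].mean(axis=1)
    f_fall = res["freqs"][:, x == 0.0].mean(axis=1)
    out = table.df[["chrom", "pos"]].copy()
    out["coef"] = res["coef"]
    out["se"] = res["se"]
    out["p"] = res["p"]
    out["q"] = bh_fdr(res["p"])
    out["S"] = cumulative_S(f_spring, f_fall)
    out["winter_allele"] = np.where(f_spring > f_fall, "alt", "ref")
    out["f_spring"] = f_spring
    out["f_fall"] = f_fall
    out.attrs["n_skipped"] = res["n_skipped"]
    return out


def clinal_scan(table: SnpTable, metas: list[SampleMeta]) -> pd.DataFrame:
    """Per-SNP GLM of allele frequency on latitude over the clinal samples
    (Pennsylvania series excluded)."""
    cl = [m for m in metas if m.role is Role.CLINAL]
    if len({m.latitude for m in cl}) < 3:
        raise ValueError("need >= 3 clinal samples with distinct latitudes")
    x = np.array([m.latitude for m in cl])
    res = _scan(table, cl, x)
    out = table.df[["chrom", "pos"]].copy()
    out["coef"] = res["coef"]
    out["se"] = res["se"]
    out["p"] = res["p"]
    out["q"] = bh_fdr(res["p"])
    out.attrs["n_skipped"] = res["n_skipped"]
    return out


def alpha_for_q(scan: pd.DataFrame, q_target: float) -> float:
    """Realised per-test alpha corresponding to a q-value threshold on a
    given scan (the largest p among records with q <= q_target)."""
    hits = scan["p"][scan["q"] <= q_target]
    return float(hits.max()) if len(hits) else 0.0


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


@dataclass
class PoolDesign:
    """Sampling design for one seasonal comparison: paired spring/fall pools
    with negative-binomial read depths."""

    n_chr: int = 100
    mean_depth: float = 80.0
    depth_shape: float = 10.0
    n_spring: int = 3
    n_fall: int = 3

    def sample_depths(self, rng: np.random.Generator, size) -> np.ndarray:
        p = self.depth_shape / (self.depth_shape + self.mean_depth)
        return np.maximum(rng.negative_binomial(self.depth_shape, p, size=size), 1)


@dataclass
class PowerCurve:
    S_grid: np.ndarray
    power: np.ndarray
    alpha: float
    design: PoolDesign
    n_reps: int
    seed: int


def power_curve(S_grid, design: PoolDesign, alpha: float = 1e-5,
                base_freq_law=(0.15, 0.85), n_reps: int = 1000,
                seed: int = 0) -> PowerCurve:
    """Monte-Carlo power to detect a seasonal SNP with cumulative selection
    coefficient S under the given pool-seq design.

    For each S, ``n_reps`` SNPs oscillate symmetrically on the logit scale
    around a base frequency drawn uniformly from ``base_freq_law``; samples
    are drawn double-binomially and fed to the seasonal GLM; power is the
    fraction with p < alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    S_grid = np.asarray(S_grid, dtype=float)
    rng = np.random.default_rng(seed)
    m = design.n_spring + design.n_fall
    x = np.r_[np.ones(design.n_spring), np.zeros(design.n_fall)]
    power = np.empty(len(S_grid))
    for i, S in enumerate(S_grid):
        base = rng.uniform(base_freq_law[0], base_freq_law[1], size=n_reps)
        f_spring = invlogit(logit(base) + S / 2.0)
        f_fall = invlogit(logit(base) - S / 2.0)
        truth = np.where(x[None, :] == 1.0, f_spring[:, None], f_fall[:, None])
        depth = design.sample_depths(rng, (n_reps, m))
        counts = double_binomial_draw(truth, design.n_chr, depth, rng)
        y = counts / depth
        w = effective_n(np.full((n_reps, m), design.n_chr, dtype=float),
                        depth.astype(float))
        _, _, p, ok = irls_many(y, x, w)
        power[i] = float(np.mean((p < alpha) & ok))
    return PowerCurve(S_grid=S_grid, power=power, alpha=alpha, design=design,
                      n_reps=n_reps, seed=seed)


def expected_total(observed_counts_by_S, curve: PowerCurve) -> float:
    """Expected number of truly oscillating SNPs: observed counts per S bin
    inflated by the reciprocal of detection power."""
    obs = np.asarray(observed_counts_by_S, dtype=float)
    if obs.shape != curve.power.shape:
        raise ValueError("observed counts must align with the power grid")
    if np.any((obs > 0) & (curve.power <= 0)):
        raise ValueError("zero power with a nonzero observed count")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs / curve.power, 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# spring-like / fall-like clinal profile
# ---------------------------------------------------------------------------


def season_cline_profile(table: SnpTable, seasonal_mask: np.ndarray,
                         metas: list[SampleMeta], block_size: int = 50_000,
                         n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """How 'spring-like' vs 'fall-like' each clinal population is at the
    seasonal SNPs.

    For every clinal sample, the mean over seasonal SNPs of the absolute
    difference between its allele frequency and the Pennsylvania spring
    (fall) mean frequency, with blocked-bootstrap 95% CIs.
    """
    from .fst import block_bootstrap_indices, block_ids

    seasonal_mask = np.asarray(seasonal_mask, dtype=bool)
    if not seasonal_mask.any():
        raise ValueError("empty seasonal set")
    pa_spring = [m for m in metas if m.role is Role.PENNSYLVANIA_SERIES
                 and m.season is Season.SPRING]
    pa_fall = [m for m in metas if m.role is Role.PENNSYLVANIA_SERIES
               and m.season is Season.FALL]
    if not pa_spring or not pa_fall:
        raise ValueError("Pennsylvania spring and fall means are not computable")
    sub = table.subset(seasonal_mask)
    f_spring = sub.freq_matrix([m.sample_id for m in pa_spring]).mean(axis=1)
    f_fall = sub.freq_matrix([m.sample_id for m in pa_fall]).mean(axis=1)
    blocks = block_ids(sub.df["chrom"].to_numpy(), sub.df["pos"].to_numpy(),
                       block_size)
    rng = np.random.default_rng(seed)
    idx = block_bootstrap_indices(blocks, n_boot, rng)
    rows = []
    for m in (m for m in metas if m.role is Role.CLINAL):
        f = sub.freqs(m.sample_id)
        d_sp, d_fa = np.abs(f - f_spring), np.abs(f - f_fall)
        sp_lo, sp_hi = np.percentile(d_sp[idx].mean(axis=1), [2.5, 97.5])
        fa_lo, fa_hi = np.percentile(d_fa[idx].mean(axis=1), [2.5, 97.5])
        rows.append({"sample_id": m.sample_id, "latitude": m.latitude,
                     "dist_spring": float(np.nanmean(d_sp)),
                     "dist_spring_lo": sp_lo, "dist_spring_hi": sp_hi,
                     "dist_fall": float(np.nanmean(d_fa)),
                     "dist_fall_lo": fa_lo, "dist_fall_hi": fa_hi})
    return pd.DataFrame(rows).sort_values("latitude").reset_index(drop=True)
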