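"""Corrected FST for pooled samples, permutation nulls and blocked bootstrap.

Pool-seq allele frequencies carry two layers of binomial noise (individuals
into the pool, reads from the pool).  The estimator here corrects expected
heterozygosities with an effective sample size

    n_eff = N_chr * N_rd / (N_chr + N_rd)

and the unbiased factor n_eff/(n_eff - 1), so that under the double-binomial
null the mean corrected FST is ~0 and individual estimates may be negative
(never clipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import SampleMeta, SnpTable


def effective_n(n_chr, depth):
    """Effective number of independent observations behind a pooled
    frequency estimate: harmonic combination of chromosomes and reads."""
    n_chr = np.asarray(n_chr, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(n_chr < 1) or np.any(depth < 1):
        raise ValueError("n_chr and depth must be >= 1")
    return n_chr * depth / (n_chr + depth)


def snp_fst(p1, p2, neff1, neff2):
    """Per-SNP corrected FST between two pooled samples.

    Each within-sample heterozygosity is unbiased for binomial sampling of
    n_eff chromosomes: h_i = 2 p_i q_i * n_i/(n_i - 1).  The total
    heterozygosity uses the pooled mean frequency p̄ = (p_1 + p_2)/2, whose
    sampling variance under panmixia is pq/(2 ñ) with ñ the harmonic mean
    of the two effective sizes, so its unbiasing factor is 2ñ/(2ñ - 1):
    H_total = 2 p̄ q̄ * 2ñ/(2ñ - 1).  This centres the estimator at zero
    under the double-binomial null.  Returns NaN where both samples are
    fixed for the same allele (H_total = 0); negative values are
    legitimate.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(neff1, dtype=float)
    n2 = np.asarray(neff2, dtype=float)
    h1 = 2.0 * p1 * (1.0 - p1) * n1 / (n1 - 1.0)
    h2 = 2.0 * p2 * (1.0 - p2) * n2 / (n2 - 1.0)
    h_within = 0.5 * (h1 + h2)
    pbar = 0.5 * (p1 + p2)
    n_harm = 2.0 * n1 * n2 / (n1 + n2)
    h_total = 2.0 * pbar * (1.0 - pbar) * 2.0 * n_harm / (2.0 * n_harm - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (h_total - h_within) / h_total
    return np.where(h_total > 0.0, out, np.nan)


# ---------------------------------------------------------------------------
# blocked bootstrap machinery
# ---------------------------------------------------------------------------


def block_ids(chroms, positions, block_size: int) -> np.ndarray:
    """Deterministic genome-anchored block labels (one id per occupied
    ``block_size`` window, windows starting at position 0 per chromosome)."""
    chroms = np.asarray(chroms)
    win = np.asarray(positions) // block_size
    keys = np.char.add(np.char.add(chroms.astype(str), ":"), win.astype(str))
    _, ids = np.unique(keys, return_inverse=True)
    return ids


def block_bootstrap_indices(blocks: np.ndarray, n_boot: int,
                            rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n_blocks) array of SNP indices: one uniformly drawn SNP per
    occupied block per replicate."""
    order = np.argsort(blocks, kind="stable")
    sorted_blocks = blocks[order]
    starts = np.flatnonzero(np.r_[True, sorted_blocks[1:] != sorted_blocks[:-1]])
    counts = np.diff(np.r_[starts, len(blocks)])
    # uniform offset within each block, per replicate
    offsets = (rng.random((n_boot, len(starts))) * counts).astype(np.int64)
    return order[starts[None, :] + offsets]


@dataclass
class FstEstimate:
    pair: tuple[str, str]
    mean_fst: float
    ci_low: float
    ci_high: float
    n_snps: int


def _pair_fst(table: SnpTable, a: SampleMeta, b: SampleMeta) -> np.ndarray:
    chroms = table.df["chrom"].to_numpy()
    na = np.array([a.chromosomes(c) for c in chroms], dtype=float)
    nb = np.array([b.chromosomes(c) for c in chroms], dtype=float)
    neff_a = effective_n(na, table.depths(a.sample_id))
    neff_b = effective_n(nb, table.depths(b.sample_id))
    return snp_fst(table.freqs(a.sample_id), table.freqs(b.sample_id),
                   neff_a, neff_b)


def genomewide_fst(table: SnpTable, sample_a: SampleMeta, sample_b: SampleMeta,
                   block_size: int = 50_000, n_boot: int = 500,
                   seed: int = 0) -> FstEstimate:
    """Genome-wide mean corrected FST with a blocked-bootstrap 95% CI.

    The point estimate is the mean of per-SNP FST over sites where it is
    defined; each bootstrap replicate draws one SNP per occupied
    ``block_size`` window.
    """
    per_snp = _pair_fst(table, sample_a, sample_b)
    defined = np.isfinite(per_snp)
    if not defined.any():
        raise ValueError("no SNPs with defined FST for this pair")
    vals = per_snp[defined]
    chroms = table.df["chrom"].to_numpy()[defined]
    positions = table.df["pos"].to_numpy()[defined]
    blocks = block_ids(chroms, positions, block_size)
    rng = np.random.default_rng(seed)
    idx = block_bootstrap_indices(blocks, n_boot, rng)
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return FstEstimate(
        pair=(sample_a.sample_id, sample_b.sample_id),
        mean_fst=float(vals.mean()), ci_low=float(lo), ci_high=float(hi),
        n_snps=int(defined.sum()),
    )


# ---------------------------------------------------------------------------
# parametric permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullFstDraws:
    """Per-SNP FST draws under the panmixia / no-change null."""

    draws: np.ndarray  # (n_snps, n_perm), NaN where undefined
    n_perm: int
    seed: int


def double_binomial_draw(freq, n_chr, depth, rng: np.random.Generator):
    """Two-stage pool-seq sampling: chromosomes into the pool, reads from
    the pool.  Returns alt read counts with the same shape as ``freq``."""
    freq = np.asarray(freq, dtype=float)
    n_chr = np.broadcast_to(np.asarray(n_chr, dtype=np.int64), freq.shape)
    depth = np.broadcast_to(np.asarray(depth, dtype=np.int64), freq.shape)
    k = rng.binomial(n_chr, np.clip(freq, 0.0, 1.0))
    return rng.binomial(depth, k / n_chr)


def permutation_null_fst(table: SnpTable, pair: tuple[SampleMeta, SampleMeta],
                         n_perm: int = 100, seed: int = 0) -> NullFstDraws:
    """Per-SNP FST draws under the null of no differentiation.

    For each SNP the mean frequency across the pair is taken as the common
    truth; pseudo-observations are drawn through each sample's own
    chromosome count and read depth (double-binomial) and fed to
    :func:`snp_fst`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = pair
    rng = np.random.default_rng(seed)
    chroms = table.df["chrom"].to_numpy()
    na = np.array([a.chromosomes(c) for c in chroms], dtype=np.int64)
    nb = np.array([b.chromosomes(c) for c in chroms], dtype=np.int64)
    dpa, dpb = table.depths(a.sample_id), table.depths(b.sample_id)
    pbar = 0.5 * (table.freqs(a.sample_id) + table.freqs(b.sample_id))
    draws = np.empty((len(table), n_perm))
    neff_a, neff_b = effective_n(na, dpa), effective_n(nb, dpb)
    for j in range(n_perm):
        ca = double_binomial_draw(pbar, na, dpa, rng)
        cb = double_binomial_draw(pbar, nb, dpb, rng)
        draws[:, j] = snp_fst(ca / dpa, cb / dpb, neff_a, neff_b)
    return NullFstDraws(draws=draws, n_perm=n_perm, seed=seed)


def proportion_exceeding(obs_fst: np.ndarray, null_draws: NullFstDraws,
                         chroms, positions, block_size: int = 50_000,
                         n_boot: int = 500, seed: int = 0,
                         null_quantile: float = 0.95) -> tuple[float, float]:
    """Proportion of SNPs whose observed FST exceeds its permutation-null
    quantile, with a blocked-bootstrap mean and SD.

    Per bootstrap replicate j (one SNP per occupied window), the statistic
    is the fraction of drawn SNPs with obs > the per-SNP null quantile;
    the estimate is the mean over j and the SD the standard deviation over j.
    """
    obs_fst = np.asarray(obs_fst, dtype=float)
    if obs_fst.shape[0] != null_draws.draws.shape[0]:
        raise ValueError("observed and null draws are not aligned")
    q = np.nanquantile(null_draws.draws, null_quantile, axis=1)
    ok = np.isfinite(obs_fst) & np.isfinite(q)
    if not ok.any():
        raise ValueError("no SNPs with both observed and null FST defined")
    exceeds = (obs_fst > q) & ok
    blocks = block_ids(np.asarray(chroms)[ok], np.asarray(positions)[ok],
                       block_size)
    rng = np.random.default_rng(seed)
    idx = block_bootstrap_indices(blocks, n_boot, rng)
    props = exceeds[ok][idx].mean(axis=1)
    return float(props.mean()), float(props.std(ddof=1))


# ---------------------------------------------------------------------------
# trend fits and the decay profile
# ---------------------------------------------------------------------------


def fit_fst_trend(x, y, form: str = "linear") -> dict:
    """Least-squares trend fits used for FST vs distance/time.

    ``linear``: y = a + b x.  ``exponential``: y = a b^x fit as
    log y = log a + x log b (back-transformed).  ``loglog``: log y on log x
    with a t-test of slope = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if form == "linear":
        res = stats.linregress(x, y)
        return {"a": res.intercept, "b": res.slope, "p_slope": res.pvalue,
                "se_slope": res.stderr, "r": res.rvalue}
    if form in ("exponential", "loglog"):
        if np.any(y <= 0):
            bad = np.flatnonzero(y <= 0).tolist()
            raise ValueError(f"non-positive y at indices {bad} under {form} fit")
        if form == "exponential":
            res = stats.linregress(x, np.log(y))
            return {"a": float(np.exp(res.intercept)), "b": float(np.exp(res.slope)),
                    "p_slope": res.pvalue, "se_slope": res.stderr, "r": res.rvalue}
        if np.any(x <= 0):
            raise ValueError("non-positive x under loglog fit")
        res = stats.linregress(np.log(x), np.log(y))
        df = len(x) - 2
        if res.stderr > 0:
            t = (res.slope - 1.0) / res.stderr
            p1 = 2.0 * stats.t.sf(abs(t), df)
        else:
            p1 = 1.0 if np.isclose(res.slope, 1.0) else 0.0
        return {"a": float(np.exp(res.intercept)), "slope": res.slope,
                "p_slope": res.pvalue, "se_slope": res.stderr,
                "p_slope_eq_1": float(p1), "r": res.rvalue}
    raise ValueError(f"unknown form {form!r}")


def fst_decay_profile(table: SnpTable, focal_mask: np.ndarray,
                      pairs: list[tuple[SampleMeta, SampleMeta]],
                      max_dist: int = 5_000, bin_width: int = 100,
                      block_size: int = 50_000, n_boot: int = 200,
                      seed: int = 0) -> "pd.DataFrame":
    """Mean temporal FST as a function of distance to the nearest focal SNP.

    Bins are half-open [k*w, (k+1)*w); the focal SNPs themselves are
    excluded; SNPs farther than ``max_dist`` from any focal SNP form the
    background.  A blocked bootstrap over windows gives the 95% band.
    """
    import pandas as pd

    focal_mask = np.asarray(focal_mask, dtype=bool)
    if not focal_mask.any():
        raise ValueError("empty focal set")
    chroms = table.df["chrom"].to_numpy()
    positions = table.df["pos"].to_numpy()

    dist = np.full(len(table), np.iinfo(np.int64).max, dtype=np.int64)
    for c in np.unique(chroms):
        on_c = chroms == c
        fpos = np.sort(positions[on_c & focal_mask])
        if len(fpos) == 0:
            continue
        p = positions[on_c]
        j = np.searchsorted(fpos, p)
        left = np.where(j > 0, p - fpos[np.maximum(j - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(j < len(fpos), fpos[np.minimum(j, len(fpos) - 1)] - p,
                         np.iinfo(np.int64).max)
        dist[on_c] = np.minimum(left, right)

    fst_mat = np.column_stack([_pair_fst(table, a, b) for a, b in pairs])
    with np.errstate(invalid="ignore"):
        mean_fst = np.nanmean(fst_mat, axis=1)

    use = ~focal_mask & np.isfinite(mean_fst)
    bin_idx = np.where(dist[use] > max_dist, -1, dist[use] // bin_width)
    blocks = block_ids(chroms[use], positions[use], block_size)
    rng = np.random.default_rng(seed)
    boot = block_bootstrap_indices(blocks, n_boot, rng)
    vals, bins_used = mean_fst[use], bin_idx

    rows = []
    n_bins = max_dist // bin_width
    for b in list(range(n_bins)) + [-1]:
        in_bin = bins_used == b
        label = "background" if b == -1 else f"[{b * bin_width},{(b + 1) * bin_width})"
        if not in_bin.any():
            rows.append({"bin": label, "mean_fst": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n_snps": 0})
            continue
        boot_in = in_bin[boot]
        with np.errstate(invalid="ignore"):
            bm = np.where(boot_in.any(axis=1),
                          np.nansum(np.where(boot_in, vals[boot], 0.0), axis=1)
                          / np.maximum(boot_in.sum(axis=1), 1), np.nan)
        lo, hi = np.nanpercentile(bm, [2.5, 97.5])
        rows.append({"bin": label, "mean_fst": float(vals[in_bin].mean()),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n_snps": int(in_bin.sum())})
    return pd.DataFrame(rows)
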