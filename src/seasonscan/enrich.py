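"""Matched-control enrichment with a 50-kb block bootstrap.

Focal SNPs (e.g. the seasonal set) are compared against control SNPs
matched exactly on discretised genomic covariates (chromosome, rounded
recombination rate, rounded allele frequency, ...).  Uncertainty combines
two resampling layers: 500 control sets (one control per focal SNP each)
and 500 block-bootstrap subsets of the focal SNPs (one per occupied 50-kb
window), which absorbs linkage disequilibrium between nearby focal SNPs.
The expectation E and SD of a statistic are its mean and standard deviation
over the (control set x block subset) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Role, SampleMeta, Season, SnpTable
from .fst import block_bootstrap_indices, block_ids


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def matching_key_frame(table: SnpTable, freq_samples: list[str] | None = None,
                       keys: tuple = ("chrom", "recomb_rate", "freq"),
                       freq_round: float = 0.05, rec_round: float = 1.0,
                       extra: dict | None = None) -> pd.DataFrame:
    """Discretised per-SNP matching covariates.

    ``freq`` is the mean alt frequency over ``freq_samples`` rounded to the
    nearest ``freq_round``; ``recomb_rate`` is rounded to ``rec_round``
    cM/Mb; ``extra`` supplies already-computed columns (values are rounded
    by the caller).
    """
    cols = {}
    if "chrom" in keys:
        cols["chrom"] = table.df["chrom"].to_numpy()
    if "recomb_rate" in keys:
        r = table.df["recomb_rate"].to_numpy(dtype=float)
        cols["recomb_rate"] = np.round(r / rec_round) * rec_round
    if "freq" in keys:
        if not freq_samples:
            raise ValueError("freq key requires freq_samples")
        f = table.freq_matrix(freq_samples).mean(axis=1)
        cols["freq"] = np.round(f / freq_round) * freq_round
    if "genic_class" in keys:
        cols["genic_class"] = table.df["genic_class"].to_numpy()
    for name, values in (extra or {}).items():
        cols[name] = np.asarray(values)
    return pd.DataFrame(cols)


@dataclass
class ControlSets:
    """Matched controls: row indices into the source table."""

    focal_idx: np.ndarray          # (n_kept,) focal rows with a match
    control_idx: np.ndarray        # (n_kept, n_sets) matched control rows
    dropped_focal: np.ndarray      # focal rows with no matching stratum
    n_sets: int
    keys: tuple


def match_controls(key_frame: pd.DataFrame, focal_mask: np.ndarray,
                   n_sets: int = 500, seed: int = 0) -> ControlSets:
    """Draw ``n_sets`` control SNPs per focal SNP from its exact-match
    stratum of non-focal SNPs (with replacement); focal SNPs whose stratum
    is empty are dropped and reported."""
    focal_mask = np.asarray(focal_mask, dtype=bool)
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(key_frame))
    rng = np.random.default_rng(seed)
    pool_rows = np.flatnonzero(~focal_mask)
    focal_rows = np.flatnonzero(focal_mask)
    pool_by_stratum: dict[int, np.ndarray] = {
        int(c): pool_rows[codes[pool_rows] == c]
        for c in np.unique(codes[pool_rows])}
    kept, dropped, controls = [], [], []
    for row in focal_rows:
        candidates = pool_by_stratum.get(int(codes[row]))
        if candidates is None or len(candidates) == 0:
            dropped.append(row)
            continue
        kept.append(row)
        controls.append(rng.choice(candidates, size=n_sets, replace=True))
    if not kept:
        raise ValueError("no focal SNP has a matching control stratum")
    return ControlSets(focal_idx=np.array(kept),
                       control_idx=np.vstack(controls),
                       dropped_focal=np.array(dropped, dtype=np.int64),
                       n_sets=n_sets, keys=tuple(key_frame.columns))


def block_sample(chroms, positions, block_size: int = 50_000,
                 n_boot: int = 500, seed: int = 0) -> np.ndarray:
    """(n_boot, n_occupied_windows) subsets of focal SNPs: exactly one
    uniformly drawn focal SNP per occupied ``block_size`` window."""
    blocks = block_ids(np.asarray(chroms), np.asarray(positions), block_size)
    rng = np.random.default_rng(seed)
    return block_bootstrap_indices(blocks, n_boot, rng)


# ---------------------------------------------------------------------------
# log2 odds-ratio enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    log2_or: float       # central estimate on the full focal set
    e_value: float       # resampling expectation E
    sd: float            # resampling SD
    ci_low: float
    ci_high: float
    p: float             # two-sided resampling sign-reversal probability
    n_focal_used: int


def _log2_odds_ratio(a, b, c, d):
    """log2 OR with the Haldane–Anscombe 0.5 correction on zero cells."""
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    add = np.where((a == 0) | (b == 0) | (c == 0) | (d == 0), 0.5, 0.0)
    return np.log2(((a + add) * (d + add)) / ((b + add) * (c + add)))


def enrichment_or(predicate: np.ndarray, controls: ControlSets, chroms,
                  positions, block_size: int = 50_000, n_boot: int = 500,
                  seed: int = 0) -> EnrichmentResult:
    """Enrichment of a per-SNP predicate in focal SNPs relative to matched
    controls.

    ``predicate`` is aligned to the source table rows; NaN entries are
    excluded cell-wise and counted out.  For every (block subset j, control
    set i) pair the 2x2 table focal-vs-control x predicate-vs-not yields a
    log2 odds ratio; E, SD, percentile CI and a two-sided sign-reversal p
    summarise the grid.
    """
    pred = np.asarray(predicate, dtype=float)
    pf = pred[controls.focal_idx]                     # (n_focal,)
    pc = pred[controls.control_idx]                   # (n_focal, n_sets)
    boot = block_sample(np.asarray(chroms)[controls.focal_idx],
                        np.asarray(positions)[controls.focal_idx],
                        block_size, n_boot, seed)     # (n_boot, n_win)
    n_focal = len(controls.focal_idx)
    sel = np.zeros((boot.shape[0], n_focal), dtype=np.float32)
    np.put_along_axis(sel, boot, 1.0, axis=1)

    vf = np.nan_to_num(pf, nan=0.0).astype(np.float32)
    kf = np.isfinite(pf).astype(np.float32)
    vc = np.nan_to_num(pc, nan=0.0).astype(np.float32)
    kc = np.isfinite(pc).astype(np.float32)

    a = sel @ vf                                      # (n_boot,)
    n1 = sel @ kf
    c = sel @ vc                                      # (n_boot, n_sets)
    n2 = sel @ kc
    lor = _log2_odds_ratio(a[:, None], n1[:, None] - a[:, None], c, n2 - c)

    # central estimate: all focal SNPs vs all control draws pooled
    central = float(_log2_odds_ratio(np.nansum(pf), np.isfinite(pf).sum() - np.nansum(pf),
                                     np.nansum(pc), np.isfinite(pc).sum() - np.nansum(pc)))
    flat = lor.ravel()
    lo, hi = np.percentile(flat, [2.5, 97.5])
    p = min(1.0, 2.0 * min(float(np.mean(flat <= 0.0)),
                           float(np.mean(flat >= 0.0))))
    return EnrichmentResult(log2_or=central, e_value=float(flat.mean()),
                            sd=float(flat.std(ddof=1)), ci_low=float(lo),
                            ci_high=float(hi), p=p,
                            n_focal_used=n_focal)


def threshold_sweep_enrichment(score: np.ndarray, controls: ControlSets,
                               thresholds, chroms, positions,
                               concordant: np.ndarray | None = None,
                               direction: str = "ge",
                               block_size: int = 50_000, n_boot: int = 500,
                               seed: int = 0) -> pd.DataFrame:
    """Enrichment as a function of a score threshold (e.g. spatial FST,
    -log10 GWAS p).  With ``concordant`` given (GWAS mode), the predicate
    is concordant-direction AND score past the threshold."""
    score = np.asarray(score, dtype=float)
    rows = []
    for t in thresholds:
        passed = score >= t if direction == "ge" else score <= t
        pred = passed.astype(float)
        pred[~np.isfinite(score)] = np.nan
        if concordant is not None:
            pred = np.where(np.isfinite(pred), pred * np.asarray(concordant,
                                                                 dtype=float), np.nan)
        if np.nansum(pred[controls.focal_idx]) == 0 and \
                np.nansum(pred[controls.control_idx]) == 0:
            rows.append({"threshold": t, "log2_or": np.nan, "e_value": np.nan,
                         "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "n_focal_used": 0, "missing": True})
            continue
        res = enrichment_or(pred, controls, chroms, positions, block_size,
                            n_boot, seed)
        rows.append({"threshold": t, "log2_or": res.log2_or,
                     "e_value": res.e_value, "sd": res.sd,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p": res.p, "n_focal_used": res.n_focal_used,
                     "missing": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frost overshoot
# ---------------------------------------------------------------------------


def overshoot_flags(f_pre: np.ndarray, f_post: np.ndarray,
                    f_longterm: np.ndarray) -> np.ndarray:
    """Directional crossing of the long-term mean: post-frost frequency on
    the opposite side of the long-term mean from the pre-frost frequency.
    NaN where pre equals the long-term mean (no direction defined)."""
    pre_side = np.sign(f_longterm - f_pre)
    post_side = np.sign(f_longterm - f_post)
    out = (pre_side != post_side).astype(float)
    out[pre_side == 0] = np.nan
    return out


def frost_overshoot(table: SnpTable, seasonal_mask: np.ndarray,
                    metas: list[SampleMeta], freq_round: float = 0.05,
                    n_sets: int = 500, block_size: int = 50_000,
                    n_boot: int = 500, seed: int = 0,
                    match_on_displacement: bool = True
                    ) -> tuple[float, float, EnrichmentResult]:
    """Do seasonal SNPs overshoot the long-term mean after an acute frost?

    Controls are matched on chromosome, rounded pre-frost frequency and —
    crucially, to cancel regression to the mean — the rounded absolute
    displacement between the pre-frost and long-term frequencies.  Returns
    (P(overshoot | seasonal), P(overshoot | control), enrichment).
    """
    pre = [m for m in metas if m.role is Role.FROST_PRE]
    post = [m for m in metas if m.role is Role.FROST_POST]
    if not post:
        raise ValueError("need a sample tagged frost_post")
    if not pre:
        # the pre-frost sample is the latest fall sample of the series
        falls = [m for m in metas if m.role is Role.PENNSYLVANIA_SERIES
                 and m.season is Season.FALL]
        if not falls:
            raise ValueError("need a frost_pre sample or a fall series sample")
        pre = [max(falls, key=lambda m: m.year)]
    longterm = [m for m in metas if m.role is Role.LONGTERM_REFERENCE]
    if not longterm:
        longterm = [m for m in metas if m.role is Role.PENNSYLVANIA_SERIES
                    and m.year < min(p.year for p in pre)]
    if not longterm:
        raise ValueError("no long-term reference samples")
    f_pre = table.freqs(pre[0].sample_id)
    f_post = table.freqs(post[0].sample_id)
    f_long = table.freq_matrix([m.sample_id for m in longterm]).mean(axis=1)
    pred = overshoot_flags(f_pre, f_post, f_long)

    extra = {"pre_freq": np.round(f_pre / freq_round) * freq_round}
    if match_on_displacement:
        disp = np.abs(f_pre - f_long)
        extra["displacement"] = np.round(disp / freq_round) * freq_round
    keys = matching_key_frame(table, keys=("chrom",), extra=extra)
    controls = match_controls(keys, seasonal_mask, n_sets=n_sets, seed=seed)

    chroms = table.df["chrom"].to_numpy()
    positions = table.df["pos"].to_numpy()
    res = enrichment_or(pred, controls, chroms, positions, block_size,
                        n_boot, seed)
    boot = block_sample(chroms[controls.focal_idx],
                        positions[controls.focal_idx], block_size, n_boot,
                        seed)
    pf = pred[controls.focal_idx]
    p_seasonal = float(np.nanmean(np.nanmean(pf[boot], axis=1)))
    p_control = float(np.nanmean(pred[controls.control_idx]))
    return p_seasonal, p_control, res


# ---------------------------------------------------------------------------
# genomic overdispersion of the seasonal-SNP rate
# ---------------------------------------------------------------------------


def dispersion_test(seasonal_mask: np.ndarray, chroms, recomb_rate,
                    window_snps: int = 1000) -> tuple[float, float]:
    """Is the count of seasonal SNPs per 1000-SNP window overdispersed
    relative to Poisson, after a Poisson GLM on chromosome type
    (autosome/X) and recombination rate?

    Returns (dispersion ratio = Pearson chi^2 / df, one-sided p from the
    Cameron–Trivedi auxiliary regression z-test).
    """
    import statsmodels.api as sm

    seasonal_mask = np.asarray(seasonal_mask, dtype=float)
    chroms = np.asarray(chroms)
    recomb_rate = np.asarray(recomb_rate, dtype=float)

    ys, xs_chr, xs_rec = [], [], []
    for c in pd.unique(chroms):
        on_c = np.flatnonzero(chroms == c)
        for start in range(0, len(on_c) - window_snps + 1, window_snps):
            win = on_c[start:start + window_snps]
            ys.append(seasonal_mask[win].sum())
            xs_chr.append(1.0 if c == "X" else 0.0)
            xs_rec.append(recomb_rate[win].mean())
    y = np.asarray(ys)
    if len(y) < 20:
        raise ValueError(f"need >= 20 windows, got {len(y)}")
    if y.sum() == 0:
        raise ValueError("no seasonal SNPs in any window")
    X = sm.add_constant(np.column_stack([xs_chr, xs_rec]))
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = fit.mu
    dof = len(y) - X.shape[1]
    ratio = float(np.sum((y - mu) ** 2 / mu) / dof)
    aux = ((y - mu) ** 2 - y) / mu
    z = float(np.mean(aux) / (np.std(aux, ddof=1) / np.sqrt(len(aux))))
    p = float(stats.norm.sf(z))
    return ratio, p
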