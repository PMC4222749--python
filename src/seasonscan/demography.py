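"""Boom-bust forward simulation and demographic plausibility models.

Three alternative explanations for rapid genome-wide allele-frequency
change through time are modelled here:

* a diploid Wright-Fisher forward simulator on one recombining chromosome
  with boom-bust demography (exponential summer growth, instantaneous
  winter crash) and seasonally alternating selection at a configurable
  number of loci — measures how much neutral spring-fall differentiation
  drift and genetic draft generate;
* a recolonisation model where a founder sample from a stable refugium
  re-seeds the population each spring — expected number of SNPs that cycle
  three years running by founder-sampling chance alone;
* a truncation-selection model bounding the number of loci that can shift
  independently between seasons given a finite fall census size.

Selection is genic and parameterised on the logit scale: an individual's
fitness is exp(s * copies of the favoured allele), so a deterministic
population shifts allele frequency by exactly s logit units per generation
and the per-season coefficients have the closed form produced by
:func:`calibrate_selection`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fst import effective_n, snp_fst
from .scan import invlogit, logit

logger = logging.getLogger("seasonscan")


@dataclass
class SimConfig:
    chrom_length: int = 20_000_000
    recomb_rate: float = 2.0          # cM/Mb
    n_neutral: int = 500              # start at 0.5, linkage equilibrium
    n_selected: int = 10              # equidistant along the chromosome
    n_max: int = 100_000
    n_min: int = 200
    summer_gens: int = 10
    winter_gens: int = 2
    total_gens: int = 96
    amplitude: float = 0.20           # designed oscillation, 0.40 <-> 0.60
    sample_n_chr: int = 100
    sample_depth: int = 100
    record_trajectories: bool = False  # keep per-generation neutral freqs
    deterministic: bool = False        # infinite-N logistic dynamics
    seed: int = 0

    def __post_init__(self):
        if self.n_min > self.n_max:
            raise ValueError("n_min must be <= n_max")
        cycle = self.summer_gens + self.winter_gens
        if self.total_gens % cycle != 0:
            raise ValueError("total_gens must be a multiple of the cycle length")
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must be in [0, 1)")

    @property
    def cycle_gens(self) -> int:
        return self.summer_gens + self.winter_gens

    @property
    def n_cycles(self) -> int:
        return self.total_gens // self.cycle_gens


def calibrate_selection(config: SimConfig) -> tuple[float, float]:
    """Per-generation logit-scale selection coefficients producing the
    configured oscillation.

    The designed trajectory swings between 0.5 - amplitude/2 and
    0.5 + amplitude/2; under logistic dynamics the total logit displacement
    per season is split evenly over that season's generations:
    s_summer = +delta/summer_gens, s_winter = -delta/winter_gens.
    """
    if config.amplitude == 0.0:
        return 0.0, 0.0
    hi = 0.5 + config.amplitude / 2.0
    lo = 0.5 - config.amplitude / 2.0
    delta = float(logit(hi) - logit(lo))
    return delta / config.summer_gens, -delta / config.winter_gens


def _schedule(config: SimConfig) -> list[tuple[int, str]]:
    """(population size, season) per generation.  Each cycle is
    winter_gens at n_min (the first is the crash) followed by summer_gens
    of exponential growth back to n_max."""
    growth = (config.n_max / config.n_min) ** (1.0 / config.summer_gens)
    sched = []
    for _ in range(config.n_cycles):
        sched.extend((config.n_min, "winter") for _ in range(config.winter_gens))
        for t in range(1, config.summer_gens + 1):
            sched.append((int(round(config.n_min * growth ** t)), "summer"))
    return sched


@dataclass
class SimResult:
    config: SimConfig
    positions: np.ndarray            # all loci, sorted
    is_selected: np.ndarray          # bool per locus
    sel_traj: np.ndarray             # (total_gens+1, n_selected) frequencies
    neutral_traj: np.ndarray | None  # (total_gens+1, n_neutral) if recorded
    pop_sizes: np.ndarray            # (total_gens+1,)
    cycles: list                     # dicts: trough_gen, spring_gen, fall_gen
    true_freqs: dict                 # gen -> (n_loci,) population frequencies
    pool_counts: dict                # gen -> (n_loci,) pseudo-pool alt reads
    mean_neutral_fst: float          # within-cycle spring-fall, last 3 cycles
    fst_per_cycle: np.ndarray
    amplitude_observed: float        # peak-to-trough, selected loci
    n_fixed_selected: int


def _make_gametes(hap: np.ndarray, parents: np.ndarray, start: np.ndarray,
                  positions: np.ndarray, chrom_length: int,
                  morgans: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent draw (crossovers ~ Poisson over a
    uniform genetic map)."""
    g = len(parents)
    out = np.empty((g, hap.shape[1]), dtype=np.uint8)
    k = rng.poisson(morgans, g) if morgans > 0 else np.zeros(g, dtype=np.int64)

    none = k == 0
    out[none] = hap[2 * parents[none] + start[none]]

    one = np.flatnonzero(k == 1)
    if len(one):
        x = rng.random(len(one)) * chrom_length
        a = hap[2 * parents[one] + start[one]]
        b = hap[2 * parents[one] + 1 - start[one]]
        out[one] = np.where(positions[None, :] >= x[:, None], b, a)

    for i in np.flatnonzero(k >= 2):
        x = np.sort(rng.random(k[i]) * chrom_length)
        parity = np.searchsorted(x, positions, side="right") % 2
        a = hap[2 * parents[i] + start[i]]
        b = hap[2 * parents[i] + 1 - start[i]]
        out[i] = np.where(parity == 1, b, a)
    return out


def forward_simulate(config: SimConfig) -> SimResult:
    """Run the boom-bust Wright-Fisher simulation.

    Neutral loci start at frequency 0.5 in linkage equilibrium; selected
    loci start at the fall peak (0.5 + amplitude/2) since the simulation
    opens at the start of winter.  Spring pseudo-pool samples are taken at
    the first generation of population expansion, fall samples at the last;
    the trough (end of winter) is also recorded so the designed
    peak-to-trough amplitude can be measured.  Mean neutral FST is the
    corrected pool-seq estimator averaged over defined neutral loci and the
    within-cycle spring-fall pairs of the last three cycles.
    """
    rng = np.random.default_rng(config.seed)
    s_summer, s_winter = calibrate_selection(config)

    # equidistant selected loci, uniform neutral loci
    sel_pos = ((np.arange(config.n_selected) + 1)
               * config.chrom_length / (config.n_selected + 1)).astype(np.int64) \
        if config.n_selected else np.empty(0, dtype=np.int64)
    neu_pos = np.sort(rng.integers(0, config.chrom_length, config.n_neutral))
    positions = np.concatenate([sel_pos, neu_pos])
    is_selected = np.r_[np.ones(len(sel_pos), bool), np.zeros(len(neu_pos), bool)]
    order = np.argsort(positions, kind="stable")
    positions, is_selected = positions[order], is_selected[order]
    sel_cols = np.flatnonzero(is_selected)
    neu_cols = np.flatnonzero(~is_selected)

    f_peak = 0.5 + config.amplitude / 2.0
    init_f = np.where(is_selected, f_peak, 0.5)
    sched = _schedule(config)
    total = len(sched)

    sample_gens = _sample_generations(config)
    wanted_gens = {g for cyc in sample_gens[-3:] for g in
                   (cyc["spring_gen"], cyc["fall_gen"])}

    sel_traj = np.empty((total + 1, len(sel_cols)))
    neutral_traj = (np.empty((total + 1, len(neu_cols)))
                    if config.record_trajectories else None)
    pop_sizes = np.empty(total + 1, dtype=np.int64)
    true_freqs: dict[int, np.ndarray] = {}
    pool_counts: dict[int, np.ndarray] = {}

    if config.deterministic:
        freqs = init_f.copy()
        pop_sizes[:] = [config.n_max] + [n for n, _ in sched]
        sel_traj[0] = freqs[sel_cols]
        if neutral_traj is not None:
            neutral_traj[0] = freqs[neu_cols]
        for g, (_, season) in enumerate(sched, start=1):
            s = s_summer if season == "summer" else s_winter
            freqs[sel_cols] = invlogit(logit(freqs[sel_cols]) + s)
            sel_traj[g] = freqs[sel_cols]
            if neutral_traj is not None:
                neutral_traj[g] = freqs[neu_cols]
            if g in wanted_gens:
                true_freqs[g] = freqs.copy()
                pool_counts[g] = _pseudo_pool(freqs, config, rng)
        return _finalise(config, positions, is_selected, sel_traj,
                         neutral_traj, pop_sizes, sample_gens, true_freqs,
                         pool_counts)

    morgans = config.recomb_rate / 100.0 * config.chrom_length / 1e6
    n0 = config.n_max
    hap = (rng.random((2 * n0, len(positions))) < init_f[None, :]).astype(np.uint8)
    pop_sizes[0] = n0
    sel_traj[0] = hap[:, sel_cols].mean(axis=0) if len(sel_cols) else np.empty(0)
    if neutral_traj is not None:
        neutral_traj[0] = hap[:, neu_cols].mean(axis=0)
    log_w = None

    for g, (n_next, season) in enumerate(sched, start=1):
        n_now = hap.shape[0] // 2
        s = s_summer if season == "summer" else s_winter
        if len(sel_cols) and s != 0.0:
            counts = (hap[0::2, :][:, sel_cols].astype(np.int16)
                      + hap[1::2, :][:, sel_cols])
            log_w = s * counts.sum(axis=1, dtype=np.float64)
            w = np.exp(log_w - log_w.max())
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            parents = np.searchsorted(cdf, rng.random(2 * n_next), side="right")
        else:
            parents = rng.integers(0, n_now, 2 * n_next)
        start = rng.integers(0, 2, 2 * n_next).astype(np.int64)
        hap = _make_gametes(hap, parents.astype(np.int64), start, positions,
                            config.chrom_length, morgans, rng)
        pop_sizes[g] = n_next
        if len(sel_cols):
            sel_traj[g] = hap[:, sel_cols].mean(axis=0)
        if neutral_traj is not None:
            neutral_traj[g] = hap[:, neu_cols].mean(axis=0)
        if g in wanted_gens:
            f = hap.mean(axis=0)
            true_freqs[g] = f
            pool_counts[g] = _pseudo_pool(f, config, rng)

    return _finalise(config, positions, is_selected, sel_traj, neutral_traj,
                     pop_sizes, sample_gens, true_freqs, pool_counts)


def _sample_generations(config: SimConfig) -> list[dict]:
    out = []
    for c in range(config.n_cycles):
        base = c * config.cycle_gens
        trough = base + config.winter_gens
        out.append({"cycle": c, "trough_gen": trough,
                    "spring_gen": trough + 1,
                    "fall_gen": base + config.cycle_gens})
    return out


def _pseudo_pool(freqs: np.ndarray, config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    k = rng.binomial(config.sample_n_chr, np.clip(freqs, 0.0, 1.0))
    return rng.binomial(config.sample_depth, k / config.sample_n_chr)


def _finalise(config, positions, is_selected, sel_traj, neutral_traj,
              pop_sizes, sample_gens, true_freqs, pool_counts) -> SimResult:
    neu_cols = np.flatnonzero(~is_selected)
    neff = effective_n(config.sample_n_chr, config.sample_depth)
    fsts = []
    for cyc in sample_gens[-3:]:
        sg, fg = cyc["spring_gen"], cyc["fall_gen"]
        if sg not in pool_counts or fg not in pool_counts:
            continue
        p1 = pool_counts[sg][neu_cols] / config.sample_depth
        p2 = pool_counts[fg][neu_cols] / config.sample_depth
        vals = snp_fst(p1, p2, neff, neff)
        fsts.append(float(np.nanmean(vals)))
    fst_per_cycle = np.asarray(fsts)

    sel_cols_traj = sel_traj  # (gens+1, n_sel)
    amps = []
    for cyc in sample_gens[-3:]:
        if sel_cols_traj.shape[1]:
            amps.append(np.abs(sel_cols_traj[cyc["fall_gen"]]
                               - sel_cols_traj[cyc["trough_gen"]]))
    amplitude_obs = float(np.mean(amps)) if amps else float("nan")
    n_fixed = int(((sel_cols_traj[-1] == 0.0) | (sel_cols_traj[-1] == 1.0)).sum()) \
        if sel_cols_traj.shape[1] else 0
    if n_fixed:
        logger.info("forward_simulate: %d selected loci fixed (oscillation "
                    "broken)", n_fixed)
    return SimResult(config=config, positions=positions,
                     is_selected=is_selected, sel_traj=sel_traj,
                     neutral_traj=neutral_traj, pop_sizes=pop_sizes,
                     cycles=sample_gens, true_freqs=true_freqs,
                     pool_counts=pool_counts,
                     mean_neutral_fst=float(fst_per_cycle.mean()),
                     fst_per_cycle=fst_per_cycle,
                     amplitude_observed=amplitude_obs,
                     n_fixed_selected=n_fixed)


def sweep_fst_grid(n_min_grid, n_selected_grid, reps: int, config: SimConfig,
                   seed: int = 0) -> pd.DataFrame:
    """Mean neutral spring-fall FST over a grid of overwintering sizes and
    numbers of seasonally selected loci, averaged over replicate seeds."""
    if reps < 3:
        raise ValueError("reps must be >= 3")
    ss = np.random.SeedSequence(seed)
    rows = []
    for n_min in n_min_grid:
        for n_sel in n_selected_grid:
            vals = []
            for child in ss.spawn(reps):
                cfg = replace(config, n_min=int(n_min), n_selected=int(n_sel),
                              seed=int(child.generate_state(1)[0] % (2**31)))
                vals.append(forward_simulate(cfg).mean_neutral_fst)
            rows.append({"n_min": int(n_min), "n_selected": int(n_sel),
                         "mean_fst": float(np.mean(vals)),
                         "sd_fst": float(np.std(vals, ddof=1)),
                         "reps": reps})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bottleneck SFS
# ---------------------------------------------------------------------------


def bottleneck_sfs(n_bottleneck: int, gens: int, n_snps: int,
                   pre_freqs=None, sample_n_chr: int = 100,
                   sample_depth: int = 100, n_bins: int = 20,
                   seed: int = 0) -> dict:
    """Site frequency spectrum before and after a short bottleneck.

    Each SNP's frequency is evolved by ``gens`` rounds of binomial sampling
    of 2*n_bottleneck chromosomes, then both the pre and post states are
    pseudo-pool sampled.  Sampled frequencies below 2/depth or above
    1 - 2/depth are excluded from the spectra (sequencing-error guard).
    """
    if n_bottleneck < 2:
        raise ValueError("n_bottleneck must be >= 2")
    if gens not in (1, 2):
        raise ValueError("gens must be 1 or 2")
    rng = np.random.default_rng(seed)
    if pre_freqs is None:
        # neutral-equilibrium-shaped spectrum: density ~ 1/f on [2e-3, 0.5],
        # alt/ref orientation randomised
        u = rng.random(n_snps)
        lo_f = 2e-3
        f0 = lo_f * (0.5 / lo_f) ** u
        flip = rng.random(n_snps) < 0.5
        f0 = np.where(flip, 1.0 - f0, f0)
    elif callable(pre_freqs):
        f0 = np.asarray(pre_freqs(rng, n_snps), dtype=float)
    else:
        f0 = np.asarray(pre_freqs, dtype=float)

    f = f0.copy()
    for _ in range(gens):
        f = rng.binomial(2 * n_bottleneck, f) / (2.0 * n_bottleneck)

    def sampled(freq):
        k = rng.binomial(sample_n_chr, freq)
        reads = rng.binomial(sample_depth, k / sample_n_chr)
        return reads / sample_depth

    lo, hi = 2.0 / sample_depth, 1.0 - 2.0 / sample_depth
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def spectrum(freq):
        obs = sampled(freq)
        keep = (obs > lo) & (obs < hi)
        h, _ = np.histogram(obs[keep], bins=edges)
        return h / max(keep.sum(), 1), obs

    pre_sfs, pre_obs = spectrum(f0)
    post_sfs, post_obs = spectrum(f)
    return {"edges": edges, "pre_sfs": pre_sfs, "post_sfs": post_sfs,
            "pre_freqs": f0, "post_freqs": f, "pre_sampled": pre_obs,
            "post_sampled": post_obs}


# ---------------------------------------------------------------------------
# migration / recolonisation cycling model
# ---------------------------------------------------------------------------


def migration_cycling_expectation(n_founders: int, refugium_freqs,
                                  deviation_threshold: float,
                                  n_years: int = 3) -> float:
    """Expected number of SNPs that appear to cycle seasonally by founder
    sampling alone.

    Each spring the orchard is re-founded by ``n_founders`` diploid
    migrants from a refugium with stable frequencies; a SNP "cycles" if the
    founder frequency deviates from the refugium frequency by at least the
    threshold in the same direction ``n_years`` springs in a row.  Exact
    binomial tail summation per SNP.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if not 0.0 < deviation_threshold < 1.0:
        raise ValueError("deviation_threshold must be in (0, 1)")
    f = np.asarray(refugium_freqs, dtype=float)
    n = 2 * n_founders
    eps = 1e-12
    hi = np.ceil(n * (f + deviation_threshold) - eps)
    lo = np.floor(n * (f - deviation_threshold) + eps)
    p_up = stats.binom.sf(hi - 1.0, n, f)         # P(k >= hi)
    p_down = stats.binom.cdf(lo, n, f)            # P(k <= lo)
    p_up = np.where(hi > n, 0.0, p_up)
    p_down = np.where(lo < 0, 0.0, p_down)
    p_cycle = p_up ** n_years + p_down ** n_years
    expected = float(p_cycle.sum())
    if expected == 0.0:
        warnings.warn("deviation threshold exceeds any achievable founder "
                      "deviation; expected count is 0", stacklevel=2)
    return expected


# ---------------------------------------------------------------------------
# truncation selection minimum census
# ---------------------------------------------------------------------------


POISSON_TAIL_SENTINEL = 1e15


def _poisson_tail(lam: float, target: float) -> float:
    """P(X >= ceil(target)) for X ~ Poisson(lam)."""
    if target <= 0:
        return 1.0
    return float(stats.poisson.sf(np.ceil(target) - 1.0, lam))


def truncation_min_census(n_loci_grid, delta_source=None, rounds: int = 1,
                          n_resamples: int = 500, seed: int = 0
                          ) -> pd.DataFrame:
    """Minimum fall census size for a given number of independently
    responding seasonal loci under truncation selection.

    The expected number of winter alleles per diploid is 2*sum(f) over
    loci; if loci segregate independently the count is ~Poisson.  The
    surviving fraction is the Poisson upper-tail probability of carrying
    the spring-expected number of winter alleles when the mean is the
    fall-expected number; the minimum census is the reciprocal of that
    fraction.  ``rounds = 2`` splits the logit displacement into two equal
    selection episodes and multiplies the two tail probabilities.

    ``delta_source`` is None for the fixed 0.40 -> 0.60 shift per locus, or
    an (m, 2) array of per-locus (f_fall, f_spring) winter-allele
    frequencies resampled with replacement.
    """
    if rounds not in (1, 2):
        raise ValueError("rounds must be 1 or 2")
    rng = np.random.default_rng(seed)
    fixed = delta_source is None
    if not fixed:
        pairs = np.asarray(delta_source, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("delta_source must be an (m, 2) array of "
                             "(f_fall, f_spring) pairs")
    rows = []
    for n_loci in n_loci_grid:
        n_loci = int(n_loci)
        census = np.empty(n_resamples if not fixed else 1)
        reps = 1 if fixed else n_resamples
        for r in range(reps):
            if n_loci == 0:
                census[r] = 1.0
                continue
            if fixed:
                f_fall = np.full(n_loci, 0.4)
                f_spring = np.full(n_loci, 0.6)
            else:
                take = rng.integers(0, len(pairs), n_loci)
                f_fall, f_spring = pairs[take, 0], pairs[take, 1]
            if rounds == 1:
                tail = _poisson_tail(2.0 * f_fall.sum(), 2.0 * f_spring.sum())
            else:
                f_mid = invlogit(0.5 * (logit(f_fall) + logit(f_spring)))
                tail = (_poisson_tail(2.0 * f_fall.sum(), 2.0 * f_mid.sum())
                        * _poisson_tail(2.0 * f_mid.sum(), 2.0 * f_spring.sum()))
            census[r] = POISSON_TAIL_SENTINEL if tail <= 0 else np.ceil(1.0 / tail)
        rows.append({"n_loci": n_loci,
                     "min_census": float(np.median(census[:reps])),
                     "ci_low": float(np.percentile(census[:reps], 2.5)),
                     "ci_high": float(np.percentile(census[:reps], 97.5)),
                     "rounds": rounds})
    return pd.DataFrame(rows)
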