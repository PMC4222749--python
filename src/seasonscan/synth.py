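"""Synthetic pooled-resequencing study generator with known truth.

Emulates the sampling design of the field study the pipeline targets: six
Pennsylvania spring/fall pools over three consecutive years plus five
clinal pools spanning ~25–45° latitude, ~100 pooled chromosomes per sample
and negative-binomially dispersed 20–200x read depths.  Planted seasonal
SNPs oscillate ~20 percentage points between spring and fall (symmetric
about the base frequency on the natural scale); planted clinal SNPs follow
a logit-linear latitude trend centred at 40°.  Every downstream stage can
therefore be tested against the generating truth without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Role, SampleMeta, Season, SnpTable

logger = logging.getLogger("seasonscan")

GENIC_CLASSES = np.array(["nonsyn", "syn", "utr3", "utr5", "short_intron",
                          "long_intron", "intergenic"])
GENIC_PROBS = np.array([0.08, 0.12, 0.05, 0.03, 0.07, 0.25, 0.40])

CLINE_CENTER_LAT = 40.0
FREQ_CLIP = (0.01, 0.99)


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def default_study_plan() -> list[tuple[SampleMeta, float, float]]:
    """The emulated study design: (sample, mean depth, depth shape) tuples.

    Six Pennsylvania spring/fall samples over 2009–2011 plus five clinal
    samples from 25° to 45°; 100 pooled chromosomes each; mean depth 80x
    with negative-binomial dispersion spanning roughly 20–200x.
    """
    plan = []
    for year in (2009, 2010, 2011):
        for season in (Season.SPRING, Season.FALL):
            sid = f"PA_{year}_{season.value}"
            plan.append((SampleMeta(sid, "PA_orchard", 39.9, season, year, 100,
                                    Role.PENNSYLVANIA_SERIES), 80.0, 10.0))
    for lat, name in [(25.5, "FL"), (30.0, "GA"), (35.0, "NC"), (39.0, "MD"),
                      (44.8, "ME")]:
        sid = f"CL_{name}"
        plan.append((SampleMeta(sid, name, lat, Season.OTHER, 2010, 100,
                                Role.CLINAL), 80.0, 10.0))
    return plan


def frost_study_plan() -> list[tuple[SampleMeta, float, float]]:
    """Study plan extended with the acute-frost contrast: a post-frost
    sample follows the 2011 fall sample (which doubles as the pre-frost
    sample, as in the emulated study), and the 2009–2010 samples provide
    the long-term reference."""
    plan = default_study_plan()
    plan.append((SampleMeta("PA_2011_postfrost", "PA_orchard", 39.9,
                            Season.OTHER, 2011, 100, Role.FROST_POST),
                 80.0, 10.0))
    return plan


@dataclass
class TruthConfig:
    n_snps: int = 5000
    chrom_plan: tuple = (("2L", 23_000_000), ("2R", 21_000_000),
                         ("3L", 24_000_000), ("3R", 28_000_000),
                         ("X", 22_000_000))
    recomb_rate: float = 2.0
    base_freq_range: tuple = (0.15, 0.85)
    frac_seasonal: float = 0.0
    seasonal_amplitude: float = 0.20
    frac_clinal: float = 0.0
    clinal_slope_sd: float = 0.05  # logit units per degree latitude
    sampling_plan: list = field(default_factory=default_study_plan)
    frost_shift: float = 0.0  # fraction of the fall->spring displacement
    gwas_concordance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.frac_seasonal + self.frac_clinal > 1.0:
            raise ValueError("frac_seasonal + frac_clinal must be <= 1")
        if not 0.0 <= self.frost_shift <= 1.0:
            raise ValueError("frost_shift must be in [0, 1]")


def simulate_truth(config: TruthConfig) -> pd.DataFrame:
    """Draw the per-SNP truth table: class, base frequency, signed seasonal
    amplitude (positive = alt higher in spring) and clinal slope."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    names = [c for c, _ in config.chrom_plan]
    lengths = np.array([l for _, l in config.chrom_plan], dtype=float)
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[ci]).astype(np.int64)
    # deduplicate (chrom,pos) collisions by redrawing
    for _ in range(20):
        df = pd.DataFrame({"ci": ci, "pos": pos})
        dup = df.duplicated().to_numpy()
        if not dup.any():
            break
        pos[dup] = (rng.random(dup.sum()) * lengths[ci[dup]]).astype(np.int64)

    cls = rng.choice(
        ["seasonal", "clinal", "neutral"], size=n,
        p=[config.frac_seasonal, config.frac_clinal,
           1.0 - config.frac_seasonal - config.frac_clinal])
    base = rng.uniform(*config.base_freq_range, size=n)
    amp = np.zeros(n)
    seas = cls == "seasonal"
    amp[seas] = rng.choice([-1.0, 1.0], size=seas.sum()) * config.seasonal_amplitude
    # redraw SNPs whose amplitude is infeasible for their base frequency
    bad = seas & ((base + np.abs(amp) / 2 >= 1.0) | (base - np.abs(amp) / 2 <= 0.0))
    if bad.any():
        logger.info("simulate_truth: redrew %d infeasible seasonal bases",
                    int(bad.sum()))
        lo = FREQ_CLIP[0] + config.seasonal_amplitude / 2
        base[bad] = rng.uniform(max(lo, config.base_freq_range[0]),
                                min(1 - lo, config.base_freq_range[1]),
                                size=bad.sum())
    slope = np.zeros(n)
    clin = cls == "clinal"
    slope[clin] = rng.normal(0.0, config.clinal_slope_sd, size=clin.sum())

    ref, alt = _draw_alleles(rng, n)
    truth = pd.DataFrame({
        "chrom": np.asarray(names)[ci], "pos": pos, "ref": ref, "alt": alt,
        "class": cls, "base_freq": base, "amplitude": amp,
        "clinal_slope": slope,
    })
    return truth.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _draw_alleles(rng: np.random.Generator, n: int):
    nts = np.array(list("ACGT"))
    ref = nts[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    alt = nts[(np.searchsorted(nts, ref) + shift) % 4]
    return ref, alt


def expected_freq(truth: pd.DataFrame, sample: SampleMeta,
                  frost_shift: float = 0.0) -> np.ndarray:
    """True alt-allele frequency of each SNP in a given sample.

    Seasonal SNPs sit at base ± amplitude/2 (spring +, fall −, clipped to
    [0.01, 0.99]); clinal SNPs follow a logit-linear latitude trend centred
    at 40°; a post-frost sample lies ``frost_shift`` of the way back from
    the fall frequency towards the spring frequency.
    """
    base = truth["base_freq"].to_numpy()
    amp = truth["amplitude"].to_numpy()
    slope = truth["clinal_slope"].to_numpy()
    f_spring = np.clip(base + amp / 2.0, *FREQ_CLIP)
    f_fall = np.clip(base - amp / 2.0, *FREQ_CLIP)
    if sample.role is Role.FROST_POST:
        return f_fall + frost_shift * (f_spring - f_fall)
    if sample.role is Role.FROST_PRE:
        return f_fall
    if sample.role is Role.CLINAL:
        return _invlogit(_logit(base) + slope * (sample.latitude - CLINE_CENTER_LAT))
    if sample.season is Season.SPRING:
        return f_spring
    if sample.season is Season.FALL:
        return f_fall
    return base.copy()


def sample_pool(true_freq, n_chr, depth, rng: np.random.Generator):
    """Two-stage pool-seq draw: k ~ Binomial(n_chr, f) chromosomes into the
    pool, then alt reads ~ Binomial(depth, k/n_chr)."""
    f = np.asarray(true_freq, dtype=float)
    n_chr_arr = np.broadcast_to(np.asarray(n_chr, dtype=np.int64), f.shape)
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=np.int64), f.shape)
    k = rng.binomial(n_chr_arr, f)
    return rng.binomial(depth_arr, k / n_chr_arr)


def simulate_study(truth: pd.DataFrame, config: TruthConfig
                   ) -> tuple[SnpTable, list[SampleMeta]]:
    """Generate the observed site-by-sample count table for a truth table.

    Depths are negative-binomial per (sample, SNP); counts go through the
    double-binomial pool sampling at each sample's expected frequency.
    Annotation columns (recombination rate, genic class, and a synthetic
    GWAS hit whose direction agrees with the winter-favoured phenotype
    prediction with probability ``gwas_concordance`` at seasonal SNPs) are
    attached so enrichment analyses can run end to end.
    """
    if not config.sampling_plan:
        raise ValueError("sampling_plan is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(truth)
    counts = {}
    metas = []
    for meta, mean_depth, shape in config.sampling_plan:
        p = shape / (shape + mean_depth)
        depth = np.maximum(rng.negative_binomial(shape, p, size=n), 1)
        f = expected_freq(truth, meta, config.frost_shift)
        n_chr = np.where(truth["chrom"].to_numpy() == "X",
                         meta.n_chr_x, meta.n_chr)
        ac = sample_pool(f, n_chr, depth, rng)
        counts[meta.sample_id] = (ac, depth)
        metas.append(meta)

    seasonal = (truth["class"] == "seasonal").to_numpy()
    concordant = rng.random(n) < config.gwas_concordance
    # the GWAS direction convention: +1 if the alt allele associates with
    # the winter phenotype; seasonal SNPs agree with their spring-favoured
    # allele with probability pi, everything else is a coin flip
    spring_alt = truth["amplitude"].to_numpy() > 0
    direction = np.where(rng.random(n) < 0.5, 1, -1)
    want = np.where(spring_alt, 1, -1)
    direction[seasonal] = np.where(concordant[seasonal], want[seasonal],
                                   -want[seasonal])
    annotations = pd.DataFrame({
        "genic_class": rng.choice(GENIC_CLASSES, size=n, p=GENIC_PROBS),
        "recomb_rate": np.maximum(rng.gamma(4.0, config.recomb_rate / 4.0,
                                            size=n), 0.01),
        "gwas_p": rng.uniform(0.0, 1.0, size=n),
        "gwas_direction": direction,
    })
    table = SnpTable.from_counts(truth["chrom"], truth["pos"], truth["ref"],
                                 truth["alt"], counts, annotations)
    return table, metas
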