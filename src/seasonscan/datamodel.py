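"""Data model and file I/O for pooled resequencing allele-count data.

The central container is :class:`SnpTable`, a thin wrapper around a pandas
DataFrame holding one row per biallelic SNP with per-sample alt read counts
and total depths, plus optional annotation columns (genic class,
recombination rate, inversion flags, GWAS hits, ...).  Sample-level metadata
(locale, latitude, season, year, pooled chromosomes) lives in
:class:`SampleMeta`.

Coordinates are 0-based half-open internally; 1-based in TSV/VCF files and
BED-native half-open in BED files.  Allele frequency always refers to the
alt allele; "minor" is computed where a statistic needs it, never stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("seasonscan")

NUCLEOTIDES = frozenset("ACGT")


class Season(str, Enum):
    SPRING = "spring"
    FALL = "fall"
    OTHER = "other"


class Role(str, Enum):
    PENNSYLVANIA_SERIES = "pennsylvania_series"
    CLINAL = "clinal"
    FROST_PRE = "frost_pre"
    FROST_POST = "frost_post"
    LONGTERM_REFERENCE = "longterm_reference"


@dataclass(frozen=True)
class SampleMeta:
    """One pooled sample of flies.

    ``n_chr`` is the autosomal count of pooled chromosomes (2 per pooled
    male).  Pools of males are hemizygous on the X, so ``n_chr_x`` defaults
    to ``n_chr // 2`` (one X per male); pass it explicitly for other designs.
    """

    sample_id: str
    locale: str
    latitude: float
    season: Season
    year: int
    n_chr: int
    role: Role = Role.PENNSYLVANIA_SERIES
    n_chr_x: int | None = None

    def __post_init__(self) -> None:
        if self.n_chr < 1:
            raise ValueError(f"{self.sample_id}: n_chr must be >= 1, got {self.n_chr}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"{self.sample_id}: latitude {self.latitude} outside [-90, 90]"
            )
        if self.n_chr_x is None:
            object.__setattr__(self, "n_chr_x", max(1, self.n_chr // 2))

    def chromosomes(self, chrom: str = "") -> int:
        """Pooled chromosome count for a chromosome name ('X' is hemizygous)."""
        return self.n_chr_x if chrom == "X" else self.n_chr


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable filtering / resampling parameters of the pipeline."""

    maf_min: float = 0.15
    depth_min: int = 10
    depth_max: int = 400
    seasonal_fdr: float = 0.3
    clinal_fdr: float = 0.1
    block_size: int = 50_000
    n_boot: int = 500
    n_control_sets: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if self.depth_min >= self.depth_max:
            raise ValueError("depth_min must be < depth_max")
        for name in ("depth_min", "block_size", "n_boot", "n_control_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


CORE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class SnpTable:
    """Site-by-sample allele count table.

    The underlying frame ``df`` has columns chrom, pos (0-based), ref, alt,
    then per-sample pairs ``<id>.alt`` / ``<id>.depth`` and any annotation
    columns.  Rows are unique on (chrom, pos).
    """

    def __init__(self, df: pd.DataFrame, samples: Sequence[str]):
        self.df = df.reset_index(drop=True)
        self.samples = list(samples)
        self.validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        counts: dict[str, tuple[np.ndarray, np.ndarray]],
        annotations: pd.DataFrame | None = None,
    ) -> "SnpTable":
        """Build a table from arrays; ``counts[s] = (alt_count, depth)``."""
        data: dict = {"chrom": list(chrom), "pos": np.asarray(pos, dtype=np.int64),
                      "ref": list(ref), "alt": list(alt)}
        for sid, (ac, dp) in counts.items():
            data[f"{sid}.alt"] = np.asarray(ac, dtype=np.int64)
            data[f"{sid}.depth"] = np.asarray(dp, dtype=np.int64)
        df = pd.DataFrame(data)
        if annotations is not None:
            df = pd.concat([df, annotations.reset_index(drop=True)], axis=1)
        return cls(df, list(counts))

    def validate(self) -> None:
        df = self.df
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"SnpTable missing columns {missing}")
        for sid in self.samples:
            for suffix in (".alt", ".depth"):
                if f"{sid}{suffix}" not in df.columns:
                    raise ValueError(f"SnpTable missing column {sid}{suffix}")
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        bad_alleles = ~(df["ref"].isin(NUCLEOTIDES) & df["alt"].isin(NUCLEOTIDES))
        if bad_alleles.any():
            row = df[bad_alleles].iloc[0]
            raise ValueError(f"non-ACGT alleles at {row.chrom}:{row.pos}")
        if (df["ref"] == df["alt"]).any():
            row = df[df["ref"] == df["alt"]].iloc[0]
            raise ValueError(f"ref == alt at {row.chrom}:{row.pos}")
        for sid in self.samples:
            ac, dp = df[f"{sid}.alt"].to_numpy(), df[f"{sid}.depth"].to_numpy()
            bad = (ac < 0) | (dp < 0) | (ac > dp)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"sample {sid}: alt_count {ac[i]} > depth {dp[i]} at "
                    f"{df['chrom'].iat[i]}:{df['pos'].iat[i]}"
                )

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def alt_counts(self, sample_id: str) -> np.ndarray:
        return self.df[f"{sample_id}.alt"].to_numpy(dtype=np.int64)

    def depths(self, sample_id: str) -> np.ndarray:
        return self.df[f"{sample_id}.depth"].to_numpy(dtype=np.int64)

    def freqs(self, sample_id: str) -> np.ndarray:
        """Alt-allele frequency estimates (NaN where depth is 0)."""
        dp = self.depths(sample_id).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(dp > 0, self.alt_counts(sample_id) / dp, np.nan)

    def freq_matrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        """(n_snps, n_samples) alt frequency matrix."""
        return np.column_stack([self.freqs(s) for s in sample_ids])

    def depth_matrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.depths(s) for s in sample_ids])

    def subset(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(self.df.loc[np.asarray(mask)], self.samples)

    def annotation_columns(self) -> list[str]:
        reserved = set(CORE_COLUMNS)
        for sid in self.samples:
            reserved.update((f"{sid}.alt", f"{sid}.depth"))
        return [c for c in self.df.columns if c not in reserved]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _samples_from_columns(columns: Iterable[str]) -> list[str]:
    samples = []
    for c in columns:
        if c.endswith(".alt"):
            sid = c[: -len(".alt")]
            if f"{sid}.depth" in columns:
                samples.append(sid)
    return samples


def read_snp_table(path: str | Path, format: str = "tsv") -> SnpTable:
    """Read an allele-count table from TSV or a biallelic-SNP VCF.

    TSV columns: chrom, pos (1-based), ref, alt, then per-sample
    ``<id>.alt`` / ``<id>.depth``.  VCF records must carry a per-sample AD
    field; multiallelic records and indels are skipped with a logged count.
    Positions are converted to the internal 0-based convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_snp_tsv(path)
    if format == "vcf":
        return _read_snp_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_snp_tsv(path: Path) -> SnpTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["pos"] = df["pos"].astype(np.int64) - 1  # file is 1-based
    return SnpTable(df, _samples_from_columns(list(df.columns)))


def _read_snp_vcf(path: Path) -> SnpTable:
    import pysam

    records: list[dict] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or rec.ref not in NUCLEOTIDES or alts[0] not in NUCLEOTIDES:
                skipped += 1
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos - 1, "ref": rec.ref,
                   "alt": alts[0]}
            for sid in sample_ids:
                ad = rec.samples[sid].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise ValueError(f"{path}: missing AD for {sid} at "
                                     f"{rec.chrom}:{rec.pos}")
                row[f"{sid}.alt"] = int(ad[1])
                row[f"{sid}.depth"] = int(ad[0]) + int(ad[1])
            records.append(row)
    if skipped:
        logger.info("read_snp_table: skipped %d non-biallelic-SNP records", skipped)
    df = pd.DataFrame(records)
    table = SnpTable(df, sample_ids)
    table.n_skipped = skipped  # type: ignore[attr-defined]
    return table


def write_snp_table(path: str | Path, table: SnpTable) -> None:
    """Write the TSV dialect (1-based positions)."""
    out = table.df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, locale, latitude,
    season, year, n_chr and optionally role, n_chr_x."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("read_sample_metadata: %s is empty", path)
        return []
    required = ["sample_id", "locale", "latitude", "season", "year", "n_chr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    metas = []
    seen_py: set[tuple] = set()
    for _, row in df.iterrows():
        try:
            season = Season(row["season"])
        except ValueError as exc:
            raise ValueError(f"unknown season token {row['season']!r}") from exc
        role = Role(row["role"]) if "role" in df.columns else Role.PENNSYLVANIA_SERIES
        n_chr_x = int(row["n_chr_x"]) if "n_chr_x" in df.columns and \
            pd.notna(row.get("n_chr_x")) else None
        meta = SampleMeta(str(row["sample_id"]), str(row["locale"]),
                          float(row["latitude"]), season, int(row["year"]),
                          int(row["n_chr"]), role, n_chr_x)
        if role is Role.PENNSYLVANIA_SERIES:
            key = (season, int(row["year"]))
            if key in seen_py:
                raise ValueError(f"duplicate (season, year) {key} in the "
                                 "Pennsylvania series")
            seen_py.add(key)
        metas.append(meta)
    return metas


def write_sample_metadata(path: str | Path, metas: Sequence[SampleMeta]) -> None:
    rows = [{"sample_id": m.sample_id, "locale": m.locale, "latitude": m.latitude,
             "season": m.season.value, "year": m.year, "n_chr": m.n_chr,
             "role": m.role.value, "n_chr_x": m.n_chr_x} for m in metas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------


def filter_snps(table: SnpTable, config: AnalysisConfig) -> tuple[SnpTable, dict]:
    """Apply the common-SNP filters.

    Keeps SNPs whose across-sample mean minor allele frequency is at least
    ``maf_min`` and whose depth in *every* sample lies in
    [depth_min, depth_max].  Returns the filtered table plus removal counts
    by reason (a SNP failing both is counted under 'depth').
    """
    freqs = table.freq_matrix(table.samples)
    depths = table.depth_matrix(table.samples)
    mean_f = np.nanmean(freqs, axis=1)
    maf = np.minimum(mean_f, 1.0 - mean_f)
    maf_ok = maf >= config.maf_min
    depth_ok = ((depths >= config.depth_min) & (depths <= config.depth_max)).all(axis=1)
    keep = maf_ok & depth_ok
    removed = {
        "depth": int((~depth_ok).sum()),
        "maf": int((~maf_ok & depth_ok).sum()),
    }
    logger.info("filter_snps: kept %d / %d SNPs (removed: %s)",
                int(keep.sum()), len(table), removed)
    return table.subset(keep), removed


# ---------------------------------------------------------------------------
# BED regions & scan-result round trip
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSet:
    """Merged, sorted 0-based half-open genomic intervals."""

    regions: tuple[tuple[str, int, int], ...]

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.regions)

    def mask(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        for c, s, e in self.regions:
            out |= (chroms == c) & (positions >= s) & (positions < e)
        return out


def read_bed_regions(path: str | Path) -> RegionSet:
    """Read a BED file; overlapping intervals are merged with a warning."""
    raw: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}")
        raw.append((parts[0], int(parts[1]), int(parts[2])))
    raw.sort()
    merged: list[list] = []
    n_merged = 0
    for chrom, start, end in raw:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            n_merged += 1
        else:
            merged.append([chrom, start, end])
    if n_merged:
        logger.warning("read_bed_regions: merged %d overlapping intervals", n_merged)
    return RegionSet(tuple((c, s, e) for c, s, e in merged))


def write_scan_results(path: str | Path, records: pd.DataFrame) -> None:
    """Write scan records (1-based positions in the file)."""
    out = records.copy()
    if "pos" in out.columns:
        out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scan_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(np.int64) - 1
    return df
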