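"""In-memory containers shared by all pipeline stages.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED/bedGraph style)
  everywhere in memory; VCF positions are converted on ingest.
* Methylation is stored as a fraction in [0, 1]; missing cells are NaN.
* Genotypes are additive codes 1 (major homozygote), 2 (heterozygote),
  3 (minor homozygote); missing codes are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")

MISSING = np.nan


def position_id(chrom: str, start: int, end: int) -> str:
    """Canonical row identifier, e.g. ``MA_160146:1616-1617``."""
    return f"{chrom}:{start}-{end}"


def parse_position_id(pid: str) -> tuple[str, int, int]:
    chrom, _, span = pid.rpartition(":")
    start, _, end = span.partition("-")
    if not chrom or not start or not end:
        raise ValueError(f"unparseable position id: {pid!r}")
    return chrom, int(start), int(end)


def snp_id(chrom: str, start: int) -> str:
    """Canonical variant identifier (0-based start), e.g. ``chr1:41``."""
    return f"{chrom}:{start}"


@dataclass
class SampleFrame:
    """Ordered samples with one environment value and optional covariates.

    Parameters
    ----------
    sample_ids : list of str
        Unique, non-empty sample identifiers; this order is the canonical
        sample order for every matrix in the pipeline.
    env : 1-D float array
        One environment / phenotype value per sample.
    covariates : DataFrame
        One column per covariate (``cov1`` ..), numeric or categorical,
        indexed like ``sample_ids``.
    """

    sample_ids: list[str]
    env: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise ValueError("SampleFrame needs at least one sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Series(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.env = np.asarray(self.env, dtype=float)
        if self.env.shape != (len(self.sample_ids),):
            raise ValueError("env must have one value per sample")
        if not np.all(np.isfinite(self.env)):
            raise ValueError("non-numeric or missing environment value")
        if self.covariates is None or len(self.covariates.columns) == 0:
            self.covariates = pd.DataFrame(index=pd.Index(self.sample_ids))
        else:
            if len(self.covariates) != len(self.sample_ids):
                raise ValueError("covariates must align with samples")
            self.covariates = self.covariates.set_axis(pd.Index(self.sample_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class MethylationMatrix:
    """Positions x samples grid of methylation fractions with NaN missing.

    ``positions`` carries chrom/start/end/context per row, aligned with the
    rows of ``values``; ``samples`` matches the SampleFrame order.
    """

    positions: pd.DataFrame  # columns chrom, start, end, context
    samples: list[str]
    values: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), len(self.samples)):
            raise ValueError("values shape must be (n_positions, n_samples)")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if np.any(bad):
            raise ValueError("methylation fractions must lie in [0, 1]")
        self.positions = self.positions.reset_index(drop=True)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def row_ids(self) -> pd.Series:
        p = self.positions
        return p["chrom"].astype(str) + ":" + p["start"].astype(str) + "-" + p["end"].astype(str)

    def is_sorted(self) -> bool:
        p = self.positions
        key = list(zip(p["chrom"], p["start"]))
        return key == sorted(key)

    def take_rows(self, idx: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            positions=self.positions.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            values=self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """positions metadata + one column per sample (NaN = missing)."""
        df = self.positions.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.values[:, j]
        return df


@dataclass
class GenotypeMatrix:
    """Variants x samples grid of additive genotype codes {1,2,3}, NaN missing."""

    variants: pd.DataFrame  # columns chrom, pos (1-based), start (0-based), ref, alt, qual
    samples: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("codes shape must be (n_variants, n_samples)")
        observed = self.codes[~np.isnan(self.codes)]
        if not np.all(np.isin(observed, (1.0, 2.0, 3.0))):
            raise ValueError("genotype codes must be 1, 2, 3 or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def snp_ids(self) -> pd.Series:
        v = self.variants
        return v["chrom"].astype(str) + ":" + v["start"].astype(str)

    def take_rows(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            codes=self.codes[idx],
        )


@dataclass
class RegionSet:
    """Genomic intervals tagged with the pairwise comparison they came from."""

    intervals: pd.DataFrame  # columns chrom, start, end, label
    merged_flag: bool = False

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("region start must be < end")
        self.intervals = iv

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique()) if len(self.intervals) else []

    def __len__(self) -> int:
        return len(self.intervals)


def empty_region_set() -> RegionSet:
    return RegionSet(
        intervals=pd.DataFrame(columns=["chrom", "start", "end", "label"]),
    )


# An AssociationTable is a plain DataFrame with columns
#   id [, snp], beta, stat, pvalue [, fdr]
# kept as pandas so it composes with the field's usual tooling.
ASSOC_COLUMNS = ["id", "beta", "stat", "pvalue", "fdr"]
ASSOC_COLUMNS_SNP = ["id", "snp", "beta", "stat", "pvalue", "fdr"]


def empty_association_table(with_snp: bool) -> pd.DataFrame:
    cols = ASSOC_COLUMNS_SNP if with_snp else ASSOC_COLUMNS
    return pd.DataFrame({c: pd.Series(dtype=(str if c in ("id", "snp") else float)) for c in cols})
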