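"""Missing-data handling: NA filtering and beta-distribution imputation.

A missing methylation cell is replaced by a draw from a beta distribution
fitted (by the method of moments) to the observed values of the other
samples at the same position, so the imputed value carries the position's
own mean and spread and has minimal pull on the downstream regression.
Crucially the random stream is keyed per cell — (chrom, start, sample,
seed) — so an imputed value never depends on which other rows happen to
be in the matrix.  This is what makes chunked runs (e.g. by scaffold)
give identical p-values to a single run; a global-mean fill computed
from "the rest of the sample" does not have that property.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix, MethylationMatrix

_DEGENERATE_VAR = 1e-12


@dataclass
class BetaParams:
    """Moment-fitted Beta(alpha, beta); degenerate rows keep only the mean."""

    alpha: float
    beta: float
    degenerate: bool
    mean: float


def filter_missing(matrix: MethylationMatrix, max_na_fraction: float) -> MethylationMatrix:
    """Keep rows whose fraction of missing cells is <= ``max_na_fraction``.

    ``max_na_fraction=0`` is the zero-tolerance setting: only rows
    observed in every sample survive.
    """
    if not 0.0 <= max_na_fraction <= 1.0:
        raise ValueError("max_na_fraction must be in [0, 1]")
    frac = np.mean(np.isnan(matrix.values), axis=1)
    return matrix.take_rows(np.flatnonzero(frac <= max_na_fraction))


def fit_beta_moments(values: np.ndarray) -> BetaParams:
    """Method-of-moments beta fit to observed fractions at one position.

    With sample mean m and sample variance v, c = m(1-m)/v - 1 gives
    alpha = m*c and beta = (1-m)*c.  The fit is degenerate (fall back to
    the mean) when the variance vanishes or c <= 0, i.e. when the spread
    exceeds what any beta distribution with that mean allows.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 observed values to fit")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    m = float(np.mean(values))
    v = float(np.var(values, ddof=1))
    if v < _DEGENERATE_VAR:
        return BetaParams(np.nan, np.nan, True, m)
    c = m * (1.0 - m) / v - 1.0
    if c <= 0.0:
        return BetaParams(np.nan, np.nan, True, m)
    return BetaParams(m * c, (1.0 - m) * c, False, m)


def _cell_rng(chrom: str, start: int, sample_id: str, seed: int) -> np.random.Generator:
    """Counter-based per-cell generator; independent of every other row."""
    key = f"{chrom}\x00{start}\x00{sample_id}\x00{seed}".encode()
    digest = hashlib.blake2b(key, digest_size=16).digest()
    return np.random.Generator(np.random.Philox(key=int.from_bytes(digest, "little")))


def impute_methylation(matrix: MethylationMatrix, seed: int) -> MethylationMatrix:
    """Replace each missing cell by a draw from the row's fitted beta.

    Degenerate rows impute the row mean.  Every row must retain at least
    two observed values (apply :func:`filter_missing` first).  For a
    fixed seed the imputed value at a cell is a pure function of the
    row's observed values and the cell key, never of the other rows.
    """
    values = matrix.values.copy()
    nan_rows = np.flatnonzero(np.isnan(values).any(axis=1))
    pos = matrix.positions
    for i in nan_rows:
        row = values[i]
        obs = row[~np.isnan(row)]
        if obs.size < 2:
            raise ValueError(
                f"row {pos['chrom'].iloc[i]}:{pos['start'].iloc[i]} has fewer than "
                "2 observed values; filter by missingness first"
            )
        params = fit_beta_moments(obs)
        chrom = str(pos["chrom"].iloc[i])
        start = int(pos["start"].iloc[i])
        for j in np.flatnonzero(np.isnan(row)):
            if params.degenerate:
                values[i, j] = params.mean
            else:
                rng = _cell_rng(chrom, start, matrix.samples[j], seed)
                values[i, j] = rng.beta(params.alpha, params.beta)
    return MethylationMatrix(positions=pos.copy(), samples=list(matrix.samples), values=values)


def impute_genotypes(g: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop over-missing variants and fill the rest with the modal code.

    Variants whose missing fraction exceeds the threshold are dropped;
    remaining missing codes become the variant's most frequent code (ties
    resolve to the code closest to the variant mean).  This is a simple
    frequency-based imputer, not a haplotype-aware one.
    """
    frac = np.mean(np.isnan(g.codes), axis=1)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    out = g.take_rows(keep)
    codes = out.codes
    for i in np.flatnonzero(np.isnan(codes).any(axis=1)):
        row = codes[i]
        obs = row[~np.isnan(row)]
        counts = {c: int(np.sum(obs == c)) for c in (1.0, 2.0, 3.0) if np.any(obs == c)}
        top = max(counts.values())
        tied = [c for c, n in counts.items() if n == top]
        fill = min(tied, key=lambda c: (abs(c - float(np.mean(obs))), c))
        row[np.isnan(row)] = fill
    return GenotypeMatrix(variants=out.variants, samples=out.samples, codes=codes)
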