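"""Mass-univariate linear-model scans: Emodel, Gmodel and GxE.

Each scan fits, per methylation row (and per cis SNP for the genetic
models), an ordinary least-squares model with covariates and reports the
coefficient of the term of interest, its two-sided t statistic and
p-value, and a Benjamini–Hochberg q-value computed globally over the
whole scan:

* Emodel:  M ~ E + cvrt            (tested term: E)
* Gmodel:  M ~ G + cvrt            (tested term: G, additive 1/2/3 dosage)
* GxE:     M ~ G + E + G:E + cvrt  (tested term: the G:E interaction)

The scans are vectorised with the Frisch–Waugh–Lovell device: both the
methylation row and the tested regressor are residualized against the
nuisance columns, and the simple regression of the residuals reproduces
the full-model coefficient and t statistic exactly.  Every per-row
quantity is a function of that row alone, so any partition of rows into
chunks merges back (with one global FDR pass) to a result bitwise equal
to the unchunked scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GenotypeMatrix,
    MethylationMatrix,
    SampleFrame,
    empty_association_table,
    parse_position_id,
)

_ZERO_RSS_RTOL = 1e-12


@dataclass
class ScanConfig:
    """Scan-wide knobs.

    distance
        Cis window in bp for the genetic models: a (position, SNP) pair is
        tested when both lie on the same chromosome within this distance
        (default 2000).
    fdr_cutoff
        q-value threshold used by downstream filtering (default 0.1).
    drop_nonfinite
        Discard rows with non-finite t statistics before FDR (default on);
        these arise from exact fits or degenerate regressors.
    all_pairs
        Test every (position, SNP) pair regardless of distance — only
        sensible on tiny datasets.
    """

    distance: int = 2000
    fdr_cutoff: float = 0.1
    drop_nonfinite: bool = True
    all_pairs: bool = False

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if not 0.0 < self.fdr_cutoff <= 1.0:
            raise ValueError("fdr_cutoff must be in (0, 1]")


@dataclass
class DesignMatrix:
    """Intercept + encoded covariates (the nuisance part of every model).

    Categorical covariates are one-hot encoded with the first level
    dropped, mirroring R's ``lm`` factor handling; numeric covariates
    enter as-is.  The matrix must be full column rank and leave at least
    one residual degree of freedom for the tested term.
    """

    X: np.ndarray
    columns: list[str]
    Q: np.ndarray = field(repr=False, default=None)  # orthonormal basis of col(X)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        q, r = np.linalg.qr(self.X)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))))
        if rank < self.X.shape[1]:
            raise ValueError("design matrix is rank-deficient after encoding")
        self.Q = q

    @classmethod
    def from_sample_frame(cls, samples: SampleFrame) -> "DesignMatrix":
        n = samples.n_samples
        cols = [np.ones(n)]
        names = ["intercept"]
        for name in samples.covariates.columns:
            col = samples.covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(dname)
        return cls(X=np.column_stack(cols), columns=names)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]


def residualize(y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Project out the design columns: y minus its least-squares fit.

    Rows of a 2-D input are projected one at a time with 1-D kernels, so
    the result for a row is bitwise independent of which other rows are in
    the batch — the property the chunk-invariance contract rests on (a
    batched matrix product would round differently per batch shape).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != design.n_samples:
        raise ValueError("length mismatch with design")
    Q = design.Q
    if y.ndim == 1:
        return y - Q @ (Q.T @ y)
    out = np.empty_like(y)
    for i in range(y.shape[0]):
        out[i] = y[i] - Q @ (Q.T @ y[i])
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped
    at 1.  The result depends only on the multiset of p-values, which is
    what makes chunk merging exact.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# internal: residual regression statistics
# ---------------------------------------------------------------------------

def _marginal_stats(
    m_resid: np.ndarray,  # (k, n) rows already residualized on nuisance
    x_resid: np.ndarray,  # (n,) tested regressor residualized on nuisance
    df: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """beta, t, p for each row of m_resid regressed on x_resid.

    Row-wise 1-D dot products keep every statistic bitwise independent of
    the batch (see :func:`residualize`).
    """
    sxx = float(x_resid @ x_resid)
    k = m_resid.shape[0]
    beta = np.empty(k)
    rss = np.empty(k)
    total = np.empty(k)
    for i in range(k):
        row = m_resid[i]
        beta[i] = (row @ x_resid) / sxx
        total[i] = row @ row
        rss[i] = total[i] - beta[i] ** 2 * sxx
    rss = np.where(rss <= _ZERO_RSS_RTOL * np.maximum(total, 1.0), 0.0, np.maximum(rss, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    p = np.array([2.0 * float(stats.t.sf(abs(ti), df)) for ti in t])
    return beta, t, p


def _finalize(table: pd.DataFrame, drop_nonfinite: bool) -> pd.DataFrame:
    if drop_nonfinite and len(table):
        table = table[np.isfinite(table["stat"].to_numpy())].reset_index(drop=True)
    table = table.copy()
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy()) if len(table) else pd.Series(dtype=float)
    return table


def _check_complete(m: MethylationMatrix) -> None:
    if np.isnan(m.values).any():
        raise ValueError("matrix contains missing values; impute or filter first")


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def emodel_scan(
    m: MethylationMatrix,
    samples: SampleFrame,
    design: DesignMatrix | None = None,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Scan every methylation row for association with the environment."""
    config = config or ScanConfig()
    design = design or DesignMatrix.from_sample_frame(samples)
    _check_complete(m)
    env = np.asarray(samples.env, dtype=float)
    if np.ptp(env) == 0:
        raise ValueError("environment is constant")
    n = design.n_samples
    df = n - design.rank - 1
    if df < 1:
        raise ValueError(f"too few samples: residual df = {df}")

    e_r = residualize(env, design)
    m_r = residualize(m.values, design)
    beta, t, p = _marginal_stats(m_r, e_r, df)
    table = pd.DataFrame({"id": m.row_ids(), "beta": beta, "stat": t, "pvalue": p})
    return _finalize(table, config.drop_nonfinite)


def _cis_pairs(
    m: MethylationMatrix, g: GenotypeMatrix, config: ScanConfig
) -> list[tuple[int, np.ndarray]]:
    """(variant row, candidate position rows) for every testable variant."""
    pos = m.positions
    out = []
    if config.all_pairs:
        all_rows = np.arange(m.n_positions)
        return [(j, all_rows) for j in range(g.n_variants)]
    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pos["chrom"].unique():
        rows = np.flatnonzero((pos["chrom"] == chrom).to_numpy())
        starts = pos["start"].to_numpy()[rows]
        order = np.argsort(starts, kind="stable")
        pos_by_chrom[chrom] = (starts[order], rows[order])
    for j in range(g.n_variants):
        chrom = g.variants["chrom"].iloc[j]
        if chrom not in pos_by_chrom:
            continue
        starts, rows = pos_by_chrom[chrom]
        vstart = int(g.variants["start"].iloc[j])
        lo = np.searchsorted(starts, vstart - config.distance, side="left")
        hi = np.searchsorted(starts, vstart + config.distance, side="right")
        if hi > lo:
            out.append((j, rows[lo:hi]))
    return out


def gmodel_scan(
    m: MethylationMatrix,
    g: GenotypeMatrix,
    design: DesignMatrix,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """methQTL scan: test every cis (position, SNP) pair for M ~ G + cvrt."""
    config = config or ScanConfig()
    _check_complete(m)
    if list(m.samples) != list(g.samples):
        raise ValueError("methylation and genotype matrices must share sample order")
    if np.isnan(g.codes).any():
        raise ValueError("genotype matrix contains missing codes; impute first")
    n = design.n_samples
    df = n - design.rank - 1
    if df < 1:
        raise ValueError(f"too few samples: residual df = {df}")

    m_r = residualize(m.values, design)
    ids = m.row_ids().to_numpy()
    snp_ids = g.snp_ids().to_numpy()
    pieces = []
    n_constant = 0
    for j, rows in _cis_pairs(m, g, config):
        g_r = residualize(g.codes[j], design)
        if float(g_r @ g_r) <= 1e-12:
            n_constant += 1
            continue
        beta, t, p = _marginal_stats(m_r[rows], g_r, df)
        pieces.append(pd.DataFrame({
            "id": ids[rows], "snp": snp_ids[j],
            "beta": beta, "stat": t, "pvalue": p,
        }))
    if n_constant:
        warnings.warn(f"skipped {n_constant} variant(s) constant after covariate adjustment")
    if not pieces:
        warnings.warn("no (position, SNP) pair inside the cis window")
        return empty_association_table(with_snp=True)
    table = pd.concat(pieces, ignore_index=True)
    table = _sort_pairs(table)
    return _finalize(table, config.drop_nonfinite)


def gxe_scan(
    m: MethylationMatrix,
    g: GenotypeMatrix,
    samples: SampleFrame,
    design: DesignMatrix,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Interaction scan: per cis pair fit M ~ G + E + G:E + cvrt, test G:E."""
    config = config or ScanConfig()
    _check_complete(m)
    if list(m.samples) != list(g.samples):
        raise ValueError("methylation and genotype matrices must share sample order")
    env = np.asarray(samples.env, dtype=float)
    if np.ptp(env) == 0:
        raise ValueError("environment is constant")
    n = design.n_samples

    m_vals = m.values
    ids = m.row_ids().to_numpy()
    snp_ids = g.snp_ids().to_numpy()
    pieces = []
    n_skipped = 0
    for j, rows in _cis_pairs(m, g, config):
        gj = g.codes[j]
        if np.unique(gj).size < 2:
            n_skipped += 1
            continue
        X0 = np.column_stack([design.X, gj, env])
        try:
            nuisance = DesignMatrix(X=X0, columns=design.columns + ["G", "E"])
        except ValueError:  # G collinear with covariates/E
            n_skipped += 1
            continue
        df = n - nuisance.rank - 1
        if df < 1:
            raise ValueError(f"too few samples: residual df = {df}")
        ge_r = residualize(gj * env, nuisance)
        if float(ge_r @ ge_r) <= 1e-12:
            n_skipped += 1
            continue
        m_r = residualize(m_vals[rows], nuisance)
        beta, t, p = _marginal_stats(m_r, ge_r, df)
        pieces.append(pd.DataFrame({
            "id": ids[rows], "snp": snp_ids[j],
            "beta": beta, "stat": t, "pvalue": p,
        }))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} variant(s) with a single genotype class "
                      "or collinear with the design")
    if not pieces:
        warnings.warn("no (position, SNP) pair inside the cis window")
        return empty_association_table(with_snp=True)
    table = pd.concat(pieces, ignore_index=True)
    table = _sort_pairs(table)
    return _finalize(table, config.drop_nonfinite)


# ---------------------------------------------------------------------------
# chunk-safe merging
# ---------------------------------------------------------------------------

def _sort_keys(table: pd.DataFrame) -> pd.DataFrame:
    parsed = [parse_position_id(i) for i in table["id"]]
    keys = pd.DataFrame({
        "_chrom": [c for c, _, _ in parsed],
        "_start": [s for _, s, _ in parsed],
    }, index=table.index)
    if "snp" in table.columns:
        sp = [i.rpartition(":") for i in table["snp"]]
        keys["_schrom"] = [c for c, _, _ in sp]
        keys["_sstart"] = [int(s) for _, _, s in sp]
    return keys


def _sort_pairs(table: pd.DataFrame) -> pd.DataFrame:
    keys = _sort_keys(table)
    order = keys.sort_values(list(keys.columns), kind="stable").index
    return table.loc[order].reset_index(drop=True)


def merge_chunked(chunks: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-chunk scan outputs (no fdr column) and FDR-correct globally.

    The chunks must be disjoint in their (id, snp) keys.  Because every
    per-row statistic is computed from that row alone and BH only sees
    the pooled p-values, the merged table is identical — bitwise on the
    q-values — to the unchunked scan.  Running FDR inside each chunk
    instead would bias the q-values, which is exactly the failure mode
    this merge step avoids.
    """
    nonempty = [c for c in chunks if len(c)]
    if not nonempty:
        return empty_association_table(with_snp=False)
    with_snp = "snp" in nonempty[0].columns
    cat = pd.concat(
        [c.drop(columns=["fdr"], errors="ignore") for c in nonempty],
        ignore_index=True,
    )
    key = cat["id"] + ("\x00" + cat["snp"] if with_snp else "")
    if key.duplicated().any():
        raise ValueError("duplicate (id, snp) keys across chunks")
    cat = cat[np.isfinite(cat["stat"].to_numpy())].reset_index(drop=True)
    cat = _sort_pairs(cat) if with_snp else cat.loc[
        _sort_keys(cat).sort_values(["_chrom", "_start"], kind="stable").index
    ].reset_index(drop=True)
    cat["fdr"] = bh_fdr(cat["pvalue"].to_numpy())
    return cat
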