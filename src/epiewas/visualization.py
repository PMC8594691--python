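"""Diagnostic plots for scan outputs.

Every plot has a pure data layer (a function returning a plottable
DataFrame) and a thin matplotlib rendering layer, so the numbers behind a
figure can be tested without touching the canvas.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import parse_position_id

GENOTYPE_LABELS = {1.0: "AA", 2.0: "AB", 3.0: "BB"}


# ---------------------------------------------------------------------------
# data layers
# ---------------------------------------------------------------------------

def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for a Q-Q plot."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to plot")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.maximum(np.sort(p), np.finfo(float).tiny))
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_data(table: pd.DataFrame, fdr_cutoff: float) -> tuple[pd.DataFrame, float | None]:
    """Genome-ordered -log10 p with per-chromosome color index.

    Returns the point table and the p-value threshold corresponding to
    the FDR cutoff (the largest p among rows with q < cutoff), or None
    when nothing is significant.
    """
    if len(table) == 0:
        raise ValueError("empty association table")
    parsed = [parse_position_id(i) for i in table["id"]]
    df = pd.DataFrame({
        "chrom": [c for c, _, _ in parsed],
        "start": [s for _, s, _ in parsed],
        "pvalue": table["pvalue"].to_numpy(),
    })
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    chroms = list(dict.fromkeys(df["chrom"]))
    offsets = {}
    running = 0
    for c in chroms:
        offsets[c] = running
        running += int(df.loc[df["chrom"] == c, "start"].max()) + 1
    df["x"] = [offsets[c] + s for c, s in zip(df["chrom"], df["start"])]
    df["color_index"] = [chroms.index(c) % 2 for c in df["chrom"]]
    df["neglog10p"] = -np.log10(np.maximum(df["pvalue"], np.finfo(float).tiny))

    sig = table.loc[table["fdr"] < fdr_cutoff, "pvalue"]
    threshold = float(sig.max()) if len(sig) else None
    return df, threshold


def genotype_interaction_data(
    m_row: np.ndarray, g_row: np.ndarray, env: np.ndarray
) -> pd.DataFrame:
    """Per-genotype-class regression lines of methylation on environment.

    One row per class present (AA/AB/BB) with its slope and intercept;
    classes with a single sample get a flat line at that value.
    """
    m_row = np.asarray(m_row, float)
    g_row = np.asarray(g_row, float)
    env = np.asarray(env, float)
    classes = np.unique(g_row[~np.isnan(g_row)])
    if classes.size < 2:
        raise ValueError("need at least two genotype classes")
    rows = []
    for c in classes:
        mask = g_row == c
        e, y = env[mask], m_row[mask]
        if e.size >= 2 and np.ptp(e) > 0:
            slope, intercept = np.polyfit(e, y, 1)
        else:
            slope, intercept = 0.0, float(np.mean(y))
        rows.append((GENOTYPE_LABELS[c], int(mask.sum()), slope, intercept))
    return pd.DataFrame(rows, columns=["genotype", "n", "slope", "intercept"])


def pvalue_histogram_data(pvalues: np.ndarray, bins: int = 20) -> pd.DataFrame:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to plot")
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return pd.DataFrame({"left": edges[:-1], "right": edges[1:], "count": counts})


def gmodel_dot_data(table: pd.DataFrame) -> pd.DataFrame:
    """Cytosine-vs-SNP coordinate dot matrix sized by -log10 q."""
    if len(table) == 0 or "snp" not in table.columns:
        raise ValueError("need a non-empty pair table with a snp column")
    pos = [parse_position_id(i)[1] for i in table["id"]]
    snp = [int(s.rpartition(":")[2]) for s in table["snp"]]
    size = -np.log10(np.maximum(table["fdr"].to_numpy(), np.finfo(float).tiny))
    return pd.DataFrame({"position": pos, "snp_position": snp, "neglog10q": size})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _save(fig: plt.Figure, path: str | Path) -> None:
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(pvalues: np.ndarray, path: str | Path) -> None:
    df = qq_data(pvalues)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(df["expected"], df["observed"], ".", ms=3)
    lim = max(df["expected"].max(), df["observed"].max())
    ax.plot([0, lim], [0, lim], "r-", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    _save(fig, path)


def manhattan_plot(table: pd.DataFrame, fdr_cutoff: float, path: str | Path) -> None:
    df, threshold = manhattan_data(table, fdr_cutoff)
    fig, ax = plt.subplots(figsize=(8, 3))
    palette = ("#3b5b92", "#9db4d9")
    for ci in (0, 1):
        sub = df[df["color_index"] == ci]
        ax.plot(sub["x"], sub["neglog10p"], ".", ms=3, color=palette[ci])
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1, ls="--")
    ax.set_xlabel("genome position")
    ax.set_ylabel("$-\\log_{10} p$")
    fig.tight_layout()
    _save(fig, path)


def genotype_interaction_plot(
    m_row: np.ndarray, g_row: np.ndarray, env: np.ndarray, path: str | Path
) -> None:
    lines = genotype_interaction_data(m_row, g_row, env)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    span = np.linspace(float(np.min(env)), float(np.max(env)), 50)
    for _, row in lines.iterrows():
        code = {v: k for k, v in GENOTYPE_LABELS.items()}[row["genotype"]]
        mask = np.asarray(g_row, float) == code
        ax.plot(np.asarray(env)[mask], np.asarray(m_row)[mask], "o", ms=4, alpha=0.6)
        ax.plot(span, row["intercept"] + row["slope"] * span, label=row["genotype"])
    ax.set_xlabel("environment")
    ax.set_ylabel("methylation fraction")
    ax.legend(title="genotype")
    fig.tight_layout()
    _save(fig, path)


def pvalue_histogram(pvalues: np.ndarray, path: str | Path) -> None:
    df = pvalue_histogram_data(pvalues)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.bar(df["left"], df["count"], width=df["right"] - df["left"], align="edge",
           color="#3b5b92", edgecolor="white")
    ax.set_xlabel("p-value")
    ax.set_ylabel("count")
    fig.tight_layout()
    _save(fig, path)


def gmodel_dot_plot(table: pd.DataFrame, path: str | Path) -> None:
    df = gmodel_dot_data(table)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(df["snp_position"], df["position"], s=4 + 8 * df["neglog10q"], alpha=0.6)
    ax.set_xlabel("SNP position")
    ax.set_ylabel("cytosine position")
    fig.tight_layout()
    _save(fig, path)
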