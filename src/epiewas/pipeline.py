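"""End-to-end orchestration: files in, output tree out.

One call analyses one input type (all MPs, DMP-restricted MPs, MPs within
DMRs, or averaged union-DMRs) for the enabled contexts, writing the
standard output tree::

    outdir/
      input/ env.txt cov.txt snps.txt gxe.txt
             bed/ unfiltered/ filtered/ imputed/   (one union table per context)
      positions/ Emodel/ Gmodel/ GxE/              (per-position input types)
      regions/   Emodel/ Gmodel/ GxE/              (averaged-region input type)

Model selection is automatic: the Emodel always runs; the Gmodel and GxE
run only when a VCF is supplied.  Each filter logs its input and output
row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import visualization as viz
from .association_models import (
    DesignMatrix,
    ScanConfig,
    emodel_scan,
    gmodel_scan,
    gxe_scan,
    merge_chunked,
)
from .containers import MethylationMatrix, SampleFrame
from .io_formats import (
    format_float,
    read_bedgraph,
    read_regions,
    read_sample_sheet,
    read_vcf_genotypes,
    write_association_table,
)
from .matrix_assembly import (
    average_over_regions,
    build_union_dmrs,
    filter_by_variation,
    restrict_to_dmps,
    restrict_to_regions,
    union_positions,
)
from .missing_data import filter_missing, impute_genotypes, impute_methylation

log = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class RunParams:
    """Everything the ``run`` entry point needs beyond the input paths."""

    contexts: tuple[str, ...] = CONTEXTS
    min_coverage: int = 5
    filter_na: float = 0.0
    distance: int = 2000
    fdr_cutoff: float = 0.1
    min_sd: float | None = None
    min_range: float | None = None
    udmr_fraction: float = 0.5
    udmr_merge: bool = True
    min_qual: float = 30.0
    max_missing_fraction: float = 0.0
    min_minor_allele_count: int = 3
    snp_max_missing: float = 0.0
    seed: int = 0
    chunks: int = 1
    plots: bool = True
    all_pairs: bool = False
    models: tuple[str, ...] | None = None  # None = auto-select from inputs


def _write_union_table(matrix: MethylationMatrix, path: Path) -> None:
    """Multi-sample union table (unionbedg style), NA for missing cells."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(matrix.samples) + "\n")
        pos = matrix.positions
        for i in range(matrix.n_positions):
            cells = [
                "NA" if np.isnan(v) else format_float(v) for v in matrix.values[i]
            ]
            fh.write(f"{pos['chrom'].iloc[i]}\t{pos['start'].iloc[i]}\t"
                     f"{pos['end'].iloc[i]}\t" + "\t".join(cells) + "\n")


def _write_inputs(samples: SampleFrame, genotypes, outdir: Path) -> None:
    inp = outdir / "input"
    inp.mkdir(parents=True, exist_ok=True)
    with open(inp / "env.txt", "w") as fh:
        fh.write("sample\tenv\n")
        for sid, e in zip(samples.sample_ids, samples.env):
            fh.write(f"{sid}\t{format_float(e)}\n")
    cov = samples.covariates
    with open(inp / "cov.txt", "w") as fh:
        fh.write("\t".join(["sample", *cov.columns]) + "\n")
        for i, sid in enumerate(samples.sample_ids):
            vals = [str(cov[c].iloc[i]) for c in cov.columns]
            fh.write("\t".join([sid, *vals]) + "\n")
    # environment combined with the covariates, as the interaction model uses it
    with open(inp / "gxe.txt", "w") as fh:
        fh.write("\t".join(["sample", "env", *cov.columns]) + "\n")
        for i, sid in enumerate(samples.sample_ids):
            vals = [str(cov[c].iloc[i]) for c in cov.columns]
            fh.write("\t".join([sid, format_float(samples.env[i]), *vals]) + "\n")
    if genotypes is not None:
        with open(inp / "snps.txt", "w") as fh:
            fh.write("snp\t" + "\t".join(genotypes.samples) + "\n")
            ids = genotypes.snp_ids()
            for i in range(genotypes.n_variants):
                codes = ["NA" if np.isnan(c) else str(int(c)) for c in genotypes.codes[i]]
                fh.write("\t".join([ids.iloc[i]] + codes) + "\n")


def _chunked(scan, matrix: MethylationMatrix, n_chunks: int, **kw) -> pd.DataFrame:
    if n_chunks <= 1 or matrix.n_positions == 0:
        return scan(matrix, **kw)
    bounds = np.linspace(0, matrix.n_positions, n_chunks + 1).astype(int)
    chunks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi > lo:
            chunks.append(scan(matrix.take_rows(np.arange(lo, hi)), **kw))
    return merge_chunked(chunks)


def run_pipeline(
    samples_path: str | Path,
    methylation_dir: str | Path,
    outdir: str | Path,
    snps_path: str | Path | None = None,
    dmp_paths: list[str | Path] | None = None,
    dmr_paths: list[str | Path] | None = None,
    dmrs_averaged: bool = False,
    params: RunParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the scans for one input type; returns {(context, model): table}."""
    params = params or RunParams()
    outdir = Path(outdir)
    methylation_dir = Path(methylation_dir)
    samples = read_sample_sheet(samples_path)
    design = DesignMatrix.from_sample_frame(samples)
    config = ScanConfig(distance=params.distance, fdr_cutoff=params.fdr_cutoff,
                        all_pairs=params.all_pairs)

    wanted = params.models
    if wanted is not None:
        unknown = set(wanted) - {"Emodel", "Gmodel", "GxE"}
        if unknown:
            raise ValueError(f"unknown model(s): {sorted(unknown)}")
        if {"Gmodel", "GxE"} & set(wanted) and snps_path is None:
            raise ValueError("the Gmodel and GxE scans require genetic variants (--snps)")

    genotypes = None
    if snps_path is not None:
        genotypes = read_vcf_genotypes(
            snps_path, samples,
            min_qual=params.min_qual,
            max_missing_fraction=params.max_missing_fraction,
            min_minor_allele_count=params.min_minor_allele_count,
        )
        log.info("VCF: %d variant(s) after filters", genotypes.n_variants)
        genotypes = impute_genotypes(genotypes, params.snp_max_missing)

    _write_inputs(samples, genotypes, outdir)
    for sub in ("unfiltered", "filtered", "imputed"):
        (outdir / "input" / "bed" / sub).mkdir(parents=True, exist_ok=True)

    dmps = read_regions(dmp_paths) if dmp_paths else None
    dmrs = read_regions(dmr_paths) if dmr_paths else None
    region_level = dmrs is not None and dmrs_averaged
    scope = "regions" if region_level else "positions"

    results: dict[tuple[str, str], pd.DataFrame] = {}
    for context in params.contexts:
        ctx_dir = methylation_dir / context
        if not ctx_dir.is_dir():
            log.warning("context %s: no directory %s, skipped", context, ctx_dir)
            continue
        per_sample = {}
        for sid in samples.sample_ids:
            path = ctx_dir / f"{sid}.bedGraph"
            if not path.exists():
                raise FileNotFoundError(f"no methylation calls for sample {sid}: {path}")
            per_sample[sid] = read_bedgraph(path, min_coverage=params.min_coverage,
                                            context=context)
        matrix = union_positions(per_sample, samples)
        log.info("%s: union matrix %d positions x %d samples",
                 context, matrix.n_positions, len(matrix.samples))
        _write_union_table(matrix, outdir / "input" / "bed" / "unfiltered"
                           / f"{context}.bedGraph")

        if dmps is not None:
            before = matrix.n_positions
            matrix = restrict_to_dmps(matrix, dmps)
            log.info("%s: DMP restriction %d -> %d rows", context, before, matrix.n_positions)
        elif dmrs is not None:
            udmrs = build_union_dmrs(dmrs, params.udmr_fraction, merge=params.udmr_merge)
            log.info("%s: %d uDMR(s) at fraction %.2f", context, len(udmrs),
                     params.udmr_fraction)
            before = matrix.n_positions
            if region_level:
                matrix = average_over_regions(matrix, udmrs)
                log.info("%s: averaged %d positions into %d regions",
                         context, before, matrix.n_positions)
            else:
                matrix = restrict_to_regions(matrix, udmrs)
                log.info("%s: DMR restriction %d -> %d rows", context, before,
                         matrix.n_positions)

        before = matrix.n_positions
        matrix = filter_by_variation(matrix, params.min_sd, params.min_range)
        if params.min_sd is not None or params.min_range is not None:
            log.info("%s: variation filter %d -> %d rows", context, before,
                     matrix.n_positions)

        before = matrix.n_positions
        matrix = filter_missing(matrix, params.filter_na)
        log.info("%s: filter_NA(%.2g) %d -> %d rows", context, params.filter_na,
                 before, matrix.n_positions)
        _write_union_table(matrix, outdir / "input" / "bed" / "filtered"
                           / f"{context}.bedGraph")

        matrix = impute_methylation(matrix, seed=params.seed)
        _write_union_table(matrix, outdir / "input" / "bed" / "imputed"
                           / f"{context}.bedGraph")
        if matrix.n_positions == 0:
            log.warning("%s: nothing left to scan", context)
            continue

        n, rank = design.n_samples, design.rank
        selected = wanted if wanted is not None else (
            ("Emodel", "Gmodel", "GxE") if genotypes is not None else ("Emodel",)
        )
        models: dict[str, pd.DataFrame] = {}
        if "Emodel" in selected:
            models["Emodel"] = _chunked(
                lambda mm, **kw: emodel_scan(mm, samples, design, config),
                matrix, params.chunks,
            )
        if "Gmodel" in selected:
            models["Gmodel"] = _chunked(
                lambda mm, **kw: gmodel_scan(mm, genotypes, design, config),
                matrix, params.chunks,
            )
        if "GxE" in selected:
            if n - (rank + 2) - 1 >= 1:
                models["GxE"] = _chunked(
                    lambda mm, **kw: gxe_scan(mm, genotypes, samples, design, config),
                    matrix, params.chunks,
                )
            else:
                log.warning("GxE skipped: %d samples leave no residual degrees of "
                            "freedom for the interaction model", n)

        for model, table in models.items():
            mdir = outdir / scope / model
            mdir.mkdir(parents=True, exist_ok=True)
            write_association_table(table, mdir / f"{context}_{model}.txt")
            filt = table[table["fdr"] < params.fdr_cutoff].reset_index(drop=True)
            write_association_table(
                filt, mdir / f"{context}_{model}.filtered_{params.fdr_cutoff:g}.txt"
            )
            log.info("%s %s: %d row(s), %d significant at q < %g",
                     context, model, len(table), len(filt), params.fdr_cutoff)
            results[(context, model)] = table
            if params.plots and len(table):
                pv = table["pvalue"].to_numpy()
                viz.qq_plot(pv, mdir / f"{context}_{model}.qq.png")
                viz.pvalue_histogram(pv, mdir / f"{context}_{model}.hist.png")
                if model == "Emodel":
                    viz.manhattan_plot(table, params.fdr_cutoff,
                                       mdir / f"{context}_{model}.manhattan.png")
                elif model == "Gmodel":
                    viz.gmodel_dot_plot(table, mdir / f"{context}_{model}.dots.png")
                elif model == "GxE":
                    _plot_top_interaction(table, matrix, genotypes, samples,
                                          mdir / f"{context}_{model}.interaction.png")
    return results


def _plot_top_interaction(table, matrix, genotypes, samples, path) -> None:
    top = table.sort_values("pvalue", kind="stable").iloc[0]
    row_ids = matrix.row_ids()
    i = int(np.flatnonzero((row_ids == top["id"]).to_numpy())[0])
    snp_ids = genotypes.snp_ids()
    j = int(np.flatnonzero((snp_ids == top["snp"]).to_numpy())[0])
    try:
        viz.genotype_interaction_plot(matrix.values[i], genotypes.codes[j],
                                      samples.env, path)
    except ValueError:
        log.warning("interaction plot skipped for %s / %s", top["id"], top["snp"])
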