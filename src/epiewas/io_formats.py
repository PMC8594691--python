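"""Readers and writers for every external format the pipeline touches.

Dialects are fixed: the sample sheet is headerless TSV; bedGraph is the
6-column bisulfite-caller dialect (chrom, start, end, %methylation,
count methylated, count unmethylated), with a 4-column fallback whose
coverage is unknown; regions are BED3+; genotypes come from VCF/vcf.gz;
association tables are TSV with an ``ID|beta|stats|pvalue|FDR`` header.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .containers import (
    GenotypeMatrix,
    RegionSet,
    SampleFrame,
    empty_region_set,
)

log = logging.getLogger(__name__)

MISSING_CODE = np.nan


@dataclass
class MethylationRecord:
    """One cytosine call: 0-based half-open interval, fraction in [0,1]."""

    chrom: str
    start: int
    end: int
    context: str
    value: float
    coverage: int  # -1 when the input dialect carries no counts


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleFrame:
    """Parse the headerless tab-separated sample sheet.

    Column 1 is the sample id, column 2 the environment value, columns
    3..k become covariates named ``cov1``..``cov(k-2)``.  A covariate
    column is numeric iff every value parses as a number, otherwise it
    stays categorical (string).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {ln}: need at least 2 columns")
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty sample sheet")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (inconsistent column count)")

    sample_ids = [r[0] for r in rows]
    try:
        env = np.array([float(r[1]) for r in rows])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric environment value: {e}") from None

    cov = pd.DataFrame(index=range(len(rows)))
    for k in range(2, width):
        col = [r[k] for r in rows]
        name = f"cov{k - 1}"
        try:
            cov[name] = [float(v) for v in col]
        except ValueError:
            cov[name] = col
    return SampleFrame(sample_ids=sample_ids, env=env, covariates=cov)


def write_sample_sheet(samples: SampleFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(samples.sample_ids):
            fields = [sid, format_float(samples.env[i])]
            for c in samples.covariates.columns:
                v = samples.covariates[c].iloc[i]
                fields.append(format_float(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph methylation calls
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: str | Path,
    min_coverage: int = 0,
    context: str = "CpG",
) -> list[MethylationRecord]:
    """Read per-cytosine methylation calls from a bedGraph file.

    The 6-column dialect carries percent methylation plus methylated /
    unmethylated read counts; records whose total count falls below
    ``min_coverage`` are dropped (they become missing downstream).  A
    4-column file is accepted with coverage unknown-but-passing.
    """
    records: list[MethylationRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) not in (4, 6):
                raise ValueError(f"{path}: line {ln}: expected 4 or 6 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}: line {ln}: malformed interval {start} >= {end}")
            pct = float(f[3])
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{path}: line {ln}: percentage {pct} outside [0, 100]")
            if len(f) == 6:
                cm, cu = int(f[4]), int(f[5])
                if cm < 0 or cu < 0:
                    raise ValueError(f"{path}: line {ln}: negative count")
                coverage = cm + cu
                if coverage < min_coverage:
                    continue
            else:
                coverage = -1
            records.append(
                MethylationRecord(chrom, start, end, context, pct / 100.0, coverage)
            )
    return records


def write_bedgraph(records: Iterable[MethylationRecord], path: str | Path) -> None:
    """Write 6-column bedGraph; records without counts get the 4-column form."""
    with open(path, "w") as fh:
        for r in records:
            pct = format_float(r.value * 100.0)
            if r.coverage >= 0:
                cm = int(round(r.value * r.coverage))
                cu = r.coverage - cm
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{pct}\t{cm}\t{cu}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{pct}\n")


# ---------------------------------------------------------------------------
# BED regions (DMPs / DMRs)
# ---------------------------------------------------------------------------

def read_regions(
    paths: Sequence[str | Path],
    labels: Sequence[str] | None = None,
) -> RegionSet:
    """Read one BED3+ file per pairwise comparison into a labelled RegionSet.

    Overlapping intervals within one comparison are merged with a warning;
    coordinates are 0-based half-open as in BED.
    """
    if labels is None:
        labels = [Path(p).stem for p in paths]
    if len(labels) != len(paths):
        raise ValueError("labels must match paths one-to-one")
    frames = []
    for path, label in zip(paths, labels):
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}: line {ln}: BED needs >= 3 columns")
                start, end = int(f[1]), int(f[2])
                if start >= end:
                    raise ValueError(f"{path}: line {ln}: start >= end")
                rows.append((f[0], start, end))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        merged = _merge_overlaps(df)
        if len(merged) < len(df):
            warnings.warn(
                f"{path}: merged {len(df) - len(merged)} overlapping interval(s) "
                f"within comparison {label!r}"
            )
        merged["label"] = label
        frames.append(merged)
    if not frames:
        return empty_region_set()
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "start", "end", "label"], kind="stable")
    return RegionSet(intervals=out.reset_index(drop=True))


def _merge_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping (not merely abutting) intervals per chromosome."""
    if df.empty:
        return df.copy()
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict overlap; abutting intervals stay separate
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def write_regions(regions: RegionSet, path: str | Path) -> None:
    regions.intervals.to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end", "label"],
    )


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def encode_genotype(gt_calls: Sequence[str]) -> np.ndarray:
    """Encode biallelic calls as 1/2/3 (major hom / het / minor hom).

    ``gt_calls`` holds per-sample strings from {"hom-ref", "het",
    "hom-alt", "missing"}.  The major allele is the more frequent allele
    among non-missing calls; ties resolve to REF.
    """
    n_ref = sum(2 for c in gt_calls if c == "hom-ref") + sum(1 for c in gt_calls if c == "het")
    n_alt = sum(2 for c in gt_calls if c == "hom-alt") + sum(1 for c in gt_calls if c == "het")
    alt_major = n_alt > n_ref  # tie -> REF stays major
    codes = np.full(len(gt_calls), MISSING_CODE)
    for i, c in enumerate(gt_calls):
        if c == "missing":
            continue
        if c == "het":
            codes[i] = 2.0
        elif c == "hom-ref":
            codes[i] = 3.0 if alt_major else 1.0
        elif c == "hom-alt":
            codes[i] = 1.0 if alt_major else 3.0
        else:
            raise ValueError(f"unknown genotype call {c!r}")
    return codes


def _classify_gt(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "missing"
    if all(a == 0 for a in alleles):
        return "hom-ref"
    if all(a == 1 for a in alleles):
        return "hom-alt"
    return "het"


def read_vcf_genotypes(
    path: str | Path,
    samples: SampleFrame,
    min_qual: float = 30.0,
    max_missing_fraction: float = 0.0,
    min_minor_allele_count: int = 3,
) -> GenotypeMatrix:
    """Read, filter and encode biallelic SNPs from a VCF (or vcf.gz).

    Sites are skipped when multiallelic or non-SNP, when QUAL falls below
    ``min_qual``, when the fraction of missing genotypes exceeds
    ``max_missing_fraction`` (default: complete genotyping required), or
    when the minor allele count among non-missing calls is below
    ``min_minor_allele_count``.  Genotypes are restricted and reordered to
    the SampleFrame order and encoded 1/2/3 via :func:`encode_genotype`.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    absent = [s for s in samples.sample_ids if s not in vcf_samples]
    if absent:
        raise ValueError(f"samples missing from VCF: {absent}")

    meta_rows = []
    code_rows = []
    n = samples.n_samples
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            continue  # SNPs only
        qual = rec.qual if rec.qual is not None else 0.0
        if qual < min_qual:
            continue
        calls = [_classify_gt(rec.samples[s]["GT"]) for s in samples.sample_ids]
        n_missing = sum(c == "missing" for c in calls)
        if n_missing / n > max_missing_fraction:
            continue
        n_ref = sum(2 for c in calls if c == "hom-ref") + sum(1 for c in calls if c == "het")
        n_alt = sum(2 for c in calls if c == "hom-alt") + sum(1 for c in calls if c == "het")
        if min(n_ref, n_alt) < min_minor_allele_count:
            continue
        meta_rows.append((rec.chrom, rec.pos, rec.pos - 1, ref, alt, qual))
        code_rows.append(encode_genotype(calls))
    vf.close()

    if not meta_rows:
        warnings.warn(f"{path}: no variant survived the filters")
        codes = np.empty((0, n))
    else:
        codes = np.vstack(code_rows)
    variants = pd.DataFrame(
        meta_rows, columns=["chrom", "pos", "start", "ref", "alt", "qual"]
    )
    return GenotypeMatrix(variants=variants, samples=list(samples.sample_ids), codes=codes)


def write_vcf(g: GenotypeMatrix, path: str | Path, contigs: Sequence[str] | None = None) -> None:
    """Write a minimal diploid VCF 4.2 with GT fields from encoded codes.

    Code 1 maps back to 0/0, 2 to 0/1, 3 to 1/1 (REF taken as the major
    allele), missing to ./. — sufficient for round-trips of matrices the
    pipeline itself produced.
    """
    if contigs is None:
        contigs = list(dict.fromkeys(g.variants["chrom"])) if len(g.variants) else []
    gtmap = {1.0: "0/0", 2.0: "0/1", 3.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for i in range(g.n_variants):
            v = g.variants.iloc[i]
            gts = "\t".join(gtmap.get(c, "./.") for c in g.codes[i])
            fh.write(f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t"
                     f"{format_float(v['qual'])}\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

def format_float(x: float) -> str:
    """6-significant-digit representation used in every text output."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


def write_association_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-marker results as ``ID[<TAB>snp]<TAB>beta<TAB>stats<TAB>pvalue<TAB>FDR``.

    Floats are rendered at 6 significant digits, so a write/read cycle
    reproduces the table to 1e-6 relative.
    """
    with_snp = "snp" in table.columns
    header = ["ID"] + (["snp"] if with_snp else []) + ["beta", "stats", "pvalue", "FDR"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in table.itertuples(index=False):
            fields = [row.id]
            if with_snp:
                fields.append(row.snp)
            fields += [format_float(row.beta), format_float(row.stat),
                       format_float(row.pvalue), format_float(row.fdr)]
            fh.write("\t".join(fields) + "\n")


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "snp": str})
    df = df.rename(columns={"ID": "id", "stats": "stat", "FDR": "fdr"})
    return df
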