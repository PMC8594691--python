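"""Synthetic input bundles with planted E, G and GxE effects.

The generator emulates the upstream products a plant EWAS consumes:
per-sample per-context bedGraph methylation calls with read counts, a
biallelic SNP VCF with genotypes in Hardy–Weinberg proportions, and a
headerless sample sheet.  Methylation counts follow a beta-binomial-like
scheme: a per-position baseline fraction, planted effects and Gaussian
noise on the logit scale, then binomial sampling at a negative-binomial
read coverage.  Effects are planted on the logit scale so fractions stay
in (0, 1) at any effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import GenotypeMatrix, SampleFrame, position_id, snp_id
from .io_formats import (
    MethylationRecord,
    format_float,
    write_bedgraph,
    write_sample_sheet,
    write_vcf,
)

CONTEXT_DIRS = {"CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


@dataclass
class PlantedEffect:
    """One causal position: ``kind`` in {"E", "G", "GxE"}, logit-scale size."""

    chrom: str
    start: int
    kind: str
    size: float
    context: str = "CpG"


@dataclass
class SimConfig:
    """Study conditions for a synthetic bundle.

    Defaults mirror a small targeted-bisulfite cohort: 28 samples split
    over three planting sites (the site is the categorical covariate), a
    standard-normal environment value, ~20x mean read coverage with
    negative-binomial overdispersion, 10% randomly missing calls, and
    moderate residual noise (sd 0.3) on the logit-methylation scale.
    """

    n_samples: int = 28
    n_contigs: int = 2
    positions_per_contig: int = 100
    contexts: tuple[str, ...] = ("CpG", "CHG", "CHH")
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    n_variants: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    env_mean: float = 0.0
    env_sd: float = 1.0
    n_sites: int = 3
    site_effect: float = 0.2
    noise_sd: float = 0.3
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0
    missing_rate: float = 0.1
    effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        starts = {(c, p) for c in self._contig_names() for p in self._starts()}
        for eff in self.effects:
            if (eff.chrom, eff.start) not in starts:
                raise ValueError(f"effect target {eff.chrom}:{eff.start} does not exist")
            if eff.kind not in ("E", "G", "GxE"):
                raise ValueError(f"unknown effect kind {eff.kind!r}")

    def _contig_names(self) -> list[str]:
        return [f"contig{k + 1}" for k in range(self.n_contigs)]

    def _starts(self) -> np.ndarray:
        # positions every 20 bp leaves room for companion SNPs in cis
        return np.arange(self.positions_per_contig) * 20 + 10


def _draw_genotype_codes(
    rng: np.random.Generator, n: int, maf: float, min_mac: int = 3,
    min_class_count: int = 0,
) -> np.ndarray:
    """HWE alt-allele dosages resampled until both alleles reach min_mac.

    ``min_class_count`` additionally requires every genotype class (0/1/2
    alt copies) to appear that many times — used for variants that carry
    planted effects, where an interaction is only identifiable when all
    three classes are represented.
    """
    for _ in range(500):
        alt = rng.binomial(2, maf, size=n)
        total = 2 * n
        n_alt = int(alt.sum())
        if min(n_alt, total - n_alt) < min_mac:
            continue
        if min_class_count and min(np.sum(alt == c) for c in (0, 1, 2)) < min_class_count:
            continue
        return alt.astype(float)
    raise RuntimeError("could not draw a polymorphic genotype vector; raise maf or n")


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full on-disk bundle and return paths plus the truth table.

    Bundle: ``samples.tsv`` (headerless sample sheet), per-sample
    bedGraphs under ``bedGraph/{context}/{sample}.bedGraph``,
    ``snps.vcf``, and ``truth.tsv`` listing each planted effect with the
    SNP that carries it (for G/GxE).  Fully reproducible from the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    contigs = config._contig_names()
    starts = config._starts()

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    env = rng.normal(config.env_mean, config.env_sd, size=n)
    sites = [f"site{(i % config.n_sites) + 1}" for i in range(n)]
    samples = SampleFrame(
        sample_ids=sample_ids, env=env,
        covariates=pd.DataFrame({"cov1": sites}),
    )
    sheet_path = outdir / "samples.tsv"
    write_sample_sheet(samples, sheet_path)

    site_shift = {f"site{k + 1}": config.site_effect * k for k in range(config.n_sites)}
    site_vec = np.array([site_shift[s] for s in sites])

    # --- variants: background SNPs plus one companion SNP per G/GxE effect
    var_rows = []  # (chrom, pos 1-based, start, codes)
    effect_keys: list[tuple[str, int]] = []
    for eff in config.effects:
        if eff.kind in ("G", "GxE") and (eff.chrom, eff.start) not in effect_keys:
            maf = rng.uniform(0.2, 0.5)
            codes = _draw_genotype_codes(rng, n, maf, min_class_count=3)
            start = eff.start + 7  # well inside any sensible cis window
            effect_keys.append((eff.chrom, eff.start))
            var_rows.append((eff.chrom, start + 1, start, codes))
    n_background = max(config.n_variants - len(var_rows), 0)
    span = int(starts[-1]) + 20
    for _ in range(n_background):
        chrom = contigs[rng.integers(len(contigs))]
        start = int(rng.integers(0, span))
        maf = rng.uniform(*config.maf_range)
        codes = _draw_genotype_codes(rng, n, maf)
        var_rows.append((chrom, start + 1, start, codes))
    var_rows.sort(key=lambda r: (r[0], r[1]))

    alt_dosage = np.vstack([r[3] for r in var_rows]) if var_rows else np.empty((0, n))
    variants = pd.DataFrame(
        [(c, p, s, "A", "G", 60.0) for c, p, s, _ in var_rows],
        columns=["chrom", "pos", "start", "ref", "alt", "qual"],
    )
    genotypes = GenotypeMatrix(
        variants=variants, samples=sample_ids, codes=alt_dosage + 1.0
    )
    vcf_path = outdir / "snps.vcf"
    write_vcf(genotypes, vcf_path, contigs=contigs)

    # major-allele orientation as the pipeline's encoder will see it, so
    # planted G/GxE betas keep their sign after re-encoding from the VCF
    encoded = np.empty_like(alt_dosage)
    for i in range(alt_dosage.shape[0]):
        n_alt = int(alt_dosage[i].sum())
        alt_major = n_alt > 2 * n - n_alt
        encoded[i] = (3.0 - alt_dosage[i]) if alt_major else (alt_dosage[i] + 1.0)

    snp_of_effect = {
        key: snp_id(variants["chrom"].iloc[_find_variant(variants, key)],
                    int(variants["start"].iloc[_find_variant(variants, key)]))
        for key in effect_keys
    }
    code_of_effect = {
        key: encoded[_find_variant(variants, key)] for key in effect_keys
    }

    effects_at = {(e.context, e.chrom, e.start): e for e in config.effects}

    # --- methylation bedGraphs
    bed_root = outdir / "bedGraph"
    truth_rows = []
    for context in config.contexts:
        ctx_dir = bed_root / CONTEXT_DIRS[context]
        ctx_dir.mkdir(parents=True, exist_ok=True)
        per_sample: dict[str, list[MethylationRecord]] = {s: [] for s in sample_ids}
        for chrom in contigs:
            base = rng.beta(config.baseline_alpha, config.baseline_beta, size=len(starts))
            base = np.clip(base, 0.02, 0.98)
            for i, start in enumerate(starts):
                eff = effects_at.get((context, chrom, int(start)))
                if eff is not None:
                    # planted positions get a mid-range baseline: a logit-scale
                    # effect at a near-0/1 baseline barely moves the fraction
                    base[i] = rng.uniform(0.35, 0.65)
                shift = np.zeros(n)
                if eff is not None:
                    if eff.kind == "E":
                        shift = eff.size * (env - config.env_mean)
                    else:
                        dosage = code_of_effect[(chrom, int(start))] - 2.0  # centred on het
                        shift = eff.size * dosage if eff.kind == "G" else eff.size * dosage * env
                    truth_rows.append((
                        position_id(chrom, int(start), int(start) + 1), context,
                        eff.kind, eff.size,
                        snp_of_effect.get((chrom, int(start)), ""),
                    ))
                logit_p = logit(base[i]) + site_vec + shift \
                    + rng.normal(0.0, config.noise_sd, size=n)
                p = expit(logit_p)
                disp = config.coverage_dispersion
                coverage = rng.negative_binomial(
                    disp, disp / (disp + config.coverage_mean), size=n
                )
                observed = (coverage > 0) & (rng.random(n) >= config.missing_rate)
                cm = rng.binomial(np.maximum(coverage, 1), p)
                for j, sid in enumerate(sample_ids):
                    if not observed[j]:
                        continue
                    value = cm[j] / coverage[j]
                    per_sample[sid].append(MethylationRecord(
                        chrom, int(start), int(start) + 1, context, value, int(coverage[j])
                    ))
        for sid in sample_ids:
            write_bedgraph(per_sample[sid], ctx_dir / f"{sid}.bedGraph")

    truth = pd.DataFrame(truth_rows, columns=["id", "context", "kind", "size", "snp"])
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return {
        "samples": sheet_path,
        "bedgraph_dir": bed_root,
        "vcf": vcf_path,
        "truth": truth_path,
        "truth_table": truth,
        "sample_frame": samples,
    }


def _find_variant(variants: pd.DataFrame, key: tuple[str, int]) -> int:
    chrom, start = key
    hit = variants.index[(variants["chrom"] == chrom) & (variants["start"] == start + 7)]
    return int(hit[0])


# ---------------------------------------------------------------------------
# tiny fixed worked example
# ---------------------------------------------------------------------------

#: 10 CpG positions on one contig; values in tenths so count/coverage is exact.
_WE_STARTS = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
_WE_SAMPLES = ["S1", "S2", "S3", "S4"]
_WE_ENV = [1.0, 2.0, 3.0, 4.0]
#: per-position methylation fractions per sample; None = not covered.
_WE_VALUES: dict[int, list[float | None]] = {
    10: [0.1, 0.2, 0.3, 0.4],    # follows the environment exactly
    20: [0.5, 0.5, 0.5, 0.5],    # constant
    30: [0.2, 0.4, 0.6, None],   # one missing cell
    40: [0.8, 0.6, 0.4, 0.2],    # follows the environment, negative slope
    50: [0.3, 0.1, 0.4, 0.2],    # noise
    60: [0.1, 0.1, 0.6, 0.7],    # tracks SNP at 54 (codes 1,1,2,3)
    70: [0.9, 0.8, None, 0.6],   # one missing cell
    80: [0.2, 0.3, 0.2, 0.3],    # noise
    90: [0.7, 0.7, 0.2, 0.1],    # tracks SNP at 94
    100: [0.4, 0.5, 0.6, 0.5],   # weak trend
}
_WE_COVERAGE = 10
#: three biallelic SNPs: (1-based pos, GT per sample)
_WE_SNPS = [
    (15, ["0/0", "0/1", "0/1", "1/1"]),   # alt count 4/8, tie -> REF major
    (55, ["0/0", "0/0", "0/1", "1/1"]),   # MAC 3 -> codes 1,1,2,3
    (95, ["1/1", "1/1", "0/1", "0/0"]),   # ALT major -> codes 1,1,2,3
]
#: two pairwise DMR comparisons for the uDMR construction
_WE_DMRS = {"AB": [("chr1", 5, 45)], "AC": [("chr1", 25, 75)]}
_WE_DMPS = [("chr1", 20, 21), ("chr1", 50, 51)]


def make_worked_example(outdir: str | Path) -> dict:
    """Write the deterministic 4-sample / 10-position / 3-SNP bundle.

    Every number is hand-checkable: methylation values are exact tenths
    at coverage 10, genotype codes follow from counting alleles, and the
    two DMR comparisons reproduce the toy union-DMR layout.
    """
    outdir = Path(outdir)
    (outdir / "bedGraph" / "CpG").mkdir(parents=True, exist_ok=True)

    with open(outdir / "samples.tsv", "w") as fh:
        for sid, e in zip(_WE_SAMPLES, _WE_ENV):
            fh.write(f"{sid}\t{format_float(e)}\n")

    for j, sid in enumerate(_WE_SAMPLES):
        records = []
        for start in _WE_STARTS:
            v = _WE_VALUES[start][j]
            if v is None:
                continue
            records.append(MethylationRecord("chr1", start, start + 1, "CpG", v, _WE_COVERAGE))
        write_bedgraph(records, outdir / "bedGraph" / "CpG" / f"{sid}.bedGraph")

    with open(outdir / "snps.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(_WE_SAMPLES) + "\n")
        for pos, gts in _WE_SNPS:
            fh.write(f"chr1\t{pos}\t.\tC\tT\t60\t.\t.\tGT\t" + "\t".join(gts) + "\n")

    dmr_paths = []
    for label, rows in _WE_DMRS.items():
        p = outdir / f"dmrs_{label}.bed"
        with open(p, "w") as fh:
            for chrom, s, e in rows:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        dmr_paths.append(p)

    dmp_path = outdir / "dmps.bed"
    with open(dmp_path, "w") as fh:
        for chrom, s, e in _WE_DMPS:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    return {
        "samples": outdir / "samples.tsv",
        "bedgraph_dir": outdir / "bedGraph",
        "vcf": outdir / "snps.vcf",
        "dmrs": dmr_paths,
        "dmps": dmp_path,
    }
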