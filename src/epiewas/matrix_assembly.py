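"""Assemble the analysis matrix for the four input types.

The pipeline accepts methylated positions (MPs), MPs restricted to
differentially methylated positions (DMPs), MPs inside differentially
methylated regions (DMRs), or per-region averages over non-overlapping
union DMRs (uDMRs) built from several pairwise comparisons.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, RegionSet, SampleFrame
from .io_formats import MethylationRecord


def union_positions(
    per_sample: Mapping[str, Sequence[MethylationRecord]],
    samples: SampleFrame,
) -> MethylationMatrix:
    """Unite per-sample calls into one positions x samples matrix.

    Semantics match ``bedtools unionbedg``: the row set is the union of
    positions seen in any sample; a sample not covering a position gets a
    missing cell.  All records must share one methylation context.
    """
    if samples.n_samples == 0:
        raise ValueError("no samples")
    contexts = {r.context for recs in per_sample.values() for r in recs}
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts in one matrix: {sorted(contexts)}")
    context = contexts.pop() if contexts else "CpG"

    keys: dict[tuple[str, int, int], int] = {}
    for sid in samples.sample_ids:
        for r in per_sample.get(sid, ()):
            keys.setdefault((r.chrom, r.start, r.end), 0)
    ordered = sorted(keys)
    index = {k: i for i, k in enumerate(ordered)}

    values = np.full((len(ordered), samples.n_samples), np.nan)
    for j, sid in enumerate(samples.sample_ids):
        for r in per_sample.get(sid, ()):
            values[index[(r.chrom, r.start, r.end)], j] = r.value

    positions = pd.DataFrame(ordered, columns=["chrom", "start", "end"])
    positions["context"] = context
    return MethylationMatrix(positions=positions, samples=list(samples.sample_ids), values=values)


def restrict_to_dmps(matrix: MethylationMatrix, dmps: RegionSet) -> MethylationMatrix:
    """Keep matrix rows lying at DMP positions (union across comparisons)."""
    return restrict_to_regions(matrix, dmps)


def restrict_to_regions(matrix: MethylationMatrix, regions: RegionSet) -> MethylationMatrix:
    """Keep matrix rows whose position falls inside any region (set union).

    Nested or abutting regions never duplicate a row; values are unchanged.
    """
    keep = np.zeros(matrix.n_positions, dtype=bool)
    pos = matrix.positions
    for chrom, sub in regions.intervals.groupby("chrom", sort=False):
        on_chrom = (pos["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        starts = pos["start"].to_numpy()[on_chrom]
        hit = np.zeros(starts.shape, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (starts >= s) & (starts < e)
        keep[np.flatnonzero(on_chrom)[hit]] = True
    if not keep.any():
        warnings.warn("region restriction produced an empty matrix")
    return matrix.take_rows(np.flatnonzero(keep))


def build_union_dmrs(
    dmrs: RegionSet,
    min_fraction: float,
    merge: bool = True,
) -> RegionSet:
    """Build non-overlapping union DMRs from pairwise-comparison DMR sets.

    Every boundary in the input splits the genome into elementary
    intervals; an elementary interval is kept when the fraction of
    distinct comparisons covering it reaches ``min_fraction``.  With
    ``merge`` adjacent kept intervals coalesce.  A single comparison is
    returned unchanged.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    labels = dmrs.labels
    if len(labels) <= 1:
        return RegionSet(intervals=dmrs.intervals.copy(), merged_flag=merge)
    n_comp = len(labels)

    out_rows = []
    for chrom, sub in dmrs.intervals.groupby("chrom", sort=True):
        bounds = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
        starts, ends = bounds[:-1], bounds[1:]
        # distinct comparisons covering each elementary interval
        count = np.zeros(len(starts), dtype=int)
        for label, lab_sub in sub.groupby("label", sort=False):
            covered = np.zeros(len(starts), dtype=bool)
            for s, e in zip(lab_sub["start"], lab_sub["end"]):
                covered |= (starts >= s) & (ends <= e)
            count += covered
        kept = count / n_comp >= min_fraction
        if merge:
            cur = None
            for i in np.flatnonzero(kept):
                if cur is not None and cur[1] == starts[i]:
                    cur = (cur[0], ends[i])
                else:
                    if cur is not None:
                        out_rows.append((chrom, *cur))
                    cur = (starts[i], ends[i])
            if cur is not None:
                out_rows.append((chrom, *cur))
        else:
            out_rows.extend((chrom, starts[i], ends[i]) for i in np.flatnonzero(kept))

    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
    df["label"] = "uDMR"
    return RegionSet(intervals=df, merged_flag=merge)


def average_over_regions(matrix: MethylationMatrix, regions: RegionSet) -> MethylationMatrix:
    """Collapse the matrix to one row per region by per-sample averaging.

    A cell is the mean of the sample's non-missing values over positions
    inside the region, and missing only when the sample is missing at all
    covered positions.  Regions covering no matrix position are dropped
    (their count is reported in a warning).
    """
    iv = regions.intervals.sort_values(["chrom", "start"], kind="stable")
    _check_non_overlapping(iv)
    pos = matrix.positions
    rows = []
    values = []
    dropped = 0
    for chrom, sub in iv.groupby("chrom", sort=True):
        on_chrom = np.flatnonzero((pos["chrom"] == chrom).to_numpy())
        starts = pos["start"].to_numpy()[on_chrom]
        order = np.argsort(starts, kind="stable")
        starts_sorted = starts[order]
        idx_sorted = on_chrom[order]
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.searchsorted(starts_sorted, s, side="left")
            hi = np.searchsorted(starts_sorted, e, side="left")
            if hi <= lo:
                dropped += 1
                continue
            block = matrix.values[idx_sorted[lo:hi]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                mean = np.nanmean(block, axis=0)
            rows.append((chrom, int(s), int(e), pos["context"].iloc[0] if len(pos) else "CpG"))
            values.append(mean)
    if dropped:
        warnings.warn(f"{dropped} region(s) covered no methylated position and were dropped")
    positions = pd.DataFrame(rows, columns=["chrom", "start", "end", "context"])
    vals = np.vstack(values) if values else np.empty((0, len(matrix.samples)))
    return MethylationMatrix(positions=positions, samples=list(matrix.samples), values=vals)


def _check_non_overlapping(iv: pd.DataFrame) -> None:
    for _, sub in iv.groupby("chrom", sort=False):
        ends = sub["end"].to_numpy()[:-1]
        starts = sub["start"].to_numpy()[1:]
        if np.any(starts < ends):
            raise ValueError("regions must be non-overlapping for averaging")


def filter_by_variation(
    matrix: MethylationMatrix,
    min_sd: float | None = None,
    min_range: float | None = None,
) -> MethylationMatrix:
    """Keep rows with enough between-sample variation.

    Thresholds are on the fraction scale (0.10 = a 10% range).  The SD is
    the sample standard deviation (n-1 denominator) over non-missing
    values; rows with fewer than two observed values are dropped whenever
    a threshold is set.
    """
    if min_sd is None and min_range is None:
        return matrix
    n_obs = np.sum(~np.isnan(matrix.values), axis=1)
    keep = n_obs >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if min_sd is not None:
            sd = np.nanstd(matrix.values, axis=1, ddof=1)
            keep &= sd >= min_sd
        if min_range is not None:
            rng = np.nanmax(matrix.values, axis=1) - np.nanmin(matrix.values, axis=1)
            keep &= rng >= min_range
    return matrix.take_rows(np.flatnonzero(keep))
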