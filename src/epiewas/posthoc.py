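"""Cross-model post-processing.

After running the E, G and GxE scans on the same input type, associations
that appear both in the environmental and in the genetic models cannot be
attributed to the environment alone: a genetic variant can create or
destroy a methylation site (e.g. a C/T SNP at the cytosine itself) and
masquerade as an epigenetic signal.  These helpers intersect significant
hits across models and strip genetically driven positions from the
Emodel output.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .containers import parse_position_id


def significant_ids(table: pd.DataFrame, fdr_cutoff: float) -> set[str]:
    """Ids of rows with q-value below the cutoff."""
    if len(table) == 0:
        return set()
    return set(table.loc[table["fdr"] < fdr_cutoff, "id"])


def membership_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exact-membership counts for every non-empty label combination.

    Upset-plot semantics: an id is counted under the one combination that
    equals its exact membership, so the counts sum to the size of the
    union.  Labels in a combination are joined with ``&`` in input order.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least two sets")
    membership: dict[frozenset, int] = {}
    for item in set().union(*sets.values()):
        combo = frozenset(l for l in labels if item in sets[l])
        membership[combo] = membership.get(combo, 0) + 1
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            rows.append(("&".join(combo), membership.get(frozenset(combo), 0)))
    return pd.DataFrame(rows, columns=["combination", "count"])


def exclude_genetic(
    emodel: pd.DataFrame,
    gmodel: pd.DataFrame,
    gxe: pd.DataFrame,
    snp_positions: Iterable[tuple[str, int]] = (),
    fdr_cutoff: float = 0.1,
    drop_snp_overlap: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove genetically driven rows from the Emodel output.

    A row is dropped when its id is significant in the Gmodel or GxE scan
    at ``fdr_cutoff``, or (optional positional rule, on by default) when
    the cytosine coordinate coincides with a SNP position — the situation
    where genetic variation at the base itself fakes a methylation
    signal.  Returns the pruned table and the removal counts by reason.
    """
    genetic = significant_ids(gmodel, fdr_cutoff) | significant_ids(gxe, fdr_cutoff)
    snp_set = set(snp_positions) if drop_snp_overlap else set()

    keep = []
    removed = {"genetic_model": 0, "snp_overlap": 0}
    for row_id in emodel["id"]:
        if row_id in genetic:
            removed["genetic_model"] += 1
            keep.append(False)
            continue
        chrom, start, _ = parse_position_id(row_id)
        if (chrom, start) in snp_set:
            removed["snp_overlap"] += 1
            keep.append(False)
            continue
        keep.append(True)
    return emodel[keep].reset_index(drop=True), removed
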