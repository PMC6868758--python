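"""Tier assignment and tier contingency tables.

A sample's n reference-gene expression values, sorted ascending, cut the
nonnegative axis into n+1 half-open intervals [b_j, b_{j+1}) with b_0 = 0 and
b_{n+1} = inf; a gene whose value falls in interval j is in tier j for that
sample. Because the boundaries move with the sample, any strictly increasing
per-sample transform of the data leaves every tier unchanged — this is what
makes tiers portable across expression platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DDRError, ExpressionMatrix, SampleMetadata
from .normalization import NormalizedMatrix
from .references import ReferenceSet, _expr_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TierMatrix:
    """Gene-by-sample integer tiers in [0, n_refs]."""

    tiers: pd.DataFrame  # int dtype
    n_refs: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tiers.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tiers.columns)


@dataclass(frozen=True)
class TierContingencyTable:
    """Condition x tier counts for one gene.

    Row order is the metadata's first-appearance condition order; row sums
    equal the per-condition sample counts.
    """

    gene_id: str
    conditions: list[str]
    counts: np.ndarray  # shape (C, n_tiers), nonnegative ints


def assign_tiers(matrix, refs: ReferenceSet) -> TierMatrix:
    """Tier of every gene in every sample.

    Boundaries are the reference genes' observed values within each sample,
    sorted ascending (occasional rank inversions between references are
    tolerated and counted in the log). A value exactly equal to a boundary
    takes the higher tier; zero is always tier 0.
    """
    expr = _expr_frame(matrix)
    missing = [g for g in refs.gene_ids if g not in expr.index]
    if missing:
        raise DDRError(f"reference gene(s) absent from matrix: {missing}")
    arr = expr.to_numpy(dtype=np.float64)
    if (arr < 0).any():
        raise DDRError("negative expression value")
    bounds = expr.loc[refs.gene_ids].to_numpy(dtype=np.float64)  # n_refs x samples
    inversions = int(np.sum(np.any(np.diff(bounds, axis=0) < 0, axis=0)))
    if inversions:
        logger.info("reference rank inversions in %d sample(s); boundaries re-sorted", inversions)
    bounds = np.sort(bounds, axis=0)
    # tier = number of boundaries <= value (ties promote to the higher tier)
    tiers = (arr[:, None, :] >= bounds[None, :, :]).sum(axis=1)
    return TierMatrix(
        tiers=pd.DataFrame(tiers.astype(np.int64), index=expr.index, columns=expr.columns),
        n_refs=refs.n_refs,
    )


def contingency_tables(
    tiers: TierMatrix,
    metadata: SampleMetadata,
    genes: list[str] | None = None,
) -> list[TierContingencyTable]:
    """One condition x tier count table per gene."""
    conditions = metadata.conditions  # row order fixed before column alignment
    meta = metadata.aligned_to(tiers.sample_ids)
    n_tiers = tiers.n_refs + 1
    if genes is None:
        genes = tiers.gene_ids
    else:
        missing = [g for g in genes if g not in tiers.tiers.index]
        if missing:
            raise DDRError(f"gene(s) absent from tier matrix: {missing}")
    cond_masks = []
    for cond in conditions:
        samples = meta.samples_for(cond)
        if not samples:
            raise DDRError(f"condition {cond!r} has zero samples")
        cond_masks.append(np.isin(np.asarray(tiers.sample_ids), samples))
    tier_arr = tiers.tiers.loc[genes].to_numpy()
    tables = []
    for gi, gene in enumerate(genes):
        counts = np.zeros((len(conditions), n_tiers), dtype=np.int64)
        for ci, mask in enumerate(cond_masks):
            counts[ci] = np.bincount(tier_arr[gi, mask], minlength=n_tiers)[:n_tiers]
        tables.append(TierContingencyTable(gene_id=gene, conditions=conditions, counts=counts))
    return tables
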