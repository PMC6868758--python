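"""Selection of data-driven reference genes.

Reference genes are housekeeping genes whose expression is stable across all
samples (low product score PS = COV * MFC) and which together span the
expression range at roughly even log2 spacing. Their per-sample expression
values define the tier boundaries used everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DDRError, ExpressionMatrix
from .normalization import NormalizedMatrix

#: matrices whose maximum value is below this are assumed to be on a log scale
LOG_SCALE_MAX = 30.0


@dataclass(frozen=True)
class StabilityScores:
    """Per-gene stability metrics across all samples (conditions pooled).

    ``cov`` is the coefficient of variation (sample sd / mean), ``mfc`` the
    maximum fold change (max / min) and ``ps = cov * mfc`` the product score.
    Genes observed at zero in any sample get ``ps = inf`` (never selectable:
    a reference must be detected in every sample for tiers to be defined).
    """

    frame: pd.DataFrame  # columns: cov, mfc, ps, mean_expr; index: gene

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered reference genes r_1..r_n (ascending typical expression).

    n genes define n+1 tiers. ``log_scale`` records whether the source
    matrix was log-scale (spacing measured as a difference, not a ratio).
    """

    gene_ids: list[str]
    ps: list[float]
    strata: list[int]
    target_log2_spacing: float
    log_scale: bool = False
    mean_expr: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise DDRError("a ReferenceSet needs at least one gene")
        if any(b <= a for a, b in zip(self.strata, self.strata[1:])):
            raise DDRError("reference strata must be strictly increasing")

    @property
    def n_refs(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tiers(self) -> int:
        return self.n_refs + 1


def _expr_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, NormalizedMatrix):
        return matrix.cpm
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise DDRError(f"unsupported matrix type {type(matrix).__name__}")


def stability_scores(matrix) -> StabilityScores:
    """COV, MFC and product score per gene, over ALL samples."""
    expr = _expr_frame(matrix)
    if expr.shape[1] < 2:
        raise DDRError("stability scores need at least two samples")
    if expr.shape[0] == 0:
        raise DDRError("empty expression matrix")
    arr = expr.to_numpy(dtype=np.float64)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    mn = arr.min(axis=1)
    mx = arr.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.inf)
        mfc = np.where(mn > 0, mx / mn, np.inf)
    ps = cov * mfc
    ps[mn == 0] = np.inf
    frame = pd.DataFrame(
        {"cov": cov, "mfc": mfc, "ps": ps, "mean_expr": mean}, index=expr.index
    )
    return StabilityScores(frame)


def _log2_axis(mean_expr: pd.Series, log_scale: bool) -> pd.Series:
    """Position of each gene on the spacing axis.

    For linear-scale data spacing is a log2 fold change; for data already on
    a log scale it is a plain difference, so the values are used directly.
    """
    return mean_expr if log_scale else np.log2(mean_expr)


def select_references(
    scores: StabilityScores,
    housekeeping: list[str],
    target_log2_spacing: float = 2.0,
    n_refs: int | None = None,
    min_expr: float = 1.0,
    candidate_quantile: float = 0.05,
    log_scale: bool | None = None,
) -> ReferenceSet:
    """Pick stable housekeeping genes spaced ~``target_log2_spacing`` apart.

    Candidates are the housekeeping genes whose product score lies in the
    lowest ``candidate_quantile`` of all finite product scores and whose mean
    expression is at least ``min_expr``. The log2 expression axis is divided
    into strata of width ``target_log2_spacing`` centred on the lowest
    candidate; the minimum-PS candidate of each nonempty stratum is chosen.
    When ``n_refs`` is given, a greedy farthest-point sweep keeps the
    ``n_refs`` most evenly spaced choices. Consecutive selections closer than
    half the target spacing are collapsed (the later one is dropped).
    """
    frame = scores.frame
    if log_scale is None:
        log_scale = bool(frame["mean_expr"].max() < LOG_SCALE_MAX)
    hk = [g.strip() for g in housekeeping]
    hk_present = [g for g in hk if g in frame.index]
    if not hk_present:
        raise DDRError("housekeeping list shares no genes with the matrix")

    finite_ps = frame.loc[np.isfinite(frame["ps"]), "ps"]
    if finite_ps.empty:
        raise DDRError("no gene has a finite product score")
    ps_cut = finite_ps.quantile(candidate_quantile)
    cand = frame.loc[hk_present]
    cand = cand[np.isfinite(cand["ps"]) & (cand["ps"] <= ps_cut) & (cand["mean_expr"] >= min_expr)]
    if cand.empty:
        raise DDRError(
            "no housekeeping candidate passes the stability/expression filters "
            f"(ps <= {ps_cut:.4g}, mean_expr >= {min_expr})"
        )

    axis = _log2_axis(cand["mean_expr"], log_scale)
    x0 = float(axis.min())
    strata = np.round((axis - x0) / target_log2_spacing).astype(int)

    chosen: list[tuple[int, str]] = []
    for stratum in sorted(strata.unique()):
        members = cand[strata == stratum].sort_index()
        members = members.sort_values("ps", kind="stable")  # min ps, ties by gene ID
        chosen.append((int(stratum), str(members.index[0])))

    if n_refs is not None:
        if n_refs < 1:
            raise DDRError("n_refs must be >= 1")
        if n_refs > len(chosen):
            raise DDRError(f"n_refs={n_refs} exceeds the {len(chosen)} available strata")
        if n_refs == 1:
            genes = [g for _, g in chosen]
            best = min(genes, key=lambda g: (cand.loc[g, "ps"], g))
            chosen = [(s, g) for s, g in chosen if g == best]
        else:
            pos = {g: float(axis.loc[g]) for _, g in chosen}
            genes = [g for _, g in chosen]
            lo = min(genes, key=lambda g: pos[g])
            hi = max(genes, key=lambda g: pos[g])
            kept = [lo] if lo == hi else [lo, hi]
            while len(kept) < n_refs:
                rest = [g for g in genes if g not in kept]
                nxt = max(rest, key=lambda g: min(abs(pos[g] - pos[k]) for k in kept))
                kept.append(nxt)
            chosen = [(s, g) for s, g in chosen if g in kept]

    # ascending mean expression, then enforce minimum separation
    chosen.sort(key=lambda sg: float(cand.loc[sg[1], "mean_expr"]))
    filtered: list[tuple[int, str]] = []
    for stratum, gene in chosen:
        if filtered:
            prev = filtered[-1][1]
            gap = abs(float(axis.loc[gene]) - float(axis.loc[prev]))
            if gap < 0.5 * target_log2_spacing:
                continue
        filtered.append((stratum, gene))

    genes = [g for _, g in filtered]
    return ReferenceSet(
        gene_ids=genes,
        ps=[float(cand.loc[g, "ps"]) for g in genes],
        strata=[s for s, _ in filtered],
        target_log2_spacing=target_log2_spacing,
        log_scale=log_scale,
        mean_expr=[float(cand.loc[g, "mean_expr"]) for g in genes],
    )


def apply_reference_ids(matrix, reference_ids: list[str], target_log2_spacing: float = 2.0) -> ReferenceSet:
    """Re-anchor a known reference gene set in a new dataset.

    The genes are re-ordered by their mean expression IN THE NEW dataset.
    A warning lists samples whose per-sample ordering of the reference values
    disagrees with the mean-expression ordering (rank inversions signal that
    tier boundaries may be unstable in those samples).
    """
    expr = _expr_frame(matrix)
    ids = [g.strip() for g in reference_ids]
    missing = [g for g in ids if g not in expr.index]
    if missing:
        raise DDRError(f"reference gene(s) absent from matrix: {missing}")
    sub = expr.loc[ids]
    mean = sub.mean(axis=1)
    order = mean.sort_values(kind="stable").index.tolist()
    sorted_vals = sub.loc[order].to_numpy()
    inversions = [
        str(expr.columns[k])
        for k in range(sorted_vals.shape[1])
        if np.any(np.diff(sorted_vals[:, k]) < 0)
    ]
    if inversions:
        warnings.warn(
            f"reference ordering disagrees with mean ordering in {len(inversions)} "
            f"sample(s): {inversions[:10]}",
            stacklevel=2,
        )
    log_scale = bool(expr.to_numpy().max() < LOG_SCALE_MAX)
    return ReferenceSet(
        gene_ids=order,
        ps=[float("nan")] * len(order),
        strata=list(range(len(order))),
        target_log2_spacing=target_log2_spacing,
        log_scale=log_scale,
        mean_expr=[float(mean.loc[g]) for g in order],
    )
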