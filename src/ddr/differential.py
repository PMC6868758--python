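"""Differential expression on tier contingency tables.

Each gene's condition x tier table is tested for independence with the
Freeman-Halton generalization of Fisher's exact test: under the null, with
all margins fixed, the table probability is multivariate hypergeometric, and
the two-sided p-value is the total probability of all margin-fixed tables no
more probable than the observed one. Small tables are enumerated exhaustively;
large ones fall back to seeded Monte-Carlo sampling of margin-fixed tables.
P-values are Benjamini-Hochberg adjusted, and genes are ranked by FDR and by
the Expression Distance (ED) — the difference between the two conditions in a
gene's mean tier index, whose sign gives the direction of regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import DDRError, SampleMetadata
from .references import ReferenceSet
from .tiering import TierContingencyTable, TierMatrix, assign_tiers, contingency_tables

#: relative tolerance when comparing table probabilities to the observed one
#: (guards against spurious tie-breaking by floating-point rounding)
_REL_TOL = 1e-7

DEFAULT_MC_THRESHOLD = 2_000_000
DEFAULT_MC_REPS = 100_000
DEFAULT_FDR_CUT = 0.1


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    test_method: str  # "exact_enumeration" | "monte_carlo" | "degenerate"
    mc_reps: int | None = None


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    p_value: float
    fdr: float
    ed: float
    table: TierContingencyTable
    test_method: str
    mc_reps: int | None = None


def _log_table_prob(counts: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a margin-fixed table."""
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def _count_2xt_tables(col: np.ndarray, r_a: int) -> int:
    """Number of 2-row tables with the given margins (polynomial DP)."""
    poly = np.zeros(r_a + 1, dtype=np.float64)
    poly[0] = 1.0
    for m in col:
        kernel = np.ones(min(int(m), r_a) + 1)
        poly = np.convolve(poly, kernel)[: r_a + 1]
    return int(poly[r_a])


def _enumerate_2xt(counts: np.ndarray) -> float:
    """Exact two-sided p for a 2 x T table by vectorized enumeration."""
    col = counts.sum(axis=0)
    r_a = int(counts.sum(axis=1)[0])
    log_obs = _log_table_prob(counts)
    base = (
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(counts.sum() + 1)
    )
    # grow (partial sum, partial log term) pairs column by column, pruning
    # prefixes that cannot reach the row-A margin
    sums = np.zeros(1, dtype=np.int64)
    lps = np.zeros(1, dtype=np.float64)
    remaining = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])
    for j, m in enumerate(col):
        a = np.arange(int(m) + 1)
        term = -gammaln(a + 1) - gammaln(m - a + 1)
        new_sums = (sums[:, None] + a[None, :]).ravel()
        new_lps = (lps[:, None] + term[None, :]).ravel()
        keep = (new_sums <= r_a) & (new_sums + remaining[j] >= r_a)
        sums, lps = new_sums[keep], new_lps[keep]
    lps += base
    mask = lps <= log_obs + _REL_TOL
    return float(min(1.0, np.exp(lps[mask]).sum()))


def _enumerate_generic(counts: np.ndarray) -> float:
    """Exact p for a C x T table by recursive enumeration (small tables)."""
    row = counts.sum(axis=1).astype(int)
    col = counts.sum(axis=0).astype(int)
    log_obs = _log_table_prob(counts)
    base = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(counts.sum() + 1)
    total = 0.0

    def compositions(margin: int, caps: list[int]):
        if len(caps) == 1:
            if margin <= caps[0]:
                yield (margin,)
            return
        lo = max(0, margin - sum(caps[1:]))
        for a in range(lo, min(margin, caps[0]) + 1):
            for rest in compositions(margin - a, caps[1:]):
                yield (a,) + rest

    def recurse(i: int, rem_col: list[int], lp: float) -> None:
        nonlocal total
        if i == len(row) - 1:
            cells = np.array(rem_col)
            lp_full = lp - gammaln(cells + 1).sum() + base
            if lp_full <= log_obs + _REL_TOL:
                total += float(np.exp(lp_full))
            return
        for vec in compositions(int(row[i]), rem_col):
            lp_i = lp - gammaln(np.array(vec) + 1).sum()
            recurse(i + 1, [c - v for c, v in zip(rem_col, vec)], lp_i)

    recurse(0, list(col), 0.0)
    return float(min(1.0, total))


def _enumeration_size(counts: np.ndarray) -> float:
    """Upper bound on the number of margin-fixed tables."""
    row = counts.sum(axis=1).astype(int)
    col = counts.sum(axis=0).astype(int)
    if counts.shape[0] == 2:
        return float(_count_2xt_tables(col, int(row[0])))
    t = counts.shape[1]
    bound = 1.0
    for r in row[:-1]:
        bound *= float(np.exp(gammaln(r + t) - gammaln(r + 1) - gammaln(t)))
    return bound


def _monte_carlo(counts: np.ndarray, reps: int, rng: np.random.Generator) -> float:
    """p estimated by sampling margin-fixed tables under the null."""
    row = counts.sum(axis=1).astype(int)
    col = counts.sum(axis=0).astype(int)
    log_obs = _log_table_prob(counts)
    base = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(counts.sum() + 1)
    if counts.shape[0] == 2:
        draws = rng.multivariate_hypergeometric(col, int(row[0]), size=reps)
        lps = (
            base
            - gammaln(draws + 1).sum(axis=1)
            - gammaln(col[None, :] - draws + 1).sum(axis=1)
        )
    else:
        # permute sample labels: tiers as a flat vector, groups as fixed slices
        tier_vec = np.repeat(np.arange(len(col)), col)
        n = tier_vec.size
        lps = np.full(reps, base)
        order = np.argsort(rng.random((reps, n)), axis=1)
        permuted = tier_vec[order]
        start = 0
        t = len(col)
        for r in row:
            block = permuted[:, start : start + r]
            cells = (block[:, :, None] == np.arange(t)[None, None, :]).sum(axis=1)
            lps -= gammaln(cells + 1).sum(axis=1)
            start += r
    hits = int(np.sum(lps <= log_obs + _REL_TOL))
    return (1 + hits) / (1 + reps)


def fisher_exact(
    table: TierContingencyTable | np.ndarray,
    mc_threshold: int = DEFAULT_MC_THRESHOLD,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | np.random.Generator | None = 0,
) -> FisherResult:
    """Two-sided exact test of condition/tier independence.

    Zero-margin rows and columns are dropped first. A table degenerate after
    dropping (fewer than 2 nonzero rows or columns) gets p = 1 with the
    ``degenerate`` method flag rather than an exception, so genome-wide runs
    complete. Enumeration is used when the table count bound is at most
    ``mc_threshold``; otherwise ``mc_reps`` seeded Monte-Carlo draws.
    """
    counts = table.counts if isinstance(table, TierContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2:
        raise DDRError("contingency table must be 2-dimensional")
    if (counts < 0).any():
        raise DDRError("negative count in contingency table")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return FisherResult(p_value=1.0, test_method="degenerate")
    if _enumeration_size(counts) <= mc_threshold:
        if counts.shape[0] == 2:
            p = _enumerate_2xt(counts)
        else:
            p = _enumerate_generic(counts)
        return FisherResult(p_value=p, test_method="exact_enumeration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _monte_carlo(counts, mc_reps, rng)
    return FisherResult(p_value=p, test_method="monte_carlo", mc_reps=mc_reps)


def expression_distance(table: TierContingencyTable | np.ndarray) -> float:
    """Mean tier index of the first condition minus that of the second.

    Tier indices enter 1-based; any constant offset cancels between the two
    group means, so only the difference of mean tiers matters.
    """
    counts = table.counts if isinstance(table, TierContingencyTable) else np.asarray(table)
    if counts.shape[0] != 2:
        raise DDRError(f"expression distance needs exactly 2 conditions, got {counts.shape[0]}")
    n_a, n_b = counts.sum(axis=1)
    if n_a == 0 or n_b == 0:
        raise DDRError("empty condition in contingency table")
    j = np.arange(1, counts.shape[1] + 1)
    return float((counts[0] * j).sum() / n_a - (counts[1] * j).sum() / n_b)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise DDRError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sorted_results(results: list[DEResult]) -> list[DEResult]:
    return sorted(results, key=lambda r: (r.fdr, -abs(r.ed), r.gene_id))


def run_de(
    matrix,
    metadata: SampleMetadata,
    refs: ReferenceSet,
    condition_a: str,
    condition_b: str,
    seed: int = 0,
    mc_threshold: int = DEFAULT_MC_THRESHOLD,
    mc_reps: int = DEFAULT_MC_REPS,
    genes: list[str] | None = None,
) -> list[DEResult]:
    """Full two-condition DE: tiers -> tables -> exact tests -> BH -> ED.

    Results are sorted by FDR ascending, then |ED| descending, then gene ID.
    Identical inputs and seed give identical output. P-values of identical
    contingency tables are computed once and shared.
    """
    for cond in (condition_a, condition_b):
        if cond not in metadata.conditions:
            raise DDRError(f"condition {cond!r} not present in metadata")
        if len(metadata.samples_for(cond)) < 2:
            raise DDRError(f"condition {cond!r} has fewer than 2 samples")
    keep = metadata.table.isin([condition_a, condition_b])
    sub_meta = SampleMetadata(metadata.table[keep])
    # impose (a, b) row order regardless of first appearance in the file
    ordered = pd.concat(
        [
            sub_meta.table[sub_meta.table == condition_a],
            sub_meta.table[sub_meta.table == condition_b],
        ]
    )
    sub_meta = SampleMetadata(ordered)

    tiers = assign_tiers(matrix, refs)
    sample_keep = [s for s in tiers.sample_ids if s in set(ordered.index)]
    tiers = TierMatrix(tiers=tiers.tiers[sample_keep], n_refs=tiers.n_refs)
    tables = contingency_tables(tiers, sub_meta, genes)

    rng = np.random.default_rng(seed)
    cache: dict[bytes, FisherResult] = {}
    results: list[DEResult] = []
    for tbl in tables:
        key = tbl.counts.tobytes()
        fr = cache.get(key)
        if fr is None:
            fr = fisher_exact(tbl, mc_threshold=mc_threshold, mc_reps=mc_reps, seed=rng)
            cache[key] = fr
        results.append(
            DEResult(
                gene_id=tbl.gene_id,
                p_value=fr.p_value,
                fdr=np.nan,
                ed=expression_distance(tbl),
                table=tbl,
                test_method=fr.test_method,
                mc_reps=fr.mc_reps,
            )
        )
    fdrs = adjust_fdr([r.p_value for r in results])
    results = [
        DEResult(r.gene_id, r.p_value, float(f), r.ed, r.table, r.test_method, r.mc_reps)
        for r, f in zip(results, fdrs)
    ]
    return _sorted_results(results)


def pairwise_markers(
    matrix,
    metadata: SampleMetadata,
    refs: ReferenceSet,
    fdr_cut: float = DEFAULT_FDR_CUT,
    ed_cut: float = 0.0,
    top_k: int | None = None,
    seed: int = 0,
    mc_threshold: int = DEFAULT_MC_THRESHOLD,
    mc_reps: int = DEFAULT_MC_REPS,
) -> list[str]:
    """Markers from every pairwise condition comparison, merged and deduplicated.

    Per pair, genes pass with fdr <= fdr_cut and |ED| >= ed_cut; if ``top_k``
    is set, only the first ``top_k`` of the pair's ranked passing genes are
    kept. The union preserves first-appearance order over pairs taken in
    condition order.
    """
    conditions = metadata.conditions
    if len(conditions) < 2:
        raise DDRError("pairwise markers need at least 2 conditions")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions) * (len(conditions) - 1) // 2)
    merged: list[str] = []
    seen: set[str] = set()
    k = 0
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            res = run_de(
                matrix, metadata, refs, a, b,
                seed=child_seed, mc_threshold=mc_threshold, mc_reps=mc_reps,
            )
            passing = [r for r in res if r.fdr <= fdr_cut and abs(r.ed) >= ed_cut]
            if top_k is not None:
                passing = passing[:top_k]
            for r in passing:
                if r.gene_id not in seen:
                    seen.add(r.gene_id)
                    merged.append(r.gene_id)
    return merged


def one_vs_rest_markers(
    matrix,
    metadata: SampleMetadata,
    refs: ReferenceSet,
    per_class_top_k: int = 5,
    ed_direction: str = "any",
    exclude: list[str] | None = None,
    fdr_cut: float = DEFAULT_FDR_CUT,
    seed: int = 0,
    mc_threshold: int = DEFAULT_MC_THRESHOLD,
    mc_reps: int = DEFAULT_MC_REPS,
) -> dict[str, list[str]]:
    """Top class-specific markers from each class-vs-pooled-rest comparison.

    ``ed_direction='up'`` ranks by ED descending (class-elevated genes only);
    ``'any'`` ranks by |ED| descending. ``exclude`` removes genes (e.g.
    non-coding RNAs) before ranking.
    """
    if ed_direction not in ("any", "up"):
        raise DDRError(f"unknown ed_direction {ed_direction!r}")
    conditions = metadata.conditions
    if len(conditions) < 2:
        raise DDRError("one-vs-rest needs at least 2 classes")
    excl = set(exclude or [])
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions))
    out: dict[str, list[str]] = {}
    for ci, cls in enumerate(conditions):
        if len(metadata.samples_for(cls)) < 2:
            raise DDRError(f"class {cls!r} has fewer than 2 samples")
        rest_label = "__rest__"
        relabeled = metadata.table.where(metadata.table == cls, rest_label)
        # class first so positive ED means elevated in the class
        ordered = pd.concat(
            [relabeled[relabeled == cls], relabeled[relabeled == rest_label]]
        )
        sub_meta = SampleMetadata(ordered)
        child_seed = int(children[ci].generate_state(1)[0] % (2**31))
        res = run_de(
            matrix, sub_meta, refs, cls, rest_label,
            seed=child_seed, mc_threshold=mc_threshold, mc_reps=mc_reps,
        )
        passing = [r for r in res if r.fdr <= fdr_cut and r.gene_id not in excl]
        if ed_direction == "up":
            passing = [r for r in passing if r.ed > 0]
            passing.sort(key=lambda r: (-r.ed, r.fdr, r.gene_id))
        else:
            passing.sort(key=lambda r: (-abs(r.ed), r.fdr, r.gene_id))
        out[cls] = [r.gene_id for r in passing[:per_class_top_k]]
    return out
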