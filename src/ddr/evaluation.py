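"""Benchmarking harness for differential-expression gene lists.

Treats the DEG list from the full dataset as the gold standard and measures
precision/recall of DEG lists from random equal-size subsamples; estimates
false discovery rates by "mock" comparisons between two random halves of a
single condition (where every discovery is false); and compares DEG lists
from different methods with the Szymkiewicz-Simpson overlap coefficient.
External tools' DEG lists are consumed as plain gene-list files, so the
harness is method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DDRError, SampleMetadata
from .differential import DEFAULT_FDR_CUT, run_de
from .references import ReferenceSet


def precision_recall(de_full: list[str], de_subset: list[str]) -> tuple[float, float]:
    """Precision and recall of a subset DEG list against the full-data list.

    Empty denominators yield NaN rather than an error.
    """
    full, sub = set(de_full), set(de_subset)
    inter = len(full & sub)
    precision = inter / len(sub) if sub else float("nan")
    recall = inter / len(full) if full else float("nan")
    return precision, recall


def overlap_coefficient(x: list[str], y: list[str]) -> float:
    """Szymkiewicz-Simpson coefficient |x ∩ y| / min(|x|, |y|)."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise DDRError("overlap coefficient requires two nonempty lists")
    return len(xs & ys) / min(len(xs), len(ys))


def overlap_matrix(lists: dict[str, list[str]]) -> pd.DataFrame:
    names = list(lists)
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            v = overlap_coefficient(lists[a], lists[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-(size, repetition) precision/recall against the full-data DEGs."""

    gold_standard: list[str]
    records: pd.DataFrame  # columns: size, repetition, n_degs, precision, recall
    fdr_cut: float
    seed: int

    def mean_by_size(self) -> pd.DataFrame:
        return self.records.groupby("size")[["precision", "recall"]].mean()


def _significant(results, fdr_cut: float) -> list[str]:
    return [r.gene_id for r in results if r.fdr <= fdr_cut]


def subset_benchmark(
    matrix,
    metadata: SampleMetadata,
    refs: ReferenceSet,
    condition_a: str,
    condition_b: str,
    sizes: list[int],
    repetitions: int = 10,
    fdr_cut: float = DEFAULT_FDR_CUT,
    seed: int = 0,
    **de_kwargs,
) -> BenchmarkReport:
    """Precision/recall of subset DEG calls against the full-data gold standard.

    For each size, ``repetitions`` random equal-n per-group subsamples (without
    replacement) are drawn, DE is re-run on each, and the resulting DEG list is
    scored against the full-data list.
    """
    groups = {c: metadata.samples_for(c) for c in (condition_a, condition_b)}
    for c, samples in groups.items():
        if max(sizes) > len(samples):
            raise DDRError(
                f"subset size {max(sizes)} exceeds group {c!r} of {len(samples)} samples"
            )
    gold = _significant(
        run_de(matrix, metadata, refs, condition_a, condition_b, seed=seed, **de_kwargs),
        fdr_cut,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(repetitions):
            chosen: list[str] = []
            for c in (condition_a, condition_b):
                samples = np.asarray(groups[c])
                chosen.extend(rng.choice(samples, size=size, replace=False))
            sub_meta = SampleMetadata(metadata.table.loc[chosen])
            de_seed = int(rng.integers(2**31))
            degs = _significant(
                run_de(matrix, sub_meta, refs, condition_a, condition_b, seed=de_seed, **de_kwargs),
                fdr_cut,
            )
            p, r = precision_recall(gold, degs)
            rows.append(
                {"size": size, "repetition": rep, "n_degs": len(degs), "precision": p, "recall": r}
            )
    return BenchmarkReport(
        gold_standard=gold,
        records=pd.DataFrame(rows),
        fdr_cut=fdr_cut,
        seed=seed,
    )


def mock_fdr(
    matrix,
    metadata: SampleMetadata,
    refs: ReferenceSet,
    condition: str,
    reference_discovery_count: int,
    repetitions: int = 10,
    fdr_cut: float = DEFAULT_FDR_CUT,
    seed: int = 0,
    **de_kwargs,
) -> list[float]:
    """False-discovery-rate estimates from mock within-condition comparisons.

    Samples of one condition are split at random into two near-equal halves
    (floor(n/2) and ceil(n/2)); any DEG between the halves is a false
    positive. Each repetition's FDR estimate is the mock DEG count divided by
    ``reference_discovery_count`` — the DEG count of the corresponding real
    two-condition comparison, supplied by the caller.
    """
    samples = metadata.samples_for(condition)
    if len(samples) < 4:
        raise DDRError(f"condition {condition!r} needs at least 4 samples for mock splits")
    if reference_discovery_count <= 0:
        raise DDRError("reference_discovery_count must be positive")
    rng = np.random.default_rng(seed)
    estimates = []
    half = len(samples) // 2
    for _ in range(repetitions):
        perm = rng.permutation(samples)
        labels = pd.Series(
            ["mockA"] * half + ["mockB"] * (len(samples) - half),
            index=pd.Index(perm, name="sample_id"),
        )
        de_seed = int(rng.integers(2**31))
        degs = _significant(
            run_de(matrix, SampleMetadata(labels), refs, "mockA", "mockB", seed=de_seed, **de_kwargs),
            fdr_cut,
        )
        estimates.append(len(degs) / reference_discovery_count)
    return estimates
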