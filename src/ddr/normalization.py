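"""Library-size normalization of count matrices.

Implements trimmed-mean-of-M-values (TMM) scale factors and the
counts-per-million transform. TMM estimates, for each sample against a
reference sample, a robust weighted mean of per-gene log expression ratios
(M-values) after doubly trimming extreme M-values and extreme average
log-intensities (A-values); the weights are inverse approximate binomial
variances of the log ratios. Factors are rescaled to geometric mean 1.

Pre-normalized (microarray) matrices bypass this module: downstream steps
consume them as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DDRError, ExpressionMatrix


@dataclass(frozen=True)
class NormalizedMatrix:
    """CPM-scale expression with the per-sample TMM scale factors used."""

    cpm: pd.DataFrame  # genes x samples
    scale_factors: pd.Series  # per sample, geometric mean 1

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


def _check_counts(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.platform_kind != "counts":
        raise DDRError("TMM/CPM require a counts matrix")
    counts = matrix.values.to_numpy(dtype=np.float64)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(libsize == 0)]
        raise DDRError(f"all-zero sample(s): {bad}")
    return counts


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, trim_m: float, trim_a: float
) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse of the delta-method variance of M under binomial sampling
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    if np.max(np.abs(m)) < 1e-6:  # samples identical up to depth
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))


def tmm_factors(
    matrix: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1.

    When ``ref_sample`` is unset, the reference is the sample whose
    upper-quartile count fraction is closest to the mean upper-quartile
    fraction. Genes with a zero count in either member of a pair are dropped
    from that pair's M/A lists.
    """
    for name, t in (("trim_m", trim_m), ("trim_a", trim_a)):
        if not (0 <= t < 0.5):
            raise DDRError(f"{name} must be in [0, 0.5), got {t}")
    counts = _check_counts(matrix)
    libsize = counts.sum(axis=0)
    samples = matrix.sample_ids

    if ref_sample is None:
        uq = np.array(
            [np.quantile(counts[:, s], 0.75) / libsize[s] for s in range(len(samples))]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in samples:
            raise DDRError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = samples.index(ref_sample)

    log_f = np.array(
        [
            _tmm_pair(counts[:, s], counts[:, ref_idx], libsize[s], libsize[ref_idx], trim_m, trim_a)
            for s in range(len(samples))
        ]
    )
    log_f -= log_f.mean()  # geometric mean 1
    return pd.Series(2.0**log_f, index=samples, name="tmm_factor")


def cpm(matrix: ExpressionMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts per million: ``1e6 * count / (libsize * factor)``."""
    counts = _check_counts(matrix)
    if factors is None:
        factors = tmm_factors(matrix)
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise DDRError("scale factors must be positive and cover every sample")
    libsize = counts.sum(axis=0)
    eff = libsize * factors.to_numpy()
    if (eff == 0).any():
        raise DDRError("zero effective library size")
    values = 1e6 * counts / eff
    return NormalizedMatrix(
        cpm=pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids),
        scale_factors=factors,
    )


def normalize(matrix: ExpressionMatrix, **tmm_kwargs) -> pd.DataFrame:
    """Expression values ready for reference selection.

    Counts are TMM-normalized and converted to CPM; pre-normalized
    (microarray) matrices pass through unchanged.
    """
    if matrix.platform_kind == "counts":
        return cpm(matrix, tmm_factors(matrix, **tmm_kwargs)).cpm
    return matrix.values.copy()
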