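"""Synthetic expression data with the structure the tier method assumes.

The generator emulates a two-(or multi-)condition bulk RNA-seq experiment:

* negative-binomial counts with gene-specific baseline means (log-uniform on
  the log2-CPM axis) and a common dispersion;
* per-sample library-size multipliers;
* a stratum of planted housekeeping genes at fixed log2-CPM levels with only
  counting (Poisson) noise plus a small lognormal biological wobble, so they
  are recoverable as references;
* planted differentially expressed genes whose group-2 mean is multiplied by
  2^(+-log2fc), with baselines kept inside the reference-spanned expression
  range so the planted fold change is observable as a tier shift;
* an optional "second platform": per-sample strictly increasing transforms
  (log-affine or random rank-preserving piecewise-linear), optionally with
  additive noise that deliberately breaks exact tier equality.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DDRError, ExpressionMatrix, SampleMetadata


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    groups: list[tuple[str, int]] = field(default_factory=lambda: [("A", 30), ("B", 30)])
    n_housekeeping: int = 5
    housekeeping_log2_levels: list[float] = field(default_factory=lambda: [2, 4, 6, 8, 10])
    housekeeping_cov_max: float = 0.05
    n_de: int = 50
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log2_mean_range: tuple[float, float] = (0.0, 12.0)
    de_log2_mean_range: tuple[float, float] | None = (3.0, 9.0)
    library_size_range: tuple[float, float] = (8e6, 1.5e7)
    platform_transform: str = "log_affine"  # none | log_affine | rank_preserving_random
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_housekeeping > self.n_genes:
            raise DDRError("n_housekeeping exceeds n_genes")
        if self.n_de > self.n_genes - self.n_housekeeping:
            raise DDRError("n_de exceeds the non-housekeeping gene count")
        if self.nb_dispersion <= 0:
            raise DDRError("nb_dispersion must be positive")
        if self.n_housekeeping != len(self.housekeeping_log2_levels):
            raise DDRError("n_housekeeping must match housekeeping_log2_levels length")
        if self.platform_transform not in ("none", "log_affine", "rank_preserving_random"):
            raise DDRError(f"unknown platform_transform {self.platform_transform!r}")
        if not all(n >= 2 for _, n in self.groups):
            raise DDRError("every group needs at least 2 samples")


@dataclass
class GroundTruth:
    housekeeping: dict[str, int]  # gene id -> intended stratum index
    de_genes: dict[str, float]  # gene id -> signed log2 fold change (group2 vs group1)
    transform_params: dict = field(default_factory=dict)
    tier_equality_exact: bool = True  # False once platform noise is applied

    def to_dict(self) -> dict:
        return asdict(self)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate a counts matrix, metadata and the planted ground truth.

    Housekeeping levels and baseline means are on the log2-CPM axis; the
    expected count of a gene is 2^level x library_size / 1e6. Differential
    genes are expressed in the second group at 2^(+-de_log2fc) times their
    first-group mean (random sign per gene); with more than two groups the
    fold change applies to every non-first group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_hk, n_de = config.n_housekeeping, config.n_de
    n_bg = config.n_genes - n_hk - n_de

    hk_ids = [f"HK{i+1:02d}" for i in range(n_hk)]
    de_ids = [f"DE{i+1:03d}" for i in range(n_de)]
    bg_ids = [f"G{i+1:05d}" for i in range(n_bg)]
    gene_ids = hk_ids + de_ids + bg_ids

    sample_ids, labels = [], []
    for name, n in config.groups:
        sample_ids.extend(f"{name}_{i+1:02d}" for i in range(n))
        labels.extend([name] * n)
    n_samples = len(sample_ids)
    group_of = np.array([g for g, (name, n) in enumerate(config.groups) for _ in range(n)])

    lo, hi = config.baseline_log2_mean_range
    de_lo, de_hi = config.de_log2_mean_range or (lo, hi)
    base_log2 = np.concatenate(
        [
            np.asarray(config.housekeeping_log2_levels, dtype=float),
            rng.uniform(de_lo, de_hi, size=n_de),
            rng.uniform(lo, hi, size=n_bg),
        ]
    )
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.atleast_1d(np.asarray(config.de_log2fc, dtype=float))
    lfc = np.resize(lfc, n_de) * signs

    libsize = rng.uniform(*config.library_size_range, size=n_samples)
    # expected counts: CPM level times depth, fold change in non-first groups
    log2_mu = np.tile(base_log2[:, None], (1, n_samples))
    de_rows = slice(n_hk, n_hk + n_de)
    log2_mu[de_rows, :] += np.where(group_of[None, :] > 0, lfc[:, None], 0.0)
    mu = 2.0**log2_mu * (libsize[None, :] / 1e6)

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    # housekeeping: Poisson counting noise plus small lognormal wobble
    hk_wobble = rng.lognormal(
        mean=0.0, sigma=config.housekeeping_cov_max, size=(n_hk, n_samples)
    )
    counts[:n_hk] = rng.poisson(mu[:n_hk] * hk_wobble)
    counts[n_hk:] = _nb_draw(rng, mu[n_hk:], config.nb_dispersion)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(
            counts.astype(np.float64), index=gene_ids, columns=sample_ids
        ),
        platform_kind="counts",
    )
    metadata = SampleMetadata(
        pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"))
    )
    truth = GroundTruth(
        housekeeping={g: i for i, g in enumerate(hk_ids)},
        de_genes={g: float(l) for g, l in zip(de_ids, lfc)},
    )
    return matrix, metadata, truth


def _rank_preserving_map(
    values: np.ndarray, rng: np.random.Generator, n_knots: int = 8
) -> np.ndarray:
    """Random increasing piecewise-linear transform of one sample."""
    vmax = values.max()
    knots_x = np.concatenate([[0.0], np.sort(rng.uniform(0, vmax, n_knots)), [vmax + 1.0]])
    increments = rng.uniform(0.05, 1.0, size=knots_x.size)
    knots_y = np.cumsum(increments)
    knots_y -= knots_y[0]  # keep f(0) = 0 so tier-0 semantics survive
    return np.interp(values, knots_x, knots_y) + values * 1e-9  # strictly increasing


def second_platform(
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Re-express the same biology through per-sample monotone transforms.

    Returns the transformed matrix (platform_kind='normalized') and a manifest
    of the per-sample transform parameters, including whether exact tier
    equality is preserved (it is not once noise_sd > 0).
    """
    if config.platform_transform == "none":
        raise DDRError("platform_transform is 'none'; no second platform to build")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arr = matrix.values.to_numpy(dtype=np.float64)
    out = np.empty_like(arr)
    params: dict[str, dict] = {}
    for k, sample in enumerate(matrix.sample_ids):
        if config.platform_transform == "log_affine":
            a = float(rng.uniform(0.5, 2.0))
            b = float(rng.uniform(0.0, 5.0))
            out[:, k] = a * np.log2(arr[:, k] + 1.0) + b
            params[sample] = {"kind": "log_affine", "a": a, "b": b}
        else:
            out[:, k] = _rank_preserving_map(arr[:, k], rng)
            params[sample] = {"kind": "rank_preserving_random"}
    exact = config.noise_sd == 0
    if config.noise_sd > 0:
        out = np.clip(out + rng.normal(0.0, config.noise_sd, size=out.shape), 0.0, None)
    manifest = {
        "transform": config.platform_transform,
        "noise_sd": config.noise_sd,
        "tier_equality_exact": exact,
        "per_sample": params,
    }
    transformed = ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        platform_kind="normalized",
    )
    return transformed, manifest
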