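import numpy as np
import pandas as pd
import pytest

import ddr


@pytest.fixture(scope="session")
def planted_sim():
    """Default simulated study: 2000 genes, 50 planted DE, 30 vs 30 samples."""
    cfg = ddr.SimulationConfig(seed=3)
    matrix, metadata, truth = ddr.simulate_counts(cfg)
    return cfg, matrix, metadata, truth


@pytest.fixture(scope="session")
def planted_refs(planted_sim):
    _, matrix, _, truth = planted_sim
    norm = ddr.normalize(matrix)
    refs = ddr.select_references(ddr.stability_scores(norm), sorted(truth.housekeeping))
    return norm, refs


@pytest.fixture
def tiny_matrix(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
    return path


def make_multiclass_dataset(
    n_classes: int = 4,
    markers_per_class: int = 5,
    n_per_class: int = 10,
    n_background: int = 40,
    seed: int = 5,
):
    """Normalized-intensity dataset with class-elevated planted markers.

    Five near-constant reference genes span the expression range; each class
    has ``markers_per_class`` genes expressed two tiers higher in that class
    than everywhere else. Background genes sit at a constant mid level.
    """
    rng = np.random.default_rng(seed)
    ref_levels = np.array([4.0, 16.0, 64.0, 256.0, 1024.0])
    classes = [f"C{k+1}" for k in range(n_classes)]
    sample_ids, labels = [], []
    for cls in classes:
        for i in range(n_per_class):
            sample_ids.append(f"{cls}_s{i+1}")
            labels.append(cls)
    n_samples = len(sample_ids)

    def jitter(shape):
        return rng.lognormal(0.0, 0.03, size=shape)

    rows, gene_ids = [], []
    for j, level in enumerate(ref_levels):
        gene_ids.append(f"REF{j+1}")
        rows.append(level * jitter(n_samples))
    truth = {}
    for k, cls in enumerate(classes):
        mask = np.array([lab == cls for lab in labels])
        for m in range(markers_per_class):
            g = f"MK_{cls}_{m+1}"
            gene_ids.append(g)
            vals = np.where(mask, 500.0, 8.0) * jitter(n_samples)
            rows.append(vals)
            truth.setdefault(cls, []).append(g)
    for b in range(n_background):
        gene_ids.append(f"BG{b+1:03d}")
        rows.append(30.0 * jitter(n_samples))

    matrix = ddr.ExpressionMatrix(
        values=pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids),
        platform_kind="normalized",
    )
    metadata = ddr.SampleMetadata(
        pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"))
    )
    refs = ddr.apply_reference_ids(matrix, [f"REF{j+1}" for j in range(5)])
    return matrix, metadata, refs, truth


@pytest.fixture(scope="session")
def multiclass_fixture():
    return make_multiclass_dataset()
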