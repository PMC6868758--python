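"""Reading and writing of expression matrices, metadata, gene lists and models.

On-disk conventions follow the GEO series-matrix habit: genes are rows,
samples are columns, the first column holds gene identifiers and the first
row sample identifiers. TSV vs CSV is chosen by file extension. Gene ID
matching everywhere in the package is exact string match after whitespace
trimming; symbol/alias resolution is deliberately out of scope.
"""

from __future__ import annotations

import json
import pickle
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1


class DDRError(Exception):
    """Base class for validation and runtime errors raised by this package."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression values.

    ``platform_kind`` is ``"counts"`` for raw RNA-seq read counts (integers;
    whole-number floats are tolerated on read) or ``"normalized"`` for
    pre-normalized intensities such as processed microarray data.
    """

    values: pd.DataFrame  # genes x samples, float64
    platform_kind: str  # "counts" | "normalized"

    def __post_init__(self) -> None:
        if self.platform_kind not in ("counts", "normalized"):
            raise DDRError(f"unknown platform_kind {self.platform_kind!r}")
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DDRError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise DDRError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            raise DDRError("missing values are not permitted in expression matrices")
        if (arr < 0).any():
            raise DDRError("negative expression value encountered")
        if self.platform_kind == "counts" and not np.allclose(arr, np.round(arr)):
            raise DDRError("counts platform requires whole-number values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SampleMetadata:
    """Mapping of sample IDs to condition labels.

    Condition ordering is first-appearance order in the source table; that
    ordering fixes the row order of every contingency table downstream.
    """

    table: pd.Series  # index = sample_id, values = condition label

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DDRError(f"sample listed twice in metadata: {dups[:5]}")
        labels = self.table.astype(str)
        if (labels.str.strip() == "").any():
            bad = self.table.index[labels.str.strip() == ""].tolist()
            raise DDRError(f"empty condition label for samples: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table:
            seen.setdefault(c)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.table.index[self.table == condition])

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Restrict to ``sample_ids``, warning about metadata-only samples."""
        idx = pd.Index(sample_ids)
        missing_meta = idx.difference(self.table.index)
        if len(missing_meta):
            raise DDRError(f"samples without metadata: {list(missing_meta)[:5]}")
        extra = self.table.index.difference(idx)
        if len(extra):
            warnings.warn(
                f"{len(extra)} metadata samples absent from the matrix were ignored: "
                f"{list(extra)[:5]}",
                stacklevel=2,
            )
        return SampleMetadata(self.table.loc[idx])


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path, platform_kind: str) -> ExpressionMatrix:
    """Read a delimited gene-by-sample matrix.

    First column: gene IDs; first row: sample IDs. Raises on missing file,
    non-numeric cells, duplicate IDs or negative values. For ``counts``,
    floats that are whole numbers (``2.0``) are accepted as integers.
    """
    path = Path(path)
    if not path.exists():
        raise DDRError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise DDRError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        raise DDRError(f"missing values in {path}")
    return ExpressionMatrix(values=df, platform_kind=platform_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep_for(path), index_label="gene", float_format="%.17g")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column sample_id/condition table (header optional)."""
    path = Path(path)
    if not path.exists():
        raise DDRError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    # Tolerate a header row: drop it if the first row repeats common labels.
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first[:2] in (["sample_id", "condition"], ["sample", "condition"]):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise DDRError(f"metadata must have two columns, got {df.shape[1]}")
    sample_ids = df.iloc[:, 0].astype(str).str.strip()
    conditions = df.iloc[:, 1].fillna("").astype(str).str.strip()
    series = pd.Series(conditions.values, index=pd.Index(sample_ids.values, name="sample_id"))
    return SampleMetadata(series)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": metadata.table.index, "condition": metadata.table.values}
    ).to_csv(path, sep=_sep_for(Path(path)), index=False, header=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file; '#' lines are comments."""
    path = Path(path)
    if not path.exists():
        raise DDRError(f"no such file: {path}")
    genes: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        g = line.strip()
        if not g or g.startswith("#"):
            continue
        if g in seen:
            raise DDRError(f"duplicate gene ID in list: {g}")
        seen.add(g)
        genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend("# " + ln for ln in header.splitlines())
    lines.extend(str(g) for g in genes)
    Path(path).write_text("\n".join(lines) + "\n")


def write_de_table(results: Sequence, path: str | Path) -> None:
    """Write DE results (already sorted by fdr asc, |ED| desc) to TSV.

    Columns: gene, p_value, fdr, ed, then one ``count_<condition>_tier<j>``
    column per contingency cell. An empty result list yields a header-only
    file with the four fixed columns.
    """
    path = Path(path)
    rows = []
    count_cols: list[str] = []
    for r in results:
        row: dict[str, object] = {
            "gene": r.gene_id,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "ed": r.ed,
        }
        tbl = r.table
        for ci, cond in enumerate(tbl.conditions):
            for j in range(tbl.counts.shape[1]):
                col = f"count_{cond}_tier{j}"
                row[col] = int(tbl.counts[ci, j])
                if col not in count_cols:
                    count_cols.append(col)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene", "p_value", "fdr", "ed"] + count_cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def save_model(model, path: str | Path) -> None:
    """Serialize a SignatureModel as a zip archive.

    The archive holds ``manifest.json`` (biomarkers, references, tier count,
    label order, classifier spec, format version) and ``payload.pkl`` (the
    fitted scikit-learn estimator).
    """
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "biomarkers": model.biomarkers,
        "reference_ids": model.reference_ids,
        "n_refs": model.n_refs,
        "labels": model.labels,
        "scheme": model.scheme,
        "classifier": model.classifier_spec,
    }
    with zipfile.ZipFile(Path(path), "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("payload.pkl", pickle.dumps(model.estimator))


def load_model(path: str | Path):
    from .classification import SignatureModel  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise DDRError(f"no such file: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            estimator = pickle.loads(zf.read("payload.pkl"))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise DDRError(f"corrupted model file {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DDRError(
            f"model format version mismatch: file has {version}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    return SignatureModel(
        biomarkers=list(manifest["biomarkers"]),
        reference_ids=list(manifest["reference_ids"]),
        n_refs=int(manifest["n_refs"]),
        labels=list(manifest["labels"]),
        scheme=manifest["scheme"],
        classifier_spec=dict(manifest["classifier"]),
        estimator=estimator,
    )
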