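"""Data model and delimited-text I/O for expression matrices, labels,
rankings and serialized classifier models.

The in-memory containers are thin, validated wrappers around numpy arrays
with explicit gene/sample identifier lists, following the microarray
convention of genes as rows and samples as columns.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DiscretizedMatrix",
    "RankingTable",
    "DataFormatError",
    "LabelingError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_ranking_table",
    "read_ranking_table",
    "serialize_model",
    "load_model",
]


class DataFormatError(ValueError):
    """Malformed matrix / table file (duplicates, non-numeric cells, ...)."""


class LabelingError(ValueError):
    """Sample present in the matrix but missing (or duplicated) in labels."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataFormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Continuous genes x samples expression matrix with per-sample class labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Expression values in arbitrary units; missing values are rejected.
    labels : list of str
        One class label per sample, aligned with ``sample_ids``.
    class_set : list of str, optional
        Ordered distinct class labels; defaults to order of first appearance.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    labels: list
    class_set: list = field(default=None)

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise DataFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(self.labels) != len(self.sample_ids):
            raise LabelingError(
                f"{len(self.labels)} labels for {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise DataFormatError(
                f"missing value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}; impute before loading"
            )
        if self.class_set is None:
            self.class_set = list(dict.fromkeys(self.labels))
        else:
            self.class_set = [str(c) for c in self.class_set]
        if len(self.class_set) < 2:
            raise LabelingError("need at least 2 distinct classes")
        bad = set(self.labels) - set(self.class_set)
        if bad:
            raise LabelingError(f"labels outside class_set: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels) -> "ExpressionMatrix":
        """Build from a genes x samples DataFrame and a sample->class mapping
        (dict or Series) or a label sequence aligned with the columns."""
        if isinstance(labels, (dict, pd.Series)):
            missing = [s for s in df.columns if str(s) not in
                       {str(k) for k in dict(labels)}]
            if missing:
                raise LabelingError(f"no class label for sample(s): {missing}")
            lab = {str(k): str(v) for k, v in dict(labels).items()}
            label_list = [lab[str(s)] for s in df.columns]
        else:
            label_list = list(labels)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float),
                   label_list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def label_codes(self) -> np.ndarray:
        """Labels as integer indices into ``class_set``."""
        lut = {c: j for j, c in enumerate(self.class_set)}
        return np.array([lut[l] for l in self.labels], dtype=np.intp)


@dataclass
class DiscretizedMatrix:
    """Integer range codes per gene, 0-based in ascending expression order."""

    gene_ids: list
    sample_ids: list
    codes: np.ndarray  # (n_genes, n_samples), int
    labels: list
    class_set: list
    ranges_per_gene: list  # m_g >= 1
    boundaries_per_gene: list  # ascending cut points, len m_g - 1

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.codes.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError("codes shape mismatch")
        for g, m in enumerate(self.ranges_per_gene):
            row = self.codes[g]
            if row.min() < 0 or row.max() >= m:
                raise DataFormatError(
                    f"gene {self.gene_ids[g]!r}: code outside [0, {m})")
            b = np.asarray(self.boundaries_per_gene[g], dtype=float)
            if b.size and not np.all(np.diff(b) > 0):
                raise DataFormatError(
                    f"gene {self.gene_ids[g]!r}: boundaries not ascending")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def label_codes(self) -> np.ndarray:
        lut = {c: j for j, c in enumerate(self.class_set)}
        return np.array([lut[l] for l in self.labels], dtype=np.intp)

    def restrict(self, gene_subset: Sequence[str]) -> "DiscretizedMatrix":
        """Sub-matrix keeping only ``gene_subset`` (in the given order)."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_subset]
        return DiscretizedMatrix(
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.codes[rows],
            list(self.labels),
            list(self.class_set),
            [self.ranges_per_gene[i] for i in rows],
            [self.boundaries_per_gene[i] for i in rows],
        )

    def restrict_samples(self, sample_idx: Sequence[int]) -> "DiscretizedMatrix":
        sample_idx = list(sample_idx)
        return DiscretizedMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in sample_idx],
            self.codes[:, sample_idx],
            [self.labels[i] for i in sample_idx],
            list(self.class_set),
            list(self.ranges_per_gene),
            list(self.boundaries_per_gene),
        )


@dataclass
class RankingTable:
    """Genes sorted by descending LorenzGini score (ties: gene id)."""

    entries: list  # list of (gene_id, GeneScore)

    def __post_init__(self):
        scores = [s.lorenzgini for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("ranking not sorted by descending score")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def gene_ids(self) -> list:
        return [g for g, _ in self.entries]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for gene, s in self.entries:
            rows.append(
                dict(gene_id=gene, lorenzgini=s.lorenzgini,
                     delta_gini=s.delta_gini, split=s.split,
                     gini_standard=s.gini_A_standard,
                     gini_weighted=s.gini_A_weighted, gini_dataset=s.gini_D,
                     n_ranges=len(s.alpha)))
        return pd.DataFrame(rows)


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_labels(path: str, delimiter: str | None = None) -> dict:
    """Two-column (sample_id, class) file -> dict; a 'sample_id' header row
    is tolerated and skipped."""
    sep = _delimiter_for(path, delimiter)
    out: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sid, cls = parts[0].strip(), parts[1].strip()
            if ln == 1 and sid.lower() in ("sample_id", "sample"):
                continue
            if sid in out:
                raise LabelingError(f"duplicate label for sample {sid!r}")
            out[sid] = cls
    return out


def write_labels(labels: dict, path: str, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write(f"sample_id{sep}class\n")
        for sid, cls in labels.items():
            fh.write(f"{sid}{sep}{cls}\n")


def read_expression_matrix(
    path: str,
    labels_path: str,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix plus its sample-label file.

    First row holds sample ids, first column gene ids.  Set
    ``transpose=True`` if the file is samples x genes; orientation is never
    guessed silently.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    _check_unique(list(df.index), "gene")
    _check_unique(list(df.columns), "sample")
    # locate non-numeric cells precisely before coercion
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        orig_na = df[col].isna()
        bad = coerced.isna() & ~orig_na
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise DataFormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}")
        df[col] = coerced
    labels = read_labels(labels_path, delimiter)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise LabelingError(
            f"sample(s) missing from labels file: {missing}")
    return ExpressionMatrix.from_dataframe(df, labels)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str, delimiter: str | None = None
) -> None:
    sep = _delimiter_for(path, delimiter)
    matrix.to_dataframe().to_csv(path, sep=sep, float_format="%.17g",
                                 index_label="gene_id")


def write_ranking_table(table: RankingTable, path: str) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False,
                                float_format="%.17g")


def read_ranking_table(path: str) -> pd.DataFrame:
    """Rankings round-trip as a plain DataFrame (scores only, no per-row
    diagnostics)."""
    return pd.read_csv(path, sep="\t")


def serialize_model(model, path: str) -> None:
    """Write a fitted Bayesian-network classifier as self-describing JSON.

    Probabilities survive the decimal round-trip bit-exactly (repr-based
    float formatting, >= 17 significant digits).
    """
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def load_model(path: str):
    from .bayesnet import BayesNetModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise DataFormatError(f"cannot parse model file {path}: {e}") from e
    return BayesNetModel.from_dict(payload)
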