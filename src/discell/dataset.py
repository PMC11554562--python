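"""Expression-matrix container plus readers/writers.

``CellDataset`` holds a cells x features matrix ``x`` (raw counts or
log-normalized values), per-cell attribute annotations validated against an
:class:`~discell.schema.AttributeSchema`, and stable cell/feature names.
Cells are rows, features are columns, everywhere.

Supported on-disk forms: an annotated h5ad container (via :mod:`anndata`),
dense CSV/TSV, and MatrixMarket MTX with ``.rows``/``.cols`` name sidecars;
attribute tables are CSV with a header row whose first column is the cell id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .schema import CATEGORICAL, MISSING, ORDERED, Attribute, AttributeSchema

__all__ = ["CellDataset", "load_dataset", "split_dataset", "write_dataset"]

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"


@dataclass
class CellDataset:
    """Validated expression matrix with per-cell attribute values.

    Parameters
    ----------
    x
        n x M numeric matrix. Non-negative for count likelihoods.
    schema
        Declares the known attributes.
    attribute_values
        Per attribute: categorical values as an object array of labels with
        ``None`` marking missing; ordered values as an (n, dim) float array
        with all-NaN rows marking missing.
    cell_ids, feature_names
        Unique string identifiers for rows and columns.
    layer_kind
        ``"raw_counts"`` or ``"log_normalized"`` — declared by the caller,
        never inferred.
    """

    x: np.ndarray
    schema: AttributeSchema
    attribute_values: Dict[str, np.ndarray] = field(default_factory=dict)
    cell_ids: List[str] = None
    feature_names: List[str] = None
    layer_kind: str = RAW_COUNTS

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2:
            raise ValueError(f"x must be 2-D (cells x features); got shape {self.x.shape}")
        n, m = self.x.shape
        if n < 1 or m < 1:
            raise ValueError(f"need n >= 1 cells and M >= 1 features; got {n} x {m}")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if self.feature_names is None:
            self.feature_names = [f"feature{j}" for j in range(m)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell axis mismatch: matrix has {n} rows, {len(self.cell_ids)} cell ids"
            )
        if len(self.feature_names) != m:
            raise ValueError(
                f"feature axis mismatch: matrix has {m} columns, "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids (ids key the per-cell embedding)")
        if self.layer_kind not in (RAW_COUNTS, LOG_NORMALIZED):
            raise ValueError(f"unknown layer_kind {self.layer_kind!r}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains non-finite entries")
        if self.layer_kind == RAW_COUNTS and np.any(self.x < 0):
            raise ValueError("raw_counts layer has negative entries")
        self._validate_attributes()

    def _validate_attributes(self):
        n = self.n
        for attr in self.schema:
            if attr.name not in self.attribute_values:
                # cells absent from an attribute table get all-missing values
                if attr.kind == CATEGORICAL:
                    self.attribute_values[attr.name] = np.array([None] * n, dtype=object)
                else:
                    self.attribute_values[attr.name] = np.full((n, attr.dim), np.nan)
            vals = self.attribute_values[attr.name]
            if attr.kind == CATEGORICAL:
                vals = np.asarray(vals, dtype=object)
                if vals.shape != (n,):
                    raise ValueError(
                        f"attribute {attr.name!r}: cell axis mismatch "
                        f"(expected {n} values, got {vals.shape})"
                    )
                vals = np.array(
                    [None if (v is None or v == MISSING or (isinstance(v, float) and np.isnan(v))) else str(v) for v in vals],
                    dtype=object,
                )
                for v in vals:
                    if v is not None and v not in attr.categories:
                        raise ValueError(
                            f"attribute {attr.name!r}: value {v!r} not in declared "
                            f"categories {list(attr.categories)}"
                        )
                self.attribute_values[attr.name] = vals
            else:
                vals = np.asarray(vals, dtype=np.float64)
                if vals.ndim == 1:
                    vals = vals.reshape(-1, 1)
                if vals.shape != (n, attr.dim):
                    raise ValueError(
                        f"attribute {attr.name!r}: expected shape ({n}, {attr.dim}), "
                        f"got {vals.shape}"
                    )
                partial = np.isnan(vals).any(axis=1) & ~np.isnan(vals).all(axis=1)
                if partial.any():
                    raise ValueError(
                        f"attribute {attr.name!r}: partially-NaN vectors; missing "
                        "ordered values must be all-NaN"
                    )
                self.attribute_values[attr.name] = vals
        extra = set(self.attribute_values) - set(self.schema.names)
        if extra:
            raise ValueError(f"attribute values {sorted(extra)} not declared in schema")

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def is_missing(self, attribute: str) -> np.ndarray:
        attr = self.schema[attribute]
        vals = self.attribute_values[attribute]
        if attr.kind == CATEGORICAL:
            return np.array([v is None for v in vals])
        return np.isnan(vals).all(axis=1)

    def category_codes(self, attribute: str) -> np.ndarray:
        """Integer codes in schema order; -1 marks missing."""
        attr = self.schema[attribute]
        vals = self.attribute_values[attribute]
        return np.array(
            [-1 if v is None else attr.categories.index(v) for v in vals], dtype=np.intp
        )

    def library_sizes(self) -> np.ndarray:
        return self.x.sum(axis=1)

    def subset(self, index) -> "CellDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        vals = {}
        for attr in self.schema:
            v = self.attribute_values[attr.name]
            vals[attr.name] = v[index].copy()
        return CellDataset(
            x=self.x[index].copy(),
            schema=self.schema,
            attribute_values=vals,
            cell_ids=[self.cell_ids[i] for i in index],
            feature_names=list(self.feature_names),
            layer_kind=self.layer_kind,
        )

    def copy(self) -> "CellDataset":
        return self.subset(np.arange(self.n))

    # -- conversions -----------------------------------------------------
    def attributes_frame(self) -> pd.DataFrame:
        """Attribute table as a DataFrame keyed by cell id (missing -> NaN)."""
        cols = {}
        for attr in self.schema:
            v = self.attribute_values[attr.name]
            if attr.kind == CATEGORICAL:
                cols[attr.name] = pd.array([x if x is not None else pd.NA for x in v])
            elif attr.dim == 1:
                cols[attr.name] = v[:, 0]
            else:
                for d in range(attr.dim):
                    cols[f"{attr.name}_{d}"] = v[:, d]
        return pd.DataFrame(cols, index=pd.Index(self.cell_ids, name="cell_id"))

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        obsm = {}
        for attr in self.schema:
            v = self.attribute_values[attr.name]
            if attr.kind == CATEGORICAL:
                obs[attr.name] = pd.Categorical(
                    [x if x is not None else np.nan for x in v],
                    categories=list(attr.categories),
                )
            else:
                obsm[attr.name] = np.asarray(v)
        adata = ad.AnnData(
            X=self.x.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.feature_names, name="feature")),
        )
        for k, v in obsm.items():
            adata.obsm[k] = v
        adata.uns["layer_kind"] = self.layer_kind
        adata.uns["attribute_schema"] = self.schema.to_dict()
        return adata

    @classmethod
    def from_anndata(cls, adata, schema: Optional[AttributeSchema] = None,
                     layer_kind: Optional[str] = None) -> "CellDataset":
        if schema is None:
            schema = AttributeSchema.from_dict(adata.uns["attribute_schema"])
        if layer_kind is None:
            layer_kind = adata.uns.get("layer_kind", RAW_COUNTS)
        x = adata.X
        if not isinstance(x, np.ndarray):
            x = np.asarray(x.todense())
        vals = {}
        for attr in schema:
            if attr.kind == CATEGORICAL:
                if attr.name in adata.obs:
                    col = adata.obs[attr.name]
                    vals[attr.name] = np.array(
                        [None if pd.isna(v) else str(v) for v in col], dtype=object
                    )
            elif attr.name in adata.obsm:
                vals[attr.name] = np.asarray(adata.obsm[attr.name], dtype=np.float64)
            elif attr.name in adata.obs:
                vals[attr.name] = np.asarray(adata.obs[attr.name], dtype=np.float64)
        return cls(
            x=np.asarray(x, dtype=np.float64),
            schema=schema,
            attribute_values=vals,
            cell_ids=list(map(str, adata.obs_names)),
            feature_names=list(map(str, adata.var_names)),
            layer_kind=layer_kind,
        )


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------


def _read_matrix(matrix_source) -> Tuple[np.ndarray, List[str], List[str]]:
    path = Path(matrix_source)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        if not isinstance(x, np.ndarray):
            x = np.asarray(x.todense())
        return np.asarray(x, dtype=np.float64), list(map(str, adata.obs_names)), list(
            map(str, adata.var_names)
        )
    if suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense(), dtype=np.float64)
        rows_path = path.with_suffix(".mtx.rows")
        cols_path = path.with_suffix(".mtx.cols")
        cell_ids = rows_path.read_text().split() if rows_path.exists() else None
        feat = cols_path.read_text().split() if cols_path.exists() else None
        if cell_ids is not None and len(cell_ids) != mat.shape[0]:
            raise ValueError(
                f"cell axis mismatch: MTX declares {mat.shape[0]} rows but sidecar "
                f"{rows_path.name} lists {len(cell_ids)} ids"
            )
        if feat is not None and len(feat) != mat.shape[1]:
            raise ValueError(
                f"feature axis mismatch: MTX declares {mat.shape[1]} columns but "
                f"sidecar {cols_path.name} lists {len(feat)} names"
            )
        return mat, cell_ids, feat
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return df.to_numpy(dtype=np.float64), list(map(str, df.index)), list(
            map(str, df.columns)
        )
    raise ValueError(f"unrecognized matrix format {suffix!r} for {path}")


def _parse_attribute_table(df: pd.DataFrame, schema: AttributeSchema,
                           cell_ids: Sequence[str]) -> Dict[str, np.ndarray]:
    df = df.copy()
    df.index = df.index.map(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell ids in attribute table: {dupes[:5]}")
    vals: Dict[str, np.ndarray] = {}
    n = len(cell_ids)
    lookup = {c: i for i, c in enumerate(cell_ids)}
    present = np.array([c in lookup for c in df.index])
    df = df.loc[present]
    row_of = np.array([lookup[c] for c in df.index], dtype=np.intp)
    for attr in schema:
        if attr.kind == CATEGORICAL:
            out = np.array([None] * n, dtype=object)
            if attr.name in df.columns:
                for r, v in zip(row_of, df[attr.name]):
                    if pd.isna(v) or v == MISSING or v == "":
                        continue
                    out[r] = str(v)
            vals[attr.name] = out
        else:
            out = np.full((n, attr.dim), np.nan)
            if attr.dim == 1 and attr.name in df.columns:
                cols = [attr.name]
            else:
                cols = [f"{attr.name}_{d}" for d in range(attr.dim)]
                if not all(c in df.columns for c in cols):
                    cols = []
            if cols:
                block = df[cols].to_numpy(dtype=np.float64)
                out[row_of] = block
            vals[attr.name] = out
    return vals


def load_dataset(matrix_source, attributes_source=None, schema: AttributeSchema = None,
                 layer_kind: str = RAW_COUNTS) -> CellDataset:
    """Load and validate a dataset from disk.

    ``matrix_source`` may be h5ad, dense CSV/TSV, or MTX (+ name sidecars).
    ``attributes_source`` is a CSV keyed by cell id; cells present in the
    matrix but absent from the table get all-missing attributes.  For h5ad
    input with embedded annotations, ``attributes_source`` may be omitted.
    """
    path = Path(matrix_source)
    if path.suffix.lower() == ".h5ad" and attributes_source is None:
        import anndata as ad

        return CellDataset.from_anndata(ad.read_h5ad(path), schema=schema,
                                        layer_kind=layer_kind)
    if schema is None:
        raise ValueError("schema is required unless reading an annotated h5ad")
    x, cell_ids, feature_names = _read_matrix(matrix_source)
    vals = {}
    if attributes_source is not None:
        table = pd.read_csv(attributes_source, index_col=0)
        if cell_ids is None:
            cell_ids = list(map(str, table.index))
            if len(cell_ids) != x.shape[0]:
                raise ValueError(
                    f"cell axis mismatch: matrix has {x.shape[0]} rows, attribute "
                    f"table has {len(cell_ids)}"
                )
        vals = _parse_attribute_table(table, schema, cell_ids)
    return CellDataset(x=x, schema=schema, attribute_values=vals,
                       cell_ids=cell_ids, feature_names=feature_names,
                       layer_kind=layer_kind)


def write_dataset(ds: CellDataset, matrix_path, attributes_path=None) -> None:
    """Write a dataset; the format follows the matrix path extension."""
    path = Path(matrix_path)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        ds.to_anndata().write_h5ad(path)
    elif suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(ds.x))
        path.with_suffix(".mtx.rows").write_text("\n".join(ds.cell_ids) + "\n")
        path.with_suffix(".mtx.cols").write_text("\n".join(ds.feature_names) + "\n")
    elif suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.DataFrame(ds.x, index=ds.cell_ids, columns=ds.feature_names)
        df.index.name = "cell_id"
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unrecognized output format {suffix!r}")
    if attributes_path is not None:
        ds.attributes_frame().to_csv(attributes_path)


def split_dataset(ds: CellDataset, held_out_labels: Optional[Dict[str, Sequence]] = None,
                  seed: int = 0, test_fraction: Optional[float] = None,
                  ) -> Tuple[CellDataset, CellDataset]:
    """Partition cells into train/test.

    With ``held_out_labels`` (attribute -> label set, or for ordered
    attributes a set of exact values), test receives every cell carrying any
    held-out value — an out-of-distribution split.  With ``test_fraction``
    a seeded random split is drawn instead.  The partition is exhaustive and
    disjoint.
    """
    if held_out_labels and test_fraction is not None:
        raise ValueError("choose label hold-out or random split, not both")
    n = ds.n
    if test_fraction is not None:
        rng = np.random.default_rng(seed)
        n_test = int(round(test_fraction * n))
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
    else:
        test_mask = np.zeros(n, dtype=bool)
        for name, labels in (held_out_labels or {}).items():
            attr = ds.schema[name]
            for label in labels:
                if attr.kind == CATEGORICAL:
                    if label not in attr.categories:
                        raise KeyError(
                            f"held-out label {label!r} not in attribute {name!r}"
                        )
                    hit = np.array([v == label for v in ds.attribute_values[name]])
                else:
                    target = np.atleast_1d(np.asarray(label, dtype=np.float64))
                    hit = np.all(np.isclose(ds.attribute_values[name], target), axis=1)
                if not hit.any():
                    warnings.warn(
                        f"held-out label {label!r} of {name!r} matches zero cells"
                    )
                test_mask |= hit
    if test_mask.all():
        raise ValueError("hold-out matches every cell; training set would be empty")
    train = ds.subset(~test_mask)
    # the container requires n >= 1, so "nothing held out" yields test=None
    test = ds.subset(test_mask) if test_mask.any() else None
    return train, test
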