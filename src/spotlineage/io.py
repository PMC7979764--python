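"""Reading and writing the standard formats the pipeline touches.

Conventions used throughout the package:

* expression matrices are oriented **genes x observations** (cells or
  spots), regardless of the on-disk orientation;
* observation/array coordinates are 0-based integer array indices;
* cross-dataset gene joins use ``gene_ids`` (stable identifiers), falling
  back to ``gene_names`` with a logged warning.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("spotlineage")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Sparse raw-count matrix (genes x observations) with metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, shape ``(n_genes, n_obs)``. Stored as
        CSR regardless of input sparse format.
    gene_ids, gene_names
        Stable identifiers and display names, one per gene row.
    obs_ids
        Barcodes/identifiers, one per observation column; must be unique.
    obs_meta
        Per-observation table (stage, section, array_row/col for spots),
        indexed by ``obs_ids``.
    kind
        Whether observations are dissociated ``"cells"`` or spatial
        ``"spots"``.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    gene_names: list[str]
    obs_ids: list[str]
    obs_meta: pd.DataFrame = None
    kind: Literal["cells", "spots"] = "cells"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.gene_names = list(self.gene_names)
        self.obs_ids = list(self.obs_ids)
        n_genes, n_obs = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise FormatError(
                f"gene annotation length ({len(self.gene_ids)}) does not match "
                f"matrix rows ({n_genes})"
            )
        if len(self.obs_ids) != n_obs:
            raise FormatError(
                f"observation ids ({len(self.obs_ids)}) do not match matrix "
                f"columns ({n_obs})"
            )
        if len(set(self.obs_ids)) != n_obs:
            raise FormatError("duplicate observation ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=pd.Index(self.obs_ids, name="barcode"))
        else:
            self.obs_meta = self.obs_meta.copy()
            self.obs_meta.index = pd.Index(self.obs_ids, name="barcode")

    # -- basic niceties -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_obs(self) -> int:
        return self.counts.shape[1]

    def subset_obs(self, mask_or_idx) -> "ExpressionMatrix":
        """Return a new matrix restricted to the selected observations."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            obs_ids=[self.obs_ids[i] for i in idx],
            obs_meta=self.obs_meta.iloc[idx],
            kind=self.kind,
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_names=[self.gene_names[i] for i in idx],
            obs_ids=self.obs_ids,
            obs_meta=self.obs_meta,
            kind=self.kind,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.gene_ids == other.gene_ids
            and self.gene_names == other.gene_names
            and self.obs_ids == other.obs_ids
            and self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
        )


# ---------------------------------------------------------------------------
# 10x-style triplet directories
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dir: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dir}")


def read_10x_counts(dir: str | Path, kind: Literal["cells", "spots"]) -> ExpressionMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + features + barcodes).

    Accepts gzipped or plain files and either feature naming convention
    (``features.tsv`` with id/name columns, or legacy ``genes.tsv``). The
    matrix is re-oriented to genes x observations if stored transposed.
    """
    dir = Path(dir)
    mtx_path = _find(dir, ["matrix.mtx"])
    feat_path = _find(dir, ["features.tsv", "genes.tsv"])
    bc_path = _find(dir, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    feats = pd.read_csv(feat_path, sep="\t", header=None)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()

    gene_ids = feats[0].astype(str).tolist()
    gene_names = (feats[1] if feats.shape[1] > 1 else feats[0]).astype(str).tolist()

    n_genes, n_obs = len(gene_ids), len(barcodes)
    if mat.shape == (n_genes, n_obs):
        pass
    elif mat.shape == (n_obs, n_genes):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither (genes={n_genes}, "
            f"obs={n_obs}) nor its transpose"
        )
    return ExpressionMatrix(
        counts=sp.csr_matrix(mat),
        gene_ids=gene_ids,
        gene_names=gene_names,
        obs_ids=barcodes,
        kind=kind,
    )


def write_10x_counts(m: ExpressionMatrix, dir: str | Path, gzipped: bool = False) -> None:
    """Write an :class:`ExpressionMatrix` as a 10x-style triplet directory."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    mtx_path = dir / f"matrix.mtx{suffix}"
    coo = sp.coo_matrix(m.counts)
    if gzipped:
        import io as _io

        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, coo)
        with gzip.open(mtx_path, "wb") as fh:
            fh.write(buf.getvalue())
    else:
        scipy.io.mmwrite(str(mtx_path), coo)

    feats = pd.DataFrame({"id": m.gene_ids, "name": m.gene_names})
    feats["type"] = "Gene Expression"
    feats.to_csv(dir / f"features.tsv{suffix}", sep="\t", header=False, index=False)
    pd.Series(m.obs_ids).to_csv(
        dir / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Spot geometry
# ---------------------------------------------------------------------------

GEOMETRY_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col"]


def read_spot_geometry(path: str | Path) -> pd.DataFrame:
    """Read a spot-geometry CSV (barcode, in_tissue, array_row, array_col).

    ``in_tissue`` is coerced to boolean; barcodes must be unique (they are
    the join key against expression matrices downstream).
    """
    df = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"geometry file missing columns: {missing}")
    df = df[GEOMETRY_COLUMNS].copy()
    df["barcode"] = df["barcode"].astype(str)
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise FormatError(f"duplicate barcodes in geometry table: {dups[:5]}")
    df["in_tissue"] = df["in_tissue"].astype(bool)
    df["array_row"] = df["array_row"].astype(int)
    df["array_col"] = df["array_col"].astype(int)
    return df.set_index("barcode")


def write_spot_geometry(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if out.index.name == "barcode":
        out = out.reset_index()
    out["in_tissue"] = out["in_tissue"].astype(int)
    out[GEOMETRY_COLUMNS].to_csv(path, index=False)


def join_geometry(m: ExpressionMatrix, geometry: pd.DataFrame) -> ExpressionMatrix:
    """Attach geometry to a spot matrix, keeping only in-tissue spots.

    Spots missing from the geometry table (and vice versa) are dropped with
    a logged count rather than raising: section edges routinely lose spots.
    """
    present = [b for b in m.obs_ids if b in geometry.index]
    n_dropped = m.n_obs - len(present)
    if n_dropped:
        logger.warning("%d spots missing from geometry table; dropped", n_dropped)
    keep = [b for b in present if bool(geometry.loc[b, "in_tissue"])]
    out = m.subset_obs([m.obs_ids.index(b) for b in keep])
    out.obs_meta = out.obs_meta.join(geometry.loc[keep])
    return out


# ---------------------------------------------------------------------------
# Result tables + manifest
# ---------------------------------------------------------------------------


def write_results(
    tables: dict[str, pd.DataFrame],
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write named result tables as CSV plus a JSON run manifest.

    A table named ``colocalization`` is checked to be square and symmetric
    before writing. NaNs in an index (key) level raise.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if df.index.to_frame().isna().any().any():
            raise ValueError(f"NaN in key column of table {name!r}")
        if name == "colocalization":
            if df.shape[0] != df.shape[1] or not np.allclose(
                df.values, df.values.T
            ):
                raise ValueError("colocalization table must be square and symmetric")
        df.to_csv(path / f"{name}.csv")
    import spotlineage

    manifest = {
        "package": "spotlineage",
        "version": spotlineage.__version__,
        "seed": seed,
        "config": config or {},
        "numpy": np.__version__,
        "tables": sorted(tables),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
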