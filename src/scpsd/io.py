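"""Readers and writers for the matrix formats the tool touches.

Supported: 10x-style MatrixMarket triplets (``matrix.mtx[.gz]`` +
``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``), dense CSV/TSV with feature
ids in the first column and cell ids in the header, and a two-column
``cell_id<TAB>label`` TSV.  MatrixMarket indices are 1-based on disk per
the standard; everything in memory is 0-based.  Gzipped inputs are accepted
transparently.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .core import OmicsMatrix, PSDResult

__all__ = ["MatrixBundle", "read_matrix", "write_matrix", "read_labels", "write_labels"]


@dataclass
class MatrixBundle:
    """Paths making up one input matrix.

    ``format`` is one of ``mtx-triplet``, ``csv``, ``tsv``; for the dense
    formats only ``matrix_path`` (and optionally ``labels_path``) is used.
    """

    matrix_path: Path
    features_path: Path | None = None
    barcodes_path: Path | None = None
    labels_path: Path | None = None
    format: str = "mtx-triplet"

    def __post_init__(self) -> None:
        if self.format not in ("mtx-triplet", "csv", "tsv"):
            raise ValueError(f"unknown format {self.format!r}")
        self.matrix_path = Path(self.matrix_path)
        for attr in ("features_path", "barcodes_path", "labels_path"):
            p = getattr(self, attr)
            if p is not None:
                setattr(self, attr, Path(p))

    @classmethod
    def from_path(cls, path: str | Path, labels_path: str | Path | None = None
                  ) -> "MatrixBundle":
        """Infer a bundle from a directory (MTX triplet) or a dense file."""
        path = Path(path)
        if path.is_dir():
            def pick(stem: str) -> Path:
                for suffix in (".tsv", ".tsv.gz", ".txt", ".txt.gz"):
                    cand = path / f"{stem}{suffix}"
                    if cand.exists():
                        return cand
                raise FileNotFoundError(f"no {stem}.tsv[.gz] in {path}")
            mtx = path / "matrix.mtx"
            if not mtx.exists():
                mtx = path / "matrix.mtx.gz"
            if not mtx.exists():
                raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
            return cls(mtx, pick("features"), pick("barcodes"),
                       Path(labels_path) if labels_path else None, "mtx-triplet")
        name = path.name.removesuffix(".gz")
        if name.endswith(".mtx"):
            raise ValueError(
                "a bare .mtx needs companion features/barcodes files; "
                "pass the bundle directory or construct MatrixBundle explicitly"
            )
        fmt = "csv" if name.endswith(".csv") else "tsv"
        return cls(path, None, None,
                   Path(labels_path) if labels_path else None, fmt)


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_labels(path: str | Path, cell_ids: list[str]) -> list[str]:
    """Read a two-column cell_id/label TSV; every id must be a known cell."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (cell id, label)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    unknown = set(mapping) - set(cell_ids)
    if unknown:
        raise ValueError(f"labels reference unknown cell id {sorted(unknown)[0]!r}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"no label for cell id {missing[0]!r}")
    return [mapping[c] for c in cell_ids]


def read_matrix(bundle: MatrixBundle, cells_in_rows: bool = False) -> OmicsMatrix:
    """Load an :class:`OmicsMatrix` from disk.

    ``cells_in_rows`` transposes dense inputs whose rows are cells (never
    guessed automatically).
    """
    if bundle.format == "mtx-triplet":
        if bundle.features_path is None or bundle.barcodes_path is None:
            raise ValueError("mtx-triplet bundle requires features and barcodes paths")
        mat = scipy.io.mmread(str(bundle.matrix_path))
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        feature_ids = _read_id_column(bundle.features_path)
        cell_ids = _read_id_column(bundle.barcodes_path)
        if values.shape != (len(feature_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {values.shape} but bundle lists "
                f"{len(feature_ids)} features x {len(cell_ids)} barcodes"
            )
    else:
        sep = "," if bundle.format == "csv" else "\t"
        df = pd.read_csv(bundle.matrix_path, sep=sep, index_col=0,
                         float_precision="round_trip")
        if cells_in_rows:
            df = df.T
        values = df.to_numpy(dtype=np.float64)
        feature_ids = [str(x) for x in df.index]
        cell_ids = [str(x) for x in df.columns]
    labels = (
        read_labels(bundle.labels_path, cell_ids)
        if bundle.labels_path is not None else None
    )
    return OmicsMatrix(values, feature_ids, cell_ids, labels)


def _write_tsv_ids(ids: list[str], path: Path) -> None:
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(ids) + "\n")


def write_matrix(
    obj: OmicsMatrix | PSDResult,
    path: str | Path,
    format: str = "mtx-triplet",
) -> list[Path]:
    """Write a matrix (or transform result) to disk; returns the paths written.

    ``mtx-triplet`` writes ``<path>/matrix.mtx`` + ``features.tsv`` +
    ``barcodes.tsv`` (+ ``labels.tsv`` when present); ``csv``/``tsv`` write
    a single dense file at ``path``.  A :class:`PSDResult` additionally
    writes ``provenance.json`` next to the matrix.  Values round-trip
    losslessly at double precision.
    """
    if isinstance(obj, PSDResult):
        values, feature_ids, cell_ids = obj.transformed, obj.feature_ids, obj.cell_ids
        labels, provenance = None, dict(obj.provenance)
    else:
        values, feature_ids, cell_ids = obj.values, obj.feature_ids, obj.cell_ids
        labels, provenance = obj.labels, None

    path = Path(path)
    written: list[Path] = []
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        mtx = path / "matrix.mtx"
        scipy.io.mmwrite(str(mtx), scipy.sparse.coo_matrix(values), precision=17)
        _write_tsv_ids(feature_ids, path / "features.tsv")
        _write_tsv_ids(cell_ids, path / "barcodes.tsv")
        written += [mtx, path / "features.tsv", path / "barcodes.tsv"]
        if labels is not None:
            write_labels(labels, cell_ids, path / "labels.tsv")
            written.append(path / "labels.tsv")
        prov_path = path / "provenance.json"
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(values, index=feature_ids, columns=cell_ids)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep=sep)  # repr-precision floats: lossless round trip
        written.append(path)
        prov_path = path.with_suffix(path.suffix + ".provenance.json")
    else:
        raise ValueError(f"unknown format {format!r}")

    if provenance is not None:
        provenance["software"] = f"scpsd {__version__}"
        prov_path.write_text(json.dumps(provenance, indent=2) + "\n", encoding="utf-8")
        written.append(prov_path)
    return written


def write_labels(labels: list[str], cell_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )
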