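"""Readers and writers for datasets, codes and matchings.

Supported on-disk layouts per technology:

* MatrixMarket: ``matrix.mtx`` (cells x features) + ``cells.tsv``
  (``cell_id`` plus optional ``branch``, ``pseudotime``, ``label`` columns)
  + ``features.tsv``;
* dense CSV with cell ids in the first column;
* ``.h5ad`` AnnData containers (annotations in ``obs``).

Latent codes and matchings travel as TSV with a ``cell_id`` column, so every
artifact stays plain text and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datasets import ExpressionDataset, LatentCodes
from .match import MatchResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "dataset_from_anndata",
    "dataset_to_anndata",
    "read_codes",
    "write_codes",
    "read_matches",
    "write_matches",
    "write_manifest",
]

_OBS_COLS = ("branch", "pseudotime", "label")


def dataset_from_anndata(adata, technology: str | None = None) -> ExpressionDataset:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    kw = {}
    for col in _OBS_COLS:
        if col in adata.obs:
            kw["labels" if col == "label" else col] = adata.obs[col].to_numpy()
    return ExpressionDataset(
        counts=np.asarray(X),
        technology=technology or str(adata.uns.get("technology", "tech")),
        cell_ids=list(adata.obs_names),
        feature_names=list(adata.var_names),
        **kw,
    )


def dataset_to_anndata(ds: ExpressionDataset):
    import anndata as ad

    obs = ds.obs_frame().set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=ds.counts.astype(np.float32), obs=obs)
    adata.var_names = ds.feature_names
    adata.uns["technology"] = ds.technology
    return adata


def _attach_obs(ds_kw: dict, cells: pd.DataFrame) -> None:
    for col in _OBS_COLS:
        if col in cells.columns:
            ds_kw["labels" if col == "label" else col] = cells[col].to_numpy()


def read_dataset(path: str | Path, fmt: str | None = None, technology: str | None = None) -> ExpressionDataset:
    """Load one technology's dataset; format auto-detected from the path.

    ``path`` is a directory for the MTX layout, a ``.csv`` file, or an
    ``.h5ad`` file; ``fmt`` (``"mtx"``, ``"csv"``, ``"h5ad"``) overrides
    detection.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix == ".csv":
            fmt = "csv"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "h5ad":
        import anndata as ad

        return dataset_from_anndata(ad.read_h5ad(path), technology=technology)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionDataset(
            counts=df.to_numpy(),
            technology=technology or path.stem,
            cell_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
        )
    if fmt == "mtx":
        counts = spio.mmread(path / "matrix.mtx")
        if sparse.issparse(counts):
            counts = counts.toarray()
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        features = pd.read_csv(path / "features.tsv", sep="\t")
        if len(cells) != counts.shape[0]:
            raise ValueError(
                f"matrix has {counts.shape[0]} cells but cells.tsv has {len(cells)} rows"
            )
        if len(features) != counts.shape[1]:
            raise ValueError(
                f"matrix has {counts.shape[1]} features but features.tsv has {len(features)} rows"
            )
        kw: dict = {}
        _attach_obs(kw, cells)
        meta = {}
        meta_path = path / "meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        return ExpressionDataset(
            counts=np.asarray(counts),
            technology=technology or meta.get("technology", path.name),
            cell_ids=[str(c) for c in cells["cell_id"]],
            feature_names=[str(f) for f in features["feature"]],
            **kw,
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(ds: ExpressionDataset, path: str | Path, fmt: str = "mtx") -> None:
    """Write a dataset; ``fmt`` is ``"mtx"`` (directory), ``"csv"`` or ``"h5ad"``."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(ds.counts))
        ds.obs_frame().to_csv(path / "cells.tsv", sep="\t", index=False)
        pd.DataFrame({"feature": ds.feature_names}).to_csv(
            path / "features.tsv", sep="\t", index=False
        )
        (path / "meta.json").write_text(json.dumps({"technology": ds.technology}))
    elif fmt == "csv":
        pd.DataFrame(
            ds.counts, index=ds.cell_ids, columns=ds.feature_names
        ).to_csv(path)
    elif fmt == "h5ad":
        dataset_to_anndata(ds).write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_codes(codes: LatentCodes, path: str | Path) -> None:
    codes.to_frame().to_csv(path, sep="\t", index=False)


def read_codes(path: str | Path, technology: str = "tech") -> LatentCodes:
    df = pd.read_csv(path, sep="\t")
    return LatentCodes(
        codes=df.drop(columns=["cell_id"]).to_numpy(float),
        technology=technology,
        cell_ids=[str(c) for c in df["cell_id"]],
    )


def write_matches(result: MatchResult, path: str | Path) -> None:
    """Write pairs and null assignments as TSV (source_id, target_id, cost)."""
    rows = [(s, t, f"{c:.6f}") for s, t, c in sorted(result.pairs)] + [
        (s, "NULL", "") for s in sorted(result.null_assigned)
    ]
    pd.DataFrame(rows, columns=["source_id", "target_id", "cost"]).to_csv(
        path, sep="\t", index=False
    )


def read_matches(path: str | Path) -> MatchResult:
    df = pd.read_csv(
        path, sep="\t", dtype={"source_id": str, "target_id": str},
        keep_default_na=False,
    )
    null_rows = df["target_id"] == "NULL"
    pairs = [
        (str(r.source_id), str(r.target_id), float(r.cost))
        for r in df[~null_rows].itertuples()
    ]
    null_assigned = [str(s) for s in df.loc[null_rows, "source_id"]]
    return MatchResult(
        pairs=pairs,
        null_assigned=null_assigned,
        k=0,
        p=float("nan"),
        total_cost=float(sum(c for _, _, c in pairs)),
        source_ids=sorted({s for s, _, _ in pairs} | set(null_assigned)),
        target_ids=sorted({t for _, t, _ in pairs}),
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Record configuration, seeds and package version next to the artifacts."""
    from . import __version__

    payload = {"scmatch_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
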