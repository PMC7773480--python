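"""In-memory containers shared across the pipeline.

The two central objects are :class:`ExpressionDataset`, a cells-by-features
count (or intensity) matrix for a single profiling technology together with
optional per-cell annotations, and :class:`LatentCodes`, the low-dimensional
embedding an encoder produces for those cells.  Cell identifiers are opaque
strings; nothing downstream relies on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellTruth:
    """Ground-truth state of one simulated cell on the lineage tree."""

    branch: str
    pseudotime: float


@dataclass
class ExpressionDataset:
    """Cells-by-features matrix for one technology.

    Parameters
    ----------
    counts
        ``(n_cells, n_features)`` non-negative matrix.  Integer counts for
        sequencing-style data; real-valued intensities are also accepted.
    technology
        Free-form tag identifying the profiling technology.
    cell_ids, feature_names
        Optional identifiers; generated as ``"<technology>_cell<i>"`` and
        ``"<technology>_f<j>"`` when omitted.
    branch, pseudotime
        Optional ground truth (one entry per cell), present for simulated data.
    labels
        Optional categorical per-cell label (cell type / branch) used for
        semi-supervised latent-space orientation and for evaluation.
    """

    counts: np.ndarray
    technology: str = "tech"
    cell_ids: list[str] | None = None
    feature_names: list[str] | None = None
    branch: np.ndarray | None = None
    pseudotime: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells-by-features matrix")
        n, g = self.counts.shape
        if self.cell_ids is None:
            self.cell_ids = [f"{self.technology}_cell{i}" for i in range(n)]
        if self.feature_names is None:
            self.feature_names = [f"{self.technology}_f{j}" for j in range(g)]
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match counts rows")
        if len(self.feature_names) != g:
            raise ValueError("feature_names length does not match counts columns")
        for name in ("branch", "pseudotime", "labels"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != n:
                    raise ValueError(f"{name} has {v.shape[0]} entries for {n} cells")
                setattr(self, name, v)
        if self.labels is None and self.branch is not None:
            self.labels = self.branch.copy()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def truth(self) -> list[CellTruth] | None:
        """Per-cell ground truth, when the dataset was simulated."""
        if self.branch is None or self.pseudotime is None:
            return None
        return [
            CellTruth(branch=str(b), pseudotime=float(t))
            for b, t in zip(self.branch, self.pseudotime)
        ]

    def obs_frame(self) -> pd.DataFrame:
        """Per-cell annotation table (cell_id, branch, pseudotime, label)."""
        obs = pd.DataFrame({"cell_id": self.cell_ids})
        if self.branch is not None:
            obs["branch"] = self.branch
        if self.pseudotime is not None:
            obs["pseudotime"] = self.pseudotime
        if self.labels is not None:
            obs["label"] = self.labels
        return obs


@dataclass
class LatentCodes:
    """Cells-by-dimensions embedding produced by a technology's encoder."""

    codes: np.ndarray
    technology: str = "tech"
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (cells x latent_dim)")
        if not np.all(np.isfinite(self.codes)):
            raise ValueError("codes contain non-finite entries")
        if not self.cell_ids:
            self.cell_ids = [f"{self.technology}_cell{i}" for i in range(len(self.codes))]
        elif len(self.cell_ids) != self.codes.shape[0]:
            raise ValueError("cell_ids length does not match codes rows")

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.codes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.codes, columns=[f"z{j}" for j in range(self.latent_dim)]
        )
        df.insert(0, "cell_id", self.cell_ids)
        return df
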