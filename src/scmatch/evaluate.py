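"""Scoring of cross-technology matchings against labels and ground truth.

All metrics operate on non-null pairs only; the share of cells sent to the
null node is reported separately by :func:`matched_fractions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .match import MatchResult

__all__ = [
    "MatchEvaluation",
    "label_accuracy",
    "pseudotime_correlation",
    "matched_fractions",
    "marker_correlation",
    "evaluate_matches",
]


@dataclass
class MatchEvaluation:
    """Bundle of matching-quality metrics."""

    label_accuracy: float | None = None
    pearson: float | None = None
    spearman: float | None = None
    matched_fraction_source: float | None = None
    matched_fraction_target: float | None = None
    per_marker_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "label_accuracy": self.label_accuracy,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "matched_fraction_source": self.matched_fraction_source,
            "matched_fraction_target": self.matched_fraction_target,
            "per_marker_correlations": {
                k: list(v) for k, v in self.per_marker_correlations.items()
            },
            "n_pairs": self.n_pairs,
        }


def _lookup(ids: list[str], values) -> dict[str, object]:
    values = np.asarray(values)
    if len(ids) != len(values):
        raise ValueError("per-cell values must align with cell ids")
    return dict(zip(ids, values))


def _paired(matches: MatchResult, vals_s, vals_t):
    ls = _lookup(matches.source_ids, vals_s)
    lt = _lookup(matches.target_ids, vals_t)
    a, b = [], []
    for s, t, _ in matches.pairs:
        if s not in ls or t not in lt:
            raise KeyError(f"no annotation for matched pair ({s}, {t})")
        a.append(ls[s])
        b.append(lt[t])
    return np.asarray(a), np.asarray(b)


def label_accuracy(matches: MatchResult, labels_s, labels_t) -> float:
    """Fraction of non-null pairs whose two cells carry the same label."""
    a, b = _paired(matches, labels_s, labels_t)
    if len(a) == 0:
        raise ValueError("no non-null pairs to score")
    return float(np.mean(a.astype(str) == b.astype(str)))


def pseudotime_correlation(
    matches: MatchResult, pt_s, pt_t
) -> tuple[float | None, float | None]:
    """(Pearson, Spearman) correlation of pseudotime over matched pairs.

    Constant inputs have no defined correlation; ``None`` is returned for
    the affected coefficient rather than a silent zero.
    """
    a, b = _paired(matches, pt_s, pt_t)
    if len(a) < 3:
        raise ValueError("need at least 3 non-null pairs")
    a = a.astype(float)
    b = b.astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None
    pearson = float(stats.pearsonr(a, b)[0])
    spearman = float(stats.spearmanr(a, b)[0])
    return pearson, spearman


def matched_fractions(
    matches: MatchResult, n_source: int, n_target: int
) -> tuple[float, float]:
    """Per-side coverage: distinct non-null matched cells / dataset size."""
    src = {s for s, _, _ in matches.pairs}
    tgt = {t for _, t, _ in matches.pairs}
    return len(src) / n_source, len(tgt) / n_target


def marker_correlation(
    matches: MatchResult,
    expr_s: dict[str, np.ndarray],
    expr_t: dict[str, np.ndarray],
    marker_map: dict[str, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-marker (Pearson, Spearman) of shared-marker expression across pairs.

    ``expr_s`` / ``expr_t`` map marker names to per-cell value vectors (in
    each technology's own units).  ``marker_map`` translates source marker
    names to target names (identity by default); a marker missing on either
    side raises.
    """
    marker_map = marker_map or {m: m for m in expr_s}
    out = {}
    for src_name, tgt_name in marker_map.items():
        if src_name not in expr_s:
            raise KeyError(f"marker {src_name!r} absent from source expression")
        if tgt_name not in expr_t:
            raise KeyError(f"marker {tgt_name!r} absent from target expression")
        a, b = _paired(matches, expr_s[src_name], expr_t[tgt_name])
        a = a.astype(float)
        b = b.astype(float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[src_name] = (None, None)
            continue
        out[src_name] = (
            float(stats.pearsonr(a, b)[0]),
            float(stats.spearmanr(a, b)[0]),
        )
    return out


def evaluate_matches(
    matches: MatchResult,
    labels_s=None,
    labels_t=None,
    pt_s=None,
    pt_t=None,
    n_source: int | None = None,
    n_target: int | None = None,
    expr_s=None,
    expr_t=None,
    marker_map=None,
) -> MatchEvaluation:
    """Compute every applicable metric for a matching in one pass."""
    ev = MatchEvaluation(n_pairs=matches.n_pairs)
    if labels_s is not None and labels_t is not None:
        ev.label_accuracy = label_accuracy(matches, labels_s, labels_t)
    if pt_s is not None and pt_t is not None:
        ev.pearson, ev.spearman = pseudotime_correlation(matches, pt_s, pt_t)
    n_source = n_source if n_source is not None else len(matches.source_ids)
    n_target = n_target if n_target is not None else len(matches.target_ids)
    ev.matched_fraction_source, ev.matched_fraction_target = matched_fractions(
        matches, n_source, n_target
    )
    if expr_s is not None and expr_t is not None:
        ev.per_marker_correlations = marker_correlation(
            matches, expr_s, expr_t, marker_map
        )
    return ev
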