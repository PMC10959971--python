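"""One-way ANOVA F-statistic feature scoring and top-k selection.

For feature ``j`` with ``G`` classes and ``n`` samples, the between- and
within-class sums of squares are

    SSB_j = sum_g n_g (m_gj - m_j)^2
    SSW_j = sum_g sum_{i in g} (x_ij - m_gj)^2

and the F statistic is ``F_j = (SSB_j / (G-1)) / (SSW_j / (n-G))``.  Large
values flag features whose class means are well separated relative to the
within-class spread; selection keeps the ``k`` largest.  Degenerate
conventions: ``SSW_j = 0`` with ``SSB_j > 0`` yields a ``+inf`` sentinel
(perfectly class-separated feature); a feature constant everywhere scores 0.

Scores must be fitted on the training partition only; ``apply_selection``
then restricts any matrix of the same width to the selected columns, so the
test partition never influences which columns survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

__all__ = ["AnovaScores", "SelectionResult", "anova_f_scores", "select_top_k",
           "apply_selection"]


@dataclass
class AnovaScores:
    """Per-feature one-way ANOVA decomposition."""

    f_values: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    df_between: int
    df_within: int

    @property
    def feature_count(self) -> int:
        return self.f_values.shape[0]


@dataclass
class SelectionResult:
    """Top-k feature choice derived from :class:`AnovaScores`."""

    k: int
    selected_indices: np.ndarray  # ascending
    ranking: np.ndarray           # all features, descending F
    scores: AnovaScores


def anova_f_scores(F: FeatureMatrix) -> AnovaScores:
    """Score every column of ``F`` with the one-way ANOVA F statistic."""
    X, y = F.values, F.labels
    classes, counts = np.unique(y, return_counts=True)
    G, n = classes.shape[0], X.shape[0]
    if G < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    if n <= G:
        raise ValueError(f"need more samples ({n}) than classes ({G})")

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, n_g in zip(classes, counts):
        Xg = X[y == c]
        mg = Xg.mean(axis=0)
        ssb += n_g * (mg - grand) ** 2
        ssw += ((Xg - mg) ** 2).sum(axis=0)

    df_b, df_w = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where(ssw == 0.0, np.where(ssb > 0.0, np.inf, 0.0), f)
    return AnovaScores(f, ssb, ssw, df_b, df_w)


def select_top_k(scores: AnovaScores, k: int) -> SelectionResult:
    """Keep the ``k`` largest F values; ties break toward the lower index.

    ``+inf`` sentinels outrank every finite score; among equal scores the
    lower feature index wins, so the result is deterministic.
    """
    d = scores.feature_count
    if not 1 <= k <= d:
        raise ValueError(f"k={k} out of range [1, {d}]")
    ranking = np.argsort(-scores.f_values, kind="stable")
    selected = np.sort(ranking[:k])
    return SelectionResult(k=k, selected_indices=selected, ranking=ranking,
                           scores=scores)


def apply_selection(F: FeatureMatrix, sel: SelectionResult) -> FeatureMatrix:
    """Restrict ``F`` to the selected columns (ascending index order)."""
    if F.n_features != sel.scores.feature_count:
        raise ValueError(
            f"selection fitted on {sel.scores.feature_count} features, "
            f"matrix has {F.n_features}"
        )
    return F.with_values(F.values[:, sel.selected_indices],
                         feature_origin="selected", k=int(sel.k))


def export_scores_csv(path, scores: AnovaScores, sel: SelectionResult | None = None) -> None:
    """Write per-feature F, rank and selection flag as CSV."""
    import pandas as pd

    rank_of = np.empty(scores.feature_count, dtype=int)
    order = (sel.ranking if sel is not None
             else np.argsort(-scores.f_values, kind="stable"))
    rank_of[order] = np.arange(scores.feature_count)
    selected = np.zeros(scores.feature_count, dtype=bool)
    if sel is not None:
        selected[sel.selected_indices] = True
    pd.DataFrame(
        {
            "feature_index": np.arange(scores.feature_count),
            "F": scores.f_values,
            "rank": rank_of,
            "selected": selected,
        }
    ).to_csv(path, index=False)
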