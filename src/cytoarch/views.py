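"""Matrix unfoldings of the child x cytokine x stimulus fold tensor, PCA,
and pairwise correlation structure.

Three unfoldings are used: *Child-Stimulus x Cytokine* (one row per child and
stimulus, cytokines as columns — used to cluster cytokines), *Child-Cytokine
x Stimulus* (used to cluster stimuli), and *Child x Cytokine-Stimulus* (one
row per child over a pair subset — used for within-group correlation
analysis).  All start from the media-normalized fold matrix, so the media
reference never appears as a column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AXIS_SEMANTICS = (
    "child_stimulus_by_cytokine",
    "child_cytokine_by_stimulus",
    "child_by_pair",
)


@dataclass
class UnfoldedView:
    values: pd.DataFrame
    axis_semantics: str

    def __post_init__(self) -> None:
        if self.axis_semantics not in AXIS_SEMANTICS:
            raise ValueError(f"unknown axis semantics {self.axis_semantics!r}")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("duplicate row or column labels")

    @property
    def row_labels(self):
        return list(self.values.index)

    @property
    def column_labels(self):
        return list(self.values.columns)


def unfold(
    folds: pd.DataFrame,
    axis_semantics: str,
    stimulus_exclusions: list[str] | None = None,
    pair_subset: list[tuple[str, str]] | None = None,
) -> UnfoldedView:
    """Reshape the fold matrix into one of the three analysis views.

    ``stimulus_exclusions`` (typically the contaminated polyIC) are removed
    from every view; ``pair_subset`` restricts the child_by_pair view to a
    functional subgroup.
    """
    exclusions = list(stimulus_exclusions or [])
    stimuli = folds.columns.get_level_values("stimulus").unique()
    for name in exclusions:
        if name not in stimuli:
            raise ValueError(f"unknown stimulus exclusion {name!r}")
    data = folds.drop(columns=exclusions, level="stimulus") if exclusions else folds
    if axis_semantics == "child_by_pair":
        if pair_subset is not None:
            data = data[list(pair_subset)]
        return UnfoldedView(data.copy(), axis_semantics)
    if axis_semantics == "child_stimulus_by_cytokine":
        long = data.stack(level="stimulus", future_stack=True)
        long.index.names = ["child", "stimulus"]
        return UnfoldedView(long, axis_semantics)
    if axis_semantics == "child_cytokine_by_stimulus":
        long = data.stack(level="cytokine", future_stack=True)
        long.index.names = ["child", "cytokine"]
        return UnfoldedView(long, axis_semantics)
    raise ValueError(f"unknown axis semantics {axis_semantics!r}")


def refold(view: UnfoldedView) -> pd.DataFrame:
    """Invert :func:`unfold` back to the child x (cytokine, stimulus) matrix."""
    if view.axis_semantics == "child_by_pair":
        return view.values.copy()
    if view.axis_semantics == "child_stimulus_by_cytokine":
        wide = view.values.unstack("stimulus")
        wide.columns.names = ["cytokine", "stimulus"]
        return wide
    wide = view.values.unstack("cytokine")
    wide.columns = wide.columns.swaplevel()
    wide.columns.names = ["cytokine", "stimulus"]
    return wide.sort_index(axis=1)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # columns x components
    variance_fraction: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray


def run_pca(view: UnfoldedView, scale_columns: bool = False) -> PCAResult:
    """Column-centered (optionally standardized) PCA by SVD.

    Requires complete data (imputation happens upstream).  Variance
    fractions are eigenvalue shares and sum to one over all components.
    """
    X = view.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before PCA")
    if X.shape[0] < 2:
        raise ValueError("at least 2 rows required")
    means = X.mean(axis=0)
    Xc = X - means
    scales = np.ones(X.shape[1])
    if scale_columns:
        scales = Xc.std(ddof=1, axis=0)
        if np.any(scales == 0):
            raise ValueError("zero-variance column cannot be standardized")
        Xc = Xc / scales
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comp_labels = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=view.values.index, columns=comp_labels)
    loadings = pd.DataFrame(Vt.T, index=view.values.columns, columns=comp_labels)
    return PCAResult(scores, loadings, frac, means, scales)


def pairwise_pearson(view: UnfoldedView, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations between columns, with p-values.

    p comes from the t transform of r with n - 2 degrees of freedom.
    Zero-variance or insufficient overlaps yield NaN entries.
    """
    X = view.values.to_numpy(dtype=float)
    cols = view.values.columns
    p_count = len(cols)
    r = np.full((p_count, p_count), np.nan)
    p = np.full((p_count, p_count), np.nan)
    n_mat = np.zeros((p_count, p_count), dtype=int)
    for i in range(p_count):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n_mat[i, i] = int(np.sum(~np.isnan(X[:, i])))
        for j in range(i + 1, p_count):
            ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            n = int(ok.sum())
            n_mat[i, j] = n_mat[j, i] = n
            if n < min_pairs:
                continue
            xi, xj = X[ok, i], X[ok, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = min(1.0, max(-1.0, rij))
            r[i, j] = r[j, i] = rij
            if n > 2 and abs(rij) < 1.0:
                t = rij * np.sqrt((n - 2) / (1 - rij**2))
                pij = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
            else:
                pij = 0.0 if abs(rij) == 1.0 else np.nan
            p[i, j] = p[j, i] = pij
    to_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)  # noqa: E731
    return to_df(r), to_df(p), to_df(n_mat)
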