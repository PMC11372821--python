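"""Model-matrix construction: point extraction, collinearity screening, PCA.

Collinearity screening follows the common two-stage rule: first drop one
member of every predictor pair with |Pearson r| >= 0.7 (the one with the
larger mean absolute correlation to everything else), then drop
predictors with a variance inflation factor >= 10, largest first.  PCA is
run on standardized variables; the niche comparison keeps the first four
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .grid import PredictorStack, points_to_cells


class ExtractionError(ValueError):
    """A record sits on a masked (non-sea) cell."""


def extract_env(occ: pd.DataFrame, stack: PredictorStack) -> pd.DataFrame:
    """Environmental values at each record's cell (nearest cell, no interpolation).

    Returns a frame indexed like ``occ`` with one column per stack layer,
    in stack order.  A record on a masked cell raises, naming its id.
    """
    r, c = points_to_cells(stack.grid, occ["lon"].to_numpy(), occ["lat"].to_numpy())
    bad = ~stack.mask[r, c]
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ExtractionError(
            f"record id={occ['id'].iloc[i]} lies on a masked cell"
        )
    data = {lyr.name: lyr.values[r, c] for lyr in stack.layers}
    return pd.DataFrame(data, index=occ.index)


def collinearity_filter(
    env: pd.DataFrame, r_max: float = 0.7, vif_max: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop collinear predictors; return survivors and a report.

    Report rows: (variable, action, statistic) with action in
    {"dropped_constant", "dropped_correlation", "dropped_vif", "retained"}.
    """
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    report_rows: list[tuple[str, str, float]] = []
    cols = list(env.columns)

    for name in list(cols):
        if env[name].nunique() <= 1:
            warnings.warn(f"constant predictor '{name}' dropped (VIF undefined)")
            report_rows.append((name, "dropped_constant", np.nan))
            cols.remove(name)

    # stage 1: pairwise Pearson correlation
    while len(cols) >= 2:
        corr = env[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst < r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        # drop the member more correlated with everything else on average
        drop = a if corr.loc[a].mean() >= corr.loc[b].mean() else b
        report_rows.append((drop, "dropped_correlation", float(worst)))
        cols.remove(drop)

    # stage 2: variance inflation factors
    while len(cols) >= 2:
        X = np.column_stack([np.ones(len(env)), env[cols].to_numpy()])
        vifs = np.array(
            [variance_inflation_factor(X, k + 1) for k in range(len(cols))]
        )
        if vifs.max() < vif_max:
            break
        k = int(np.argmax(vifs))
        report_rows.append((cols[k], "dropped_vif", float(vifs[k])))
        cols.pop(k)

    for name in cols:
        report_rows.append((name, "retained", np.nan))
    report = pd.DataFrame(report_rows, columns=["variable", "action", "statistic"])
    return cols, report


@dataclass
class PcaResult:
    """Standardized PCA: loadings and scores of the retained components plus
    the full variance-share spectrum."""

    loadings: pd.DataFrame          # variables x retained components
    scores: np.ndarray              # records x retained components
    variance_explained: np.ndarray  # all p components, fractions summing to 1
    k: int

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_explained[: self.k].sum())


def pca_fit(env: pd.DataFrame, k: int = 4) -> PcaResult:
    """PCA on standardized predictors, keeping the first ``k`` components.

    Components are signed so each component's largest-magnitude loading is
    positive, which removes the eigenvector sign ambiguity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = env.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available variables")
    X = env.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = env.columns[sd == 0][0]
        raise ValueError(f"cannot standardize constant variable '{bad}'")
    Z = (X - mu) / sd
    pca = PCA(n_components=p, svd_solver="full")
    scores_full = pca.fit_transform(Z)
    comps = pca.components_          # p x p, rows are components
    # sign convention: largest |loading| positive
    for i in range(p):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores_full[:, i] *= -1.0
    loadings = pd.DataFrame(
        comps[:k].T, index=env.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return PcaResult(
        loadings=loadings,
        scores=scores_full[:, :k],
        variance_explained=pca.explained_variance_ratio_.copy(),
        k=k,
    )
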