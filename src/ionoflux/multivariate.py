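"""Principal component analysis with explained-variance reporting.

Used on two matrices of the drought study: elemental concentrations
(samples x 20 elements, wildly different ppm ranges, hence unit-variance
scaling by default) and log2(normalized counts + 1) of transport-associated
genes. The quantity of interest is the cumulative proportion of variance
explained by the first components, which measures how strongly harvest time
and water regime structure the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class ScoresAndLoadings:
    """PCA output: sample scores, variable loadings, variance fractions."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components (orthonormal columns)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_ratio)


def pca(
    matrix: Union[pd.DataFrame, np.ndarray],
    center: bool = True,
    scale: bool = True,
) -> ScoresAndLoadings:
    """PCA of a samples x variables matrix.

    The decomposition acts on the (optionally centered and unit-variance
    scaled) data; all min(n_samples, n_variables) components are returned
    with a deterministic sign convention (the largest-magnitude loading of
    each component is positive). Missing values and, with ``scale=True``,
    constant columns are rejected with the offending column named.
    """
    df = pd.DataFrame(matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; imputation is not done here")
    X = df.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = df.columns[sd == 0].tolist()
            raise ValueError(f"constant columns cannot be scaled: {bad}")
        X = X / sd
    model = PCA(n_components=min(X.shape), svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # variables x components
    # sign convention: largest-magnitude loading positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return ScoresAndLoadings(
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def cumulative_variance(fractions: Sequence[float], k: int) -> float:
    """Cumulative proportion of variance explained by the first k components."""
    fr = np.asarray(fractions, dtype=float)
    if not 1 <= k <= fr.size:
        raise ValueError(f"k must lie in [1, {fr.size}], got {k}")
    return float(fr[:k].sum())


def log_normalized_counts(
    counts: pd.DataFrame, effective_library_sizes: pd.Series, pseudo: float = 1.0
) -> pd.DataFrame:
    """log2(CPM + pseudo) expression matrix (samples x genes) for PCA."""
    cpm = counts.div(effective_library_sizes, axis=1) * 1e6
    return np.log2(cpm + pseudo).T
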