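"""PCA-based complementary limb motion estimation (CLME).

The input channels and the target are stacked into one vector; PCA of
the pooled training samples yields an orthonormal loading matrix.  The
loadings are partitioned into an input block and a target block, and
the reconstruction operator maps mean-centered inputs to component
scores via the pseudo-inverse of the input block, then to the target
through the target block.  The map is exactly linear-affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .datasets import SequenceDataset


class PcaClme:
    """PCA-subspace linear synergy model (statsmodels-style Model class).

    Parameters
    ----------
    dataset:
        Training data; all subjects present are pooled.
    variance_target:
        Retained-variance fraction used to pick the component count.
    """

    def __init__(self, dataset: SequenceDataset, variance_target: float = 0.95):
        if not 0.0 < variance_target <= 1.0:
            raise ValueError("variance_target must lie in (0, 1]")
        if len(dataset.subjects) < 1:
            raise ValueError("training dataset is empty")
        self.dataset = dataset
        self.variance_target = variance_target

    def fit(self) -> "PcaClmeResults":
        X = np.concatenate([self.dataset.inputs[s] for s in self.dataset.subjects])
        y = np.concatenate([self.dataset.targets[s] for s in self.dataset.subjects])
        if X.shape[0] <= X.shape[1] + 1:
            raise ValueError("need more time samples than channels")
        Z = np.column_stack([X, y])
        mean = Z.mean(axis=0)
        Zc = Z - mean
        cov = (Zc.T @ Zc) / (len(Zc) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        keep = evals > 1e-12 * max(total, 1.0)
        frac = np.cumsum(evals) / total
        k = int(np.searchsorted(frac, self.variance_target - 1e-12) + 1)
        k = min(k, int(keep.sum()))
        k = max(k, 1)
        loadings = evecs[:, :k]
        U_x = loadings[:-1, :]  # (C, k)
        U_y = loadings[-1, :]  # (k,)
        # guard against an input block that cannot resolve the scores
        sv = np.linalg.svd(U_x, compute_uv=False)
        while k > 1 and sv[min(k, len(sv)) - 1] < 1e-10:
            k -= 1
            warnings.warn("input loading block rank-deficient; reducing component count")
            U_x = evecs[:-1, :k]
            U_y = evecs[-1, :k]
            sv = np.linalg.svd(U_x, compute_uv=False)
        return PcaClmeResults(
            model=self,
            mean=mean,
            loadings=evecs[:, :k],
            eigenvalues=evals,
            k=k,
            explained_variance=float(frac[k - 1]),
        )


@dataclass
class PcaClmeResults:
    """Fitted PCA-CLME estimator."""

    model: PcaClme
    mean: np.ndarray  # (C+1,)
    loadings: np.ndarray  # (C+1, k), orthonormal columns
    eigenvalues: np.ndarray
    k: int
    explained_variance: float

    @property
    def input_loadings(self) -> np.ndarray:
        return self.loadings[:-1, :]

    @property
    def target_loadings(self) -> np.ndarray:
        return self.loadings[-1, :]

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Estimate the target series from an input matrix (T, C)."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        if inputs.shape[1] != self.loadings.shape[0] - 1:
            raise ValueError("input channel count does not match the fitted model")
        centered = inputs - self.mean[:-1]
        scores = np.linalg.lstsq(self.input_loadings, centered.T, rcond=None)[0]
        return self.mean[-1] + self.target_loadings @ scores

    def summary(self) -> pd.DataFrame:
        rows = {
            "components_retained": self.k,
            "explained_variance": self.explained_variance,
            "n_channels": self.loadings.shape[0] - 1,
            "variance_target": self.model.variance_target,
        }
        return pd.DataFrame({"value": rows})
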