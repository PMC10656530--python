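"""Differential identifiability and the PCA-reconstruction sweep.

Functional connectomes act like fingerprints: a subject's test and retest
FC matrices resemble each other more than they resemble other subjects'.
Differential identifiability quantifies that margin,

    I_diff = (mean within-subject similarity - mean between-subject similarity) * 100,

where similarity is the Pearson correlation between edge vectors and the
within/between averages are taken over the S x S identifiability matrix
whose (i, j) entry correlates subject i's test (monoband) connectome with
subject j's retest (multiband) connectome.

Reconstructing the group matrix from its top K principal components
denoises the connectomes; sweeping K and keeping the reconstruction that
maximizes I_diff yields a subject-optimal denoised group matrix that the
ICA stage decomposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .connectome import SESSIONS, GroupFCMatrix

__all__ = [
    "IdentifiabilityResult",
    "IdentifiabilityReconstruction",
    "identifiability_matrix",
    "compute_idiff",
    "pca_reconstruct",
    "sweep_identifiability",
]


@dataclass(frozen=True)
class IdentifiabilityResult:
    """I_diff summary for one (possibly reconstructed) group matrix."""

    ident_matrix: np.ndarray
    i_self: float
    i_others: float
    i_diff: float
    k: int | None = None  # None = unreconstructed original


def _row_standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def identifiability_matrix(group: GroupFCMatrix) -> np.ndarray:
    """S x S matrix of Pearson correlations, monoband rows vs multiband rows.

    Entry (i, j) correlates subject i's monoband edge vector with subject
    j's multiband edge vector; the diagonal holds test-retest self
    similarities.
    """
    mono = group.values[group.session_rows(SESSIONS[0])]
    multi = group.values[group.session_rows(SESSIONS[1])]
    if mono.shape[0] != multi.shape[0] or mono.shape[0] == 0:
        raise ValueError("every subject needs exactly one row per session")
    return _row_standardize(mono) @ _row_standardize(multi).T


def compute_idiff(ident: np.ndarray) -> tuple[float, float, float]:
    """(i_self, i_others, i_diff) from an identifiability matrix.

    i_self is the diagonal mean, i_others the off-diagonal mean, and
    i_diff = (i_self - i_others) * 100 — the percent-like scale on which
    identifiability gains are conventionally reported.
    """
    ident = np.asarray(ident, dtype=float)
    s = ident.shape[0]
    if ident.ndim != 2 or ident.shape[1] != s or s < 2:
        raise ValueError("need a square identifiability matrix with S >= 2")
    i_self = float(np.trace(ident) / s)
    i_others = float((ident.sum() - np.trace(ident)) / (s * (s - 1)))
    return i_self, i_others, (i_self - i_others) * 100.0


def _idiff_of(values: np.ndarray, mono_rows: np.ndarray, multi_rows: np.ndarray) -> IdentifiabilityResult:
    ident = _row_standardize(values[mono_rows]) @ _row_standardize(values[multi_rows]).T
    i_self, i_others, i_diff = compute_idiff(ident)
    return IdentifiabilityResult(ident, i_self, i_others, i_diff)


def pca_reconstruct(group: GroupFCMatrix, k: int) -> GroupFCMatrix:
    """Reconstruct the group matrix from its top-k principal components.

    Edges (columns) are mean-centered over the M rows, the centered matrix
    is reconstructed from the top-k singular triplets, and the means are
    added back.  No variance scaling: all edges already share the Pearson-r
    scale.
    """
    m, e = group.values.shape
    if not 1 <= k <= min(m, e):
        raise ValueError(f"k={k} out of range [1, {min(m, e)}]")
    mean = group.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(group.values - mean, full_matrices=False)
    recon = (u[:, :k] * s[:k]) @ vt[:k] + mean
    return GroupFCMatrix(values=recon, index=group.index)


class IdentifiabilityReconstruction(BaseEstimator, TransformerMixin):
    """PCA reconstruction at the K that maximizes differential identifiability.

    Scikit-learn style transformer over an M x E group matrix whose rows are
    ordered subject-major with monoband before multiband (the layout
    :func:`connica.connectome.assemble_group_matrix` produces).  ``fit``
    sweeps K over ``k_range`` (default every integer in [2, min(M, E)]),
    computing I_diff of the rank-K reconstruction at each step, and keeps
    the principal basis at the maximizing K (ties broken to the smallest K,
    for parsimony).  ``transform`` projects a matrix onto that basis and
    reconstructs it.

    Parameters
    ----------
    k_range : sequence of int or None
        Candidate component counts.  None sweeps the full range [2, rank].
    stride : int
        Subsample the default range by this step (speed knob; the chosen K
        is then only optimal over the visited grid).

    Attributes
    ----------
    optimal_k_ : int
        K attaining the maximum I_diff over the grid.
    idiff_curve_ : pandas.DataFrame
        Columns k, i_self, i_others, i_diff, one row per visited K.
    idiff_original_ : float
        I_diff of the input before any reconstruction.
    idiff_optimal_ : float
        I_diff at ``optimal_k_``.
    components_ : ndarray of shape (optimal_k_, E)
        Principal axes (rows of V^T) retained for reconstruction.
    mean_ : ndarray of shape (E,)
        Per-edge training mean.
    """

    def __init__(self, k_range=None, stride: int = 1):
        self.k_range = k_range
        self.stride = stride

    def fit(self, X, y=None):
        group = self._as_group(X)
        values = group.values
        m, e = values.shape
        mono = group.session_rows(SESSIONS[0])
        multi = group.session_rows(SESSIONS[1])
        if mono.size != multi.size or mono.size < 2:
            raise ValueError("need >= 2 subjects, each with both sessions")

        mean = values.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(values - mean, full_matrices=False)
        rank = int((s > s[0] * max(m, e) * np.finfo(float).eps).sum()) if s.size else 0
        max_k = min(m, e)
        if self.k_range is not None:
            ks = sorted(set(int(k) for k in self.k_range))
            if not ks:
                raise ValueError("empty k_range")
            if ks[0] < 2 or ks[-1] > max_k:
                raise ValueError(f"k_range must lie within [2, {max_k}]")
        else:
            ks = list(range(2, max_k + 1, max(1, int(self.stride))))
            if ks[-1] != max_k:
                ks.append(max_k)

        orig = _idiff_of(values, mono, multi)
        self.idiff_original_ = orig.i_diff

        # incremental rank-k reconstructions: add one scaled outer product per step
        rows = []
        best = None
        recon = np.broadcast_to(mean, values.shape).copy()
        prev_k = 0
        for k in ks:
            recon += (u[:, prev_k:k] * s[prev_k:k]) @ vt[prev_k:k]
            prev_k = k
            res = _idiff_of(recon, mono, multi)
            rows.append((k, res.i_self, res.i_others, res.i_diff))
            if best is None or res.i_diff > best[1] + 1e-12:
                best = (k, res.i_diff)
        self.idiff_curve_ = pd.DataFrame(rows, columns=["k", "i_self", "i_others", "i_diff"])
        self.optimal_k_, self.idiff_optimal_ = best
        self.rank_ = rank
        self.mean_ = mean.ravel()
        self.components_ = vt[: self.optimal_k_]
        self.n_features_in_ = e
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        group = X if isinstance(X, GroupFCMatrix) else None
        values = group.values if group is not None else np.asarray(X, dtype=float)
        centered = values - self.mean_
        recon = centered @ self.components_.T @ self.components_ + self.mean_
        if group is not None:
            return GroupFCMatrix(values=recon, index=group.index)
        return recon

    @staticmethod
    def _as_group(X) -> GroupFCMatrix:
        if isinstance(X, GroupFCMatrix):
            return X
        raise TypeError(
            "IdentifiabilityReconstruction needs a GroupFCMatrix (the row "
            "index carries the subject/session structure)"
        )


@dataclass(frozen=True)
class SweepResult:
    """Convenience bundle around a fitted IdentifiabilityReconstruction."""

    per_k: pd.DataFrame
    optimal_k: int
    idiff_original: float
    idiff_optimal: float
    reconstructed: GroupFCMatrix


def sweep_identifiability(group: GroupFCMatrix, k_range=None, stride: int = 1) -> SweepResult:
    """Functional wrapper over :class:`IdentifiabilityReconstruction`."""
    est = IdentifiabilityReconstruction(k_range=k_range, stride=stride).fit(group)
    return SweepResult(
        per_k=est.idiff_curve_,
        optimal_k=est.optimal_k_,
        idiff_original=est.idiff_original_,
        idiff_optimal=est.idiff_optimal_,
        reconstructed=est.transform(group),
    )
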