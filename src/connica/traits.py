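"""Robust ICA decomposition of the group FC matrix into FC-traits.

The group matrix X (M connectomes x E edges) is modelled as X ~ A @ S,
where the rows of S are statistically independent edge patterns (the
FC-traits) and the columns of A weight each trait's expression in every
connectome.  ICA is run many times from different initialisations;
components that reappear across runs (matched by absolute pattern
correlation) are kept and represented by their run centroid, which guards
against the well-known run-to-run instability of fixed-point ICA.  Weights
are then re-estimated by least squares of X on the retained patterns, so
reconstruction fidelity holds exactly for the reported traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .connectome import GroupFCMatrix

__all__ = ["FCTrait", "ConnICA", "extract_traits", "canonicalize_sign", "match_traits"]


@dataclass
class FCTrait:
    """One independent FC pattern plus its per-connectome weights.

    ``pattern`` (length E, unit L2 norm, sign-canonicalized) is the edge
    loading vector; ``weights`` (length M) quantifies how present the trait
    is in each FC matrix; ``robustness`` is the fraction of ICA runs in
    which a matching component appeared.
    """

    trait_id: int
    pattern: np.ndarray
    weights: pd.Series = field(repr=False)
    robustness: float = 1.0


def canonicalize_sign(trait: FCTrait) -> FCTrait:
    """Resolve ICA's sign indeterminacy deterministically.

    The pattern is flipped so its skewness is positive (a trait is read as
    'edges that strengthen together'); at zero skewness the largest-|loading|
    edge is made positive.  Weights flip jointly so pattern x weights — and
    hence the reconstruction — is unchanged.
    """
    pattern = np.asarray(trait.pattern, dtype=float)
    if not pattern.any():
        raise ValueError("cannot canonicalize an all-zero pattern")
    skew = sstats.skew(pattern)
    if skew != 0:
        flip = skew < 0
    else:
        flip = pattern[np.argmax(np.abs(pattern))] < 0
    if flip:
        return replace(trait, pattern=-pattern, weights=-trait.weights)
    return trait


def _greedy_pairing(corr: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy maximum-|correlation| bipartite pairing on a correlation table."""
    corr = np.abs(np.asarray(corr, dtype=float))
    n_a, n_b = corr.shape
    order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j), float(corr[i, j])))
        used_a.add(int(i))
        used_b.add(int(j))
        if len(pairs) == min(n_a, n_b):
            break
    return pairs


def _pattern_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between two stacks of patterns."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def match_traits(set_a: list[FCTrait], set_b: list[FCTrait]) -> list[tuple[int, int, float]]:
    """Greedy max-|r| pairing between two trait sets.

    Returns (index_in_a, index_in_b, |pattern correlation|) triples, one per
    matched pair (min(|A|, |B|) pairs).  Used both for run-to-run matching
    and for scoring recovery against planted ground truth.
    """
    if not set_a or not set_b:
        raise ValueError("both trait sets must be non-empty")
    corr = _pattern_corr(
        np.vstack([t.pattern for t in set_a]),
        np.vstack([t.pattern for t in set_b]),
    )
    return _greedy_pairing(corr)


class ConnICA(BaseEstimator, TransformerMixin):
    """Robust multi-run ICA of connectome edge vectors (connICA).

    Each run applies whitened fixed-point ICA with the logcosh contrast to
    the transposed group matrix (edges as samples, connectomes as signals),
    yielding candidate edge patterns.  Components are matched to the first
    converged run by absolute pattern correlation >= ``match_threshold``;
    a component is retained if it recurs in at least ``min_frequency`` of
    the ``n_runs`` runs (non-converged runs count toward the denominator),
    and is represented by its sign-aligned run centroid, unit-normalized.
    Weights are re-estimated by least squares, so all scale lives in the
    weights.

    Parameters
    ----------
    n_components : int or None
        Number of ICA components per run.  None defers to ``fit``'s caller
        (the pipeline passes the identifiability sweep's optimal K).
    n_runs : int
        ICA restarts; robustness is measured across these.
    match_threshold : float
        Minimum |pattern r| for two runs' components to count as the same.
    min_frequency : float
        Minimum fraction of runs a component must recur in to be kept.
    max_iter, tol : fixed-point iteration controls per run.
    random_state : seed for the run sequence.

    Attributes
    ----------
    patterns_ : (n_traits, E) unit-norm, sign-canonicalized edge patterns.
    weights_ : (M, n_traits) least-squares weights.
    robustness_ : (n_traits,) fraction of runs each trait recurred in.
    n_converged_ : number of runs that converged.
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_runs: int = 100,
        match_threshold: float = 0.75,
        min_frequency: float = 0.75,
        max_iter: int = 1000,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.match_threshold = match_threshold
        self.min_frequency = min_frequency
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        values, index = self._unpack(X)
        m, e = values.shape
        k = self.n_components or min(m, e)
        if k > min(m, e):
            raise ValueError(f"n_components={k} exceeds min(M, E)={min(m, e)}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        rng = np.random.default_rng(self.random_state)
        run_seeds = rng.integers(0, 2**31 - 1, size=self.n_runs)

        run_patterns: list[np.ndarray] = []
        for seed in run_seeds:
            ica = FastICA(
                n_components=k,
                fun="logcosh",
                whiten="unit-variance",
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=int(seed),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                try:
                    sources = ica.fit_transform(values.T)  # (E, k): edge patterns
                except (ValueError, np.linalg.LinAlgError):
                    continue
            if ica.n_iter_ >= self.max_iter:
                continue  # non-converged: dropped, still in the denominator
            run_patterns.append(sources.T)
        if not run_patterns:
            raise RuntimeError("ICA failed to converge in every run")
        self.n_converged_ = len(run_patterns)

        reference = run_patterns[0]
        counts = np.ones(k)
        aligned_sum = reference.copy()
        for other in run_patterns[1:]:
            corr = _pattern_corr(reference, other)
            for i, j, r in _greedy_pairing(corr):
                if r < self.match_threshold:
                    continue
                sign = np.sign(corr[i, j]) or 1.0
                aligned_sum[i] += sign * other[j]
                counts[i] += 1

        keep = counts / self.n_runs >= self.min_frequency
        if not keep.any():
            raise RuntimeError(
                "no component recurred in at least "
                f"{self.min_frequency:.0%} of {self.n_runs} runs"
            )
        centroids = aligned_sum[keep] / counts[keep, None]
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)

        # least-squares weights: minimize ||X - A S||_F given the patterns
        weights = np.linalg.lstsq(centroids.T, values.T, rcond=None)[0].T

        # canonical sign per trait
        for t in range(centroids.shape[0]):
            skew = sstats.skew(centroids[t])
            flip = skew < 0 if skew != 0 else centroids[t][np.argmax(np.abs(centroids[t]))] < 0
            if flip:
                centroids[t] = -centroids[t]
                weights[:, t] = -weights[:, t]

        self.patterns_ = centroids
        self.weights_ = weights
        self.robustness_ = counts[keep] / self.n_runs
        self.row_index_ = index
        self.n_features_in_ = e
        return self

    def transform(self, X):
        """Least-squares weights of new edge vectors on the fitted patterns."""
        check_is_fitted(self, "patterns_")
        values, _ = self._unpack(X)
        return np.linalg.lstsq(self.patterns_.T, values.T, rcond=None)[0].T

    def traits_(self) -> list[FCTrait]:
        """The fitted decomposition as a list of FCTrait records."""
        check_is_fitted(self, "patterns_")
        out = []
        for t in range(self.patterns_.shape[0]):
            out.append(
                FCTrait(
                    trait_id=t,
                    pattern=self.patterns_[t].copy(),
                    weights=pd.Series(self.weights_[:, t], index=self.row_index_),
                    robustness=float(self.robustness_[t]),
                )
            )
        return out

    @staticmethod
    def _unpack(X):
        if isinstance(X, GroupFCMatrix):
            return X.values, X.index
        values = np.asarray(X, dtype=float)
        return values, pd.RangeIndex(values.shape[0])


def extract_traits(
    reconstructed: GroupFCMatrix,
    n_components: int,
    n_runs: int = 100,
    match_threshold: float = 0.75,
    min_frequency: float = 0.75,
    seed: int | None = None,
) -> list[FCTrait]:
    """Functional wrapper over :class:`ConnICA`; returns FCTrait records."""
    est = ConnICA(
        n_components=n_components,
        n_runs=n_runs,
        match_threshold=match_threshold,
        min_frequency=min_frequency,
        random_state=seed,
    ).fit(reconstructed)
    return est.traits_()
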