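"""Functional-connectivity matrix construction from parcellated time series.

Covers motion-based frame censoring, subject-level exclusion, Pearson FC
computation over retained frames, upper-triangle edge vectorization and the
assembly of the subject-by-edge group matrix that the identifiability and
ICA stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SESSIONS = ("monoband", "multiband")

__all__ = [
    "SESSIONS",
    "TimeSeriesMatrix",
    "FCMatrix",
    "GroupFCMatrix",
    "MotionTable",
    "compute_enorm",
    "censor_frames",
    "exclude_subjects",
    "compute_fc",
    "vectorize_fc",
    "devectorize",
    "assemble_group_matrix",
]


@dataclass
class TimeSeriesMatrix:
    """T x R ROI signal table for one subject-session."""

    values: np.ndarray
    session: str = "monoband"
    tr_seconds: float = 2.0
    keep_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x R matrix")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
            if self.keep_mask.shape != (self.values.shape[0],):
                raise ValueError("keep_mask length must equal the number of frames")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def retained(self) -> np.ndarray:
        return self.values[self.keep_mask]


@dataclass
class FCMatrix:
    """R x R symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    subject: str = ""
    session: str = "monoband"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix diagonal must be 1")
        if np.abs(v).max() > 1.0 + 1e-10:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class MotionTable:
    """Realignment parameters (T x 6) with derived censoring inputs.

    ``params`` holds 3 translations (mm) and 3 rotations in commensurate
    units (upstream conventions such as AFNI's degrees-as-mm are assumed
    already applied).  ``despike_fraction`` is the per-frame proportion of
    voxels adjusted during despiking; it is an input, not computed here.
    """

    params: np.ndarray
    despike_fraction: np.ndarray | None = None
    enorm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be a T x 6 table")
        if self.despike_fraction is None:
            self.despike_fraction = np.zeros(self.params.shape[0])
        else:
            self.despike_fraction = np.asarray(self.despike_fraction, dtype=float)
            if self.despike_fraction.shape != (self.params.shape[0],):
                raise ValueError("despike_fraction length must match the frame count")
        self.enorm = compute_enorm(self.params)


def compute_enorm(params: np.ndarray) -> np.ndarray:
    """Euclidean norm of the frame-to-frame derivative of 6 rigid-body params.

    ``enorm[t] = sqrt(sum_p (params[t, p] - params[t-1, p])**2)``; the first
    frame has no predecessor and is 0 by convention.
    """
    params = np.asarray(params, dtype=float)
    if not np.isfinite(params).all():
        raise ValueError("motion parameters contain non-finite values")
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("expected a T x 6 parameter table")
    out = np.zeros(params.shape[0])
    if params.shape[0] > 1:
        out[1:] = np.sqrt((np.diff(params, axis=0) ** 2).sum(axis=1))
    return out


def censor_frames(
    motion: MotionTable,
    enorm_limit: float = 0.4,
    despike_limit: float = 0.10,
) -> np.ndarray:
    """Frame keep-mask: drop frames with ENORM *larger than* ``enorm_limit``
    or despiked-voxel fraction *exceeding* ``despike_limit``.

    Both rules are strict inequalities, so a frame sitting exactly on a
    limit is kept.
    """
    if enorm_limit < 0 or despike_limit < 0:
        raise ValueError("censoring limits must be non-negative")
    return (motion.enorm <= enorm_limit) & (motion.despike_fraction <= despike_limit)


def exclude_subjects(
    masks: dict[tuple[str, str], np.ndarray],
    max_censored_fraction: float = 0.20,
) -> tuple[list[str], pd.DataFrame]:
    """Drop subjects losing *more than* ``max_censored_fraction`` of frames
    in either session.

    Returns the included subject list plus a per-subject report with both
    sessions' censored fractions.  Every subject must have both sessions.
    """
    subjects = sorted({s for s, _ in masks})
    rows = []
    included = []
    for subj in subjects:
        fracs = {}
        for sess in SESSIONS:
            if (subj, sess) not in masks:
                raise ValueError(f"subject {subj!r} is missing session {sess!r}")
            mask = np.asarray(masks[(subj, sess)], dtype=bool)
            fracs[sess] = 1.0 - mask.mean()
        excluded = any(f > max_censored_fraction for f in fracs.values())
        if not excluded:
            included.append(subj)
        rows.append(
            {
                "subject": subj,
                "censored_monoband": fracs["monoband"],
                "censored_multiband": fracs["multiband"],
                "excluded": excluded,
            }
        )
    return included, pd.DataFrame(rows)


def compute_fc(ts: TimeSeriesMatrix, subject: str = "") -> FCMatrix:
    """Pairwise Pearson correlation between ROI time series over retained frames."""
    data = ts.retained()
    if data.shape[0] < 3:
        raise ValueError("need at least 3 retained frames to correlate")
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant time series for ROI(s) {(flat + 1).tolist()}")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return FCMatrix(values=r, subject=subject, session=ts.session)


def vectorize_fc(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (excluding diagonal) edge vector.

    Edge order is (1,2), (1,3), ..., (1,R), (2,3), ... — the single fixed
    convention used throughout the package.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    i, j = np.triu_indices(values.shape[0], k=1)
    return values[i, j]


def devectorize(v: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`: symmetric matrix with unit diagonal."""
    v = np.asarray(v, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"edge vector length {v.size} != R(R-1)/2 = {expected} for R={n_rois}")
    out = np.eye(n_rois)
    i, j = np.triu_indices(n_rois, k=1)
    out[i, j] = v
    out[j, i] = v
    return out


def edge_endpoints(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based ROI id pairs for each edge in the fixed vectorization order."""
    i, j = np.triu_indices(n_rois, k=1)
    return i + 1, j + 1


@dataclass
class GroupFCMatrix:
    """M x E stack of edge vectors with a (subject, session) row index.

    Rows are ordered subject-major, monoband before multiband, so every
    subject occupies two consecutive rows.
    """

    values: np.ndarray
    index: pd.MultiIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("group matrix must be 2-D")
        if len(self.index) != self.values.shape[0]:
            raise ValueError("row index length must match the matrix")
        if self.index.duplicated().any():
            raise ValueError("duplicate (subject, session) rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def n_rois(self) -> int:
        e = self.n_edges
        r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        if r * (r - 1) // 2 != e:
            raise ValueError(f"edge count {e} is not of the form R(R-1)/2")
        return r

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.index.get_level_values(0)))

    def session_rows(self, session: str) -> np.ndarray:
        """Row positions of one session, in subject order."""
        mask = self.index.get_level_values(1) == session
        return np.flatnonzero(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index)


def assemble_group_matrix(fcs: list[FCMatrix]) -> GroupFCMatrix:
    """Stack vectorized FC matrices into the M x E group matrix.

    Each (subject, session) pair must appear exactly once and all matrices
    must share R.  Row order is deterministic: subjects sorted, monoband
    first within each subject.
    """
    if not fcs:
        raise ValueError("no FC matrices given")
    n_rois = {fc.n_rois for fc in fcs}
    if len(n_rois) != 1:
        raise ValueError(f"mixed ROI counts: {sorted(n_rois)}")
    by_key = {}
    for fc in fcs:
        key = (fc.subject, fc.session)
        if key in by_key:
            raise ValueError(f"duplicate FC matrix for {key}")
        by_key[key] = fc
    subjects = sorted({fc.subject for fc in fcs})
    keys = []
    rows = []
    for subj in subjects:
        for sess in SESSIONS:
            if (subj, sess) not in by_key:
                raise ValueError(f"subject {subj!r} is missing session {sess!r}")
            keys.append((subj, sess))
            rows.append(vectorize_fc(by_key[(subj, sess)]))
    index = pd.MultiIndex.from_tuples(keys, names=["subject", "session"])
    return GroupFCMatrix(values=np.vstack(rows), index=index)
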