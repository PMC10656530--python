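"""On-disk layout: plain TSV/CSV/JSON artifacts shared by all stages.

* time series: one TSV per subject-session (``{subject}_{session}.tsv``),
  T rows x R columns, header = roi_id;
* parcellation: TSV with roi_id, roi_name, hemisphere, network;
* motion: TSV with 6 realignment columns plus an optional
  despike_fraction column;
* covariates/clinical: one TSV row per subject;
* group matrix: TSV of edge values with a sidecar row-index TSV
  (subject, session);
* FC matrix: square CSV with roi_id header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import FCMatrix, GroupFCMatrix, MotionTable, TimeSeriesMatrix
from .parcellation import ParcellationScheme
from .simulate import SyntheticCohort

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "write_group_matrix",
    "read_group_matrix",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_cohort",
]


def write_timeseries(ts: TimeSeriesMatrix, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(ts.values, columns=np.arange(1, ts.n_rois + 1))
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_timeseries(path, session: str | None = None, tr_seconds: float = 2.0) -> TimeSeriesMatrix:
    path = Path(path)
    if session is None:
        # filename convention {subject}_{session}.tsv
        session = path.stem.rsplit("_", 1)[-1]
    frame = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(values=frame.to_numpy(dtype=float), session=session, tr_seconds=tr_seconds)


def write_motion(motion: MotionTable, path) -> Path:
    path = Path(path)
    cols = {f"param{i + 1}": motion.params[:, i] for i in range(6)}
    cols["despike_fraction"] = motion.despike_fraction
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


def read_motion(path) -> MotionTable:
    frame = pd.read_csv(path, sep="\t")
    params = frame.iloc[:, :6].to_numpy(dtype=float)
    despike = (
        frame["despike_fraction"].to_numpy(dtype=float)
        if "despike_fraction" in frame.columns
        else None
    )
    return MotionTable(params=params, despike_fraction=despike)


def write_group_matrix(group: GroupFCMatrix, path, index_path=None) -> tuple[Path, Path]:
    path = Path(path)
    if index_path is None:
        index_path = path.with_name(path.stem + "_index.tsv")
    index_path = Path(index_path)
    pd.DataFrame(group.values).to_csv(path, sep="\t", index=False, header=False)
    group.index.to_frame(index=False).to_csv(index_path, sep="\t", index=False)
    return path, index_path


def read_group_matrix(path, index_path=None) -> GroupFCMatrix:
    path = Path(path)
    if index_path is None:
        index_path = path.with_name(path.stem + "_index.tsv")
    values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    idx = pd.read_csv(index_path, sep="\t")
    index = pd.MultiIndex.from_frame(idx[["subject", "session"]])
    return GroupFCMatrix(values=values, index=index)


def write_fc_matrix(fc: FCMatrix, path) -> Path:
    path = Path(path)
    ids = np.arange(1, fc.n_rois + 1)
    pd.DataFrame(fc.values, index=ids, columns=ids).to_csv(path)
    return path


def read_fc_matrix(path, subject: str = "", session: str = "monoband") -> FCMatrix:
    frame = pd.read_csv(path, index_col=0)
    return FCMatrix(values=frame.to_numpy(dtype=float), subject=subject, session=session)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a synthetic cohort in the exact layout the pipeline reads.

    Produces the per-session time-series TSVs (when simulated), the
    covariate/clinical table, the parcellation lookup, per-session FC CSVs
    and a ground-truth JSON for evaluation.  Returns a manifest of paths.
    """
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    fc_dir = out_dir / "fc"
    out_dir.mkdir(parents=True, exist_ok=True)
    fc_dir.mkdir(exist_ok=True)
    manifest: dict = {"timeseries": [], "fc": []}

    cohort.parcellation.to_tsv(out_dir / "parcellation.tsv")
    manifest["parcellation"] = str(out_dir / "parcellation.tsv")

    rows = []
    for s in cohort.subjects:
        row = {
            "subject": s.subject_id,
            "group": s.group,
            "age": s.age,
            "gender": s.gender,
            "education": s.education,
            "tgm": s.tgm,
            "etiv": s.etiv,
            "avg_enorm": s.avg_enorm,
        }
        row.update(s.clinical)
        row.update(s.raw_tests)
        rows.append(row)
    cov_path = out_dir / "covariates.tsv"
    pd.DataFrame(rows).to_csv(cov_path, sep="\t", index=False)
    manifest["covariates"] = str(cov_path)

    if cohort.timeseries:
        ts_dir.mkdir(exist_ok=True)
        for (subj, sess), ts in cohort.timeseries.items():
            p = write_timeseries(ts, ts_dir / f"{subj}_{sess}.tsv")
            manifest["timeseries"].append(str(p))
    for (subj, sess), fc in cohort.fc_matrices.items():
        p = write_fc_matrix(fc, fc_dir / f"{subj}_{sess}.csv")
        manifest["fc"].append(str(p))

    truth = cohort.ground_truth
    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "trait_patterns": truth.trait_patterns.tolist(),
                "true_weights": truth.true_weights.to_numpy().tolist(),
                "weight_index": [list(k) for k in truth.true_weights.index],
                "effect_trait_index": truth.effect_trait_index,
                "group_effect_size": truth.group_effect_size,
                "session_noise_sd": truth.session_noise_sd,
                "edge_noise_sd": truth.edge_noise_sd,
                "seed": truth.seed,
            },
            fh,
        )
    manifest["ground_truth"] = str(truth_path)
    return manifest
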