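"""End-to-end orchestration: censor -> FC -> assemble -> sweep -> ICA ->
screen -> characterize, with every intermediate written to disk and a JSON
run report declaring the full file manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import export_plot_data, summarize_trait
from .connectome import (
    SESSIONS,
    assemble_group_matrix,
    censor_frames,
    compute_fc,
    exclude_subjects,
)
from .identifiability import IdentifiabilityReconstruction
from .io import read_fc_matrix, read_motion, read_timeseries, write_group_matrix
from .parcellation import ParcellationScheme
from .stats import RM_COVARIATES, screen_traits
from .traits import ConnICA

log = logging.getLogger("connica")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; loadable from a YAML file.

    Defaults mirror the described analysis: censoring at ENORM > 0.4 mm and
    despike fraction > 10%, subject exclusion above 20% censored volumes,
    full identifiability sweep, robust ICA at the sweep's optimal K,
    BH-FDR at q < 0.05 with post-hoc alpha 0.01, and top-1% edge
    characterization with z-score loading normalization.
    """

    # paths
    timeseries_dir: str | None = None
    fc_dir: str | None = None
    parcellation: str | None = None
    covariates: str | None = None
    motion_dir: str | None = None
    output_dir: str = "connica_out"
    # censoring
    enorm_limit: float = 0.4
    despike_limit: float = 0.10
    max_censored_fraction: float = 0.20
    # FC
    fisher_z: bool = False
    # sweep
    k_range: list[int] | None = None
    sweep_stride: int = 1
    # ICA
    n_components: int | None = None  # None = sweep's optimal K
    n_runs: int = 100
    match_threshold: float = 0.75
    min_frequency: float = 0.75
    seed: int = 0
    # stats
    fdr_q: float = 0.05
    posthoc_alpha: float = 0.01
    rm_covariates: list[str] = field(default_factory=lambda: list(RM_COVARIATES))
    association_vars: list[str] = field(
        default_factory=lambda: [
            "attention",
            "executive",
            "memory",
            "language",
            "visuospatial",
            "MOCA",
            "MMSE",
            "MDS-UPDRS-III",
        ]
    )
    # characterization
    top_pct: float = 1.0
    normalization: str = "zscore"
    label_t_low: float = 1.0
    label_t_high: float = 1.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def _load_fcs(config: PipelineConfig, parc: ParcellationScheme):
    """Build (or read) per-session FC matrices, applying censoring when
    motion tables are available."""
    fcs = []
    exclusion_report = None
    if config.timeseries_dir:
        ts_dir = Path(config.timeseries_dir)
        files = sorted(ts_dir.glob("*_*.tsv"))
        if not files:
            raise FileNotFoundError(f"no time-series files found in {ts_dir}")
        masks = {}
        series = {}
        for path in files:
            subj, sess = path.stem.rsplit("_", 1)
            if sess not in SESSIONS:
                raise ValueError(f"unrecognized session tag in {path.name}")
            ts = read_timeseries(path, session=sess)
            if config.motion_dir:
                motion = read_motion(Path(config.motion_dir) / f"{subj}_{sess}.tsv")
                ts.keep_mask = censor_frames(motion, config.enorm_limit, config.despike_limit)
            series[(subj, sess)] = ts
            masks[(subj, sess)] = ts.keep_mask
        included, exclusion_report = exclude_subjects(masks, config.max_censored_fraction)
        for (subj, sess), ts in series.items():
            if subj in included:
                fcs.append(compute_fc(ts, subject=subj))
    elif config.fc_dir:
        for path in sorted(Path(config.fc_dir).glob("*_*.csv")):
            subj, sess = path.stem.rsplit("_", 1)
            fcs.append(read_fc_matrix(path, subject=subj, session=sess))
        if not fcs:
            raise FileNotFoundError(f"no FC matrices found in {config.fc_dir}")
    else:
        raise ValueError("config must set timeseries_dir or fc_dir")
    for fc in fcs:
        if fc.n_rois != parc.n_rois:
            raise ValueError(
                f"FC matrix for {fc.subject}/{fc.session} has {fc.n_rois} ROIs, "
                f"parcellation has {parc.n_rois}"
            )
    return fcs, exclusion_report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the JSON-serializable run report."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def declare(path) -> Path:
        manifest.append(str(path))
        return Path(path)

    if not config.parcellation:
        raise ValueError("config must set the parcellation path")
    parc_path = Path(config.parcellation)
    if not parc_path.exists():
        raise FileNotFoundError(f"parcellation file not found: {parc_path}")
    parc = ParcellationScheme.from_tsv(parc_path)

    # --- censor + FC + assemble -------------------------------------------
    fcs, exclusion_report = _load_fcs(config, parc)
    group = assemble_group_matrix(fcs)
    if config.fisher_z:
        group.values = np.arctanh(np.clip(group.values, -1 + 1e-12, 1 - 1e-12))
    log.info("assembled group matrix: %d rows x %d edges", group.n_rows, group.n_edges)
    write_group_matrix(group, declare(out / "group_matrix.tsv"), declare(out / "group_matrix_index.tsv"))
    if exclusion_report is not None:
        exclusion_report.to_csv(declare(out / "exclusion_report.tsv"), sep="\t", index=False)

    # --- identifiability sweep --------------------------------------------
    sweep = IdentifiabilityReconstruction(k_range=config.k_range, stride=config.sweep_stride)
    reconstructed = sweep.fit_transform(group)
    sweep.idiff_curve_.to_csv(declare(out / "idiff_curve.tsv"), sep="\t", index=False)
    write_group_matrix(
        reconstructed, declare(out / "reconstructed.tsv"), declare(out / "reconstructed_index.tsv")
    )
    log.info(
        "identifiability: original %.2f -> %.2f at K=%d",
        sweep.idiff_original_,
        sweep.idiff_optimal_,
        sweep.optimal_k_,
    )

    # --- ICA trait extraction ---------------------------------------------
    n_components = config.n_components or sweep.optimal_k_
    ica = ConnICA(
        n_components=n_components,
        n_runs=config.n_runs,
        match_threshold=config.match_threshold,
        min_frequency=config.min_frequency,
        random_state=config.seed,
    ).fit(reconstructed)
    traits = ica.traits_()
    pd.DataFrame(ica.patterns_).to_csv(declare(out / "trait_patterns.tsv"), sep="\t", index=False, header=False)
    weights = pd.DataFrame(
        ica.weights_, index=group.index, columns=[f"trait{t}" for t in range(len(traits))]
    )
    weights.to_csv(declare(out / "trait_weights.tsv"), sep="\t")
    with open(declare(out / "trait_robustness.json"), "w") as fh:
        json.dump({f"trait{t.trait_id}": t.robustness for t in traits}, fh, indent=2)

    # --- statistics ---------------------------------------------------------
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_rows": group.n_rows,
        "n_edges": group.n_edges,
        "optimal_k": int(sweep.optimal_k_),
        "idiff_original": float(sweep.idiff_original_),
        "idiff_optimal": float(sweep.idiff_optimal_),
        "n_traits": len(traits),
    }
    n_significant = None
    if config.covariates:
        design_all = pd.read_csv(config.covariates, sep="\t").set_index("subject")
        design = design_all.loc[group.subjects]
        w_indexed = pd.DataFrame(ica.weights_, index=group.index)
        session_codes = (group.index.get_level_values(1) == SESSIONS[1]).astype(float)
        baseline = pd.DataFrame(
            {
                "age": design["age"].reindex(group.index.get_level_values(0)).to_numpy(),
                "sequence": session_codes,
                "avg_enorm": design["avg_enorm"].reindex(group.index.get_level_values(0)).to_numpy(),
                "tgm": design["tgm"].reindex(group.index.get_level_values(0)).to_numpy(),
                "etiv": design["etiv"].reindex(group.index.get_level_values(0)).to_numpy(),
            }
        )
        assoc_cols = [v for v in config.association_vars if v in design.columns]
        assoc = pd.DataFrame(
            {
                v: design[v].reindex(group.index.get_level_values(0)).to_numpy()
                for v in assoc_cols
            }
        )
        results = screen_traits(
            w_indexed,
            design,
            q=config.fdr_q,
            covariates=tuple(config.rm_covariates),
            association_vars=assoc if not assoc.empty else None,
            baseline=baseline,
        )
        table = pd.DataFrame(
            {
                "trait_id": [r.trait_id for r in results],
                "f_stat": [r.f_stat for r in results],
                "p_value": [r.p_value for r in results],
                "q_value": [r.q_value for r in results],
                "significant": [r.significant for r in results],
            }
        )
        table.to_csv(declare(out / "trait_tests.tsv"), sep="\t", index=False)
        posthoc_rows = []
        assoc_rows = []
        for r in results:
            for (a, b), (f, p) in r.posthoc.items():
                posthoc_rows.append(
                    {
                        "trait_id": r.trait_id,
                        "pair": f"{a} vs {b}",
                        "f_stat": f,
                        "p_value": p,
                        "significant": p < config.posthoc_alpha,
                    }
                )
            for var, (f, p) in r.associations.items():
                assoc_rows.append({"trait_id": r.trait_id, "variable": var, "f_stat": f, "p_value": p})
        pd.DataFrame(posthoc_rows).to_csv(declare(out / "posthoc_tests.tsv"), sep="\t", index=False)
        pd.DataFrame(assoc_rows).to_csv(declare(out / "associations.tsv"), sep="\t", index=False)
        n_significant = int(table["significant"].sum())
        report["n_significant_traits"] = n_significant
        report["significant_trait_ids"] = table.loc[table["significant"], "trait_id"].tolist()

        # --- characterization of significant traits ----------------------
        char_dir = out / "characterization"
        for r in results:
            if not r.significant:
                continue
            summary = summarize_trait(
                traits[r.trait_id],
                parc,
                pct=config.top_pct,
                normalization=config.normalization,
                t_low=config.label_t_low,
                t_high=config.label_t_high,
            )
            for p in export_plot_data(summary, char_dir).values():
                declare(p)

    report["elapsed_seconds"] = round(time.time() - t0, 3)
    report["label_rule"] = (
        f"network score < {config.label_t_low} -> '-', "
        f"< {config.label_t_high} -> '+', else '++'"
    )
    report["manifest"] = manifest
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
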