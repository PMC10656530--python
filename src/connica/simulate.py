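"""Seeded synthetic cohorts with planted FC-traits.

Real patient connectomes for this kind of study are not publicly
deposited, so every downstream stage is exercised against cohorts whose
ground truth is known by construction:

* a small number of network-block-structured, near-orthogonal edge
  patterns (the planted FC-traits);
* per-subject trait weights, copied to both acquisition sessions with
  session jitter, with one trait's weights shifted in one group (the
  planted group effect);
* edge vectors mixed as weights' x patterns plus edge noise, squashed
  through tanh into (-1, 1) and devectorized to valid FC matrices;
* optional multivariate-normal time series whose population correlation
  matches each FC matrix (after a nearest-positive-definite repair), so
  the Pearson-FC stage can be exercised end to end;
* covariates and cognitive/clinical scores whose group distributions
  follow the published cohort where available, with configurable linear
  links between chosen variables and the planted effect-trait weights.

Defaults mirror the study conditions: three groups of 23/19/21 subjects,
two sessions each (126 connectomes), 5 planted traits, a standardized
group shift of 1.5 on one trait, and edge noise calibrated so the planted
signal explains about half the pre-squash edge variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import SESSIONS, FCMatrix, GroupFCMatrix, TimeSeriesMatrix, devectorize
from .parcellation import ParcellationScheme, make_parcellation
from .stats import ALL_TESTS, DOMAINS

__all__ = [
    "GroundTruth",
    "SubjectRecord",
    "SyntheticCohort",
    "CohortConfig",
    "generate_trait_patterns",
    "generate_weights",
    "synthesize_fc",
    "synthesize_timeseries",
    "synthesize_clinical",
    "generate_cohort",
    "DEFAULT_CONTROL_STATS",
]

DEFAULT_GROUP_SIZES = {"HC": 21, "PD-CN": 19, "PD-MCI": 23}
EFFECT_GROUP = "PD-MCI"

#: Published group means/SDs used for covariate draws (age in years,
#: avg ENORM in mm, MDS-UPDRS-III in points, male proportion).
GROUP_COVARIATE_STATS = {
    "HC": {"age": (68.65, 3.9), "male_p": 0.524, "avg_enorm": (0.100, 0.045), "updrs": (0.0, 0.0), "education": (12.9, 3.0)},
    "PD-CN": {"age": (66.58, 7.0), "male_p": 0.80, "avg_enorm": (0.098, 0.041), "updrs": (18.63, 8.51), "education": (13.8, 3.0)},
    "PD-MCI": {"age": (72.22, 5.43), "male_p": 0.522, "avg_enorm": (0.099, 0.048), "updrs": (26.36, 12.07), "education": (9.0, 2.5)},
}

#: Anatomical covariates (cm^3): total grey matter and intracranial volume.
TGM_STATS = (620.0, 55.0)
ETIV_STATS = (1500.0, 150.0)

#: Healthy-control normative (mean, SD) per neuropsychological test, used
#: to back-compute raw scores from simulated z-scores.
DEFAULT_CONTROL_STATS = pd.DataFrame(
    {
        "mean": [5.0, 45.0, 90.0, 15.0, 8.0, 18.0, 20.0, 52.0, 17.0, 8.0],
        "sd": [1.2, 10.0, 30.0, 4.0, 3.0, 6.0, 5.0, 5.0, 2.0, 1.5],
    },
    index=list(ALL_TESTS),
)

#: Default linear links between clinical variables and the planted
#: effect-trait weight (per-variable slope; domains on the z scale,
#: MOCA/MMSE/MDS-UPDRS-III on their raw scales).
DEFAULT_COEFF_MAP = {
    "attention": -0.6,
    "memory": -0.6,
    "language": -0.45,
    "MDS-UPDRS-III": 4.0,
    "MOCA": -1.5,
    "MMSE": -0.8,
}


@dataclass
class GroundTruth:
    """The planted structure behind one synthetic cohort."""

    trait_patterns: np.ndarray  # n_traits x E, unit-norm rows
    true_weights: pd.DataFrame  # M x n_traits, (subject, session) index
    effect_trait_index: int
    group_effect_size: float
    session_noise_sd: float
    edge_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.trait_patterns, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("trait patterns must have unit L2 norm")
        if not 0 <= self.effect_trait_index < self.trait_patterns.shape[0]:
            raise ValueError("effect_trait_index out of range")
        if self.session_noise_sd < 0 or self.edge_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class SubjectRecord:
    """One subject's group label, covariates and clinical scores."""

    subject_id: str
    group: str
    age: float
    gender: str
    education: float
    tgm: float
    etiv: float
    avg_enorm: float
    clinical: dict[str, float] = field(default_factory=dict)
    raw_tests: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """A full simulated cohort plus its ground truth."""

    subjects: list[SubjectRecord]
    fc_matrices: dict[tuple[str, str], FCMatrix]
    ground_truth: GroundTruth
    parcellation: ParcellationScheme
    timeseries: dict[tuple[str, str], TimeSeriesMatrix] = field(default_factory=dict)

    def group_matrix(self) -> GroupFCMatrix:
        """Stack the true (target) FC matrices into the group matrix."""
        from .connectome import assemble_group_matrix

        return assemble_group_matrix(list(self.fc_matrices.values()))

    def design_frame(self) -> pd.DataFrame:
        """Subject-level design table (group + covariates), subject-indexed."""
        rows = {
            s.subject_id: {
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "education": s.education,
                "tgm": s.tgm,
                "etiv": s.etiv,
                "avg_enorm": s.avg_enorm,
                **s.clinical,
            }
            for s in self.subjects
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")


# ---------------------------------------------------------------------------
# trait patterns
# ---------------------------------------------------------------------------


def generate_trait_patterns(
    parcellation: ParcellationScheme,
    n_traits: int,
    block_density: float = 0.5,
    seed: int = 0,
    n_blocks: int = 3,
    max_cosine: float = 0.3,
    max_redraws: int = 50,
) -> np.ndarray:
    """Network-block-structured, near-orthogonal unit-norm edge patterns.

    Each trait picks ``n_blocks`` random within/between-network edge blocks
    and fills a ``block_density`` fraction of their edges with Gaussian
    loadings; everything else is zero.  Rows are unit-normalized and
    redrawn until all pairwise |cosines| stay below ``max_cosine``.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    networks = parcellation.networks
    if len(networks) < 2:
        raise ValueError("parcellation must define at least 2 networks")
    if not 0 < block_density <= 1:
        raise ValueError("block_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    r = parcellation.n_rois
    i, j = np.triu_indices(r, k=1)
    net = parcellation.network_of()
    blocks = [
        (a, b) for ai, a in enumerate(networks) for b in networks[ai:]
    ]
    block_masks = {
        (a, b): ((net[i] == a) & (net[j] == b)) | ((net[i] == b) & (net[j] == a))
        for a, b in blocks
    }
    patterns: list[np.ndarray] = []
    for t in range(n_traits):
        for _ in range(max_redraws):
            chosen = rng.choice(len(blocks), size=min(n_blocks, len(blocks)), replace=False)
            mask = np.zeros(i.size, dtype=bool)
            for c in chosen:
                mask |= block_masks[blocks[c]]
            mask &= rng.random(i.size) < block_density
            if not mask.any():
                continue
            vec = np.zeros(i.size)
            vec[mask] = rng.standard_normal(mask.sum())
            vec /= np.linalg.norm(vec)
            if all(abs(vec @ p) < max_cosine for p in patterns):
                patterns.append(vec)
                break
        else:
            raise RuntimeError(
                f"could not draw trait {t} with pairwise |cosine| < {max_cosine} "
                f"in {max_redraws} tries (n_traits too large for E={i.size}?)"
            )
    return np.vstack(patterns)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def _subject_ids(group_sizes: Mapping[str, int]) -> list[tuple[str, str]]:
    out = []
    n = 0
    for group, size in group_sizes.items():
        if size < 0:
            raise ValueError(f"negative group size for {group!r}")
        for _ in range(size):
            n += 1
            out.append((f"sub-{n:03d}", group))
    return out


def generate_weights(
    group_sizes: Mapping[str, int],
    n_traits: int,
    effect_trait: int = 0,
    effect_size: float = 1.5,
    session_effect_sd: float = 0.3,
    seed: int = 0,
    effect_group: str = EFFECT_GROUP,
) -> tuple[pd.DataFrame, pd.Series]:
    """Subject trait weights copied to both sessions with jitter.

    Baseline weights are i.i.d. standard normal per subject and trait; each
    session row adds N(0, session_effect_sd^2) jitter.  The ``effect_trait``
    column of ``effect_group`` subjects is shifted by ``effect_size``
    (a standardized mean difference, the baseline SD being 1).  Returns the
    M x n_traits weight table with a (subject, session) row index plus the
    subject -> group map.
    """
    if effect_group not in group_sizes:
        raise KeyError(f"unknown effect group {effect_group!r}")
    if session_effect_sd < 0:
        raise ValueError("session_effect_sd must be non-negative")
    if not 0 <= effect_trait < n_traits:
        raise ValueError("effect_trait out of range")
    rng = np.random.default_rng(seed)
    subjects = _subject_ids(group_sizes)
    rows = []
    keys = []
    groups = {}
    for subj, group in subjects:
        base = rng.standard_normal(n_traits)
        if group == effect_group:
            base[effect_trait] += effect_size
        for sess in SESSIONS:
            jitter = rng.standard_normal(n_traits) * session_effect_sd
            rows.append(base + jitter)
            keys.append((subj, sess))
        groups[subj] = group
    index = pd.MultiIndex.from_tuples(keys, names=["subject", "session"])
    weights = pd.DataFrame(np.vstack(rows), index=index)
    return weights, pd.Series(groups, name="group")


# ---------------------------------------------------------------------------
# FC matrices and time series
# ---------------------------------------------------------------------------


def synthesize_fc(
    trait_patterns: np.ndarray,
    weights: pd.DataFrame,
    edge_noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], FCMatrix], float]:
    """Mix traits into edge vectors, add edge noise, squash, devectorize.

    Pre-squash edge vector = weights_row @ patterns + N(0, edge_noise_sd^2);
    tanh maps it into (-1, 1) monotonically, and the vector is devectorized
    into a symmetric unit-diagonal FC matrix.  ``edge_noise_sd=None``
    calibrates the noise so the planted signal explains ~half the pre-squash
    edge variance (noise SD = RMS of the composite signal).  Returns the FC
    map plus the noise SD actually used.
    """
    patterns = np.asarray(trait_patterns, dtype=float)
    if patterns.shape[0] != weights.shape[1]:
        raise ValueError("weights columns must match the number of trait patterns")
    rng = np.random.default_rng(seed)
    signal = weights.to_numpy() @ patterns
    if edge_noise_sd is None:
        edge_noise_sd = float(np.sqrt((signal**2).mean()))
    if edge_noise_sd < 0:
        raise ValueError("edge_noise_sd must be non-negative")
    noisy = signal + rng.standard_normal(signal.shape) * edge_noise_sd
    squashed = np.tanh(noisy)
    r = int(round((1 + np.sqrt(1 + 8 * patterns.shape[1])) / 2))
    out = {}
    for row, (subj, sess) in enumerate(weights.index):
        out[(subj, sess)] = FCMatrix(
            values=devectorize(squashed[row], r), subject=subj, session=sess
        )
    return out, float(edge_noise_sd)


def nearest_correlation(matrix: np.ndarray, eig_floor: float = 1e-6) -> tuple[np.ndarray, float]:
    """Positive-definite repair: clip eigenvalues at ``eig_floor``, rescale
    to unit diagonal.  Returns the corrected matrix and the largest absolute
    entry change applied."""
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    fixed = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, float(np.abs(fixed - matrix).max())


def synthesize_timeseries(
    fc_target: FCMatrix | np.ndarray,
    n_frames: int,
    seed: int = 0,
    session: str = "monoband",
    tr_seconds: float = 2.0,
) -> tuple[TimeSeriesMatrix, float]:
    """Draw T frames of a zero-mean MVN whose correlation is the nearest-PD
    repair of ``fc_target``.  Returns the series plus the largest entry
    change the repair introduced (0 when the target was already PD)."""
    target = fc_target.values if isinstance(fc_target, FCMatrix) else np.asarray(fc_target, float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("fc_target must be square")
    corr, correction = nearest_correlation(target)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    data = rng.standard_normal((n_frames, target.shape[0])) @ chol.T
    return TimeSeriesMatrix(values=data, session=session, tr_seconds=tr_seconds), correction


# ---------------------------------------------------------------------------
# covariates and clinical scores
# ---------------------------------------------------------------------------


def synthesize_clinical(
    weights: pd.DataFrame,
    effect_trait: int,
    groups: pd.Series,
    coeff_map: Mapping[str, float] | None = None,
    control_stats: pd.DataFrame | None = None,
    clinical_noise_sd: float = 0.5,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Subject records with covariates and weight-linked clinical variables.

    Each variable named in ``coeff_map`` (cognitive domains, MDS-UPDRS-III,
    MOCA, MMSE) is generated as intercept + coeff * mean effect-trait
    weight + noise; domain variables live on the z scale and their two raw
    test scores are back-computed through ``control_stats``
    (raw = control mean + z * control SD).  Covariates follow the published
    per-group distributions.  HC subjects always carry 0 for MDS-UPDRS-III.
    """
    if coeff_map is None:
        coeff_map = DEFAULT_COEFF_MAP
    if control_stats is None:
        control_stats = DEFAULT_CONTROL_STATS
    known = set(DOMAINS) | {"MDS-UPDRS-III", "MOCA", "MMSE"}
    unknown = set(coeff_map) - known
    if unknown:
        raise ValueError(f"coeff_map keys not recognized: {sorted(unknown)}")
    for domain in set(coeff_map) & set(DOMAINS):
        for test in DOMAINS[domain]:
            if test not in control_stats.index:
                raise ValueError(f"control_stats missing entry for test {test!r}")
    rng = np.random.default_rng(seed)
    mean_w = weights.iloc[:, effect_trait].groupby(level=0).mean()
    records = []
    for subj in mean_w.index:
        group = groups[subj]
        gs = GROUP_COVARIATE_STATS[group]
        w = float(mean_w[subj])
        clinical: dict[str, float] = {}
        raw_tests: dict[str, float] = {}
        for domain, tests in DOMAINS.items():
            coeff = coeff_map.get(domain, 0.0)
            domain_z = coeff * w + rng.standard_normal() * clinical_noise_sd
            clinical[domain] = float("nan")  # filled with mean of the two tests below
            zs = []
            for test in tests:
                z = domain_z + rng.standard_normal() * 0.3
                mu, sd = control_stats.loc[test, ["mean", "sd"]]
                raw_tests[test] = float(mu + z * sd)
                zs.append(z)
            clinical[domain] = float(np.mean(zs))
        if group == "HC":
            clinical["MDS-UPDRS-III"] = 0.0  # controls are untested, coded 0
        else:
            mu, sd = gs["updrs"]
            clinical["MDS-UPDRS-III"] = float(
                max(0.0, mu + coeff_map.get("MDS-UPDRS-III", 0.0) * w + rng.standard_normal() * sd * 0.5)
            )
        clinical["MOCA"] = float(
            np.clip(26.0 + coeff_map.get("MOCA", 0.0) * w + rng.standard_normal() * 1.5, 0, 30)
        )
        clinical["MMSE"] = float(
            np.clip(29.0 + coeff_map.get("MMSE", 0.0) * w + rng.standard_normal() * 0.8, 0, 30)
        )
        records.append(
            SubjectRecord(
                subject_id=subj,
                group=group,
                age=float(rng.normal(*gs["age"])),
                gender="male" if rng.random() < gs["male_p"] else "female",
                education=float(max(3.0, rng.normal(*gs["education"]))),
                tgm=float(rng.normal(*TGM_STATS)),
                etiv=float(rng.normal(*ETIV_STATS)),
                avg_enorm=float(max(0.01, rng.normal(*gs["avg_enorm"]))),
                clinical=clinical,
                raw_tests=raw_tests,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the emulated cohort: 23/19/21 subjects in the PD-MCI,
    PD-CN and HC groups, two sessions each, 5 planted traits with a
    standardized group shift of 1.5 on trait 0, session jitter SD 0.3, and
    edge noise calibrated to a planted-signal R^2 of ~0.5.  ``n_rois``
    defaults to 100 for desk-scale runs; the full-scale parcellation is
    408.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_rois: int = 100
    n_traits: int = 5
    effect_trait: int = 0
    effect_size: float = 1.5
    effect_group: str = EFFECT_GROUP
    session_effect_sd: float = 0.3
    edge_noise_sd: float | None = None  # None = calibrate to signal R^2 ~ 0.5
    block_density: float = 0.5
    #: frames per session: ~395 s at TR 2 s (monoband), 480 s at TR 0.8 s
    #: (multiband), mirroring the two acquisition types
    n_frames: dict[str, int] = field(
        default_factory=lambda: {"monoband": 198, "multiband": 600}
    )
    tr_seconds: dict[str, float] = field(
        default_factory=lambda: {"monoband": 2.0, "multiband": 0.8}
    )
    with_timeseries: bool = False
    seed: int = 0


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a full cohort from a config (fields overridable by keyword)."""
    if config is None:
        config = CohortConfig()
    for key, value in overrides.items():
        if not hasattr(config, key):
            raise TypeError(f"unknown cohort option {key!r}")
        setattr(config, key, value)
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    parcellation = make_parcellation(config.n_rois)
    patterns = generate_trait_patterns(
        parcellation,
        config.n_traits,
        block_density=config.block_density,
        seed=int(sub_seeds[0]),
    )
    weights, groups = generate_weights(
        config.group_sizes,
        config.n_traits,
        effect_trait=config.effect_trait,
        effect_size=config.effect_size,
        session_effect_sd=config.session_effect_sd,
        seed=int(sub_seeds[1]),
        effect_group=config.effect_group,
    )
    fcs, noise_sd = synthesize_fc(patterns, weights, config.edge_noise_sd, seed=int(sub_seeds[2]))
    subjects = synthesize_clinical(
        weights, config.effect_trait, groups, seed=int(sub_seeds[3])
    )
    timeseries: dict[tuple[str, str], TimeSeriesMatrix] = {}
    if config.with_timeseries:
        ts_rng = np.random.default_rng(int(sub_seeds[2]) + 1)
        for key, fc in fcs.items():
            ts, _ = synthesize_timeseries(
                fc,
                config.n_frames[key[1]],
                seed=int(ts_rng.integers(0, 2**31 - 1)),
                session=key[1],
                tr_seconds=config.tr_seconds[key[1]],
            )
            timeseries[key] = ts
    truth = GroundTruth(
        trait_patterns=patterns,
        true_weights=weights,
        effect_trait_index=config.effect_trait,
        group_effect_size=config.effect_size,
        session_noise_sd=config.session_effect_sd,
        edge_noise_sd=noise_sd,
        seed=config.seed,
    )
    return SyntheticCohort(
        subjects=subjects,
        fc_matrices=fcs,
        ground_truth=truth,
        parcellation=parcellation,
        timeseries=timeseries,
    )
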