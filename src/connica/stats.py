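"""Group statistics on FC-trait weights and cognitive z-scoring.

Three families of tests:

* a mixed-design (repeated-measures) ANOVA per trait — group (HC, PD-CN,
  PD-MCI) as the between-subjects factor, acquisition sequence as the
  within-subject factor, and covariates (age, gender, TGM by default) —
  screened across traits with Benjamini-Hochberg FDR at q < 0.05;
* covariate-adjusted pairwise post-hoc F tests between group pairs
  (significance read at p < 0.01);
* nested-model partial F tests regressing pooled session weights on one
  cognitive/clinical variable over a baseline of five nuisance variables
  (age, sequence, average ENORM, TGM, eTIV).

Cognitive scores are z-scored against a control sample, combined into five
two-test domain composites, and Level-II mild-cognitive-impairment status
is assigned when more than 1.5 SD below control values on at least two
tests (within or across domains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DOMAINS",
    "ZScoreTable",
    "TraitTestResult",
    "compute_zscores",
    "classify_mci",
    "rm_anova_trait",
    "fdr_adjust",
    "posthoc_pairwise",
    "nested_model_f",
    "screen_traits",
]

GROUPS = ("HC", "PD-CN", "PD-MCI")

#: Five cognitive domains, each scored by exactly two tests.
DOMAINS: dict[str, tuple[str, str]] = {
    "attention": ("span_inverse", "digit_symbol"),
    "executive": ("trail_making", "phonemic_fluency"),
    "memory": ("ravlt", "rocf"),
    "language": ("semantic_fluency", "boston_naming"),
    "visuospatial": ("vosp_objects", "vosp_numeric"),
}

ALL_TESTS = tuple(t for pair in DOMAINS.values() for t in pair)

#: Covariates of the repeated-measures group model.
RM_COVARIATES = ("age", "gender", "tgm")
#: Baseline nuisance variables of the nested association models.
BASELINE_VARS = ("age", "sequence", "avg_enorm", "tgm", "etiv")


# ---------------------------------------------------------------------------
# cognitive z-scoring and MCI classification
# ---------------------------------------------------------------------------


@dataclass
class ZScoreTable:
    """Per-subject test z-scores, domain composites and the control stats used."""

    z: pd.DataFrame = field(repr=False)  # subjects x tests
    domain_composites: pd.DataFrame = field(repr=False)  # subjects x domains
    control_stats: pd.DataFrame = field(repr=False)  # tests x (mean, sd)


def compute_zscores(raw: pd.DataFrame, control_stats: pd.DataFrame) -> ZScoreTable:
    """z = (raw score - control mean) / control SD, per test.

    ``control_stats`` is indexed by test name with columns ``mean`` and
    ``sd`` estimated on the healthy control sample.  Domain composites are
    the unweighted mean of each domain's two test z-scores.
    """
    unknown = set(raw.columns) - set(control_stats.index)
    if unknown:
        raise ValueError(f"no control stats for test(s): {sorted(unknown)}")
    sd = control_stats.loc[raw.columns, "sd"]
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"control SD must be positive; offending test(s): {bad}")
    z = (raw - control_stats.loc[raw.columns, "mean"]) / sd
    composites = {}
    for domain, tests in DOMAINS.items():
        present = [t for t in tests if t in z.columns]
        if len(present) == 2:
            composites[domain] = z[list(present)].mean(axis=1)
    return ZScoreTable(
        z=z,
        domain_composites=pd.DataFrame(composites, index=raw.index),
        control_stats=control_stats.loc[raw.columns],
    )


def classify_mci(
    z: ZScoreTable, threshold: float = -1.5, min_tests: int = 2
) -> pd.DataFrame:
    """Level-II criterion: MCI iff strictly below ``threshold`` on at least
    ``min_tests`` tests, whether within one cognitive domain or across
    domains.

    A score of exactly -1.5 does not count as impaired (the rule is "more
    than 1.5 SD below").  All ten tests must be present; missing scores are
    an error rather than silently imputed.
    """
    missing = set(ALL_TESTS) - set(z.z.columns)
    if missing:
        raise ValueError(f"missing test score(s): {sorted(missing)}")
    if z.z[list(ALL_TESTS)].isna().any().any():
        bad = z.z.index[z.z[list(ALL_TESTS)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing cognitive scores for subject(s): {bad}")
    impaired = z.z[list(ALL_TESTS)] < threshold
    status = np.where(impaired.sum(axis=1) >= min_tests, "MCI", "CN")
    impaired_lists = [
        [t for t in ALL_TESTS if impaired.at[subj, t]] for subj in z.z.index
    ]
    return pd.DataFrame(
        {"status": status, "impaired_tests": impaired_lists}, index=z.z.index
    )


# ---------------------------------------------------------------------------
# OLS building blocks
# ---------------------------------------------------------------------------


def _ols_rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank of an OLS fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _nested_f(
    y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray
) -> tuple[float, float, int, int]:
    """Extra-sum-of-squares F test of the full against the nested model."""
    n = y.size
    rss_full, rank_full = _ols_rss(y, x_full)
    rss_red, rank_red = _ols_rss(y, x_reduced)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_num <= 0 or df_den <= 0:
        raise ValueError(
            f"insufficient degrees of freedom (num={df_num}, den={df_den})"
        )
    if rss_full <= 0:
        return float("inf"), 0.0, df_num, df_den
    f = (rss_red - rss_full) / df_num / (rss_full / df_den)
    f = max(f, 0.0)
    p = float(sstats.f.sf(f, df_num, df_den))
    return float(f), p, df_num, df_den


def _design_columns(design: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for name in covariates:
        if name not in design.columns:
            raise ValueError(f"covariate {name!r} missing from the design table")
        col = design[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            col = numeric
        else:  # genuinely categorical (e.g. gender): binary indicator
            col = pd.get_dummies(col, drop_first=True).iloc[:, 0]
        col = np.asarray(col, dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {name!r} is constant (rank-deficient design)")
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(design), 0))


def _group_dummies(groups: pd.Series) -> np.ndarray:
    return pd.get_dummies(groups, drop_first=True).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# trait-level tests
# ---------------------------------------------------------------------------


def _subject_table(weights: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """Collapse session rows to one row per subject: weight mean and
    between-session difference, joined with subject-level covariates."""
    if not isinstance(weights.index, pd.MultiIndex):
        raise ValueError("weights need a (subject, session) MultiIndex")
    per_subj = weights.groupby(level=0)
    if (per_subj.size() != 2).any():
        raise ValueError("every subject needs exactly two weight rows")
    table = pd.DataFrame(
        {"weight_mean": per_subj.mean(), "weight_diff": per_subj.diff().groupby(level=0).last()}
    )
    return table.join(design, how="inner")


def rm_anova_trait(
    weights: pd.Series,
    design: pd.DataFrame,
    covariates=RM_COVARIATES,
) -> tuple[float, float]:
    """Between-subjects group F from the mixed-design ANOVA on one trait.

    The within-subject (sequence) stratum is removed by averaging each
    subject's two session weights; the group effect is then the
    covariate-adjusted extra-sum-of-squares F of group membership on those
    subject means (classical two-stage treatment of a design with one
    between factor, one within factor and subject-level covariates).
    ``design`` is indexed by subject and must carry ``group`` plus the
    covariates.

    Returns (F, p) for the group effect.
    """
    table = _subject_table(weights, design)
    y = table["weight_mean"].to_numpy(dtype=float)
    cov = _design_columns(table, covariates)
    g = _group_dummies(table["group"])
    if g.shape[1] == 0:
        raise ValueError("need at least two groups")
    ones = np.ones((len(table), 1))
    x_reduced = np.hstack([ones, cov])
    x_full = np.hstack([ones, cov, g])
    if y.var() == 0:
        return 0.0, 1.0
    f, p, _, _ = _nested_f(y, x_full, x_reduced)
    return f, p


def posthoc_pairwise(
    weights: pd.Series,
    design: pd.DataFrame,
    pair: tuple[str, str],
    covariates=RM_COVARIATES,
) -> tuple[float, float]:
    """Covariate-adjusted group F restricted to one pair of groups.

    The same two-stage model as :func:`rm_anova_trait` on the two groups'
    subjects only; with a single between-group contrast the F equals the
    squared t of the adjusted group difference.  Raises when either group
    has too few subjects for the model's degrees of freedom.
    """
    keep = design["group"].isin(pair)
    if design.loc[keep, "group"].nunique() < 2:
        raise ValueError(f"both groups of {pair} must be present")
    sub_design = design.loc[keep]
    sub_weights = weights[weights.index.get_level_values(0).isin(sub_design.index)]
    return rm_anova_trait(sub_weights, sub_design, covariates=covariates)


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    flags, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, flags


def nested_model_f(
    weights: pd.Series | np.ndarray,
    baseline: pd.DataFrame,
    explanatory: pd.Series | np.ndarray,
    condition_limit: float = 1e10,
) -> tuple[float, float, float]:
    """Partial F of one explanatory variable over the five-nuisance baseline.

    Both models are ordinary least squares on the pooled session rows
    (M rows; both sessions of every subject enter, the sequence indicator
    being one of the baseline variables).  Returns
    ``(partial_f, p, delta_r2)`` where the partial F has (1, M - 7)
    degrees of freedom.  The overall augmented-model F with (6, M - 7) df
    is available via :func:`nested_model_report`.
    """
    rep = nested_model_report(weights, baseline, explanatory, condition_limit)
    return rep["partial_f"], rep["partial_p"], rep["delta_r2"]


def nested_model_report(
    weights,
    baseline: pd.DataFrame,
    explanatory,
    condition_limit: float = 1e10,
) -> dict:
    """Full report of the baseline-vs-augmented model comparison."""
    y = np.asarray(weights, dtype=float)
    missing = [v for v in BASELINE_VARS if v not in baseline.columns]
    if missing:
        raise ValueError(f"baseline table missing {missing}")
    xb = _design_columns(baseline, BASELINE_VARS)
    xe = np.asarray(explanatory, dtype=float).reshape(-1, 1)
    if not (len(y) == xb.shape[0] == xe.shape[0]):
        raise ValueError("weights, baseline and explanatory lengths differ")
    ones = np.ones((len(y), 1))
    x_base = np.hstack([ones, xb])
    x_aug = np.hstack([x_base, xe])
    if np.linalg.cond(x_aug) > condition_limit:
        raise ValueError("explanatory variable is collinear with the baseline model")
    partial_f, partial_p, _, df_den = _nested_f(y, x_aug, x_base)
    tss = float(((y - y.mean()) ** 2).sum())
    rss_base, _ = _ols_rss(y, x_base)
    rss_aug, rank_aug = _ols_rss(y, x_aug)
    overall_f, overall_p, df_o_num, df_o_den = _nested_f(y, x_aug, ones)
    return {
        "partial_f": partial_f,
        "partial_p": partial_p,
        "partial_df": (1, df_den),
        "overall_f": overall_f,
        "overall_p": overall_p,
        "overall_df": (df_o_num, df_o_den),
        "delta_r2": (rss_base - rss_aug) / tss if tss > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# trait screening across the whole decomposition
# ---------------------------------------------------------------------------


@dataclass
class TraitTestResult:
    """Per-trait screening outcome (group F/p/q plus follow-up tests)."""

    trait_id: int
    f_stat: float
    p_value: float
    q_value: float
    significant: bool
    posthoc: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    associations: dict[str, tuple[float, float]] = field(default_factory=dict)


def screen_traits(
    weights: pd.DataFrame,
    design: pd.DataFrame,
    q: float = 0.05,
    covariates=RM_COVARIATES,
    association_vars: pd.DataFrame | None = None,
    baseline: pd.DataFrame | None = None,
) -> list[TraitTestResult]:
    """rmANOVA every trait, BH-adjust across traits, follow up significants.

    ``weights`` is the M x n_traits table with (subject, session) row
    index.  For traits surviving FDR, pairwise post-hoc F tests are run for
    every group pair, and, when ``association_vars``/``baseline`` (M-row
    tables) are given, a nested-model partial F per association variable.
    """
    stats = [
        rm_anova_trait(weights.iloc[:, t], design, covariates=covariates)
        for t in range(weights.shape[1])
    ]
    p_values = np.array([p for _, p in stats])
    q_values, flags = fdr_adjust(p_values, q=q)
    results = []
    groups = [g for g in GROUPS if g in set(design["group"])]
    for t, ((f, p), qv, sig) in enumerate(zip(stats, q_values, flags)):
        res = TraitTestResult(t, f, p, float(qv), bool(sig))
        if sig:
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    pair = (groups[i], groups[j])
                    res.posthoc[pair] = posthoc_pairwise(
                        weights.iloc[:, t], design, pair, covariates=covariates
                    )
            if association_vars is not None and baseline is not None:
                for var in association_vars.columns:
                    pf, pp, _ = nested_model_f(
                        weights.iloc[:, t].to_numpy(),
                        baseline,
                        association_vars[var],
                    )
                    res.associations[var] = (pf, pp)
        results.append(res)
    return results
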