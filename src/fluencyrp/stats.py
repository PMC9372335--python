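"""Cohort filtering, Welch group comparisons, and nested logistic-model
ladders compared by likelihood-ratio tests.

The analysis sample takes one first chronological pair per participant
(sample independence: later visits of the same person are not independent
observations), keeps only participants consistently labeled healthy control
(HC) or probable Alzheimer's disease (ProbAD), and drops anyone who ever
carried both labels. Group differences on each pair metric use the Welch
unequal-variance t-test. Diagnostic value of the distance-from-diagonal
score is assessed by logistic regressions predicting diagnosis from
z-scored metrics plus all their interactions, with and without the DfD
terms, compared by the LR chi-squared test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io_model import Cohort, Vocabulary
from .metrics import RepDenominator, metrics_table, pair_metrics
from .recurrence import annotate_pair

logger = logging.getLogger("fluencyrp")

GROUP_HC = "HC"
GROUP_PROBAD = "ProbAD"
#: Outcome coding for the logistic models: HC = 0, ProbAD = 1.
OUTCOME_CODING = {GROUP_HC: 0, GROUP_PROBAD: 1}


# ---------------------------------------------------------------- cohort

@dataclass
class AnalysisSample:
    """One row per retained participant: group + first-pair metrics."""

    rows: pd.DataFrame
    filter_counts: dict[str, int] = field(default_factory=dict)

    def group_values(self, metric: str, group: str) -> np.ndarray:
        return self.rows.loc[self.rows["group"] == group, metric].to_numpy(float)

    def n_by_group(self) -> dict[str, int]:
        return self.rows["group"].value_counts().to_dict()


def apply_cohort_filters(
    cohort: Cohort,
    vocab: Vocabulary | None = None,
    rep_denominator: RepDenominator = "total",
) -> AnalysisSample:
    """Filter a cohort to the independent analysis sample.

    Drops, in order: participants with fewer than two lists; participants
    ever labeled both HC and ProbAD (group transitioners); participants
    never labeled HC or ProbAD. Each survivor contributes the metrics of
    their FIRST chronological pair only, with the group taken from that
    pair's labels.
    """
    counts = {"input": len(cohort.lists), "lt2_lists": 0, "dual_group": 0,
              "other_group": 0, "retained": 0}
    records = []
    for pid in cohort.participants():
        pls = cohort.lists[pid]
        if len(pls) < 2:
            counts["lt2_lists"] += 1
            continue
        labels = {fl.group for fl in pls}
        if GROUP_HC in labels and GROUP_PROBAD in labels:
            counts["dual_group"] += 1
            continue
        if not labels & {GROUP_HC, GROUP_PROBAD}:
            counts["other_group"] += 1
            continue
        a, b = pls[0], pls[1]  # first chronological pair (lists are visit-sorted)
        group = a.group if a.group in OUTCOME_CODING else b.group
        pm = pair_metrics(
            annotate_pair(a, b, vocab=vocab), rep_denominator=rep_denominator
        ).as_dict()
        pm["group"] = group
        records.append(pm)
        counts["retained"] += 1
    if not records:
        raise ValueError(f"cohort filtering left no participants (counts: {counts})")
    rows = pd.DataFrame(records)
    assert rows["participant_id"].is_unique
    return AnalysisSample(rows=rows, filter_counts=counts)


# ---------------------------------------------------------------- t-tests

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    degenerate: bool = False


def welch_ttest(x, y) -> WelchResult:
    """Two-sample unequal-variance t-test with Welch–Satterthwaite df.

    Two-sided p. Both samples need n >= 2. Zero spread in both samples
    yields a degenerate result: t = 0 if the means agree (error — nothing
    to test), else infinite |t| flagged ``degenerate``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"welch_ttest needs n >= 2 per sample (got {nx}, {ny})")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    mx, my = x.mean(), y.mean()
    if vx == 0 and vy == 0:
        if mx == my:
            raise ValueError("both samples constant and equal: nothing to test")
        return WelchResult(np.inf if mx > my else -np.inf, float(nx + ny - 2), 0.0,
                           mx, my, 0.0, 0.0, degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / nx, vy / ny
    df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    return WelchResult(float(t), float(df), float(p), mx, my,
                       float(np.sqrt(vx)), float(np.sqrt(vy)))


def zscore(values, name: str = "predictor") -> np.ndarray:
    """Standardize with the sample SD (n−1 denominator); errors on a
    constant vector, naming the offending predictor."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError(f"zscore needs n >= 2 for {name!r}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"constant predictor {name!r}: cannot z-score")
    return (v - v.mean()) / sd


# ---------------------------------------------------------------- models

@dataclass
class ModelFit:
    """A fitted logistic model: design column names (z-scored mains plus all
    interaction products), coefficients, log-likelihood, and an honest
    convergence flag."""

    predictors: tuple[str, ...]         # main-effect metric names
    column_names: tuple[str, ...]       # full design, including "intercept"
    params: np.ndarray
    log_likelihood: float
    n_params: int                       # including intercept
    converged: bool
    n_obs: int

    @property
    def df(self) -> int:
        """Parameters excluding the intercept (the convention model tables
        in this literature report)."""
        return self.n_params - 1


def interaction_design(z: pd.DataFrame) -> pd.DataFrame:
    """Intercept + z-scored mains + all products of the mains (2-way up to
    n-way). Interaction columns are not re-standardized."""
    cols = {"intercept": np.ones(len(z))}
    names = list(z.columns)
    for name in names:
        cols[name] = z[name].to_numpy()
    for order in range(2, len(names) + 1):
        for combo in itertools.combinations(names, order):
            # canonical (sorted) column name so nesting checks are
            # insensitive to predictor order
            cols[":".join(sorted(combo))] = np.prod(
                [z[c].to_numpy() for c in combo], axis=0)
    return pd.DataFrame(cols, index=z.index)


def fit_logistic_ladder(sample: AnalysisSample, predictors: list[str]) -> ModelFit:
    """Fit diagnosis ~ z-scored mains + all interactions by maximum
    likelihood.

    Separation or failure to converge is reported via ``converged=False``
    rather than an exception — some predictor combinations legitimately do
    not converge and the ladder must be able to say so.
    """
    rows = sample.rows
    y = rows["group"].map(OUTCOME_CODING)
    if y.isna().any():
        raise ValueError("sample contains groups outside {HC, ProbAD}")
    z = pd.DataFrame(
        {p: zscore(rows[p].to_numpy(float), name=p) for p in predictors},
        index=rows.index,
    )
    X = interaction_design(z)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.to_numpy(float), X.to_numpy()).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params, llf = res.params, float(res.llf)
        except Exception as exc:  # perfect separation, singular Hessian, ...
            logger.warning("logistic fit failed for %s: %s", predictors, exc)
            converged = False
            params, llf = np.full(X.shape[1], np.nan), float("nan")
    if converged and np.abs(params).max() > 50:
        converged = False  # quasi-separation: likelihood flat, estimates diverging
    return ModelFit(
        predictors=tuple(predictors),
        column_names=tuple(X.columns),
        params=np.asarray(params, float),
        log_likelihood=llf,
        n_params=X.shape[1],
        converged=converged,
        n_obs=len(rows),
    )


@dataclass
class ModelComparison:
    lr_statistic: float
    df_diff: int
    p_value: float
    reduced: tuple[str, ...] = ()
    full: tuple[str, ...] = ()


def lr_from_loglikelihoods(ll_reduced: float, ll_full: float, df_diff: int) -> ModelComparison:
    """LR chi-squared test from two log-likelihoods of nested fits."""
    lr = 2.0 * (ll_full - ll_reduced)
    if df_diff == 0:
        # degenerate nesting (identical designs): chi-squared point mass at 0
        p = 1.0 if lr <= 1e-12 else 0.0
    else:
        p = float(sps.chi2.sf(lr, df_diff))
    return ModelComparison(lr_statistic=lr, df_diff=df_diff, p_value=p)


def lr_compare(reduced: ModelFit, full: ModelFit) -> ModelComparison:
    """Likelihood-ratio test between nested converged logistic fits.

    Nesting is checked on design column names (order-insensitive); either
    fit not having converged is an error — an LR statistic from a
    non-converged likelihood is meaningless.
    """
    if not (reduced.converged and full.converged):
        raise ValueError("lr_compare requires both fits to have converged")
    if not set(reduced.column_names) <= set(full.column_names):
        raise ValueError(
            "models are not nested: reduced design has columns "
            f"{sorted(set(reduced.column_names) - set(full.column_names))} "
            "absent from the full design"
        )
    cmp = lr_from_loglikelihoods(
        reduced.log_likelihood, full.log_likelihood,
        full.n_params - reduced.n_params,
    )
    cmp.reduced = reduced.predictors
    cmp.full = full.predictors
    return cmp


# ------------------------------------------------------------- the ladder

#: The model ladder: each entry is (reduced predictors, full = reduced + DfD).
#: Metric names refer to AnalysisSample columns.
LADDER = [
    (["average_length", "repetition_proportion_avg"],),
    (["average_length", "intrusion_count_pair"],),
    (["average_length", "length_difference", "repetition_proportion_avg"],),
    (["length_difference", "repetition_proportion_avg"],),
    (["length_difference", "intrusion_count_pair"],),
]


def run_model_ladder(sample: AnalysisSample, include_sex: bool = False) -> dict:
    """Fit every reduced/full (± DfD) model pair and LR-compare them.

    Returns a JSON-ready dict: per-model log-likelihood, df (excluding
    intercept), parameter count and convergence; per-comparison LR
    statistic, df and p. Sex joins every model behind ``include_sex`` if the
    sample carries a ``sex`` column; MMSE never enters (the ladder compares
    fluency quantifications only).
    """
    out = {"outcome_coding": OUTCOME_CODING, "models": [], "comparisons": []}
    idx = 0
    for (reduced_preds,) in LADDER:
        preds_r = list(reduced_preds)
        preds_f = preds_r + ["dfd"]
        if include_sex and "sex" in sample.rows.columns:
            preds_r, preds_f = preds_r + ["sex"], preds_f + ["sex"]
        fit_r = fit_logistic_ladder(sample, preds_r)
        fit_f = fit_logistic_ladder(sample, preds_f)
        for tag, fit in (("reduced", fit_r), ("full", fit_f)):
            idx += 1
            out["models"].append(
                {"model": idx, "role": tag, "predictors": list(fit.predictors),
                 "log_likelihood": None if np.isnan(fit.log_likelihood) else round(fit.log_likelihood, 3),
                 "df": fit.df, "n_params": fit.n_params, "converged": fit.converged}
            )
        if fit_r.converged and fit_f.converged:
            cmp = lr_compare(fit_r, fit_f)
            out["comparisons"].append(
                {"reduced_model": idx - 1, "full_model": idx,
                 "lr": round(cmp.lr_statistic, 3), "df": cmp.df_diff,
                 "p": float(f"{cmp.p_value:.4g}")}
            )
        else:
            out["comparisons"].append(
                {"reduced_model": idx - 1, "full_model": idx,
                 "lr": None, "df": None, "p": None, "note": "non-converged fit"}
            )
    return out


def group_descriptives(
    sample: AnalysisSample,
    metrics: tuple[str, ...] = ("dfd", "average_length", "repetition_proportion_avg",
                                "intrusion_count_pair"),
) -> pd.DataFrame:
    """Tidy per-metric table: group means/SDs and the Welch comparison."""
    rows = []
    for metric in metrics:
        hc = sample.group_values(metric, GROUP_HC)
        ad = sample.group_values(metric, GROUP_PROBAD)
        res = welch_ttest(hc, ad)
        rows.append(
            {"metric": metric, "mean_hc": res.mean_x, "sd_hc": res.sd_x,
             "mean_probad": res.mean_y, "sd_probad": res.sd_y,
             "t": res.t, "df": res.df, "p": res.p,
             "n_hc": len(hc), "n_probad": len(ad)}
        )
    return pd.DataFrame(rows)
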