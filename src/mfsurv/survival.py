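"""Prognostic modelling: Cox regression, AIC selection, concordance, IPCW Brier.

The module wraps established survival machinery (lifelines for Cox partial
likelihood with Efron tie handling, Kaplan-Meier and log-rank;
scikit-survival for censoring-aware concordance and inverse-probability-of-
censoring-weighted Brier scores) behind a small, uniform surface, and adds
the pieces a prognostic-imaging workflow needs on top: greedy backward
elimination on AIC, an event-stratified train/test split, z-scoring of
texture features by training statistics, and a model-comparison report
(clinical vs texture vs combined).

Clinical covariate encoding is fixed: ``sex_male`` (reference female),
``mgmt_methylated`` (reference unmethylated), ``resection_nontotal``
(reference gross-total resection), ``age`` in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sksurv.metrics import brier_score as _sksurv_brier
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "SurvivalData",
    "CoxFit",
    "ConcordanceResult",
    "KMEstimate",
    "ConvergenceFailure",
    "encode_clinical",
    "fit_cox",
    "univariate_screen",
    "backward_eliminate_aic",
    "harrell_c",
    "km_estimate",
    "log_rank",
    "brier_ipcw",
    "integrated_brier",
    "ibs_time_grid",
    "stratified_split",
    "zscore_by_train",
    "compare_models",
    "run_prognostic_workflow",
    "CLINICAL_ENCODED",
]

CLINICAL_ENCODED = ["age", "sex_male", "mgmt_methylated", "resection_nontotal"]

# Ridge guard: when the covariate count approaches the event count the Newton
# steps of an unpenalized fit become unstable; a fixed small L2 penalty keeps
# them bounded and is reported in the fit metadata.
_EVENTS_PER_COVARIATE = 5
_GUARD_PENALIZER = 0.1


class ConvergenceFailure(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. monotone likelihood)."""


class SurvivalData(NamedTuple):
    """Covariates plus right-censored outcomes for one cohort arm."""

    X: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "os_days", event_col: str = "event"):
        X = df.drop(columns=[time_col, event_col])
        return cls(X, df[time_col].to_numpy(float), df[event_col].to_numpy(int))

    def surv(self):
        return Surv.from_arrays(event=self.event.astype(bool), time=self.time)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model with Wald and LRT summaries."""

    covariates: list[str]
    summary: pd.DataFrame  # coef, se, hr, hr_lower, hr_upper, p per covariate
    log_likelihood: float
    aic: float
    lrt_statistic: float
    lrt_p: float
    n: int
    n_events: int
    penalizer: float
    model: CoxPHFitter = field(repr=False)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor (log partial hazard); higher = worse prognosis."""
        return self.model.predict_log_partial_hazard(X[self.covariates]).to_numpy(float)

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """Predicted survival probabilities, shape (n_subjects, n_times)."""
        sf = self.model.predict_survival_function(X[self.covariates], times=np.asarray(times))
        return sf.to_numpy().T


def encode_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the categorical clinical table."""
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["sex_male"] = (df["sex"] == "male").astype(float)
    out["mgmt_methylated"] = (df["mgmt"] == "methylated").astype(float)
    out["resection_nontotal"] = (df["resection"] == "non-total").astype(float)
    return out


def _auto_penalizer(n_covariates: int, n_events: int) -> float:
    return _GUARD_PENALIZER if n_covariates >= n_events / _EVENTS_PER_COVARIATE else 0.0


def fit_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    penalizer: float | None = None,
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron correction for ties).

    Returns Wald 95% CIs per covariate and a likelihood-ratio test against
    the null model.  ``penalizer=None`` enables the ridge guard automatically
    when covariates are numerous relative to events.
    """
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("need at least one event to fit a Cox model")
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise ValueError(f"constant covariates cannot be fit: {constant}")
    if penalizer is None:
        penalizer = _auto_penalizer(X.shape[1], n_events)

    df = X.copy()
    df["_time"], df["_event"] = time, event
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise ConvergenceFailure(f"Cox fit failed to converge: {exc}") from exc
    if not np.isfinite(cph.params_.to_numpy()).all():
        raise ConvergenceFailure("Cox fit produced non-finite coefficients")

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    ll = float(cph.log_likelihood_)
    k = X.shape[1]
    lrt = cph.log_likelihood_ratio_test()
    return CoxFit(
        covariates=list(X.columns),
        summary=summary,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        lrt_statistic=float(lrt.test_statistic),
        lrt_p=float(lrt.p_value),
        n=len(time),
        n_events=n_events,
        penalizer=float(penalizer),
        model=cph,
    )


def univariate_screen(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> pd.DataFrame:
    """One single-covariate Cox fit per column: HR, 95% CI, p."""
    rows = {}
    for col in X.columns:
        fit = fit_cox(X[[col]], time, event, penalizer=0.0)
        rows[col] = fit.summary.loc[col]
    return pd.DataFrame(rows).T[["coef", "se", "hr", "hr_lower", "hr_upper", "p"]]


def backward_eliminate_aic(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    penalizer: float | None = None,
) -> tuple[list[str], CoxFit | None]:
    """Greedy backward elimination on AIC.

    Repeatedly drops the single covariate whose removal lowers AIC the most;
    stops when no removal lowers it.  Ties are broken by dropping the
    covariate latest in the declared column order.  May reduce to the empty
    (null) model, in which case the returned fit is ``None``.
    """
    order = {c: i for i, c in enumerate(X.columns)}
    current = list(X.columns)
    best = fit_cox(X[current], time, event, penalizer=penalizer)
    # null-model log-likelihood, recovered from the LRT statistic
    ll_null = best.log_likelihood - best.lrt_statistic / 2.0

    while current:
        candidates: list[tuple[float, int, str, CoxFit | None]] = []
        for col in current:
            remaining = [c for c in current if c != col]
            if remaining:
                try:
                    fit = fit_cox(X[remaining], time, event, penalizer=penalizer)
                except ConvergenceFailure:
                    continue
                aic = fit.aic
            else:
                fit, aic = None, -2.0 * ll_null
            candidates.append((aic, -order[col], col, fit))
        if not candidates:
            break
        # min AIC; among ties the most negative -order wins = latest declared
        aic, _, col, fit = min(candidates, key=lambda c: (c[0], c[1]))
        if aic < best.aic - 1e-9:
            current = [c for c in current if c != col]
            if fit is None:
                return [], None
            best = fit
        else:
            break
    return current, best


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with the number of comparable (usable) pairs."""

    c_index: float
    n_pairs: int


def harrell_c(risk_scores, time, event) -> ConcordanceResult:
    """Harrell's concordance over censoring-comparable pairs.

    ``risk_scores``: one value per subject, higher = predicted worse.  Ties
    in score are credited 0.5.
    """
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    risk = np.asarray(risk_scores, dtype=float)
    try:
        c, concordant, discordant, tied_risk, _ = concordance_index_censored(event, time, risk)
    except Exception as exc:  # sksurv raises on zero comparable pairs
        raise ValueError(f"concordance undefined: {exc}") from exc
    return ConcordanceResult(float(c), int(concordant + discordant + tied_risk))


@dataclass
class KMEstimate:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    fitter: KaplanMeierFitter = field(repr=False)

    def at(self, t) -> np.ndarray:
        return self.fitter.survival_function_at_times(np.asarray(t)).to_numpy(float)


def km_estimate(time, event) -> KMEstimate:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("cannot estimate a survival curve from an empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return KMEstimate(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float), kmf)


def log_rank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi2 statistic, p)."""
    if len(np.asarray(time_a)) == 0 or len(np.asarray(time_b)) == 0:
        raise ValueError("log-rank requires a non-empty group on each side")
    res = logrank_test(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def _predicted_survival_matrix(fit, train: SurvivalData, test: SurvivalData, times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if fit is None:  # covariate-free reference: training-set Kaplan-Meier
        km = km_estimate(train.time, train.event)
        return np.tile(km.at(times), (len(test.time), 1))
    if isinstance(fit, np.ndarray):
        est = np.asarray(fit, dtype=float)
        return est.reshape(len(test.time), len(times))
    return fit.predict_survival(test.X, times)


def brier_ipcw(fit, train: SurvivalData, test: SurvivalData, times) -> np.ndarray:
    """IPCW Brier score of predicted survival probabilities at given times.

    Censoring weights come from the Kaplan-Meier estimate of the censoring
    distribution on the *training* arm.  ``fit`` may be a :class:`CoxFit`,
    ``None`` (the training-KM reference model) or a precomputed
    (n_test, n_times) matrix of survival probabilities.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    estimate = _predicted_survival_matrix(fit, train, test, times)
    t_last, train_max = float(times.max()), float(train.time.max())
    if t_last >= train_max:
        raise ValueError(
            f"evaluation time {t_last} is beyond the censoring-weight support "
            f"(training follow-up ends at {train_max})"
        )
    # Test subjects still at risk past the last evaluation time enter the
    # score only through the at-risk indicator, so their times can be
    # truncated into the training follow-up range without changing it.
    clip = 0.5 * (t_last + train_max)
    clipped_time = np.minimum(test.time, clip)
    clipped = Surv.from_arrays(
        event=np.where(test.time > clip, False, test.event.astype(bool)),
        time=clipped_time,
    )
    try:
        _, scores = _sksurv_brier(train.surv(), clipped, estimate, times)
    except ValueError as exc:
        raise ValueError(f"Brier score undefined at requested times: {exc}") from exc
    return scores


def integrated_brier(fit, train: SurvivalData, test: SurvivalData, times) -> float:
    """Trapezoidal time-average of the IPCW Brier score over the grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("integrated Brier score needs a grid of at least 2 times")
    scores = brier_ipcw(fit, train, test, times)
    return float(np.trapezoid(scores, times) / (times[-1] - times[0]))


def ibs_time_grid(train: SurvivalData, test: SurvivalData) -> np.ndarray:
    """Unique test-set event times up to the shorter arm's maximum follow-up."""
    t_max = min(float(train.time.max()), float(test.time.max()))
    grid = np.unique(test.time[test.event == 1])
    grid = grid[grid < t_max]
    if len(grid) < 2:
        raise ValueError("too few test-set event times for an evaluation grid")
    return grid


def stratified_split(
    df: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    event_col: str = "event",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split stratified on the event indicator.

    The test arm receives ``floor(n * (1 - ratio))`` subjects, allocated
    across the event strata by largest remainder so the survival-status mix
    of both arms matches the cohort's.  Reproducible under ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    n = len(df)
    n_test = int(np.floor(n * (1.0 - ratio)))
    if n_test < 1 or n - n_test < 1:
        raise ValueError(f"cannot split {n} subjects at ratio {ratio}")
    rng = np.random.default_rng(seed)

    strata = []
    for value, group in df.groupby(event_col, sort=True):
        if len(group) < 2:
            raise ValueError(f"stratum {event_col}={value!r} too small to stratify")
        quota = len(group) * (1.0 - ratio)
        strata.append([value, group, int(np.floor(quota)), quota - np.floor(quota)])
    leftover = n_test - sum(s[2] for s in strata)
    for s in sorted(strata, key=lambda s: (-s[3], -len(s[1]))):
        if leftover <= 0:
            break
        if s[2] < len(s[1]) - 1:
            s[2] += 1
            leftover -= 1

    test_idx = []
    for _, group, k, _ in strata:
        order = rng.permutation(len(group))
        test_idx.extend(group.index[order[:k]])
    test_mask = df.index.isin(test_idx)
    return df.loc[~test_mask].copy(), df.loc[test_mask].copy()


def zscore_by_train(
    train: pd.DataFrame, test: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize the named columns by training-set mean and SD.

    Columns constant on the training arm are centered but not scaled.
    """
    train, test = train.copy(), test.copy()
    mu = train[columns].mean()
    sd = train[columns].std(ddof=0).replace(0.0, 1.0)
    train[columns] = (train[columns] - mu) / sd
    test[columns] = (test[columns] - mu) / sd
    return train, test


def compare_models(
    train: SurvivalData,
    test: SurvivalData,
    feature_sets: dict[str, list[str]],
    penalizer: float | None = None,
) -> dict:
    """Fit each named covariate set on the training arm and validate on test.

    Per model: training-set Harrell's C and likelihood-ratio p, plus the
    test-set IPCW prediction-error curve and integrated Brier score.  The
    covariate-free training Kaplan-Meier is always reported as ``reference``.
    """
    grid = ibs_time_grid(train, test)
    report: dict = {
        "n_train": len(train.time),
        "n_test": len(test.time),
        "ibs_grid": {"start": float(grid[0]), "stop": float(grid[-1]), "n_times": len(grid)},
        "models": {},
        "reference": {
            "ibs": integrated_brier(None, train, test, grid),
            "brier_times": grid.tolist(),
            "brier_scores": brier_ipcw(None, train, test, grid).tolist(),
        },
    }
    for name, cols in feature_sets.items():
        fit = fit_cox(train.X[cols], train.time, train.event, penalizer=penalizer)
        conc = harrell_c(fit.predict_risk(train.X), train.time, train.event)
        report["models"][name] = {
            "covariates": list(cols),
            "c_index": conc.c_index,
            "n_pairs": conc.n_pairs,
            "lrt_p": fit.lrt_p,
            "aic": fit.aic,
            "penalizer": fit.penalizer,
            "hazard_ratios": fit.summary["hr"].to_dict(),
            "p_values": fit.summary["p"].to_dict(),
            "ibs": integrated_brier(fit, train, test, grid),
            "brier_times": grid.tolist(),
            "brier_scores": brier_ipcw(fit, train, test, grid).tolist(),
        }
    return report


def run_prognostic_workflow(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    alpha: float = 0.05,
    mf_prescreen: int | None = None,
) -> dict:
    """Full prognostic pipeline on a feature table plus clinical table.

    Split (event-stratified) -> univariate clinical screen -> AIC backward
    elimination over the z-scored texture features -> clinical / texture /
    combined Cox models with concordance and test-set IPCW validation ->
    sex-stratified Kaplan-Meier log-rank by MGMT methylation.

    The clinical model keeps the univariately significant covariates plus
    MGMT methylation status regardless of its p-value (an established
    prognostic marker).  ``mf_prescreen`` optionally restricts backward
    elimination to the k univariately strongest texture features.
    """
    clin = clinical.set_index("subject_id")
    missing = features.index.difference(clin.index)
    if len(missing):
        raise ValueError(f"subjects missing from clinical table: {list(missing)[:5]}")
    clin = clin.loc[features.index]
    encoded = encode_clinical(clin)
    mf_cols = list(features.columns)

    df = pd.concat(
        [encoded, features, clin[["os_days", "event"]].astype(float)], axis=1
    )
    train_df, test_df = stratified_split(df, ratio=ratio, seed=seed)
    train_df, test_df = zscore_by_train(train_df, test_df, mf_cols)
    train = SurvivalData.from_frame(train_df)
    test = SurvivalData.from_frame(test_df)

    screen = univariate_screen(train.X[CLINICAL_ENCODED], train.time, train.event)
    clinical_model = [c for c in CLINICAL_ENCODED if screen.loc[c, "p"] < alpha]
    if "mgmt_methylated" not in clinical_model:
        clinical_model.append("mgmt_methylated")

    candidates = mf_cols
    if mf_prescreen is not None and mf_prescreen < len(mf_cols):
        usable = [c for c in mf_cols if np.ptp(train.X[c].to_numpy()) > 0]
        mf_screen = univariate_screen(train.X[usable], train.time, train.event)
        candidates = list(mf_screen.sort_values("p").index[:mf_prescreen])
    else:
        candidates = [c for c in candidates if np.ptp(train.X[c].to_numpy()) > 0]
    selected, _ = backward_eliminate_aic(train.X[candidates], train.time, train.event)

    feature_sets = {"clinical": clinical_model}
    if selected:
        feature_sets["mf"] = selected
        feature_sets["combined"] = clinical_model + [c for c in selected if c not in clinical_model]
    report = compare_models(train, test, feature_sets)
    report["split"] = {"ratio": ratio, "seed": seed}
    report["univariate_clinical"] = screen.to_dict(orient="index")
    report["selected_mf_features"] = selected

    km_by_sex: dict = {}
    for sex in ("male", "female"):
        sub = clin[clin["sex"] == sex]
        meth = sub[sub["mgmt"] == "methylated"]
        unmeth = sub[sub["mgmt"] == "unmethylated"]
        if len(meth) and len(unmeth):
            stat, p = log_rank(
                meth["os_days"], meth["event"], unmeth["os_days"], unmeth["event"]
            )
            km_by_sex[sex] = {"logrank_statistic": stat, "logrank_p": p,
                              "n_methylated": len(meth), "n_unmethylated": len(unmeth)}
    report["km_sex_mgmt"] = km_by_sex
    return report
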