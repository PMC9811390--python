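"""Survival risk stratification from band features (Experiments 2-3 style).

The radiomic risk score (RRS) is the weighted sum of the band features
selected by an L1-penalized (LASSO) Cox model, with the penalty chosen by
k-fold cross-validation on the held-out partial-likelihood deviance. The
continuous score is thresholded at the cutpoint maximizing the two-group
log-rank chi-square on the training cohort (an X-tile-style grid search
over candidate thresholds with a minimum-group-size guard), and the
resulting low/high-risk groups are compared by Kaplan-Meier / log-rank.
Univariate and multivariate Cox models report per-stratum hazard ratios
(baseline stratum fixed at 1) and Harrell's C-index; McNemar and Pearson
chi-square tests quantify agreement between the RRS stratification and the
clinical ones (Chang risk class, molecular subgroup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._rng import stream

__all__ = [
    "RiskModel",
    "SurvivalFit",
    "split_cohort",
    "fit_lasso_cox",
    "compute_rrs",
    "find_cutpoint",
    "logrank_chi2",
    "km_logrank",
    "cox_fit",
    "concordance",
    "mcnemar_test",
    "chi2_independence",
    "cox_partial_loglik",
]


# ---------------------------------------------------------------------------
# cohort splitting


def split_cohort(
    clinical: pd.DataFrame,
    train_fraction: float = 0.7,
    stratify_by: str = "subgroup",
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified train/test split preserving subgroup proportions.

    Within each stratum round(fraction * n) subjects go to training (at
    least one, so no stratum is absent from training); a stratum of size 1
    is assigned wholly to training with a warning. Deterministic for a
    fixed seed. Returns (train subject_ids, test subject_ids).
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = stream(seed, "cohort-split")
    train: list = []
    test: list = []
    for stratum, grp in clinical.groupby(stratify_by, sort=True, dropna=False):
        ids = grp["subject_id"].to_numpy()
        if len(ids) == 1:
            warnings.warn(
                f"stratum {stratum!r} has a single subject; assigned to training",
                stacklevel=2,
            )
            train.extend(ids.tolist())
            continue
        perm = rng.permutation(len(ids))
        n_train = min(len(ids), max(1, int(round(train_fraction * len(ids)))))
        train.extend(ids[perm[:n_train]].tolist())
        test.extend(ids[perm[n_train:]].tolist())
    if not test:
        warnings.warn("empty test set (train_fraction too close to 1)", stacklevel=2)
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow) -- used for CV deviance


def cox_partial_loglik(linear_predictor, time, event) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    lp = np.asarray(linear_predictor, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(-t)  # decreasing time: risk sets are cumulative prefixes
    lp, t, e = lp[order], t[order], e[order]
    # log cumulative sum of exp(lp) over the risk set, numerically stable
    m = lp.max()
    log_risk = np.log(np.cumsum(np.exp(lp - m))) + m
    # ties (Breslow): every event at time t_i uses the full risk set {t >= t_i}
    # -> for tied times use the last index of the tie block
    _, inv, counts = np.unique(-t, return_inverse=True, return_counts=True)
    last_idx = np.cumsum(counts) - 1
    log_risk_tied = log_risk[last_idx[inv]]
    return float(np.sum(e * (lp - log_risk_tied)))


# ---------------------------------------------------------------------------
# LASSO-Cox


@dataclass
class RiskModel:
    """LASSO-selected band features, their Cox weights and the RRS cutpoint."""

    selected_features: list[str]
    coefficients: dict[str, float]
    cutpoint: float | None = None
    training_ids: list = field(default_factory=list)
    alpha: float | None = None

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.selected_features):
            raise ValueError("coefficients must cover exactly the selected features")


def _cv_folds(n: int, k: int, event: np.ndarray, rng: np.random.Generator, max_tries: int = 100):
    """Random k-fold assignment re-drawn until every fold contains an event."""
    for _ in range(max_tries):
        assign = rng.permutation(n) % k
        if all(event[assign == f].sum() > 0 for f in range(k)):
            return assign
    raise RuntimeError(f"could not draw {k} folds each containing an event")


def fit_lasso_cox(
    features: pd.DataFrame,
    time,
    event,
    folds: int = 3,
    seed: int = 0,
    rule: str = "min",
    n_alphas: int = 50,
    alpha: float | None = None,
) -> RiskModel:
    """L1-penalized Cox fit with the penalty chosen by cross-validation.

    The coxnet regularization path is fitted on the full training data; the
    penalty is chosen by k-fold CV on the held-out partial-likelihood
    deviance, either at its minimum (``rule='min'``) or at the largest
    penalty within one standard error of it (``rule='1se'``). Passing
    ``alpha`` skips CV and fits at that penalty (``alpha=np.inf`` returns
    the empty model). Nonzero coefficients define the selected features.
    """
    X = features.astype(float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    if alpha is not None and np.isinf(alpha):
        return RiskModel(selected_features=[], coefficients={}, alpha=float(alpha))

    path_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, fit_baseline_model=False)
    path_model.fit(X.to_numpy(), y)
    alphas = np.asarray(path_model.alphas_)

    if alpha is None:
        rng = stream(seed, "lasso-cv")
        assign = _cv_folds(len(t), folds, e, rng)
        dev = np.full((folds, len(alphas)), np.nan)
        for f in range(folds):
            tr = assign != f
            te = assign == f
            try:
                m = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alphas=alphas, fit_baseline_model=False
                )
                m.fit(X.to_numpy()[tr], y[tr])
            except Exception:  # degenerate fold; leave deviance nan
                continue
            coefs = m.coef_  # (p, n_alphas_fit)
            fit_alphas = np.asarray(m.alphas_)
            for j, a in enumerate(alphas):
                jj = int(np.argmin(np.abs(fit_alphas - a)))
                lp = X.to_numpy()[te] @ coefs[:, jj]
                dev[f, j] = -2.0 * cox_partial_loglik(lp, t[te], e[te])
        mean_dev = np.nanmean(dev, axis=0)
        if np.all(np.isnan(mean_dev)):
            raise RuntimeError("cross-validation failed on every fold")
        j_min = int(np.nanargmin(mean_dev))
        if rule == "min":
            chosen = alphas[j_min]
        elif rule == "1se":
            se = np.nanstd(dev[:, j_min], ddof=1) / np.sqrt(folds)
            ok = np.where(mean_dev <= mean_dev[j_min] + se)[0]
            chosen = alphas[ok.min()]  # alphas are decreasing: first = largest penalty
        else:
            raise ValueError("rule must be 'min' or '1se'")
    else:
        chosen = float(alpha)

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[chosen], fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final.fit(X.to_numpy(), y)
    coef = np.asarray(final.coef_).ravel()
    nz = np.flatnonzero(coef != 0)
    selected = [X.columns[i] for i in nz]
    model = RiskModel(
        selected_features=selected,
        coefficients={X.columns[i]: float(coef[i]) for i in nz},
        alpha=float(chosen),
    )
    if not selected:
        warnings.warn("LASSO selected no features (all coefficients zero)", stacklevel=2)
    return model


def compute_rrs(features: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Radiomic risk score: the sparse linear score sum_j coef_j * x_j."""
    missing = [f for f in model.selected_features if f not in features.columns]
    if missing:
        raise ValueError(f"feature column(s) {missing} missing from the table")
    score = pd.Series(0.0, index=features.index)
    for name in model.selected_features:
        score = score + model.coefficients[name] * features[name].astype(float)
    return score


# ---------------------------------------------------------------------------
# log-rank and cutpoint search


def logrank_chi2(group: np.ndarray, time, event) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square, p).

    ``group`` is a boolean array marking membership of group A. Standard
    observed-minus-expected form with the hypergeometric variance.
    """
    g = np.asarray(group, dtype=bool)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if g.all() or not g.any():
        raise ValueError("log-rank needs two nonempty groups")
    if e[g].sum() == 0 or e[~g].sum() == 0:
        warnings.warn("a group has zero events; log-rank statistic still defined", stacklevel=2)
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n_a = (at_risk & g).sum()
        d = ((t == et) & (e == 1)).sum()
        d_a = ((t == et) & (e == 1) & g).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def find_cutpoint(
    scores, time, event, min_group_frac: float = 0.1
) -> float:
    """X-tile-style optimal threshold: maximize the training log-rank chi-square.

    Every midpoint between consecutive sorted unique scores whose induced
    groups both hold at least ``min_group_frac`` of subjects is evaluated;
    ties go to the lower cutpoint. No optimism correction is applied (an
    optional permutation p-value is available downstream).
    """
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct scores")
    n = s.size
    best_cut = None
    best_chi2 = -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = s > cut
        if high.sum() < min_group_frac * n or (~high).sum() < min_group_frac * n:
            continue
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="a group has zero events")
            chi2, _ = logrank_chi2(high, time, event)
        if chi2 > best_chi2 + 1e-12:  # strict improvement: ties keep the lower cut
            best_chi2 = chi2
            best_cut = cut
    if best_cut is None:
        raise ValueError("no admissible cutpoint under the minimum-group-size guard")
    return float(best_cut)


@dataclass
class KMResult:
    chi2: float
    p: float
    curves: dict  # group label -> (times, survival probabilities)


def km_logrank(group_labels, time, event) -> KMResult:
    """Kaplan-Meier curves per group plus the two-sample log-rank test."""
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq.size}")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    curves = {}
    for g in uniq:
        kmf = KaplanMeierFitter()
        kmf.fit(t[labels == g], e[labels == g])
        sf = kmf.survival_function_
        curves[g] = (sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
    chi2, p = logrank_chi2(labels == uniq[0], t, e)
    return KMResult(chi2=chi2, p=p, curves=curves)


# ---------------------------------------------------------------------------
# Cox models with per-stratum hazard ratios


def concordance(time, event, risk_score) -> tuple[float, float]:
    """Harrell's C-index of a risk score, with an approximate SE.

    C is the fraction of usable (comparable) pairs the score orders
    correctly, ties counting 1/2. The SE is the binomial-style
    approximation sqrt(C (1 - C) / m) on the m comparable pairs.
    """
    from sksurv.metrics import concordance_index_censored

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    r = np.asarray(risk_score, dtype=float)
    c, concordant, discordant, tied_risk, _ = concordance_index_censored(e, t, r)
    m = concordant + discordant + tied_risk
    se = float(np.sqrt(c * (1 - c) / m)) if m > 0 else float("nan")
    return float(c), se


@dataclass
class SurvivalFit:
    """Cox fit summary: per-stratum HRs (baseline = 1), C-index, model p."""

    hr_per_stratum: dict[str, float]
    c_index: float
    c_index_se: float
    p: float
    coefficients: pd.Series
    n: int
    flags: list[str] = field(default_factory=list)


def cox_fit(
    data: pd.DataFrame,
    time_col: str = "os_days",
    event_col: str = "event",
    continuous: tuple[str, ...] = (),
    categorical: dict[str, str] | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties) with per-stratum HRs.

    ``categorical`` maps column name -> baseline stratum; each non-baseline
    stratum is dummy-coded against it and reported as exp(coef), with the
    baseline printed as 1. Rows with missing values in any used column are
    dropped (count warned). Monotone-likelihood / separation problems are
    flagged rather than raised.
    """
    categorical = categorical or {}
    cols = [time_col, event_col, *continuous, *categorical]
    df = data[cols].copy()
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} row(s) with missing values", stacklevel=2)
    if df[event_col].sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")

    design = df[[time_col, event_col, *continuous]].astype(float)
    stratum_cols: dict[str, tuple[str, str]] = {}  # design col -> (covariate, stratum)
    for cov, baseline in categorical.items():
        levels = [lv for lv in pd.unique(df[cov]) if lv != baseline]
        if baseline not in set(df[cov]):
            raise ValueError(f"baseline stratum {baseline!r} absent from column {cov!r}")
        for lv in levels:
            col = f"{cov}[{lv}]"
            design[col] = (df[cov] == lv).astype(float)
            stratum_cols[col] = (cov, str(lv))

    flags: list[str] = []
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=time_col, event_col=event_col)
    except Exception:
        flags.append("ridge-stabilized")  # separation / monotone likelihood
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=time_col, event_col=event_col)
    if np.abs(cph.params_).max() > 10:
        flags.append("possible-separation")

    hr: dict[str, float] = {}
    for cov, baseline in categorical.items():
        hr[f"{cov}={baseline}"] = 1.0
    for col, (cov, lv) in stratum_cols.items():
        hr[f"{cov}={lv}"] = float(np.exp(cph.params_[col]))
    for cov in continuous:
        hr[cov] = float(np.exp(cph.params_[cov]))

    lp = cph.predict_partial_hazard(design)
    c, se = concordance(df[time_col], df[event_col], np.log(lp))
    p = float(cph.log_likelihood_ratio_test().p_value)
    return SurvivalFit(
        hr_per_stratum=hr,
        c_index=c,
        c_index_se=se,
        p=p,
        coefficients=cph.params_.copy(),
        n=len(df),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# end-to-end RRS experiment


@dataclass
class RRSExperiment:
    model: RiskModel
    scaler: object
    train_ids: list
    test_ids: list
    scores: pd.Series  # all subjects
    risk_group: pd.Series  # 'low' / 'high'
    train_km: KMResult
    test_km: KMResult | None


def rrs_stratification_experiment(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    train_fraction: float = 0.7,
    folds: int = 3,
    seed: int = 0,
    prune_threshold: float = 0.95,
    min_group_frac: float = 0.1,
) -> RRSExperiment:
    """Full chain: split -> prune -> z-score -> LASSO-Cox -> RRS -> cutpoint -> KM.

    The correlation pruning, z-scoring parameters, LASSO penalty and
    cutpoint are all derived from the training cohort only; the stored
    transform and threshold are then applied unchanged to the test cohort.
    Feature rows are aligned to ``clinical.subject_id``.
    """
    from .subgroups import FeatureScaler, prune_correlated

    clin = clinical.set_index("subject_id")
    X = features.loc[clin.index]
    train_ids, test_ids = split_cohort(
        clinical, train_fraction=train_fraction, seed=seed
    )
    X_tr = prune_correlated(X.loc[train_ids], threshold=prune_threshold)
    scaler = FeatureScaler().fit(X_tr)
    Z = scaler.transform(X[X_tr.columns])
    model = fit_lasso_cox(
        Z.loc[train_ids],
        clin.loc[train_ids, "os_days"],
        clin.loc[train_ids, "event"],
        folds=folds,
        seed=seed,
    )
    if not model.selected_features:
        raise RuntimeError("empty risk model: LASSO selected no features")
    model.training_ids = list(train_ids)
    scores = compute_rrs(Z, model)
    model.cutpoint = find_cutpoint(
        scores.loc[train_ids],
        clin.loc[train_ids, "os_days"],
        clin.loc[train_ids, "event"],
        min_group_frac=min_group_frac,
    )
    risk_group = pd.Series(
        np.where(scores > model.cutpoint, "high", "low"), index=scores.index
    )
    train_km = km_logrank(
        risk_group.loc[train_ids],
        clin.loc[train_ids, "os_days"],
        clin.loc[train_ids, "event"],
    )
    test_km = None
    if test_ids and risk_group.loc[test_ids].nunique() == 2:
        test_km = km_logrank(
            risk_group.loc[test_ids],
            clin.loc[test_ids, "os_days"],
            clin.loc[test_ids, "event"],
        )
    return RRSExperiment(
        model=model,
        scaler=scaler,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        scores=scores,
        risk_group=risk_group,
        train_km=train_km,
        test_km=test_km,
    )


# ---------------------------------------------------------------------------
# agreement tests


def mcnemar_test(table: np.ndarray) -> tuple[float, float]:
    """McNemar chi-square on the discordant cells of a 2x2 table.

    statistic = (b - c)^2 / (b + c) without continuity correction; p from
    chi-square(1). b + c = 0 returns (0, 1) by convention.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("McNemar needs a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.number):
        raise ValueError("counts must be nonnegative numbers")
    b, c = float(tab[0, 1]), float(tab[1, 0])
    if b + c == 0:
        return 0.0, 1.0
    chi2 = (b - c) ** 2 / (b + c)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def chi2_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence on an R x C count table.

    All-zero rows/columns are dropped with a warning; df = (R-1)(C-1) on
    the reduced table. No Yates correction.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("need an R x C table with R, C >= 2")
    if np.any(tab < 0):
        raise ValueError("counts must be nonnegative")
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero row(s)/column(s)", stacklevel=2)
        tab = tab[keep_r][:, keep_c]
    if min(tab.shape) < 2:
        raise ValueError("table degenerate after dropping empty rows/columns")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)
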