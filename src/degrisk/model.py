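"""Spatial logistic modelling of degraded land and risk mapping.

The binary degraded-land outcome y (from the trend stage) is regressed on
the factor stack with the logistic model

    P(y = 1 | x) = 1 / (1 + exp(-(b0 + sum_i b_i x_i)))

The workflow mirrors standard spatial-risk practice: one cell is sampled
per non-overlapping 3x3 window (750 m at 250 m cells) to thin spatial
autocorrelation; the sample is split 50/50 into calibration and validation;
predictors with variance inflation factor above 5 are removed iteratively;
the full model and a backward-stepwise reduction are fitted by maximum
likelihood and compared on validation AUC with a correlated-AUC (DeLong)
test; the retained fit is validated by ROC/AUC, percent correctly predicted
at the 0.5 threshold, and the likelihood-ratio chi-square; coefficients are
reported with the odds-percent interpretation 100*(e^b - 1); and the fitted
probabilities over the whole grid are cut into ten equal-count risk classes
(class 1 = top decile of risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .factors import FactorStack
from .geodata import Grid

__all__ = [
    "block_sample",
    "split_calibration",
    "vif_screen",
    "DegradationLogit",
    "LogisticFit",
    "fit_logistic",
    "backward_stepwise",
    "auc_rank",
    "compare_auc",
    "ValidationReport",
    "validate_fit",
    "odds_percent",
    "significance_stars",
    "fit_report",
    "RiskMap",
    "risk_deciles",
]


# ---------------------------------------------------------------------------
# Sampling


def block_sample(y: Grid, stack: FactorStack, block: int = 3, seed: int = 0) -> pd.DataFrame:
    """Systematic unbalanced random sampling: one random unmasked cell per window.

    The grid is partitioned into non-overlapping block x block windows from
    the top-left corner; every window containing at least one unmasked cell
    contributes exactly one uniformly chosen cell.  Returns a table with
    cell indices, the outcome and every factor layer.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    rng = np.random.default_rng(seed)
    mask = y.nodata_mask | stack.mask
    n_rows, n_cols = y.spec.shape
    rows, cols = [], []
    for bi in range(0, n_rows, block):
        for bj in range(0, n_cols, block):
            sub = ~mask[bi:bi + block, bj:bj + block]
            cand = np.argwhere(sub)
            if len(cand):
                pick = cand[rng.integers(len(cand))]
                rows.append(bi + pick[0])
                cols.append(bj + pick[1])
    rows = np.array(rows, dtype=int)
    cols = np.array(cols, dtype=int)
    if rows.size == 0:
        return pd.DataFrame(columns=["row", "col", "y"] + stack.names)
    table = stack.frame_at(rows, cols)
    table.insert(2, "y", y.values[rows, cols].astype(int))
    return table


def split_calibration(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Label a uniform random 50/50 calibration/validation split (sizes differ <= 1)."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    n = len(table)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[: n // 2]] = "calibration"
    labels[order[n // 2:]] = "validation"
    out = table.copy()
    out["split"] = labels
    return out


# ---------------------------------------------------------------------------
# Multicollinearity screen


def _r_squared(yv: np.ndarray, X: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(yv)), X])
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    tss = ((yv - yv.mean()) ** 2).sum()
    if tss <= 0:
        return 0.0
    return 1.0 - float((resid ** 2).sum()) / float(tss)


def vif_screen(table: pd.DataFrame, predictors: list[str] | None = None,
               threshold: float = 5.0) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the largest-VIF predictor while any VIF exceeds *threshold*.

    VIF_j = 1 / (1 - R²_j) from regressing predictor j on the other retained
    predictors; exact collinearity counts as infinite VIF and is removed
    first.  Returns the retained names and a table of final VIFs plus the
    removal sequence.
    """
    retained = list(predictors) if predictors is not None else \
        [c for c in table.columns if c not in ("row", "col", "y", "split")]
    if len(retained) < 2:
        raise ValueError("need at least 2 predictors for a VIF screen")
    removed: list[tuple[str, float]] = []
    while True:
        X = table[retained].to_numpy(dtype=float)
        vifs = {}
        for j, name in enumerate(retained):
            others = np.delete(X, j, axis=1)
            r2 = _r_squared(X[:, j], others)
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda k: vifs[k])
        if vifs[worst] > threshold and len(retained) > 1:
            removed.append((worst, vifs[worst]))
            retained.remove(worst)
            continue
        break
    report = pd.DataFrame({"variable": list(vifs), "vif": list(vifs.values())})
    report["removed"] = False
    if removed:
        rem = pd.DataFrame({"variable": [r[0] for r in removed],
                            "vif": [r[1] for r in removed],
                            "removed": True})
        report = pd.concat([rem, report], ignore_index=True)
    return retained, report


# ---------------------------------------------------------------------------
# Logistic fit


class DegradationLogit(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic regression with Wald inference.

    A thin scikit-learn-style estimator over the Newton/IRLS logistic fit:
    no regularisation, standard errors from the inverse observed
    information, so coefficients carry the odds-percent interpretation
    100*(e^b - 1).

    Attributes (after fit)
    ----------------------
    feature_names_ : list of predictor names ('const' first)
    params_, bse_, zvalues_, pvalues_ : pandas Series indexed by name
    cov_ : DataFrame, coefficient covariance
    llf_, llnull_ : model and intercept-only log-likelihoods
    n_ : number of observations
    converged_ : bool; False signals possible complete separation
    """

    def __init__(self, maxiter: int = 100, tol: float = 1e-8):
        self.maxiter = maxiter
        self.tol = tol

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        if len(classes) < 2:
            raise ValueError("both outcome classes must be present")
        design = sm.add_constant(X.astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design)
            res = model.fit(method="newton", maxiter=self.maxiter, tol=self.tol, disp=0)
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        if not self.converged_:
            warnings.warn("logistic fit did not converge: possible complete separation",
                          RuntimeWarning, stacklevel=2)
        self.feature_names_ = list(design.columns)
        self.params_ = res.params
        self.bse_ = res.bse
        self.zvalues_ = res.tvalues
        self.pvalues_ = res.pvalues
        self.cov_ = res.cov_params()
        self.llf_ = float(res.llf)
        self.llnull_ = float(res.llnull)
        self.n_ = int(res.nobs)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        design = sm.add_constant(X.astype(float), has_constant="add")
        design = design[self.feature_names_]
        return design.to_numpy() @ self.params_.to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, Wald inference, likelihoods."""

    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    n: int
    converged: bool = True
    drop_sequence: list[str] = field(default_factory=list)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.params["const"], dtype=float)
        for name in self.predictors:
            eta += self.params[name] * table[name].to_numpy(dtype=float)
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(table)))

    @property
    def lr_chi_square(self) -> float:
        return 2.0 * (self.llf - self.llnull)


def fit_logistic(table: pd.DataFrame, predictors: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit of y on the given predictors."""
    if predictors is None:
        predictors = [c for c in table.columns if c not in ("row", "col", "y", "split")]
    est = DegradationLogit().fit(table[predictors], table["y"].to_numpy())
    return LogisticFit(predictors=list(predictors), params=est.params_, bse=est.bse_,
                       zvalues=est.zvalues_, pvalues=est.pvalues_, cov=est.cov_,
                       llf=est.llf_, llnull=est.llnull_, n=est.n_,
                       converged=est.converged_)


def backward_stepwise(table: pd.DataFrame, predictors: list[str] | None = None,
                      alpha_remove: float = 0.05) -> LogisticFit:
    """Backward elimination on Wald p: drop the worst p > alpha_remove, refit.

    Degenerates to the intercept-only model if every predictor is dropped.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c not in ("row", "col", "y", "split")]
    current = list(predictors)
    dropped: list[str] = []
    fit = fit_logistic(table, current)
    while current:
        pv = fit.pvalues.drop("const")
        worst = pv.idxmax()
        if pv[worst] <= alpha_remove:
            break
        current.remove(worst)
        dropped.append(worst)
        if not current:
            fit = _intercept_only_fit(table)
            break
        fit = fit_logistic(table, current)
    fit.drop_sequence = dropped
    return fit


def _intercept_only_fit(table: pd.DataFrame) -> LogisticFit:
    y = table["y"].to_numpy(dtype=float)
    p = y.mean()
    beta0 = np.log(p / (1 - p))
    n = len(y)
    llf = float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    se = float(np.sqrt(1.0 / (n * p * (1 - p))))
    params = pd.Series({"const": beta0})
    return LogisticFit(predictors=[], params=params,
                       bse=pd.Series({"const": se}),
                       zvalues=pd.Series({"const": beta0 / se}),
                       pvalues=pd.Series({"const": 2 * stats.norm.sf(abs(beta0 / se))}),
                       cov=pd.DataFrame({"const": [se ** 2]}, index=["const"]),
                       llf=llf, llnull=llf, n=n)


# ---------------------------------------------------------------------------
# Validation


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: probability a random positive outscores a random negative.

    Ties count one half; equals the mean over all positive x negative pairs
    exactly (Mann-Whitney identity).
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_placements(y: np.ndarray, scores: np.ndarray):
    """Per-observation placement values of the paired-AUC U statistic."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n          # placements of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placements of negatives
    auc = v10.mean()
    return auc, v10, v01


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    diff: float
    z: float
    p_value: float
    recommended: str  # "a" or "b"
    degenerate: bool = False


def compare_auc(fit_a: LogisticFit, fit_b: LogisticFit,
                validation: pd.DataFrame, alpha: float = 0.05) -> AUCComparison:
    """Correlated-AUC (DeLong-type) z test of two models on one validation set.

    When the test is significant at *alpha* the higher-AUC model is
    recommended, otherwise the more parsimonious one (fewer predictors).
    """
    y = validation["y"].to_numpy(dtype=float)
    sa = fit_a.predict_proba(validation)
    sb = fit_b.predict_proba(validation)
    if np.allclose(sa, sa[0]) and np.allclose(sb, sb[0]):
        return AUCComparison(0.5, 0.5, 0.0, 0.0, 1.0, recommended="b", degenerate=True)
    auc_a, v10a, v01a = _delong_placements(y, sa)
    auc_b, v10b, v01b = _delong_placements(y, sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    if p < alpha:
        recommended = "a" if auc_a >= auc_b else "b"
    else:
        recommended = "a" if len(fit_a.predictors) <= len(fit_b.predictors) else "b"
    return AUCComparison(float(auc_a), float(auc_b), float(diff), float(z), p, recommended)


@dataclass
class ValidationReport:
    auc: float | None
    pcp: float
    chi_square: float
    chi_square_df: int
    chi_square_p: float
    threshold: float
    n: int
    single_class: bool = False

    def to_dict(self) -> dict:
        return {"auc": self.auc, "pcp": self.pcp, "chi_square": self.chi_square,
                "chi_square_df": self.chi_square_df, "chi_square_p": self.chi_square_p,
                "threshold": self.threshold, "n": self.n,
                "single_class": self.single_class}


def validate_fit(fit: LogisticFit, validation: pd.DataFrame,
                 threshold: float = 0.5) -> ValidationReport:
    """ROC/AUC and PCP on the validation rows; LR chi-square of the fit.

    PCP = 100 x correctly classified / total at the probability *threshold*;
    chi-square is the likelihood-ratio statistic of the fitted vs the
    intercept-only model, df = number of slope coefficients.
    """
    y = validation["y"].to_numpy(dtype=float)
    p = fit.predict_proba(validation)
    pred = (p >= threshold).astype(float)
    pcp = 100.0 * float((pred == y).mean())
    single = len(np.unique(y)) < 2
    auc = None if single else auc_rank(y, p)
    chi2 = fit.lr_chi_square
    df = len(fit.predictors)
    chi_p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ValidationReport(auc=auc, pcp=pcp, chi_square=float(chi2),
                            chi_square_df=df, chi_square_p=chi_p,
                            threshold=threshold, n=len(y), single_class=single)


# ---------------------------------------------------------------------------
# Reporting and risk mapping


def odds_percent(beta: float) -> float:
    """Percent change in the odds per unit predictor change: 100*(e^beta - 1)."""
    return 100.0 * (np.exp(beta) - 1.0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "****"
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "n.s."


def fit_report(fit: LogisticFit) -> pd.DataFrame:
    """Coefficient table: variable, coefficient, odds %, SE, z, p, stars."""
    rows = []
    for name in fit.predictors + ["const"]:
        rows.append({
            "variable": name,
            "coefficient": float(fit.params[name]),
            "odds_percent": odds_percent(float(fit.params[name])) if name != "const" else np.nan,
            "se": float(fit.bse[name]),
            "z": float(fit.zvalues[name]),
            "p": float(fit.pvalues[name]),
            "stars": significance_stars(float(fit.pvalues[name])),
        })
    return pd.DataFrame(rows)


@dataclass
class RiskMap:
    classes: Grid       # decile codes 1..10, 1 = highest risk
    probability: Grid


def risk_deciles(fit: LogisticFit, stack: FactorStack) -> RiskMap:
    """Apply the fitted model to the factor stack and cut ten equal-count classes.

    Unmasked cells are ranked by probability descending (ties broken by
    (row, col) order); class c takes ranks ((c-1)N/10, cN/10], so class 1
    holds the top 10 % of risk and class sizes differ by at most one cell.
    """
    missing = [p for p in fit.predictors if p not in stack.layers]
    if missing:
        raise KeyError(f"factor stack lacks predictor layers: {missing}")
    eta = np.full(stack.spec.shape, fit.params["const"], dtype=float)
    for name in fit.predictors:
        eta += fit.params[name] * stack.values(name)
    prob = 1.0 / (1.0 + np.exp(-eta))
    mask = stack.mask.copy()
    prob_grid = Grid(stack.spec, prob, mask)

    valid = np.argwhere(~mask)
    N = len(valid)
    cls = np.zeros(stack.spec.shape, dtype=float)
    if N:
        pv = prob[~mask]
        # stable ordering: descending probability, then row, then col
        order = np.lexsort((valid[:, 1], valid[:, 0], -pv))
        bounds = np.round(np.arange(11) * N / 10.0).astype(int)
        for c in range(1, 11):
            sel = valid[order[bounds[c - 1]:bounds[c]]]
            cls[sel[:, 0], sel[:, 1]] = c
    return RiskMap(classes=Grid(stack.spec, cls, mask.copy()), probability=prob_grid)
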