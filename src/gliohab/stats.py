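"""Group comparison and IDH-prediction statistics.

Covers the diagnostic-modeling toolchain: normality-gated two-group
tests, ROC/AUC with DeLong variance and the DeLong paired test, logistic
regression with Wald odds-ratio intervals, variance-inflation-factor
collinearity screening, backward stepwise selection at alpha = 0.05,
Hosmer-Lemeshow calibration, and leave-one-out cross-validation of a
fixed variable set.

AUC is the Mann-Whitney pair-counting estimator (half credit for ties);
its variance and the paired comparison use the DeLong placement-value
construction.  Logistic fits are maximum likelihood (statsmodels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class GroupComparison:
    feature: str
    test: str  # "welch-t" or "mann-whitney"
    statistic: float
    pvalue: float
    group_stats: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)


def compare_groups(values, groups, feature: str = "") -> GroupComparison:
    """Welch t-test if both groups pass Shapiro-Wilk at 0.05, else
    Mann-Whitney U; two-tailed."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups[~pd.isna(groups)])
    if len(names) != 2:
        raise ValueError(f"{feature}: exactly two groups required, got {list(names)}")
    samples, gstats = [], {}
    for name in names:
        x = values[(groups == name) & np.isfinite(values)]
        if x.size < 3:
            raise ValueError(f"{feature}: group {name!r} has <3 non-missing values")
        samples.append(x)
        gstats[str(name)] = (float(x.mean()), float(x.std(ddof=1)), int(x.size))
    a, b = samples

    def _normal(x):
        if np.ptp(x) == 0:
            return False  # degenerate; Shapiro undefined
        return sps.shapiro(x).pvalue > ALPHA

    if _normal(a) and _normal(b):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            return GroupComparison(feature, "welch-t", 0.0, 1.0, gstats)
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison(feature, "welch-t", float(res.statistic), float(res.pvalue), gstats)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(feature, "mann-whitney", float(res.statistic), float(res.pvalue), gstats)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10[i] = P(neg < pos_i) + P(neg = pos_i)/2
    and symmetrically V01."""
    ns = np.sort(neg)
    lo = np.searchsorted(ns, pos, side="left")
    hi = np.searchsorted(ns, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size
    ps = np.sort(pos)
    lo = np.searchsorted(ps, neg, side="left")
    hi = np.searchsorted(ps, neg, side="right")
    v01 = ((ps.size - hi) + 0.5 * (hi - lo)) / pos.size
    return v10, v01


def empirical_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    v10, _ = _placements(np.asarray(pos, float), np.asarray(neg, float))
    return float(v10.mean())


@dataclass
class RocResult:
    auc: float
    variance: float  # DeLong
    ci: tuple[float, float]  # normal approximation, clipped to [0, 1]
    sensitivity: float
    specificity: float
    accuracy: float
    cutoff: float  # on the oriented score scale; positive iff score > cutoff
    orientation: int  # +1: higher raw score indicates the positive class
    scores: np.ndarray = field(repr=False)  # oriented scores
    labels: np.ndarray = field(repr=False)  # 1 = positive class
    pvalue: float = float("nan")  # H0: AUC = 0.5


def roc_auc(scores, labels, positive_label=1, orientation: str | int = "auto") -> RocResult:
    """ROC analysis with DeLong variance and the Youden operating point.

    ``orientation="auto"`` flips the score sign if needed so the AUC for
    the stated positive class is >= 0.5; the flip is recorded.  Youden-J
    ties are broken toward the higher-specificity cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive_label).astype(int)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    sign = 1
    if orientation == "auto":
        if empirical_auc(scores[y == 1], scores[y == 0]) < 0.5:
            sign = -1
            log.info("roc_auc: orientation flipped (higher score marks the negative class)")
    else:
        sign = int(orientation)
    s = sign * scores
    pos, neg = s[y == 1], s[y == 0]
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size
           if pos.size > 1 and neg.size > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    p = 1.0 if var == 0 else float(2 * sps.norm.sf(abs(auc - 0.5) / np.sqrt(var)))

    # Youden operating point over all achievable cutoffs (predict positive
    # iff score > cutoff); -inf = call everything positive.
    cuts = np.concatenate([[-np.inf], np.unique(s)])
    best = None
    for c in cuts:
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, c)
    _, sens, spec, cut = best
    acc = (sens * pos.size + spec * neg.size) / (pos.size + neg.size)
    return RocResult(auc=auc, variance=float(var), ci=ci, sensitivity=sens,
                     specificity=spec, accuracy=float(acc), cutoff=float(cut),
                     orientation=sign, scores=s, labels=y, pvalue=p)


@dataclass(frozen=True)
class DelongComparison:
    auc_difference: float
    z: float
    pvalue: float
    degenerate: bool = False


def delong_compare(r1: RocResult, r2: RocResult, paired: bool = True) -> DelongComparison:
    """DeLong test for a difference between two AUCs.

    Paired mode requires both results to score the same subjects in the
    same order and uses the placement-value covariance; unpaired mode
    treats the variances as independent.
    """
    diff = r1.auc - r2.auc
    if paired:
        if r1.scores.size != r2.scores.size or not np.array_equal(r1.labels, r2.labels):
            raise ValueError("paired comparison requires identical subjects and labels")
        y = r1.labels
        v10 = np.column_stack([_placements(r.scores[y == 1], r.scores[y == 0])[0] for r in (r1, r2)])
        v01 = np.column_stack([_placements(r.scores[y == 1], r.scores[y == 0])[1] for r in (r1, r2)])
        s10 = np.cov(v10, rowvar=False, ddof=1)
        s01 = np.cov(v01, rowvar=False, ddof=1)
        cov = s10 / v10.shape[0] + s01 / v01.shape[0]
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    else:
        var = r1.variance + r2.variance
    if var <= 0:
        return DelongComparison(0.0, 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(var)
    return DelongComparison(float(diff), float(z), float(2 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    variables: list[str]
    coef: pd.Series  # includes "const"
    se: pd.Series
    pvalues: pd.Series
    or_table: pd.DataFrame  # index variables; columns OR, ci_low, ci_high, p
    fitted_prob: np.ndarray
    llf: float
    converged: bool
    separation: bool
    vif: pd.Series | None = None

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        x = design[self.variables].to_numpy(dtype=float) if self.variables else \
            np.empty((len(design), 0))
        eta = self.coef["const"] + x @ self.coef[self.variables].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _check_rank(x: pd.DataFrame) -> None:
    mat = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        bad = [c for c in x.columns
               if np.linalg.matrix_rank(
                   sm.add_constant(x.drop(columns=c).to_numpy(dtype=float),
                                   has_constant="add")) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_logistic(design: pd.DataFrame, outcome, check_rank: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald OR intervals.

    Diverging coefficients (|beta| > 15 on standardized-scale problems,
    or a statsmodels separation error) are flagged; the fit returned is
    the last iterate.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(design) <= len(design.columns) + 1:
        raise ValueError("need n > number of variables + 1")
    if check_rank and len(design.columns):
        _check_rank(design)
    xmat = sm.add_constant(design.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation raises in some versions
            separation = True
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=200, method="bfgs")
    coef = pd.Series(res.params, index=xmat.columns)
    se = pd.Series(res.bse, index=xmat.columns)
    if np.any(np.abs(coef.drop("const")) > 15) if len(design.columns) else False:
        separation = True
    if separation:
        log.warning("fit_logistic: complete/quasi-separation suspected")
    z = 1.959963984540054
    variables = list(design.columns)
    ors = np.exp(coef[variables]) if variables else pd.Series(dtype=float)
    or_table = pd.DataFrame(
        {
            "OR": ors,
            "ci_low": np.exp(coef[variables] - z * se[variables]),
            "ci_high": np.exp(coef[variables] + z * se[variables]),
            "p": pd.Series(res.pvalues, index=xmat.columns)[variables],
        }
    )
    return LogisticFit(
        variables=variables,
        coef=coef,
        se=se,
        pvalues=pd.Series(res.pvalues, index=xmat.columns),
        or_table=or_table,
        fitted_prob=np.asarray(res.predict()),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1/(1-R^2_j) regressing each
    variable on the others with an intercept; +inf for perfect
    collinearity."""
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two variables")
    if len(design) <= design.shape[1]:
        raise ValueError("VIF needs n > number of variables")
    out = {}
    for col in design.columns:
        yj = design[col].to_numpy(dtype=float)
        xj = sm.add_constant(design.drop(columns=col).to_numpy(dtype=float),
                             has_constant="add")
        r2 = sm.OLS(yj, xj).fit().rsquared
        out[col] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out)
    if np.isinf(s).any():
        log.warning("vif: perfect collinearity in %s", list(s.index[np.isinf(s)]))
    return s


def univariable_screen(design: pd.DataFrame, outcome, alpha: float = ALPHA) -> pd.DataFrame:
    """Single-variable logistic fits; 'selected' marks p < alpha."""
    rows = []
    for col in design.columns:
        fit = fit_logistic(design[[col]], outcome, check_rank=False)
        r = fit.or_table.loc[col]
        rows.append({"variable": col, "OR": r["OR"], "ci_low": r["ci_low"],
                     "ci_high": r["ci_high"], "p": r["p"], "selected": r["p"] < alpha})
    return pd.DataFrame(rows).set_index("variable")


def screen_vif(design: pd.DataFrame, max_vif: float = 5.0) -> list[str]:
    """Iteratively drop the worst-VIF variable until all VIFs < max_vif."""
    cols = list(design.columns)
    while len(cols) >= 2:
        v = vif(design[cols])
        worst = v.idxmax()
        if v[worst] < max_vif:
            break
        log.info("screen_vif: dropping %s (VIF=%.2f)", worst, v[worst])
        cols.remove(worst)
    return cols


def stepwise_select(
    design: pd.DataFrame, outcome, stay_p: float = ALPHA
) -> tuple[LogisticFit, list[str]]:
    """Backward elimination on Wald p-values.

    Starts from all candidates and repeatedly drops the variable with the
    largest p until every remaining one has p < ``stay_p``.  Returns the
    final fit and the ordered list of dropped variables.
    """
    cols = list(design.columns)
    path: list[str] = []
    if not cols:
        log.warning("stepwise_select: empty candidate set; intercept-only model")
        return fit_logistic(design[[]], outcome, check_rank=False), path
    while True:
        fit = fit_logistic(design[cols], outcome, check_rank=False)
        pv = fit.pvalues.drop("const").fillna(1.0)  # undefined Wald p -> eliminate
        worst = pv.idxmax()
        if pv[worst] < stay_p or len(cols) == 0:
            return fit, path
        cols.remove(worst)
        path.append(worst)
        if not cols:
            log.warning("stepwise_select: all candidates eliminated; intercept-only model")
            return fit_logistic(design[[]], outcome, check_rank=False), path


def hosmer_lemeshow(probabilities, outcomes, g: int = 10) -> tuple[float, float, pd.DataFrame]:
    """Hosmer-Lemeshow goodness-of-fit on deciles of predicted risk.

    chi2 = sum (O-E)^2 / (E (1 - E/n_bin)) over bins, df = bins - 2.
    Bins with fewer distinct probabilities than requested, or degenerate
    expected counts, are merged and logged.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size < 2 * g:
        raise ValueError(f"need n >= 2g = {2 * g} observations")
    df = pd.DataFrame({"p": p, "y": y})
    try:
        df["bin"] = pd.qcut(df["p"], g, labels=False, duplicates="drop")
    except ValueError:
        df["bin"] = 0
    n_bins = int(df["bin"].nunique())
    if n_bins < g:
        log.info("hosmer_lemeshow: %d bins after merging duplicate quantiles", n_bins)
    grp = df.groupby("bin").agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"),
                                mean_p=("p", "mean"))
    # merge bins whose variance term would vanish into their neighbor
    rows = grp.reset_index(drop=True)
    merged, i = [], 0
    while i < len(rows):
        r = rows.iloc[i].copy()
        while (r["exp"] <= 0 or r["exp"] >= r["n"]) and i + 1 < len(rows):
            log.info("hosmer_lemeshow: merging degenerate bin")
            i += 1
            nxt = rows.iloc[i]
            r[["n", "obs", "exp"]] = r[["n", "obs", "exp"]] + nxt[["n", "obs", "exp"]]
        merged.append(r)
        i += 1
    table = pd.DataFrame(merged).reset_index(drop=True)
    denom = table["exp"] * (1 - table["exp"] / table["n"])
    denom = denom.replace(0, np.nan)
    chi2 = float((((table["obs"] - table["exp"]) ** 2) / denom).dropna().sum())
    dof = max(len(table) - 2, 1)
    pval = float(sps.chi2.sf(chi2, dof))
    return chi2, pval, table


@dataclass
class ValidationResult:
    probabilities: np.ndarray  # one out-of-fold probability per subject
    roc: RocResult
    hl_chi2: float
    hl_p: float
    flagged_folds: list[int]


def loocv_auc(
    design: pd.DataFrame,
    outcome,
    variables: list[str],
    positive_label=1,
    hl_bins: int = 10,
) -> ValidationResult:
    """Leave-one-out cross-validation of a fixed logistic variable set.

    For each subject the coefficients are refitted on the other n-1 and
    the held-out probability recorded; the pooled vector feeds a ROC
    analysis and a Hosmer-Lemeshow test.  A fold whose training outcome
    is single-class is flagged and predicted from the full-data fit.
    """
    y = np.asarray(outcome, dtype=float)
    x = design[variables].reset_index(drop=True)
    n = len(x)
    probs = np.empty(n)
    flagged: list[int] = []
    full = fit_logistic(x, y, check_rank=False)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if ytr.min() == ytr.max():
            flagged.append(i)
            log.warning("loocv_auc: fold %d has single-class training data", i)
            fit = full
        else:
            fit = fit_logistic(x.loc[tr].reset_index(drop=True), ytr, check_rank=False)
        probs[i] = float(fit.predict(x.iloc[[i]])[0])
    roc = roc_auc(probs, (y == 1).astype(int), positive_label=1, orientation=1)
    hl_chi2, hl_p, _ = hosmer_lemeshow(probs, y, g=min(hl_bins, n // 2))
    return ValidationResult(probs, roc, hl_chi2, hl_p, flagged)


# ---------------------------------------------------------------------------
# binormal helpers

def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two normal score distributions."""
    return float(sps.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


def simulate_group_auc(
    n_pos: int, mu_pos: float, sd_pos: float,
    n_neg: int, mu_neg: float, sd_neg: float,
    n_replicates: int = 1000, seed: int = 0,
) -> float:
    """Mean empirical AUC over replicate two-group normal simulations."""
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_replicates)
    for r in range(n_replicates):
        pos = rng.normal(mu_pos, sd_pos, n_pos)
        neg = rng.normal(mu_neg, sd_neg, n_neg)
        aucs[r] = empirical_auc(pos, neg)
    return float(aucs.mean())
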