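"""Group-level statistics for K-Score tables and pain measures.

Stages mirror the analysis plan: pressure-pain-threshold readings are
averaged per subject; distributions are screened with Shapiro-Wilk;
patient-reported metrics and PPT are compared between sexes by rank-transform
ANCOVA correcting for age and BMI (reported as median +/- IQR); K-Scores are
modeled by a maximum-likelihood linear mixed model with a per-subject random
intercept and group-specific residual variances, a likelihood-ratio test for
the group x repetition interaction, and single-step max-|t|-adjusted
per-repetition group contrasts; and pain-biomechanics associations are
explored by OLS of repetition-averaged trunk scores on Spearman-rank-
transformed predictors, with the R^2 strength taxonomy (weak < 0.16,
moderate to 0.36, strong above).

The heteroskedastic mixed model is written out here rather than delegated:
each subject's marginal covariance is sigma_b^2 J + sigma_g^2 I, whose
determinant and inverse have Sherman-Morrison closed forms, so the profile
log-likelihood over the variance parameters is cheap to optimize directly.
statsmodels' MixedLM covers only the shared-residual-variance special case
and serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    ModelError,
    ParameterError,
    RangeError,
)

PPT_CEILING_KPA = 1500.0

#: internal seed for the common-draw max-|t| reference distribution; fixed so
#: reruns are bit-identical and adjusted p-values are monotone in |t|.
_MAXT_SEED = 987654321
_MAXT_DRAWS = 1 << 17


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    label: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    extra: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    outcome: str
    predictors: tuple[str, ...]
    n: int
    r_squared: float
    p_value: float          # p of the pain-measure coefficient
    slope: float            # sign-carrying coefficient of the pain measure
    strength: str

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))


@dataclass
class MixedModelResult:
    loglik: float
    params: pd.Series
    cov_params: pd.DataFrame
    random_intercept_sd: float
    residual_sd: dict
    cell_means: pd.DataFrame
    contrasts: list[ComparisonResult]
    interaction_stat: float
    interaction_df: int
    interaction_p: float
    converged: bool


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def aggregate_ppt(readings: Sequence[float], policy: str = "error") -> float:
    """Average the three PPT repetitions for one subject-site.

    Readings above the 1500 kPa instrument ceiling are a range error. With
    ``policy='error'`` (default) fewer than 3 readings raise; with
    ``policy='mean_available'`` any positive number of readings is averaged.
    """
    readings = [float(r) for r in readings]
    if any(r <= 0 for r in readings):
        raise RangeError(f"PPT readings must be positive: {readings}")
    if any(r > PPT_CEILING_KPA for r in readings):
        raise RangeError(
            f"PPT reading exceeds the {PPT_CEILING_KPA:.0f} kPa instrument "
            f"ceiling: {readings}"
        )
    if len(readings) != 3:
        if policy == "error" or not readings:
            raise ParameterError(
                f"expected 3 PPT readings, got {len(readings)}"
            )
        if policy != "mean_available":
            raise ParameterError(f"unknown policy {policy!r}")
    return float(np.mean(readings))


def check_normality(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; degenerate on constant input."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ParameterError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no distribution shape")
    stat, p = scipy.stats.shapiro(x)
    return float(stat), float(p)


def summarize_median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quantiles)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def classify_r2(r2: float) -> str:
    """Strength taxonomy: weak (< 0.16), moderate (to 0.36), strong (> 0.36).

    Boundary values fall to the lower category (the published cutoffs are
    strict inequalities, so 0.16 and 0.36 are not otherwise covered).
    """
    if not 0.0 <= r2 <= 1.0:
        raise ParameterError(f"R^2 must lie in [0, 1], got {r2}")
    if r2 <= 0.16:
        return "weak"
    if r2 <= 0.36:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# Rank-based ANCOVA
# ---------------------------------------------------------------------------

def rank_ancova(
    outcome: Sequence[float],
    group: Sequence,
    age: Sequence[float],
    bmi: Sequence[float],
    label: str = "group",
    n_permutations: int = 0,
    seed: int = 0,
) -> ComparisonResult:
    """Two-group rank-transform ANCOVA correcting for age and BMI.

    The outcome is rank-transformed (average ranks on ties) and regressed on
    the group indicator plus the covariates; the group coefficient's t-test
    is the reported comparison. With ``n_permutations > 0`` the p-value is
    replaced by a group-label permutation p. Group medians +/- IQR ride along
    in ``extra``.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ModelError(f"rank_ancova needs exactly 2 groups, got {len(levels)}")
    counts = {lv: int((g == lv).sum()) for lv in levels}
    if min(counts.values()) < 3:
        raise ModelError(f"each group needs n >= 3, got {counts}")
    indicator = (g == levels[1]).astype(float)
    for name, cov in (("age", age), ("bmi", bmi)):
        if np.ptp(cov) == 0:
            raise ModelError(f"covariate {name} is constant; design is degenerate")

    ranks = scipy.stats.rankdata(y)
    X = sm.add_constant(np.column_stack([indicator, age, bmi]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("confounded design: covariates collinear with group")
    fit = sm.OLS(ranks, X).fit()
    t_obs = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, 1] = rng.permutation(indicator)
            tp = float(sm.OLS(ranks, Xp).fit().tvalues[1])
            if abs(tp) >= abs(t_obs):
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    med_iqr = {
        str(lv): summarize_median_iqr(y[g == lv]) for lv in levels
    }
    return ComparisonResult(
        label=f"{label}: {levels[1]} vs {levels[0]}",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_raw=p,
        p_adjusted=p,
        adjustment="none" if n_permutations == 0 else "permutation",
        extra={"median_iqr": med_iqr, "n": counts, "t": t_obs},
    )


# ---------------------------------------------------------------------------
# Heteroskedastic random-intercept mixed model
# ---------------------------------------------------------------------------

def _design(groups: np.ndarray, reps: np.ndarray, g_levels, r_levels,
            interaction: bool) -> np.ndarray:
    """Treatment-coded design matrix for group * repetition."""
    cols = [np.ones(groups.size)]
    for gl in g_levels[1:]:
        cols.append((groups == gl).astype(float))
    for rl in r_levels[1:]:
        cols.append((reps == rl).astype(float))
    if interaction:
        for gl in g_levels[1:]:
            for rl in r_levels[1:]:
                cols.append(((groups == gl) & (reps == rl)).astype(float))
    return np.column_stack(cols)


def _param_names(g_levels, r_levels, interaction: bool) -> list[str]:
    names = ["intercept"]
    names += [f"group[{gl}]" for gl in g_levels[1:]]
    names += [f"rep[{rl}]" for rl in r_levels[1:]]
    if interaction:
        names += [
            f"group[{gl}]:rep[{rl}]"
            for gl in g_levels[1:] for rl in r_levels[1:]
        ]
    return names


class _BlockML:
    """Profile ML machinery for y = X beta + b_subject + eps(group)."""

    def __init__(self, y, X, subject_ids, subject_groups, g_levels,
                 shared_residual: bool):
        order = np.argsort(subject_ids, kind="stable")
        self.y = y[order]
        self.X = X[order]
        sid = subject_ids[order]
        self.blocks = []  # (slice, group index)
        g_index = {gl: i for i, gl in enumerate(g_levels)}
        start = 0
        for i in range(1, sid.size + 1):
            if i == sid.size or sid[i] != sid[start]:
                self.blocks.append(
                    (slice(start, i), g_index[subject_groups[order[start]]])
                )
                start = i
        self.n = y.size
        self.p = X.shape[1]
        self.n_groups = 1 if shared_residual else len(g_levels)
        self.shared = shared_residual

    def _gls(self, tau2: float, sig2: np.ndarray):
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        logdet = 0.0
        for sl, gi in self.blocks:
            s2 = sig2[0] if self.shared else sig2[gi]
            Xb, yb = self.X[sl], self.y[sl]
            ni = yb.size
            shrink = tau2 / (s2 + ni * tau2)
            # V^-1 = (I - shrink * J) / s2
            Xs, ys = Xb.sum(axis=0), yb.sum()
            XtVX += (Xb.T @ Xb - shrink * np.outer(Xs, Xs)) / s2
            XtVy += (Xb.T @ yb - shrink * Xs * ys) / s2
            logdet += ni * np.log(s2) + np.log1p(ni * tau2 / s2)
        beta = np.linalg.solve(XtVX, XtVy)
        return beta, XtVX, logdet

    def _quadform(self, beta, tau2, sig2) -> float:
        q = 0.0
        for sl, gi in self.blocks:
            s2 = sig2[0] if self.shared else sig2[gi]
            r = self.y[sl] - self.X[sl] @ beta
            ni = r.size
            shrink = tau2 / (s2 + ni * tau2)
            q += (r @ r - shrink * r.sum() ** 2) / s2
        return q

    def negloglik(self, theta: np.ndarray) -> float:
        tau2 = np.exp(theta[0])
        sig2 = np.exp(theta[1:])
        try:
            beta, _, logdet = self._gls(tau2, sig2)
        except np.linalg.LinAlgError:
            return 1e12
        q = self._quadform(beta, tau2, sig2)
        return 0.5 * (logdet + q + self.n * np.log(2.0 * np.pi))

    def fit(self):
        resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        v0 = max(resid.var(), 1e-8)
        x0 = np.log(np.full(1 + self.n_groups, v0 / 2.0))
        res = scipy.optimize.minimize(
            self.negloglik, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if not res.success:
            raise ConvergenceError(
                f"mixed-model ML fit did not converge: {res.message} "
                f"(nit={res.nit}, fun={res.fun:.6g})"
            )
        tau2 = float(np.exp(res.x[0]))
        sig2 = np.exp(res.x[1:])
        beta, XtVX, _ = self._gls(tau2, sig2)
        cov = np.linalg.inv(XtVX)
        return beta, cov, tau2, sig2, -float(res.fun)


def _maxt_adjust(tvals: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step max-|t| adjusted p-values via common-draw Monte Carlo."""
    rng = np.random.default_rng(_MAXT_SEED)
    corr = corr + 1e-10 * np.eye(corr.shape[0])
    L = np.linalg.cholesky(corr)
    draws = rng.standard_normal((_MAXT_DRAWS, corr.shape[0])) @ L.T
    maxabs = np.abs(draws).max(axis=1)
    return np.array([
        (np.count_nonzero(maxabs >= abs(t)) + 1) / (_MAXT_DRAWS + 1)
        for t in tvals
    ])


def _adjust(pvals: np.ndarray, tvals: np.ndarray, corr: np.ndarray,
            method: str) -> np.ndarray:
    m = pvals.size
    if method == "max-t":
        adj = _maxt_adjust(tvals, corr)
    elif method == "bonferroni":
        adj = np.minimum(1.0, pvals * m)
    elif method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * pvals[i])
            adj[i] = min(1.0, running)
    else:
        raise ParameterError(f"unknown adjustment method {method!r}")
    return np.maximum(adj, pvals)


def fit_kscore_model(
    table: pd.DataFrame,
    group_col: str = "group",
    contrast_pairs: Sequence[tuple[str, str]] | None = None,
    adjustment: str = "max-t",
    shared_residual_variance: bool = False,
) -> MixedModelResult:
    """Heteroskedastic random-intercept model of a K-Score table.

    ``table`` must hold one landmark set with columns subject_id,
    ``group_col``, repetition_index and kscore. Fixed effects are the
    saturated group x repetition means model; each subject gets a random
    intercept; each group its own residual variance (unless
    ``shared_residual_variance``). Estimation is maximum likelihood, the
    group x repetition interaction is tested by likelihood ratio against the
    additive model, and per-repetition contrasts for each requested group
    pair are adjusted by the chosen single-step method.
    """
    required = {"subject_id", group_col, "repetition_index", "kscore"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"K-Score table missing columns {sorted(missing)}")
    if "landmark_set" in table.columns and table["landmark_set"].nunique() > 1:
        raise ParameterError("fit one landmark set at a time")

    groups = table[group_col].to_numpy()
    reps = table["repetition_index"].to_numpy()
    y = table["kscore"].to_numpy(dtype=float)
    sid = table["subject_id"].to_numpy()
    g_levels = sorted(pd.unique(groups).tolist())
    r_levels = sorted(pd.unique(reps).tolist())
    if len(g_levels) < 2:
        raise ModelError("need at least 2 groups")
    for gl in g_levels:
        if pd.unique(sid[groups == gl]).size < 2:
            raise ModelError(f"group {gl!r} has fewer than 2 subjects")

    subj_group = {s: g for s, g in zip(sid, groups)}
    sgroups = np.array([subj_group[s] for s in sid])

    X_full = _design(groups, reps, g_levels, r_levels, interaction=True)
    ml_full = _BlockML(y, X_full, sid, sgroups, g_levels,
                       shared_residual_variance)
    beta, cov, tau2, sig2, ll_full = ml_full.fit()

    X_add = _design(groups, reps, g_levels, r_levels, interaction=False)
    ml_add = _BlockML(y, X_add, sid, sgroups, g_levels,
                      shared_residual_variance)
    _, _, _, _, ll_add = ml_add.fit()
    lr_df = (len(g_levels) - 1) * (len(r_levels) - 1)
    lr_stat = max(0.0, 2.0 * (ll_full - ll_add))
    lr_p = float(scipy.stats.chi2.sf(lr_stat, lr_df))

    names = _param_names(g_levels, r_levels, interaction=True)

    def cell_row(gl, rl):
        x = np.zeros(len(names))
        x[0] = 1.0
        if gl != g_levels[0]:
            x[names.index(f"group[{gl}]")] = 1.0
        if rl != r_levels[0]:
            x[names.index(f"rep[{rl}]")] = 1.0
        if gl != g_levels[0] and rl != r_levels[0]:
            x[names.index(f"group[{gl}]:rep[{rl}]")] = 1.0
        return x

    # observed and fitted cell summaries (published-table layout)
    cells = []
    for gl in g_levels:
        for rl in r_levels:
            mask = (groups == gl) & (reps == rl)
            cells.append(dict(
                group=gl, repetition=rl, n=int(mask.sum()),
                mean=float(y[mask].mean()) if mask.any() else np.nan,
                sd=float(y[mask].std(ddof=1)) if mask.sum() > 1 else np.nan,
                fitted=float(cell_row(gl, rl) @ beta),
            ))
    cell_means = pd.DataFrame(cells)

    if contrast_pairs is None:
        contrast_pairs = [
            (g_levels[i], g_levels[j])
            for i in range(len(g_levels)) for j in range(i + 1, len(g_levels))
        ]
    cvecs, labels = [], []
    for ga, gb in contrast_pairs:
        for rl in r_levels:
            cvecs.append(cell_row(ga, rl) - cell_row(gb, rl))
            labels.append(f"{ga} - {gb} @ rep {rl}")
    C = np.array(cvecs)
    est = C @ beta
    vmat = C @ cov @ C.T
    se = np.sqrt(np.diag(vmat))
    tvals = est / se
    corr = vmat / np.outer(se, se)
    p_raw = 2.0 * scipy.stats.norm.sf(np.abs(tvals))
    p_adj = _adjust(p_raw, tvals, corr, adjustment)
    contrasts = [
        ComparisonResult(
            label=lab, estimate=float(e), se=float(s),
            p_raw=float(pr), p_adjusted=float(pa), adjustment=adjustment,
        )
        for lab, e, s, pr, pa in zip(labels, est, se, p_raw, p_adj)
    ]

    residual_sd = (
        {"all": float(np.sqrt(sig2[0]))} if shared_residual_variance
        else {gl: float(np.sqrt(s2)) for gl, s2 in zip(g_levels, sig2)}
    )
    return MixedModelResult(
        loglik=ll_full,
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        random_intercept_sd=float(np.sqrt(tau2)),
        residual_sd=residual_sd,
        cell_means=cell_means,
        contrasts=contrasts,
        interaction_stat=lr_stat,
        interaction_df=lr_df,
        interaction_p=lr_p,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Pain ~ biomechanics regressions
# ---------------------------------------------------------------------------

def subject_mean_kscores(
    table: pd.DataFrame, landmark_set: str = "trunk"
) -> pd.Series:
    """Per-subject mean K-Score over repetitions 2-5 for one landmark set."""
    sub = table[table["landmark_set"] == landmark_set]
    if sub.empty:
        raise ParameterError(f"no rows for landmark set {landmark_set!r}")
    return sub.groupby("subject_id")["kscore"].mean()


def regress_pain_on_kscore(
    mean_kscores: pd.Series,
    subjects: pd.DataFrame,
    pain_measure: str,
    stratify_sex: bool = False,
) -> dict[str, RegressionResult]:
    """OLS of repetition-averaged K-Scores on rank-transformed predictors.

    Predictors (the pain measure, age, BMI) are Spearman-rank transformed;
    the outcome stays on its original scale. Returns one result per stratum
    (key "all", or "F"/"M" when stratified by sex).
    """
    df = subjects.set_index("subject_id").join(
        mean_kscores.rename("mean_kscore"), how="inner"
    )
    strata = (
        {s: df[df["sex"] == s] for s in ("F", "M")} if stratify_sex
        else {"all": df}
    )
    out: dict[str, RegressionResult] = {}
    for key, sub in strata.items():
        sub = sub.dropna(subset=[pain_measure, "age_years", "bmi", "mean_kscore"])
        if len(sub) < 10:
            raise ModelError(
                f"stratum {key!r}: need >= 10 subjects, got {len(sub)}"
            )
        preds = {}
        for col in (pain_measure, "age_years", "bmi"):
            vals = sub[col].to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                raise ModelError(f"predictor {col} is constant in stratum {key!r}")
            preds[col] = scipy.stats.rankdata(vals)
        X = sm.add_constant(np.column_stack(list(preds.values())))
        fit = sm.OLS(sub["mean_kscore"].to_numpy(dtype=float), X).fit()
        r2 = float(np.clip(fit.rsquared, 0.0, 1.0))
        out[key] = RegressionResult(
            outcome="mean_kscore",
            predictors=(pain_measure, "age_years", "bmi"),
            n=len(sub),
            r_squared=r2,
            p_value=float(fit.pvalues[1]),
            slope=float(fit.params[1]),
            strength=classify_r2(r2),
        )
    return out


def attach_ppt_sites(subjects: pd.DataFrame) -> pd.DataFrame:
    """Add per-site averaged PPT columns from the three raw readings."""
    df = subjects.copy()
    for site in ("control", "pain"):
        cols = [f"ppt_{site}_{i}_kpa" for i in (1, 2, 3)]
        df[f"ppt_{site}_site"] = [
            aggregate_ppt(row) for row in df[cols].to_numpy()
        ]
    return df
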