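"""Longitudinal two-group statistics for network outcomes.

The primary analysis is a mixed model for repeated measures (MMRM) on the
post-baseline visits: outcome ~ group * visit + baseline + sample rate,
with random intercepts for (pooled) site and for subject nested in site,
estimated by REML. The treatment signal is read off two contrasts:

* trajectory -- the joint 2-df Wald F-test of the group difference at
  week 12 and at week 24 (the "difference in trajectories" between arms);
* endpoint -- the t contrast of the group difference at week 24.

Missing baseline covariates are imputed with the site mean; small sites
are pooled before entering as a random effect. The exploratory memory
association fits memory ~ outcome + outcome^2 and tests the quadratic
term against the linear-only model, per time point and (per group) in a
subject-level mixed model across time points.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import AssociationResult, MMRMResult

POST_VISITS = ("wk12", "wk24")


def impute_baseline_site_mean(data: pd.DataFrame) -> pd.DataFrame:
    """Fill missing baseline covariates with the site-mean baseline.

    The mean is taken over subjects (not rows) with an observed baseline
    within the same site; sites with no observed baseline fall back to
    the grand mean with a warning. Adds a boolean ``baseline_imputed``
    column.
    """
    df = data.copy()
    subj = df.drop_duplicates("subject_id")[
        ["subject_id", "site_id", "baseline_value"]]
    site_means = subj.groupby("site_id")["baseline_value"].mean()
    grand = subj["baseline_value"].mean()
    if np.isnan(grand):
        raise ValueError("no observed baselines anywhere: cannot impute")
    missing = df["baseline_value"].isna()
    df["baseline_imputed"] = missing
    fill = df.loc[missing, "site_id"].map(site_means)
    if fill.isna().any():
        warnings.warn(
            "site(s) with no observed baseline: grand mean imputed",
            stacklevel=2,
        )
        fill = fill.fillna(grand)
    df.loc[missing, "baseline_value"] = fill
    return df


def pool_small_sites(data: pd.DataFrame, min_n: int = 16) -> pd.DataFrame:
    """Merge small sites until every pooled site has >= ``min_n`` subjects.

    Repeatedly merges the two smallest pools (smallest first) while any
    pool is below ``min_n`` and more than one pool remains. The pooled
    assignment replaces ``site_id``; the mapping from original sites to
    pooled sites is recorded on ``DataFrame.attrs['site_pooling']``.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    df = data.copy()
    sizes = (df.drop_duplicates("subject_id").groupby("site_id").size()
             .sort_values())
    pools: list[tuple[list[str], int]] = [([s], int(c)) for s, c in sizes.items()]
    while len(pools) > 1 and min(c for _, c in pools) < min_n:
        pools.sort(key=lambda x: (x[1], x[0][0]))
        a, b = pools[0], pools[1]
        pools = pools[2:] + [(sorted(a[0] + b[0]), a[1] + b[1])]
    mapping = {}
    for members, _ in sorted(pools, key=lambda x: x[0][0]):
        name = "+".join(members) if len(members) > 1 else members[0]
        for m in members:
            mapping[m] = name
    df["site_id"] = df["site_id"].map(mapping)
    df.attrs["site_pooling"] = mapping
    return df


def _fixed_formula(outcome_col: str, df: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Build the fixed-effect formula, standardizing the covariates.

    Continuous covariates are z-scored before the fit (sample rates are
    O(100) while outcomes are O(1); the raw scale conditions the REML
    optimization badly). Covariates without variance (single-rate
    studies, degenerate fixtures) are dropped to keep the design full
    rank. Group and visit contrasts are unaffected by either choice.
    """
    df = df.copy()
    terms = [f"{outcome_col} ~ C(group, Treatment('control'))"
             " * C(visit, Treatment('wk12'))"]
    for cov in ("baseline_value", "sample_rate_hz"):
        if cov in df.columns and df[cov].nunique(dropna=True) > 1:
            z = f"{cov}_z"
            df[z] = (df[cov] - df[cov].mean()) / df[cov].std(ddof=0)
            terms.append(z)
    return " + ".join(terms), df


def fit_mmrm(data: pd.DataFrame, outcome_col: str = "outcome",
             df_method: str = "between_within") -> MMRMResult:
    """Fit the MMRM and compute trajectory/endpoint contrasts and ICC.

    Parameters
    ----------
    data : tidy longitudinal table; only the post-baseline rows (wk12,
        wk24) enter as outcomes. Baselines are imputed on the fly (with a
        warning) when missing values remain.
    df_method : denominator-df approximation for the Wald tests.
        "between_within" (default): n_obs - n_subjects - p_within, with
        p_within the fixed-effect columns involving visit.
        "residual": n_obs - rank(X).

    Notes
    -----
    ICC is reported as (site variance + subject variance) / total
    variance -- the share of outcome variance attributable to the
    grouping structure.
    """
    if df_method not in ("between_within", "residual"):
        raise ValueError(f"unknown df_method {df_method!r}")
    df = data[data["visit"].isin(POST_VISITS)].copy()
    if df.empty:
        raise ValueError("no post-baseline rows to analyse")
    caught: list[str] = []
    if df["baseline_value"].isna().any():
        caught.append("missing baselines imputed with site means")
        df = impute_baseline_site_mean(df)
    df = df.dropna(subset=[outcome_col])
    formula, df = _fixed_formula(outcome_col, df)

    def _fit(frame, with_site):
        """Best-of-portfolio REML fit.

        The REML optimum frequently lies on the variance boundary, where
        single-optimizer runs can stall short of it; running the default
        gradient method and Powell and keeping the higher restricted
        likelihood is deterministic and invariant to row order and to
        site relabeling (verified against lme4 on the same data).
        """
        if with_site:
            model = smf.mixedlm(
                formula, frame, groups=frame["site_id"],
                re_formula="1",
                vc_formula={"subject": "0 + C(subject_id)"},
            )
        else:
            model = smf.mixedlm(formula, frame,
                                groups=frame["subject_id"])
        candidates, msgs = [], []
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always", ConvergenceWarning)
            for method in (None, "powell"):
                try:
                    r = (model.fit(reml=True) if method is None
                         else model.fit(reml=True, method=method,
                                        maxiter=2000))
                except (np.linalg.LinAlgError, ValueError) as exc:
                    msgs.append(f"optimizer {method or 'default'} "
                                f"failed: {exc}")
                    continue
                if np.isfinite(r.fe_params).all() and np.isfinite(r.llf):
                    candidates.append(r)
        msgs.extend(str(w.message) for w in wrec)
        if not candidates:
            raise np.linalg.LinAlgError("all optimizers failed")
        best = max(candidates, key=lambda r: r.llf)
        return best, msgs

    site_dropped = False
    try:
        res, msgs = _fit(df, with_site=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        res, msgs = None, [f"three-level fit failed: {exc}"]
    if res is None:
        res, msgs2 = _fit(df, with_site=False)
        msgs = msgs + msgs2
        site_dropped = True
        caught.append("site variance singular: refit with subject "
                      "random intercept only")
    caught.extend(msgs)

    fe = res.fe_params
    names = list(fe.index)
    V = np.asarray(res.cov_params())[:len(names), :len(names)]
    b = np.asarray(fe)

    grp_hits = [i for i, nm in enumerate(names)
                if "group" in nm and "[T.active]" in nm and ":" not in nm]
    if len(grp_hits) != 1:
        raise RuntimeError(f"group main-effect column lookup failed: {names}")
    i_grp = grp_hits[0]
    i_int = [i for i, nm in enumerate(names)
             if "group" in nm and "visit" in nm and ":" in nm]
    # group difference at wk12 and wk24 (wk12 is the visit reference)
    L = np.zeros((2, len(names)))
    L[0, i_grp] = 1.0
    L[1, i_grp] = 1.0
    for i in i_int:
        L[1, i] = 1.0

    n_obs = len(df)
    n_subjects = df["subject_id"].nunique()
    p = len(names)
    p_within = sum(1 for nm in names if "visit" in nm)
    if df_method == "between_within":
        ddf = float(n_obs - n_subjects - p_within)
    else:
        ddf = float(n_obs - p)
    ddf = max(ddf, 1.0)

    Lb = L @ b
    LVL = L @ V @ L.T
    W = float(Lb @ np.linalg.solve(LVL, Lb))
    traj_F = W / L.shape[0]
    traj_p = float(sps.f.sf(traj_F, L.shape[0], ddf))

    c = L[1]
    est = float(c @ b)
    se = float(np.sqrt(c @ V @ c))
    t = est / se
    end_p = float(2 * sps.t.sf(abs(t), ddf))

    if site_dropped:
        var_site = 0.0
        var_subject = float(res.cov_re.iloc[0, 0])
    else:
        var_site = float(res.cov_re.iloc[0, 0])
        var_subject = float(res.vcomp[0])
    var_resid = float(res.scale)
    total = var_site + var_subject + var_resid
    icc = (var_site + var_subject) / total if total > 0 else 0.0

    return MMRMResult(
        params={nm: float(v) for nm, v in fe.items()},
        trajectory_F=float(traj_F), trajectory_df=(2, ddf),
        trajectory_p=traj_p,
        endpoint_estimate=est, endpoint_se=se, endpoint_t=float(t),
        endpoint_df=ddf, endpoint_p=end_p,
        icc=float(icc), var_site=var_site, var_subject=var_subject,
        var_residual=var_resid, converged=bool(res.converged),
        df_method=df_method, n_obs=n_obs, n_subjects=n_subjects,
        site_dropped=site_dropped, warnings_=caught,
    )


class TrajectoryMMRM(BaseEstimator):
    """MMRM trajectory analysis as an sklearn-style estimator.

    fit(data) imputes missing baselines with site means, pools small
    sites, fits the REML mixed model and exposes the contrasts as fitted
    attributes (``trajectory_F_``, ``trajectory_p_``, ``endpoint_t_``,
    ``endpoint_p_``, ``icc_``, ``result_``).

    Parameters
    ----------
    outcome_col : name of the outcome column (default "outcome").
    pool_min_n : minimum subjects per pooled site (default 16); None
        disables pooling.
    df_method : "between_within" (default) or "residual".
    """

    def __init__(self, outcome_col: str = "outcome",
                 pool_min_n: int | None = 16,
                 df_method: str = "between_within"):
        self.outcome_col = outcome_col
        self.pool_min_n = pool_min_n
        self.df_method = df_method

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        if df["baseline_value"].isna().any():
            df = impute_baseline_site_mean(df)
        if self.pool_min_n is not None:
            df = pool_small_sites(df, self.pool_min_n)
        self.result_ = fit_mmrm(df, outcome_col=self.outcome_col,
                                df_method=self.df_method)
        self.trajectory_F_ = self.result_.trajectory_F
        self.trajectory_p_ = self.result_.trajectory_p
        self.endpoint_t_ = self.result_.endpoint_t
        self.endpoint_p_ = self.result_.endpoint_p
        self.icc_ = self.result_.icc
        return self


def association_per_timepoint(data: pd.DataFrame, timepoint: str,
                              group: str | None = None,
                              outcome_col: str = "outcome") -> AssociationResult:
    """Quadratic-vs-linear memory association at one visit.

    At baseline the arms are combined (pass group=None); at the
    post-baseline visits each arm is analysed separately. Fits
    memory_z ~ outcome + outcome^2 by OLS and reports the 1-df F-test of
    the quadratic term against the linear-only model.
    """
    df = data[data["visit"] == timepoint]
    if group is not None:
        df = df[df["group"] == group]
    df = df.dropna(subset=[outcome_col, "memory_z"])
    if len(df) < 10:
        raise ValueError(
            f"only {len(df)} complete pairs at {timepoint}: need >= 10"
        )
    x = df[outcome_col] - df[outcome_col].mean()  # center: conditioning
    X2 = sm.add_constant(np.column_stack([x, x ** 2]))
    fit2 = sm.OLS(df["memory_z"], X2).fit()
    t_quad = fit2.tvalues[2]
    return AssociationResult(
        statistic=float(t_quad ** 2), p_value=float(fit2.pvalues[2]),
        quadratic_coef=float(fit2.params[2]),
        linear_coef=float(fit2.params[1]),
        group=group, timepoint=timepoint, model="per_timepoint", n=len(df),
    )


def association_mixed(data: pd.DataFrame, group: str,
                      outcome_col: str = "outcome") -> AssociationResult:
    """Quadratic memory association across visits, per group.

    Mixed model of memory_z on outcome and outcome^2 with a subject
    random intercept, pooling the group's data over all visits. Falls
    back to OLS (flagged) when no subject has repeated visits.
    """
    df = data[data["group"] == group].dropna(
        subset=[outcome_col, "memory_z"]).copy()
    if len(df) < 10:
        raise ValueError(f"only {len(df)} complete rows for group {group!r}")
    df["x_c"] = df[outcome_col] - df[outcome_col].mean()
    df["x_c2"] = df["x_c"] ** 2
    repeated = (df.groupby("subject_id").size() > 1).any()
    degenerate = not repeated
    if repeated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = smf.mixedlm("memory_z ~ x_c + x_c2", df,
                              groups=df["subject_id"]).fit(reml=True)
        params, pvals, tvals = res.fe_params, res.pvalues, res.tvalues
    else:
        res = smf.ols("memory_z ~ x_c + x_c2", df).fit()
        params, pvals, tvals = res.params, res.pvalues, res.tvalues
    return AssociationResult(
        statistic=float(tvals["x_c2"] ** 2),
        p_value=float(pvals["x_c2"]),
        quadratic_coef=float(params["x_c2"]),
        linear_coef=float(params["x_c"]),
        group=group, timepoint=None, model="mixed", n=len(df),
        degenerate_random_effect=degenerate,
    )


def descriptive_table(data: pd.DataFrame,
                      outcome_col: str = "outcome") -> pd.DataFrame:
    """Per-group, per-visit mean (SD) [n] summary of an outcome."""
    rows = []
    for (group, visit), sub in data.groupby(["group", "visit"]):
        vals = sub[outcome_col].dropna()
        rows.append({
            "group": group, "visit": visit, "n": len(vals),
            "mean": vals.mean(), "sd": vals.std(ddof=1),
            "cell": f"{vals.mean():.3f} ({vals.std(ddof=1):.3f}) [{len(vals)}]",
        })
    return pd.DataFrame(rows).sort_values(["group", "visit"]).reset_index(drop=True)
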