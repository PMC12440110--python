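"""Seed-to-ROI connectivity and the covariate-adjusted association layer.

Every analysis in the pipeline that relates a per-subject quantity (a
connectivity estimate, an influence degree, a model parameter) to group
membership or a symptom/hormone score goes through this module: OLS group
contrasts with nuisance covariates, residualization-based partial
correlations, Benjamini-Hochberg FDR over ROI families, rank tests, a
trial-level mixed model for learning curves, and cross-state Spearman
correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AssociationResult",
    "seed_roi_connectivity",
    "connectivity_table",
    "fit_adjusted_regression",
    "adjusted_group_difference",
    "adjusted_partial_correlation",
    "bh_fdr",
    "rank_sum_test",
    "signed_rank_test",
    "learning_mixed_model",
    "cross_state_spearman",
]


@dataclass
class AssociationResult:
    """One association analysis row: effect size, test statistic, p, optional q."""

    analysis_id: str
    coefficient: float
    statistic: float
    p_uncorr: float
    n: int
    covariates: tuple[str, ...] = ()
    q_fdr: float | None = None
    family_id: str | None = None
    family_size: int | None = None

    def to_dict(self) -> dict:
        return {
            "analysis_id": self.analysis_id,
            "coefficient": self.coefficient,
            "statistic": self.statistic,
            "p_uncorr": self.p_uncorr,
            "q_fdr": self.q_fdr,
            "n": self.n,
            "covariates": ",".join(self.covariates),
            "family_id": self.family_id,
            "family_size": self.family_size,
        }


def _clip_r(r: float) -> float:
    return float(np.clip(r, -0.99, 0.99))


def seed_roi_connectivity(panel: np.ndarray, seed_idx: int, roi_idx: int) -> float:
    """Fisher-z Pearson correlation between a seed node's series and one ROI's.

    Perfect correlations are pulled to 0.99 before atanh (shared clip policy
    with the dependency-network code).
    """
    panel = np.asarray(panel, dtype=float)
    if panel.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    x, y = panel[seed_idx], panel[roi_idx]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant time series: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.arctanh(_clip_r(r)))


def connectivity_table(
    panels: list[np.ndarray],
    subject_ids: list[str],
    node_names: list[str],
    seed: str,
    state: str = "task_free",
) -> pd.DataFrame:
    """Subject x ROI Fisher-z seed-to-ROI table for one brain state."""
    seed_idx = node_names.index(seed)
    rois = [nm for nm in node_names if nm != seed]
    rows = {}
    for sid, panel in zip(subject_ids, panels, strict=True):
        rows[sid] = [
            seed_roi_connectivity(panel, seed_idx, node_names.index(roi)) for roi in rois
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=rois)
    out.index.name = "subject_id"
    out["state"] = state
    return out


def _design_matrix(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design columns; binary categoricals are dummy-coded."""
    X = pd.DataFrame(index=cohort.index)
    for col in columns:
        s = cohort[col]
        if s.dtype == object or s.dtype.name in ("category", "bool"):
            levels = sorted(pd.unique(s.dropna()))
            if len(levels) > 2:
                raise ValueError(f"column {col!r} has >2 levels; pre-code it numerically")
            X[col] = (s == levels[-1]).astype(float)
        else:
            X[col] = s.astype(float)
    return X


def fit_adjusted_regression(
    values: np.ndarray,
    cohort: pd.DataFrame,
    predictor: str,
    covariates: list[str],
    analysis_id: str = "",
) -> AssociationResult:
    """OLS of ``values`` on predictor + covariates; reports the predictor row.

    Rows with missing values in the outcome, predictor or covariates are
    dropped listwise. Rank-deficient designs raise an error naming the
    collinear columns.
    """
    y = pd.Series(np.asarray(values, dtype=float), index=cohort.index, name="y")
    X = _design_matrix(cohort, [predictor] + list(covariates))
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        pairs = [
            f"{a}~{b}"
            for a, b in itertools.combinations(X.columns, 2)
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(X.columns)}")
    fit = sm.OLS(y, Xc).fit()
    return AssociationResult(
        analysis_id=analysis_id or f"y~{predictor}",
        coefficient=float(fit.params[predictor]),
        statistic=float(fit.tvalues[predictor]),
        p_uncorr=float(fit.pvalues[predictor]),
        n=int(fit.nobs),
        covariates=tuple(covariates),
    )


def adjusted_group_difference(
    values_by_roi: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: list[str],
    group_col: str = "group",
    family_id: str = "roi",
) -> list[AssociationResult]:
    """Covariate-adjusted group contrast per ROI column, BH-corrected as a family."""
    results = []
    for roi in values_by_roi.columns:
        res = fit_adjusted_regression(
            values_by_roi[roi].to_numpy(), cohort, group_col, covariates,
            analysis_id=f"{roi}~{group_col}",
        )
        res.family_id = family_id
        results.append(res)
    _attach_fdr(results)
    return results


def adjusted_partial_correlation(
    values: np.ndarray,
    score: np.ndarray,
    covariates: pd.DataFrame | None = None,
    analysis_id: str = "partial_r",
) -> AssociationResult:
    """Partial Pearson correlation via double residualization.

    Both ``values`` and ``score`` are residualized on the covariates (with
    intercept) and the residuals correlated; the t test uses n - 2 - k
    degrees of freedom. With no covariates this reduces to the plain Pearson
    correlation.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(score, dtype=float)
    if covariates is not None and covariates.shape[1] > 0:
        Z = sm.add_constant(_design_matrix(covariates, list(covariates.columns)).to_numpy())
        keep = np.isfinite(y) & np.isfinite(x) & np.isfinite(Z).all(axis=1)
        y, x, Z = y[keep], x[keep], Z[keep]
        k = Z.shape[1] - 1
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        cov_names = tuple(covariates.columns)
    else:
        keep = np.isfinite(y) & np.isfinite(x)
        y, x = y[keep], x[keep]
        k = 0
        cov_names = ()
    n = y.size
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough observations (n={n}) for {k} covariates")
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return AssociationResult(analysis_id, r, float(t), p, n, cov_names)


def _attach_fdr(results: list[AssociationResult]) -> None:
    qs = bh_fdr(np.array([r.p_uncorr for r in results]))
    for r, q in zip(results, qs):
        r.q_fdr = float(q)
        r.family_size = len(results)


def adjusted_partial_correlation_family(
    values_by_roi: pd.DataFrame,
    score: np.ndarray,
    covariates: pd.DataFrame | None,
    family_id: str = "roi",
) -> list[AssociationResult]:
    """Partial correlation of one score against each ROI column, BH family-corrected."""
    results = []
    for roi in values_by_roi.columns:
        res = adjusted_partial_correlation(
            values_by_roi[roi].to_numpy(), score, covariates, analysis_id=f"{roi}~score"
        )
        res.family_id = family_id
        results.append(res)
    _attach_fdr(results)
    return results


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))  # midranks
    return float(ranks[: x.size].sum())


def rank_sum_test(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test for independent samples.

    Returns (W, p) where W is the rank sum of ``x`` with midranks for ties.
    When the pooled sample is small (total size <= ``exact_max_n``) the
    two-sided p comes from full enumeration of all group assignments, which
    remains valid under ties; larger samples use the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    w = _rank_sum_statistic(x, y)
    n1, n2 = x.size, y.size
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if n <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        stats = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n1)]
        )
        p = float(np.mean(np.abs(stats - mu) >= np.abs(w - mu) - 1e-12))
    else:
        ranks = sps.rankdata(np.concatenate([x, y]))
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            return w, 1.0
        z = (w - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return w, min(p, 1.0)


def signed_rank_test(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided), for within-subject contrasts."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def learning_mixed_model(
    trial_table: pd.DataFrame, family: str = "linear"
) -> pd.DataFrame:
    """Mixed model for learning curves: correct ~ group * trial_type + trial + (1|subject).

    ``trial_table`` needs columns subject_id, group, trial_type (gain/loss
    rows only are used), trial and correct. The default fit is a linear
    mixed-effects model on the binary outcome with a random intercept per
    participant; ``family='logistic'`` switches to a GEE logistic fit with an
    exchangeable working correlation. Returns the fixed-effect table with the
    group x trial-type interaction row labelled ``interaction``.
    """
    df = trial_table[trial_table["trial_type"].isin(["gain", "loss"])].copy()
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    df["correct"] = df["correct"].astype(float)
    df["group_c"] = (df["group"] == sorted(df["group"].unique())[-1]).astype(float)
    # gain coded 1 so a reward-specific group deficit loads on the interaction
    df["type_c"] = (df["trial_type"] == "gain").astype(float)
    formula = "correct ~ group_c * type_c + trial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "linear":
            model = smf.mixedlm(formula, df, groups=df["subject_id"])
            fit = model.fit(reml=True, method="lbfgs")
            params, tvals, pvals = fit.fe_params, fit.tvalues, fit.pvalues
        elif family == "logistic":
            model = smf.gee(
                formula, groups="subject_id", data=df,
                family=sm.families.Binomial(), cov_struct=sm.cov_struct.Exchangeable(),
            )
            fit = model.fit()
            params, tvals, pvals = fit.params, fit.tvalues, fit.pvalues
        else:
            raise ValueError("family must be 'linear' or 'logistic'")
    rows = []
    label_map = {"group_c:type_c": "interaction"}
    for name in params.index:
        rows.append(
            {
                "term": label_map.get(name, name),
                "coef": float(params[name]),
                "stat": float(tvals[name]),
                "p": float(pvals[name]),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def cross_state_spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation between two per-subject vectors (e.g. the same
    connectivity estimate in task-free vs task-based states)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
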