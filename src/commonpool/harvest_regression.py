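"""ΔHarvest regressions with treatment interactions and cluster bootstrap.

Model 1 regresses the trial-to-trial harvest adjustment on the
participant's previous harvest, the current pool value, and an
overharvester-present indicator (underharvester/none as referent), each
interacted with a depleted-treatment indicator (control group as
referent). Model 2 keeps the structural main effects, adds the rank of
the previous harvest within the group norm together with its square and
cube, and interacts only the rank polynomial (and intercept) with
treatment.

Estimation is pooled ordinary least squares. Standard errors are
cluster-robust at the participant level; 95% confidence intervals come
from a participant-level (cluster) bootstrap. The default interval is
bootstrap-t (studentized with per-resample cluster-robust standard
errors), which is better calibrated than the raw percentile interval
when the number of clusters is small; plain percentile intervals are
available via ``ci_method="percentile"``. Standardized coefficients
z-score the response and every non-binary regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from commonpool.agent_models import Treatment

MODEL_TAGS = ("model1", "model2")

#: columns build_design needs in the tidy trial table
REQUIRED_COLUMNS = (
    "participant_id",
    "treatment",
    "own_harvest",
    "own_prev_harvest",
    "delta_harvest",
    "resource_before",
    "over_present",
    "rank",
    "rank2",
    "rank3",
)

_STRUCTURAL = ("own_prev_harvest", "resource_before", "over_present")
_RANK_TERMS = ("rank", "rank2", "rank3")


class DesignError(ValueError):
    """Raised when the trial table cannot support the requested design."""


@dataclass(frozen=True)
class RegressionResult:
    """Fitted coefficients for one model.

    ``table`` holds one row per term: raw estimate, cluster-robust SE,
    bootstrap percentile CI, and the standardized counterparts.
    """

    model_tag: str
    table: pd.DataFrame
    n_obs: dict[str, int]
    n_boot: int
    seed: int
    standardized: bool = True

    def __post_init__(self) -> None:
        bad = self.table.query("ci_low > estimate or estimate > ci_high")
        if len(bad):
            raise ValueError(f"CI does not bracket estimate for terms {list(bad.term)}")

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def build_design(
    rows: pd.DataFrame, model_tag: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Assemble the design matrix, response, and cluster ids for a model.

    First-trial rows (no previous harvest, hence no ΔHarvest) are
    dropped, as are rows where the pool ran short and truncated the
    player's request (when an ``own_request`` column is available):
    there the recorded harvest is censored by the environment rather
    than chosen, so its ΔHarvest does not reflect the policy. The
    depleted group (T–) is coded 1 against the control referent; the
    overharvester indicator is 1 when one or two salient overharvesters
    are present, with underharvesters (or none) as referent.
    """
    if model_tag not in MODEL_TAGS:
        raise DesignError(f"model_tag must be one of {MODEL_TAGS}")
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise DesignError(f"trial table missing columns: {missing}")
    data = rows.dropna(subset=["own_prev_harvest", "delta_harvest", "rank"]).copy()
    if "own_request" in data.columns:
        data = data[data["own_request"] == data["own_harvest"]]
    if data.empty:
        raise DesignError("no usable rows: every row lacks a previous harvest")
    treatments = set(data["treatment"].unique())
    if not treatments <= {t.value for t in Treatment}:
        raise DesignError(f"unrecognized treatment labels: {treatments}")
    if len(treatments) < 2:
        raise DesignError(
            "treatment interactions need both groups present, "
            f"found only {sorted(treatments)}"
        )
    treat = (data["treatment"] == Treatment.T_MINUS.value).astype(float)

    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["treatment"] = treat
    for col in _STRUCTURAL:
        X[col] = data[col].astype(float)
    if model_tag == "model1":
        for col in _STRUCTURAL:
            X[f"treatment:{col}"] = treat * data[col].astype(float)
    else:
        for col in _RANK_TERMS:
            X[col] = data[col].astype(float)
            X[f"treatment:{col}"] = treat * data[col].astype(float)
    y = data["delta_harvest"].astype(float).rename("delta_harvest")
    clusters = data["participant_id"].rename("participant_id")
    return X, y, clusters


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via QR pivoting on the correlation scale
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
            f"collinear terms: {bad or 'unidentified'}"
        )


def _standardize_scales(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, float]:
    """Per-column multipliers mapping raw coefficients to standardized ones."""
    sy = float(y.std(ddof=0))
    scales = np.ones(X.shape[1])
    for j, col in enumerate(X.columns):
        vals = X[col]
        unique = np.unique(vals)
        if col == "const" or set(unique) <= {0.0, 1.0}:
            continue  # intercept and binary indicators stay on the raw scale
        sx = float(vals.std(ddof=0))
        if sx > 0 and sy > 0:
            scales[j] = sx / sy
    return scales, sy


def _cluster_robust_se(
    X: np.ndarray, resid: np.ndarray, XtX_inv: np.ndarray, cluster_slices: list
) -> np.ndarray:
    """Sandwich standard errors clustering on participants."""
    k = X.shape[1]
    meat = np.zeros((k, k))
    for idx in cluster_slices:
        g = X[idx].T @ resid[idx]
        meat += np.outer(g, g)
    cov = XtX_inv @ meat @ XtX_inv
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_model(
    design: pd.DataFrame,
    response: pd.Series,
    cluster_ids: pd.Series,
    n_boot: int = 500,
    seed: int = 0,
    model_tag: str = "model1",
    ci_method: str = "bootstrap-t",
) -> RegressionResult:
    """Pooled OLS with participant-cluster bootstrap confidence intervals.

    Point estimates are ordinary least squares; standard errors are
    cluster-robust. The 95% CIs resample whole participants with
    replacement ``n_boot`` times; with ``ci_method="bootstrap-t"``
    (default) the interval is studentized on per-resample cluster-robust
    standard errors, with ``"percentile"`` it is the raw percentile
    interval of the resampled estimates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if ci_method not in ("bootstrap-t", "percentile"):
        raise ValueError("ci_method must be 'bootstrap-t' or 'percentile'")
    ids = np.asarray(cluster_ids)
    unique_ids = pd.unique(ids)
    if len(unique_ids) < 2:
        raise ValueError("cluster bootstrap needs at least 2 clusters")
    _check_full_rank(design)

    Xm = design.to_numpy(float)
    ym = response.to_numpy(float)
    ols = sm.OLS(ym, Xm)
    fit = ols.fit(cov_type="cluster", cov_kwds={"groups": ids})
    est = fit.params
    se = fit.bse

    # participant-level bootstrap
    rng = np.random.default_rng(seed)
    cluster_rows = {cid: np.flatnonzero(ids == cid) for cid in unique_ids}
    n_clusters = len(unique_ids)
    draws = np.empty((n_boot, Xm.shape[1]))
    tstats = np.empty((n_boot, Xm.shape[1]))
    for b in range(n_boot):
        chosen = rng.choice(unique_ids, size=n_clusters, replace=True)
        slices = [cluster_rows[c] for c in chosen]
        idx = np.concatenate(slices)
        Xb, yb = Xm[idx], ym[idx]
        XtX = Xb.T @ Xb
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            draws[b] = est
            tstats[b] = 0.0
            continue
        beta_b = XtX_inv @ (Xb.T @ yb)
        draws[b] = beta_b
        # studentize against per-resample cluster-robust SEs; resampled
        # clusters are treated as distinct even when drawn twice
        offsets = np.cumsum([0] + [len(s) for s in slices])
        local = [np.arange(offsets[i], offsets[i + 1]) for i in range(len(slices))]
        se_b = _cluster_robust_se(Xb, yb - Xb @ beta_b, XtX_inv, local)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstats[b] = np.where(se_b > 0, (beta_b - est) / se_b, 0.0)
    if ci_method == "bootstrap-t":
        t_low, t_high = np.percentile(tstats, [2.5, 97.5], axis=0)
        ci_low = est - t_high * se
        ci_high = est - t_low * se
    else:
        ci_low, ci_high = np.percentile(draws, [2.5, 97.5], axis=0)
    # degenerate guard: bootstrap CIs can exclude the full-sample point
    # estimate through resampling noise alone; widen to include it
    ci_low = np.minimum(ci_low, est)
    ci_high = np.maximum(ci_high, est)

    scales, _ = _standardize_scales(design, response)
    table = pd.DataFrame(
        {
            "term": design.columns,
            "estimate": est,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "estimate_std": est * scales,
            "se_std": se * scales,
            "ci_low_std": ci_low * scales,
            "ci_high_std": ci_high * scales,
        }
    ).reset_index(drop=True)

    treat_col = design["treatment"].to_numpy()
    n_obs = {
        Treatment.T_PLUS.value: int((treat_col == 0).sum()),
        Treatment.T_MINUS.value: int((treat_col == 1).sum()),
    }
    return RegressionResult(
        model_tag=model_tag,
        table=table,
        n_obs=n_obs,
        n_boot=n_boot,
        seed=seed,
    )


def fit_trial_table(
    rows: pd.DataFrame, model_tag: str, n_boot: int = 500, seed: int = 0
) -> RegressionResult:
    """Convenience: build the design from a tidy trial table and fit."""
    X, y, clusters = build_design(rows, model_tag)
    return fit_model(X, y, clusters, n_boot=n_boot, seed=seed, model_tag=model_tag)


def _stars(est: float, se: float) -> str:
    from scipy import stats

    if se <= 0 or not np.isfinite(se):
        return ""
    p = 2.0 * stats.norm.sf(abs(est / se))
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_fit(result: RegressionResult) -> pd.DataFrame:
    """Report table: term, estimate (SE), 95% CI, significance stars.

    Mirrors the shape of a standard coefficient table, with raw and
    standardized estimates side by side.
    """
    if result.table.empty:
        raise ValueError("cannot summarize an empty regression result")
    tab = result.table.copy()
    tab["stars"] = [_stars(e, s) for e, s in zip(tab.estimate, tab.se)]
    tab["formatted"] = [
        f"{e:.3f} ({s:.3f}){st}" for e, s, st in zip(tab.estimate, tab.se, tab.stars)
    ]
    tab["formatted_std"] = [
        f"{e:.3f} ({s:.3f})" for e, s in zip(tab.estimate_std, tab.se_std)
    ]
    tab.attrs["model_tag"] = result.model_tag
    tab.attrs["n_obs"] = result.n_obs
    return tab
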