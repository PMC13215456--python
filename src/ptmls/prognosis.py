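"""Latent-space survival screening, GMM subtyping and risk stratification.

Each latent dimension is screened by univariate Cox proportional-hazards
regression (Newton-Raphson on the Breslow-ties partial likelihood);
dimensions with Wald p below the screening threshold are retained. Patients
are clustered in the selected subspace with a Gaussian mixture model, the
number of components chosen by maximizing the mean silhouette coefficient.
The risk score is the Cox linear predictor over the selected dimensions
(sum of beta_j * z_j) and patients are split into high/low risk at the
training-set median; Kaplan-Meier curves, the two-group log-rank test and
the group hazard ratio quantify the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

__all__ = ["CoxScreenResult", "RiskModel", "cox_fit", "screen_latent",
           "gmm_cluster", "select_k", "fit_risk_model", "risk_score",
           "stratify", "km_estimate", "logrank", "group_hr"]

ALPHA_SCREEN = 0.05


@dataclass
class CoxScreenResult:
    dim: int
    beta: float
    se: float
    p: float
    selected: bool
    error: str = None


@dataclass
class RiskModel:
    selected_dims: list
    betas: np.ndarray
    dim_means: np.ndarray = None   # training-set standardization of dims
    dim_sds: np.ndarray = None
    median_cutoff: float = None
    k_selected: int = None
    cluster_labels: pd.Series = field(default=None, repr=False)
    screen: list = field(default=None, repr=False)


def _breslow_loglik_parts(beta, x, times, events):
    """Log partial likelihood and derivatives under Breslow tie handling."""
    order = np.argsort(times, kind="stable")
    x, times, events = x[order], times[order], events[order]
    eta = beta * x
    w = np.exp(eta)
    # cumulative risk-set sums from the end (subjects with time >= t_i)
    rs_w = np.cumsum(w[::-1])[::-1]
    rs_wx = np.cumsum((w * x)[::-1])[::-1]
    rs_wxx = np.cumsum((w * x * x)[::-1])[::-1]
    # for ties: risk set of an event time t = all with time >= t; map each
    # event to the first index of its time value
    first = np.searchsorted(times, times, side="left")
    ev = events == 1
    fi = first[ev]
    ll = np.sum(eta[ev]) - np.sum(np.log(rs_w[fi]))
    mean_x = rs_wx[fi] / rs_w[fi]
    grad = np.sum(x[ev]) - np.sum(mean_x)
    info = np.sum(rs_wxx[fi] / rs_w[fi] - mean_x ** 2)
    return ll, grad, info


def cox_fit(x, times, events, tol=1e-8, max_iter=50):
    """Univariate Cox PH fit: (beta, se, Wald p).

    Newton-Raphson maximization of the Breslow partial likelihood,
    convergence at |delta beta| < 1e-8 or 50 iterations. Raises on zero
    events, constant covariate, or monotone likelihood (perfect
    separation).
    """
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    beta = 0.0
    for _ in range(max_iter):
        ll, grad, info = _breslow_loglik_parts(beta, x, times, events)
        if info <= 1e-12:
            raise ValueError("non-convergent: vanishing information")
        step = grad / info
        # step-halving to keep the likelihood finite
        while abs(step) > 5.0:
            step /= 2.0
        beta_new = beta + step
        if abs(beta_new) > 50.0:
            raise ValueError("non-convergent: monotone likelihood")
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    _, _, info = _breslow_loglik_parts(beta, x, times, events)
    se = 1.0 / np.sqrt(info)
    p = 2.0 * sps.norm.sf(abs(beta) / se)
    return float(beta), float(se), float(p)


def screen_latent(latent, surv, alpha_screen=ALPHA_SCREEN):
    """Univariate Cox screen of each (standardized) latent dimension.

    ``latent`` is an n x m DataFrame; ``surv`` a DataFrame with ``time`` and
    ``event`` columns aligned on the same index. If no dimension clears the
    threshold, the single smallest-p dimension is kept with a warning.
    """
    surv = surv.loc[latent.index]
    t = surv["time"].to_numpy(float)
    e = surv["event"].to_numpy(int)
    if e.sum() < 10:
        warnings.warn("fewer than 10 events: screening will be unstable")
    results = []
    for j, col in enumerate(latent.columns):
        x = latent[col].to_numpy(float)
        sd = x.std()
        try:
            xs = (x - x.mean()) / sd if sd > 0 else x
            beta, se, p = cox_fit(xs, t, e)
            results.append(CoxScreenResult(j, beta, se, p, p < alpha_screen))
        except (ValueError, FloatingPointError) as exc:
            results.append(CoxScreenResult(j, np.nan, np.nan, np.nan, False,
                                           error=str(exc)))
    if not any(r.selected for r in results):
        ok = [r for r in results if np.isfinite(r.p)]
        if ok:
            best = min(ok, key=lambda r: r.p)
            best.selected = True
            warnings.warn("no dimension passed the screen; keeping the "
                          f"smallest-p dimension {best.dim}")
    return results


def gmm_cluster(z_sel, k, seed=0):
    """Diagonal-covariance GMM with 10 seeded k-means++ restarts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(z_sel, float)
    gm = GaussianMixture(n_components=k, covariance_type="diag", n_init=10,
                         init_params="k-means++", reg_covar=1e-6,
                         random_state=seed)
    labels = gm.fit_predict(X)
    return labels, gm.means_, gm.covariances_, float(gm.score(X) * len(X))


def select_k(z_sel, k_range=range(2, 7), seed=0):
    """Silhouette-maximizing component count; ties go to the smaller k."""
    X = np.asarray(z_sel, float)
    if len(X) < 3 * max(k_range):
        warnings.warn("few samples relative to k_max; silhouette unstable")
    best_k, best_s = None, -np.inf
    for k in k_range:
        try:
            labels, *_ = gmm_cluster(X, k, seed=seed)
            if len(np.unique(labels)) < 2:
                raise ValueError("degenerate clustering")
            s = silhouette_score(X, labels, metric="euclidean")
        except Exception as exc:  # noqa: BLE001 - skip infeasible k
            warnings.warn(f"k={k} failed: {exc}")
            continue
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no k in range produced a valid clustering")
    return best_k


def fit_risk_model(latent, surv, alpha_screen=ALPHA_SCREEN, seed=0,
                   cluster=True, k_range=range(2, 7)):
    """Screen dimensions, fit per-dimension betas, set the median cutoff."""
    screen = screen_latent(latent, surv, alpha_screen)
    sel = [r for r in screen if r.selected]
    dims = [latent.columns[r.dim] for r in sel]
    betas = np.array([r.beta for r in sel])
    z = latent[dims].to_numpy(float)
    sds = z.std(axis=0)
    sds[sds == 0] = 1.0
    model = RiskModel(selected_dims=dims, betas=betas, screen=screen,
                      dim_means=z.mean(axis=0), dim_sds=sds)
    risks = risk_score(model, latent)
    model.median_cutoff = float(np.median(risks))
    if cluster:
        z_sel = latent[dims].to_numpy(float)
        try:
            k = select_k(z_sel, k_range, seed=seed)
            labels, *_ = gmm_cluster(z_sel, k, seed=seed)
            model.k_selected = k
            model.cluster_labels = pd.Series(labels, index=latent.index)
        except ValueError as exc:
            warnings.warn(f"subtype clustering skipped: {exc}")
    return model


def risk_score(model, latent):
    """Cox linear predictor over selected dimensions.

    Dimensions are standardized with the training-set statistics stored in
    the model, so validation scoring uses training-derived quantities only.
    """
    if not model.selected_dims:
        raise ValueError("no selected dimensions")
    z = latent[model.selected_dims].to_numpy(float)
    zs = (z - model.dim_means) / model.dim_sds
    return pd.Series(zs @ model.betas, index=latent.index, name="risk")


def stratify(risk, median_cutoff):
    """High iff risk > cutoff; ties at the median go to low risk."""
    return pd.Series(np.where(risk > median_cutoff, "high", "low"),
                     index=risk.index, name="group")


def km_estimate(surv):
    """Kaplan-Meier product-limit curve as a (time, survival) DataFrame."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank(surv_a, surv_b):
    """Two-group log-rank test -> (chi2, p)."""
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("both groups must be nonempty")
    r = _ll_logrank(surv_a["time"], surv_b["time"],
                    event_observed_A=surv_a["event"],
                    event_observed_B=surv_b["event"])
    return float(r.test_statistic), float(r.p_value)


def group_hr(groups, surv):
    """Hazard ratio (high vs low) with 95% CI from the univariate Cox fit."""
    g = np.asarray(groups) == "high"
    if g.all() or (~g).all():
        raise ValueError("need both risk groups to estimate a hazard ratio")
    beta, se, p = cox_fit(g.astype(float), surv["time"].to_numpy(float),
                          surv["event"].to_numpy(int))
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return hr, ci, p
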