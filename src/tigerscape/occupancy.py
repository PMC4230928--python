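"""Single-season occupancy modeling with imperfect detection.

Implements the MacKenzie-style zero-inflated detection likelihood
P(history) = psi * prod_j p_j^y_j (1-p_j)^(1-y_j) + (1-psi) * 1{all zero},
with logit links on occupancy (psi) and per-survey detection (p), three
detection structures (constant, survey-specific, abundance-indexed), AIC
selection and model averaging, and a parametric-bootstrap goodness-of-fit
with the overdispersion statistic c-hat. Site covariates are first reduced
by PCA with varimax rotation, retaining components with eigenvalue > 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit


@dataclass
class SiteDetectionHistory:
    """Replicated detection/non-detection outcomes for one survey grid."""

    grid_id: str
    outcomes: list[int | None]
    covariates: dict[str, float] = field(default_factory=dict)
    abundance_index: float = 0.0
    flagged: str | None = None

    def n_surveys(self) -> int:
        return sum(1 for o in self.outcomes if o is not None)

    def detected(self) -> bool:
        return any(o == 1 for o in self.outcomes)


# ---------------------------------------------------------------------------
# Covariate reduction: PCA + varimax
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loadings matrix."""
    p, k = loadings.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - (lam * (lam ** 2).sum(axis=0)) / p))
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return rot


@dataclass
class CovariateReduction:
    loadings: pd.DataFrame          # covariate x retained PC, varimax-rotated
    eigenvalues: np.ndarray         # all eigenvalues, descending
    retained: int
    scores: pd.DataFrame            # site x retained PC, rotated
    variance_explained: np.ndarray  # per retained PC, % of total
    dropped: list[str] = field(default_factory=list)


def reduce_covariates(covariates: pd.DataFrame,
                      eigenvalue_min: float = 1.0) -> CovariateReduction:
    """PCA on the correlation matrix, keep eigenvalue > threshold, varimax.

    Covariates are standardized internally; constant columns are dropped
    with a warning. Rotated scores are regression scores and can be used
    directly as site covariates in the occupancy models.
    """
    if covariates.shape[1] < 2 or covariates.shape[0] < 3:
        raise ValueError("need at least 2 covariates and 3 sites")
    dropped = [c for c in covariates.columns if covariates[c].std() == 0]
    if dropped:
        warnings.warn(f"constant covariates dropped: {dropped}")
    x = covariates.drop(columns=dropped)
    z = (x - x.mean()) / x.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    retained = max(1, int(np.sum(vals > eigenvalue_min)))
    load = vecs[:, :retained] * np.sqrt(vals[:retained])
    rot = varimax(load) if retained > 1 else np.eye(1)
    load_rot = load @ rot
    # regression scores for the rotated solution
    scores = z.to_numpy() @ load_rot @ np.linalg.inv(load_rot.T @ load_rot)
    cols = [f"PC{i + 1}" for i in range(retained)]
    return CovariateReduction(
        loadings=pd.DataFrame(load_rot, index=x.columns, columns=cols),
        eigenvalues=vals, retained=retained,
        scores=pd.DataFrame(scores, index=covariates.index, columns=cols),
        variance_explained=100.0 * vals[:retained] / len(vals),
        dropped=dropped)


# ---------------------------------------------------------------------------
# Occupancy likelihood
# ---------------------------------------------------------------------------

DETECTION_MODELS = ("constant", "survey_specific", "abundance_index")


@dataclass
class OccupancyFit:
    model: str
    detection_model: str
    beta_psi: np.ndarray
    beta_p: np.ndarray
    se: np.ndarray | None
    neg2ll: float
    aic: float
    n_params: int
    psi_hat: np.ndarray
    p_hat: np.ndarray               # (n_sites, max_surveys)
    converged: bool
    psi_design: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def _design(histories: list[SiteDetectionHistory],
            psi_covariates: pd.DataFrame | None):
    sites = [h for h in histories if h.n_surveys() > 0]
    kmax = max(len(h.outcomes) for h in sites)
    y = np.full((len(sites), kmax), np.nan)
    for i, h in enumerate(sites):
        for j, o in enumerate(h.outcomes):
            if o is not None:
                y[i, j] = o
    if psi_covariates is None:
        x = np.ones((len(sites), 1))
    else:
        sub = psi_covariates.loc[[h.grid_id for h in sites]]
        x = np.column_stack([np.ones(len(sites)), sub.to_numpy(dtype=float)])
    abund = np.array([h.abundance_index for h in sites], dtype=float)
    return sites, y, x, abund


def _unpack(theta, n_psi, detection_model, kmax, abund, n_sites):
    bpsi = theta[:n_psi]
    bp = theta[n_psi:]
    if detection_model == "constant":
        p = np.full((n_sites, kmax), expit(bp[0]))
    elif detection_model == "survey_specific":
        p = np.tile(expit(bp)[None, :], (n_sites, 1))
    else:
        p = expit(bp[0] + bp[1] * abund)[:, None] * np.ones((1, kmax))
    return bpsi, p


def _neg_loglik(theta, x, y, abund, detection_model, kmax):
    n = len(y)
    n_psi = x.shape[1]
    bpsi, p = _unpack(theta, n_psi, detection_model, kmax, abund, n)
    psi = expit(x @ bpsi)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    obs = ~np.isnan(y)
    yy = np.where(obs, y, 0.0)
    log_bern = np.where(obs, yy * np.log(p) + (1 - yy) * np.log1p(-p), 0.0)
    cond = log_bern.sum(axis=1)
    detected = np.nansum(yy, axis=1) > 0
    with np.errstate(divide="ignore"):
        log_psi = np.log(np.clip(psi, 1e-300, 1.0))
        log_1mpsi = np.log(np.clip(1 - psi, 1e-300, 1.0))
    ll = np.where(detected,
                  log_psi + cond,
                  np.logaddexp(log_psi + cond, log_1mpsi))
    return -float(ll.sum())


def fit_occupancy(histories: list[SiteDetectionHistory],
                  psi_covariates: pd.DataFrame | None = None,
                  detection_model: str = "constant",
                  n_starts: int = 3, tol: float = 1e-8,
                  seed: int | None = None,
                  compute_se: bool = True,
                  model_label: str | None = None) -> OccupancyFit:
    """Maximum-likelihood single-season occupancy fit.

    ``psi_covariates`` (indexed by grid_id) enter psi's logit linearly; the
    detection model is constant, survey-specific, or a linear function of
    the grid's abundance index on p's logit. Sites with zero usable surveys
    are excluded; NA replicates are skipped in the likelihood. Quasi-Newton
    optimization with multiple starts guards against local optima.
    """
    if detection_model not in DETECTION_MODELS:
        raise ValueError(f"unknown detection model {detection_model}")
    sites, y, x, abund = _design(histories, psi_covariates)
    kmax = y.shape[1]
    n_psi = x.shape[1]
    n_p = {"constant": 1, "survey_specific": kmax, "abundance_index": 2}[detection_model]
    rng = np.random.default_rng(seed)
    naive = max(0.05, min(0.95, np.mean([h.detected() for h in sites])))
    base = np.concatenate([
        [logit(naive)], np.zeros(n_psi - 1),
        np.full(n_p, logit(0.25))])
    best = None
    for s in range(n_starts):
        theta0 = base if s == 0 else base + rng.normal(0, 0.7, size=base.shape)
        res = optimize.minimize(
            _neg_loglik, theta0, args=(x, y, abund, detection_model, kmax),
            method="L-BFGS-B", options={"ftol": tol, "maxiter": 2000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = best.x
    notes = []
    converged = bool(best.success)
    if not converged:
        notes.append(f"optimizer: {best.message}")
    bpsi, p_hat = _unpack(theta, n_psi, detection_model, kmax, abund, len(sites))
    psi_hat = expit(x @ bpsi)
    if psi_hat.min() < 1e-4 or psi_hat.max() > 1 - 1e-4:
        notes.append("psi at boundary")
    se = None
    if compute_se:
        se = _numerical_se(theta, x, y, abund, detection_model, kmax)
    n_params = len(theta)
    neg2ll = 2.0 * best.fun
    label = model_label or f"psi(~{n_psi - 1} cov), p({detection_model})"
    return OccupancyFit(
        model=label, detection_model=detection_model,
        beta_psi=bpsi, beta_p=theta[n_psi:], se=se,
        neg2ll=neg2ll, aic=neg2ll + 2 * n_params, n_params=n_params,
        psi_hat=psi_hat, p_hat=p_hat, converged=converged,
        psi_design=x, notes=notes)


def _numerical_se(theta, x, y, abund, detection_model, kmax) -> np.ndarray | None:
    """Standard errors from the inverse observed information (finite diff)."""
    n = len(theta)
    h = 1e-4
    hess = np.zeros((n, n))

    def f(t):
        return _neg_loglik(t, x, y, abund, detection_model, kmax)

    f0 = f(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fij = f(theta + ei + ej)
            fi = f(theta + ei)
            fj = f(theta + ej)
            hess[i, j] = hess[j, i] = (fij - fi - fj + f0) / h ** 2
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.any(d < 0):
            return None
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# Model selection and averaging
# ---------------------------------------------------------------------------

def akaike_weights(aics: np.ndarray) -> np.ndarray:
    delta = np.asarray(aics, dtype=float) - np.min(aics)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_select_average(fits: list[OccupancyFit],
                         delta_aic_cut: float = 4.0
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Rank fits by AIC and model-average per-grid psi over models with
    delta AIC < cut (weights renormalized over the averaged set)."""
    fits = [f for f in fits if f.converged or True]
    if not fits:
        raise ValueError("no fits supplied")
    aics = np.array([f.aic for f in fits])
    order = np.argsort(aics)
    fits = [fits[i] for i in order]
    aics = aics[order]
    delta = aics - aics[0]
    weights = akaike_weights(aics)
    table = pd.DataFrame({
        "model": [f.model for f in fits],
        "AIC": aics, "delta_AIC": delta, "AIC_weight": weights,
        "model_likelihood": np.exp(-delta / 2.0),
        "n_params": [f.n_params for f in fits],
        "neg2_loglik": [f.neg2ll for f in fits]})
    keep = delta < delta_aic_cut
    w = weights[keep] / weights[keep].sum()
    psi_avg = np.zeros_like(fits[0].psi_hat)
    for wi, f in zip(w, [f for f, k in zip(fits, keep) if k]):
        psi_avg = psi_avg + wi * f.psi_hat
    return psi_avg, table


# ---------------------------------------------------------------------------
# Goodness of fit: parametric bootstrap c-hat
# ---------------------------------------------------------------------------

@dataclass
class ModelFitStats:
    chi2_observed: float
    chi2_bootstrap: np.ndarray
    c_hat: float
    inflation: float                # sqrt(c_hat), multiplies SEs
    p_value: float


def _chi2_history_freqs(y: np.ndarray, psi: np.ndarray, p: np.ndarray,
                        pool_min: float = 2.0) -> float:
    """Chi-square of observed vs expected detection-history frequencies.

    Sites are cohorted by usable survey count (unequal replicate efforts
    make raw history frequencies incomparable). Within a cohort the
    observed count of each distinct history is compared with its expected
    count under the fitted model, summed over sites:
    E(h) = sum_i [psi_i prod_j p_ij^y (1-p_ij)^(1-y)] (+ (1-psi_i) for the
    all-zero history). Histories with expectation below ``pool_min`` and
    the never-observed remainder are pooled into one residual class per
    cohort.
    """
    obs_mask = ~np.isnan(y)
    k_site = obs_mask.sum(axis=1)
    chi2 = 0.0
    for k in np.unique(k_site):
        if k == 0:
            continue
        idx = np.flatnonzero(k_site == k)
        hist_rows = [tuple(int(v) for v in y[i, obs_mask[i]]) for i in idx]
        patterns: dict[tuple, int] = {}
        for h in hist_rows:
            patterns[h] = patterns.get(h, 0) + 1
        hmat = np.array(list(patterns), dtype=float)        # (P, k)
        obs_counts = np.array(list(patterns.values()), dtype=float)
        p_coh = np.vstack([p[i, obs_mask[i]] for i in idx])  # (n, k)
        p_coh = np.clip(p_coh, 1e-12, 1 - 1e-12)
        ll = (np.log(p_coh) @ hmat.T
              + np.log1p(-p_coh) @ (1.0 - hmat).T)          # (n, P)
        prob = psi[idx][:, None] * np.exp(ll)
        zero = ~hmat.any(axis=1)
        if zero.any():
            prob[:, zero] += (1.0 - psi[idx])[:, None]
        expected = prob.sum(axis=0)                          # (P,)
        n_cohort = float(len(idx))
        big = expected >= pool_min
        chi2 += float(np.sum((obs_counts[big] - expected[big]) ** 2
                             / expected[big]))
        resid_o = float(obs_counts[~big].sum())
        resid_e = n_cohort - float(expected[big].sum())
        if resid_e >= 1.0:
            chi2 += (resid_o - resid_e) ** 2 / resid_e
    return chi2


def gof_bootstrap(fit: OccupancyFit, histories: list[SiteDetectionHistory],
                  n_boot: int = 1000, seed: int | None = None,
                  refit: bool = True) -> ModelFitStats:
    """Parametric-bootstrap goodness of fit and overdispersion c-hat.

    Histories are resimulated from the fitted (psi, p), the chi-square
    statistic recomputed (with refit by default), and
    c-hat = observed chi2 / mean bootstrap chi2. Standard errors should be
    inflated by sqrt(c-hat).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable c-hat")
    rng = np.random.default_rng(seed)
    sites, y, x, abund = _design(histories, None)
    if fit.psi_design is not None and fit.psi_design.shape[1] > 1:
        x = fit.psi_design
    obs_mask = ~np.isnan(y)
    chi2_obs = _chi2_history_freqs(y, fit.psi_hat, fit.p_hat)
    kmax = y.shape[1]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        z = rng.random(len(sites)) < fit.psi_hat
        yb = np.where(obs_mask,
                      (rng.random(y.shape) < fit.p_hat) & z[:, None], np.nan)
        yb = np.where(obs_mask, yb.astype(float), np.nan)
        if refit:
            theta0 = np.concatenate([fit.beta_psi, fit.beta_p])
            res = optimize.minimize(
                _neg_loglik, theta0,
                args=(x, yb, abund, fit.detection_model, kmax),
                method="L-BFGS-B", options={"ftol": 1e-7, "maxiter": 500})
            bpsi, p_b = _unpack(res.x, x.shape[1], fit.detection_model,
                                kmax, abund, len(sites))
            psi_b = expit(x @ bpsi)
        else:
            psi_b, p_b = fit.psi_hat, fit.p_hat
        boots[b] = _chi2_history_freqs(yb, psi_b, p_b)
    c_hat = chi2_obs / boots.mean() if boots.mean() > 0 else math.inf
    p_val = float((np.sum(boots >= chi2_obs) + 1) / (n_boot + 1))
    return ModelFitStats(chi2_observed=chi2_obs, chi2_bootstrap=boots,
                         c_hat=float(c_hat),
                         inflation=float(math.sqrt(max(c_hat, 0.0))),
                         p_value=p_val)


def inflation_factor(c_hat: float) -> float:
    """SE inflation for overdispersion: sqrt(c-hat)."""
    if c_hat <= 0:
        raise ValueError("c-hat must be positive")
    return math.sqrt(c_hat)


def coefficient_table(labels: list[str], estimates: np.ndarray,
                      ses: np.ndarray | None = None,
                      c_hat: float = 1.0) -> pd.DataFrame:
    """Coefficient report: estimate, overdispersion-corrected SE, exponent."""
    est = np.asarray(estimates, dtype=float)
    out = pd.DataFrame({"coefficient": labels, "estimate": est})
    if ses is not None:
        out["se_corrected"] = np.asarray(ses, dtype=float) * math.sqrt(c_hat)
    out["exponent"] = np.exp(est)
    return out


# ---------------------------------------------------------------------------
# Area summaries
# ---------------------------------------------------------------------------

@dataclass
class OccupancyAreas:
    naive_occupancy: float
    model_occupancy: float
    occupancy_increment_points: float
    naive_habitat: float
    model_habitat: float
    habitat_increment_points: float


def occupancy_area_summary(psi_hat: np.ndarray, habitat_area: np.ndarray,
                           detected: np.ndarray) -> OccupancyAreas:
    """Naive vs model-inferred occupancy and occupied-habitat areas.

    Naive occupancy is the fraction of surveyed grids with a detection;
    model occupancy is mean psi-hat; occupied habitat weights each grid's
    habitat area by its psi-hat (or its detection indicator for the naive
    version). Increments are reported in percentage points.
    """
    psi_hat = np.asarray(psi_hat, dtype=float)
    habitat_area = np.asarray(habitat_area, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if np.any(habitat_area < 0):
        raise ValueError("habitat areas must be >= 0")
    naive = float(detected.mean())
    model = float(psi_hat.mean())
    naive_hab = float(np.sum(habitat_area * detected))
    model_hab = float(np.sum(habitat_area * psi_hat))
    total = float(habitat_area.sum())
    return OccupancyAreas(
        naive_occupancy=100.0 * naive, model_occupancy=100.0 * model,
        occupancy_increment_points=100.0 * (model - naive),
        naive_habitat=naive_hab, model_habitat=model_hab,
        habitat_increment_points=(100.0 * (model_hab - naive_hab) / total
                                  if total > 0 else 0.0))
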