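"""Metabolome-wide interaction screen.

For every metabolite two nested models are fitted against a neuropathology
outcome:

    base:        outcome ~ metabolite + group + sex + age + PMI + APOE4
    interaction: base + metabolite : group

Braak, CERAD and Reagan scores are ordinal, so both models are cumulative-
logit (proportional-odds) regressions; the binary AD diagnosis uses
logistic regression on the case/control subset.  The added value of the
interaction term is assessed with the likelihood-ratio statistic
``Lambda = -2 (L0 - L1)``, referred to a chi-square whose degrees of
freedom equal the parameter difference (number of group contrasts, 2 for a
three-group cohort).  p-values are Benjamini-Hochberg adjusted within each
outcome and metabolites with q below the hit threshold are flagged.
Within-group follow-up refits the base model without the group covariate
inside each ethnoracial group to locate the source of the heterogeneity.

The proportional-odds maximum likelihood is computed by a damped Newton
ascent with analytic gradient and Hessian, started from the empirical
cumulative logits with zero slopes; the K=2 case reduces exactly to
logistic regression and is reused by :func:`fit_logistic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from metabomwas.containers import AbundanceMatrix

MAX_NEWTON_ITER = 100
GRAD_TOL = 1e-8
SEPARATION_NORM = 30.0

STAR_TIERS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class OrdinalFit:
    """A fitted cumulative-logit (or, for K=2, logistic) regression."""

    thresholds: np.ndarray  # K-1 ordered cutpoints
    coefficients: pd.Series  # named slopes
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    vcov: pd.DataFrame | None = None  # over (threshold_1.., slopes..)

    def __post_init__(self) -> None:
        if self.converged:
            if not np.all(np.diff(self.thresholds) > 0):
                raise ValueError("thresholds must be strictly increasing")
            if not np.isfinite(self.loglik):
                raise ValueError("log-likelihood must be finite at convergence")

    @property
    def param_names(self) -> list[str]:
        return [f"threshold_{k+1}" for k in range(len(self.thresholds))] + list(
            self.coefficients.index
        )

    def wald(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, two-sided p) for one slope."""
        if self.vcov is None:
            raise ValueError("fit carries no covariance matrix")
        est = float(self.coefficients[name])
        se = float(np.sqrt(self.vcov.loc[name, name]))
        p = 2.0 * float(norm.sf(abs(est) / se)) if se > 0 else np.nan
        return est, se, p


@dataclass
class LRTResult:
    lam: float
    df: int
    p_value: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.lam < -1e-8:
            raise ValueError("likelihood-ratio statistic must be nonnegative")
        self.lam = max(self.lam, 0.0)


def _loglik_parts(theta: np.ndarray, y: np.ndarray, X: np.ndarray, K: int):
    """Log-likelihood, gradient and Hessian of the cumulative-logit model.

    ``theta`` = (c_1..c_{K-1}, beta); P(y <= k | x) = expit(c_k - x beta).
    """
    n, p = X.shape
    c = theta[: K - 1]
    beta = theta[K - 1 :]
    eta = X @ beta

    # upper/lower threshold per observation (inf sentinels)
    c_ext = np.concatenate([[-np.inf], c, [np.inf]])
    a = c_ext[y] - eta  # upper: c_k - eta
    b = c_ext[y - 1] - eta  # lower: c_{k-1} - eta

    Fa, Fb = expit(a), expit(b)
    P = np.clip(Fa - Fb, 1e-300, None)
    ll = float(np.log(P).sum())

    fa = np.where(np.isfinite(a), Fa * (1 - Fa), 0.0)
    fb = np.where(np.isfinite(b), Fb * (1 - Fb), 0.0)
    ga, gb = fa / P, fb / P
    # f'(x) = f(x) (1 - 2 F(x))
    ha = np.where(np.isfinite(a), fa * (1 - 2 * Fa), 0.0) / P
    hb = np.where(np.isfinite(b), fb * (1 - 2 * Fb), 0.0) / P

    grad = np.zeros(K - 1 + p)
    upper_idx = y - 1  # c index of the upper threshold (valid when y < K)
    lower_idx = y - 2  # c index of the lower threshold (valid when y > 1)
    has_upper = y < K
    has_lower = y > 1
    np.add.at(grad, upper_idx[has_upper], ga[has_upper])
    np.add.at(grad, lower_idx[has_lower], -gb[has_lower])
    grad[K - 1 :] = X.T @ (gb - ga)

    Laa = ha - ga**2
    Lbb = -hb - gb**2
    Lab = ga * gb

    H = np.zeros((K - 1 + p, K - 1 + p))
    # threshold block (tridiagonal)
    np.add.at(np.reshape(H, -1), upper_idx[has_upper] * (K + p), Laa[has_upper])
    np.add.at(np.reshape(H, -1), lower_idx[has_lower] * (K + p), Lbb[has_lower])
    both = has_upper & has_lower
    if both.any():
        flat_off = lower_idx[both] * (K - 1 + p) + upper_idx[both]
        np.add.at(np.reshape(H, -1), flat_off, Lab[both])
        H[: K - 1, : K - 1] += np.triu(H[: K - 1, : K - 1], 1).T

    # threshold x slope block
    wu = np.where(has_upper, Laa + Lab, 0.0)
    wl = np.where(has_lower, Lbb + Lab, 0.0)
    for j in range(K - 1):
        sel_u = has_upper & (upper_idx == j)
        sel_l = has_lower & (lower_idx == j)
        row = -(wu[sel_u] @ X[sel_u]) - (wl[sel_l] @ X[sel_l]) if (sel_u.any() or sel_l.any()) else np.zeros(p)
        H[j, K - 1 :] = row
        H[K - 1 :, j] = row

    # slope block
    w = Laa + 2 * Lab + Lbb
    H[K - 1 :, K - 1 :] = X.T @ (X * w[:, None])
    return ll, grad, H


def _loglik_only(theta: np.ndarray, y: np.ndarray, X: np.ndarray, K: int) -> float:
    c = theta[: K - 1]
    eta = X @ theta[K - 1 :]
    c_ext = np.concatenate([[-np.inf], c, [np.inf]])
    P = expit(c_ext[y] - eta) - expit(c_ext[y - 1] - eta)
    if (P <= 0).any():
        return -np.inf
    return float(np.log(P).sum())


def ordinal_loglik(thresholds, beta, y, X) -> float:
    """Public cumulative-logit log-likelihood (used by tests as a probe)."""
    y = np.asarray(y, dtype=int)
    K = int(y.max())
    theta = np.concatenate([np.asarray(thresholds, float), np.asarray(beta, float)])
    return _loglik_only(theta, y, np.asarray(X, float), K)


def fit_proportional_odds(y, X=None, feature_names=None) -> OrdinalFit:
    """Maximum-likelihood cumulative-logit fit by damped Newton ascent.

    ``y`` holds ordinal levels coded 1..K (levels are compressed to the
    observed set first); ``X`` is the slope design without intercept.
    The ascent starts from the empirical cumulative logits with zero slopes
    and halves the step whenever the likelihood fails to improve or the
    thresholds lose their ordering.
    """
    y = np.asarray(y)
    if X is None:
        X = np.empty((len(y), 0))
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j+1}" for j in range(X.shape[1])]
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 observed levels")
    y_idx = np.searchsorted(levels, y) + 1  # 1..K over observed levels
    K = len(levels)
    n, p = X.shape
    if p and np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("design is rank deficient")

    cum = np.cumsum(np.bincount(y_idx, minlength=K + 1)[1:K]) / n
    theta = np.concatenate([np.log(cum / (1 - cum)), np.zeros(p)])
    ll = _loglik_only(theta, y_idx, X, K)

    converged = False
    for _ in range(MAX_NEWTON_ITER):
        ll, grad, H = _loglik_parts(theta, y_idx, X, K)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)  # H is the (negative-definite) Hessian
        except np.linalg.LinAlgError:
            break
        # damped update: keep thresholds ordered and the likelihood increasing
        scale = 1.0
        for _halving in range(40):
            cand = theta + scale * step
            if np.all(np.diff(cand[: K - 1]) > 0):
                cand_ll = _loglik_only(cand, y_idx, X, K)
                if cand_ll > ll - 1e-12:
                    break
            scale *= 0.5
        else:
            break
        theta = cand
        if np.linalg.norm(theta[K - 1 :]) > SEPARATION_NORM:
            break  # quasi-separation: slopes diverging

    ll, grad, H = _loglik_parts(theta, y_idx, X, K)
    converged = converged or (np.max(np.abs(grad)) < 1e-6)
    if np.linalg.norm(theta[K - 1 :]) > SEPARATION_NORM:
        converged = False

    vcov = None
    if converged:
        try:
            cov = np.linalg.inv(-H)
            names = [f"threshold_{k+1}" for k in range(K - 1)] + list(feature_names)
            vcov = pd.DataFrame(cov, index=names, columns=names)
        except np.linalg.LinAlgError:
            converged = False
    return OrdinalFit(
        thresholds=theta[: K - 1].copy(),
        coefficients=pd.Series(theta[K - 1 :], index=list(feature_names)),
        loglik=ll,
        n_params=K - 1 + p,
        n_obs=n,
        converged=converged,
        vcov=vcov,
    )


def fit_logistic(y, X=None, feature_names=None) -> OrdinalFit:
    """Logistic regression as the K=2 case of the cumulative-logit model.

    ``y`` is binary (0/1 or two arbitrary sorted levels; the larger level is
    the event).  The reported ``intercept`` is the log-odds of the event at
    ``X = 0`` (i.e. minus the single cumulative threshold).
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("logistic outcome must have exactly 2 levels")
    fit = fit_proportional_odds(y, X, feature_names=feature_names)
    coeffs = pd.concat([pd.Series({"intercept": -fit.thresholds[0]}), fit.coefficients])
    return OrdinalFit(
        thresholds=fit.thresholds,
        coefficients=coeffs,
        loglik=fit.loglik,
        n_params=fit.n_params,
        n_obs=fit.n_obs,
        converged=fit.converged,
        vcov=fit.vcov,
    )


def lrt(base: OrdinalFit, full: OrdinalFit) -> LRTResult:
    """Likelihood-ratio test of nested fits: Lambda = -2 (L0 - L1)."""
    base_slopes = [c for c in base.coefficients.index if c != "intercept"]
    full_slopes = [c for c in full.coefficients.index if c != "intercept"]
    if not set(base_slopes) <= set(full_slopes):
        raise ValueError("base model is not nested in the full model")
    df = full.n_params - base.n_params
    if df < 0:
        raise ValueError("full model must have at least as many parameters as the base model")
    if not (base.converged and full.converged):
        raise ValueError("both fits must have converged")
    lam = max(0.0, -2.0 * (base.loglik - full.loglik))
    p = 1.0 if df == 0 else float(chi2.sf(lam, df))  # identical designs: df 0, p 1
    return LRTResult(lam=lam, df=df, p_value=p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(j) = min_{l >= j} m p_(l) / l.

    NaN entries (e.g. non-converged fits excluded from the family) receive
    NaN q-values and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


# ---------------------------------------------------------------------------
# screen drivers
# ---------------------------------------------------------------------------

ORDINAL_OUTCOMES = ("braak", "cerad", "reagan")
SCREEN_COVARIATES = ("sex", "age_at_death", "pmi", "apoe4_count")


def _screen_frame(metadata: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Samples, covariates and coded outcome for one screen."""
    meta = metadata.copy()
    if outcome in ORDINAL_OUTCOMES:
        meta = meta[meta[outcome].notna()]
        y = meta[outcome].to_numpy(int)
    elif outcome == "diagnosis":
        meta = meta[meta["diagnosis"].isin(["case", "control"])]
        y = (meta["diagnosis"] == "case").to_numpy(int)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 observed levels")
    return meta, y


def _covariate_block(meta: pd.DataFrame) -> pd.DataFrame:
    """Standardized covariate columns (sex as 0/1, age & PMI z-scored)."""
    block = pd.DataFrame(index=meta.index)
    block["sex"] = (meta["sex"].astype(str) == sorted(meta["sex"].astype(str).unique())[0]).astype(float)
    for col in ("age_at_death", "pmi"):
        x = meta[col].astype(float)
        block[col] = (x - x.mean()) / (x.std() or 1.0)
    block["apoe4_count"] = meta["apoe4_count"].astype(float)
    return block


def _group_dummies(meta: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded group contrasts with the largest group as reference."""
    counts = meta["group"].value_counts()
    ref = sorted(counts.index[counts == counts.max()])[0]
    others = sorted(g for g in counts.index if g != ref)
    out = pd.DataFrame(index=meta.index)
    for g in others:
        out[f"group[{g}]"] = (meta["group"] == g).astype(float)
    return out


def mwas_interaction_screen(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    outcome: str = "braak",
    hit_q: float = 0.1,
) -> pd.DataFrame:
    """Fit base and interaction models for every metabolite; LRT + BH.

    Returns one row per metabolite with the likelihood-ratio statistic, its
    degrees of freedom (= number of group contrasts), p, BH q within this
    outcome, the hit flag at ``q < hit_q``, and the slope estimates.
    """
    meta, y = _screen_frame(metadata.loc[matrix.sample_ids], outcome)
    sub = matrix.subset(samples=meta.index)
    covs = _covariate_block(meta)
    gdum = _group_dummies(meta)
    base_design = pd.concat([gdum, covs], axis=1)
    Xb = base_design.to_numpy(float)
    gmat = gdum.to_numpy(float)
    base_names = list(base_design.columns)
    inter_names = [f"metabolite:{c}" for c in gdum.columns]

    fitter = fit_proportional_odds if outcome in ORDINAL_OUTCOMES else fit_logistic
    rows = []
    n_nonconverged = 0
    vals = sub.values.to_numpy(float)
    for j, met in enumerate(sub.metabolite_ids):
        x = vals[:, j]
        sd = x.std()
        z = (x - x.mean()) / (sd if sd > 0 else 1.0)
        X0 = np.column_stack([z, Xb])
        X1 = np.column_stack([z, Xb, gmat * z[:, None]])
        try:
            f0 = fitter(y, X0, feature_names=["metabolite"] + base_names)
            f1 = fitter(y, X1, feature_names=["metabolite"] + base_names + inter_names)
            res = lrt(f0, f1)
            row = {
                "metabolite": met,
                "outcome": outcome,
                "n": f1.n_obs,
                "lambda": res.lam,
                "df": res.df,
                "p": res.p_value,
                "beta_metabolite": float(f0.coefficients["metabolite"]),
            }
            for name in inter_names:
                row[name.replace("metabolite:group", "beta_interaction")] = float(
                    f1.coefficients[name]
                )
        except (ValueError, np.linalg.LinAlgError):
            n_nonconverged += 1
            row = {"metabolite": met, "outcome": outcome, "n": len(y), "lambda": np.nan,
                   "df": len(inter_names), "p": np.nan, "beta_metabolite": np.nan}
        rows.append(row)

    table = pd.DataFrame(rows).set_index("metabolite")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["hit"] = table["q"] < hit_q
    table.attrs["n_nonconverged"] = n_nonconverged
    table.attrs["hit_q"] = hit_q
    return table


def star_tier(p: float) -> str:
    """Significance stars: *** p<0.005, ** p<0.01, * p<0.05."""
    if np.isnan(p):
        return ""
    for cutoff, stars in STAR_TIERS:
        if p < cutoff:
            return stars
    return ""


def within_group_associations(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    hits,
    outcome: str = "braak",
) -> pd.DataFrame:
    """Per-group metabolite-outcome fits for the hit metabolites.

    Inside each ethnoracial group the base model is refitted without the
    group covariate; the metabolite slope, its Wald p and a star tier are
    reported per (metabolite, group).  Groups where the fit fails are
    reported with missing estimates.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("no hit metabolites supplied")
    meta_all, _ = _screen_frame(metadata.loc[matrix.sample_ids], outcome)
    fitter = fit_proportional_odds if outcome in ORDINAL_OUTCOMES else fit_logistic
    rows = []
    for group in sorted(meta_all["group"].unique()):
        meta = meta_all[meta_all["group"] == group]
        sub = matrix.subset(samples=meta.index, metabolites=hits)
        _, y = _screen_frame(meta, outcome)
        covs = _covariate_block(meta)
        names = ["metabolite"] + list(covs.columns)
        vals = sub.values.to_numpy(float)
        for j, met in enumerate(hits):
            x = vals[:, j]
            sd = x.std()
            z = (x - x.mean()) / (sd if sd > 0 else 1.0)
            X = np.column_stack([z, covs.to_numpy(float)])
            try:
                fit = fitter(y, X, feature_names=names)
                if not fit.converged:
                    raise ValueError("fit did not converge")
                est, se, p = fit.wald("metabolite")
                rows.append(
                    {"metabolite": met, "group": group, "n": fit.n_obs, "slope": est,
                     "se": se, "p": p, "stars": star_tier(p)}
                )
            except (ValueError, np.linalg.LinAlgError):
                rows.append(
                    {"metabolite": met, "group": group, "n": len(y), "slope": np.nan,
                     "se": np.nan, "p": np.nan, "stars": ""}
                )
    return pd.DataFrame(rows)
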