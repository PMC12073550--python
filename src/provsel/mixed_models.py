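"""REML mixed models for provenance-trial data.

Two models are supported.  Within a site,

    Y_jkl = mu + B_k + P_j + (PxB)_jk + e_jkl

with the block B_k fixed and the provenance P_j and the provenance-by-block
interaction random.  Across sites,

    Y_ijkl = mu + S_i + B_k(i) + P_j + (SxP)_ij + e_ijkl

with site and block-within-site fixed and the provenance and the
provenance-by-site interaction random.

Estimation profiles the restricted likelihood over the variance ratios
gamma_m = sigma^2_m / sigma^2_e.  With Z the stacked random-effect indicator
matrix and Gamma = diag(gamma) the marginal covariance is
V = sigma^2_e (I + Z Gamma Z'), and the Woodbury identity reduces every
quantity in the restricted log-likelihood to dense q x q linear algebra on
the cross-products Z'Z, Z'X, Z'y (q = total number of random-effect levels).
Non-negativity is enforced by box constraints on gamma; sigma^2_e has a
closed-form profile solution.  BLUPs are the conditional means
u_hat = Gamma Z' H^{-1} (y - X beta_hat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

from .exceptions import ConvergenceError, DesignError, ParameterError
from .simulate import TrialDataset

logger = logging.getLogger(__name__)

REML_TOL = 1e-8        # relative change of the restricted log-likelihood
REML_MAX_ITER = 500
GAMMA_UPPER = 1e8


# ---------------------------------------------------------------------------
# Core REML engine
# ---------------------------------------------------------------------------

def _indicator(codes: np.ndarray, n_levels: int) -> sp.csc_matrix:
    n = codes.shape[0]
    return sp.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


@dataclass
class _RemlProblem:
    """Pre-computed cross-products for one REML fit."""

    n: int
    p: int                      # rank of X
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    ZtZ: np.ndarray
    ZtX: np.ndarray
    Zty: np.ndarray
    sizes: tuple[int, ...]      # random-effect levels per term
    term_names: tuple[str, ...]

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        return np.repeat(gamma, self.sizes)

    def neg2_reml(self, gamma: np.ndarray, want_fit: bool = False):
        d = np.sqrt(self._expand(np.maximum(gamma, 0.0)))
        q = d.shape[0]
        K = (d[:, None] * self.ZtZ) * d[None, :]
        K[np.diag_indices(q)] += 1.0
        cK, low = sla.cho_factor(K, lower=True, check_finite=False)
        logdet_h = 2.0 * np.log(np.diag(cK)).sum()

        dZtX = d[:, None] * self.ZtX
        dZty = d * self.Zty
        KiX = sla.cho_solve((cK, low), dZtX, check_finite=False)
        Kiy = sla.cho_solve((cK, low), dZty, check_finite=False)

        XtHiX = self.XtX - dZtX.T @ KiX
        XtHiy = self.Xty - dZtX.T @ Kiy
        ytHiy = self.yty - dZty @ Kiy

        sign, logdet_x = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            # ridge the fixed-effect normal equations on near-singularity
            XtHiX = XtHiX + 1e-10 * np.eye(self.p) * max(1.0, np.trace(XtHiX))
            sign, logdet_x = np.linalg.slogdet(XtHiX)
        beta = np.linalg.solve(XtHiX, XtHiy)
        ypy = max(ytHiy - XtHiy @ beta, 1e-300)
        df = self.n - self.p
        sigma2 = ypy / df
        n2ll = (
            df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_h + logdet_x
        )
        if not want_fit:
            return n2ll
        # BLUPs: u = Gamma Z' H^{-1} r with r = y - X beta.
        # Z' H^{-1} r = Z'r - (Z'Z) D K^{-1} D Z'r
        Ztr = self.Zty - self.ZtX @ beta
        dZtr = d * Ztr
        ZtHir = Ztr - self.ZtZ @ (d * sla.cho_solve((cK, low), dZtr,
                                                    check_finite=False))
        u = self._expand(gamma) * ZtHir
        return n2ll, beta, sigma2, u


def _reml_optimize(prob: _RemlProblem) -> tuple[np.ndarray, dict]:
    m = len(prob.sizes)
    if m == 0:
        n2ll = _ols_neg2_reml(prob)
        return np.zeros(0), {"converged": True, "n2ll": n2ll, "n_eval": 0}
    best = None
    for x0 in (np.full(m, 0.1), np.full(m, 1.0)):
        res = optimize.minimize(
            prob.neg2_reml,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, GAMMA_UPPER)] * m,
            options={"maxiter": REML_MAX_ITER, "ftol": REML_TOL,
                     "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not best.success and best.nit >= REML_MAX_ITER:
        raise ConvergenceError(
            f"REML failed to converge after {best.nit} iterations: "
            f"{best.message} (gamma={best.x}, -2logLik={best.fun:.6g})"
        )
    return best.x, {"converged": True, "n2ll": best.fun, "n_eval": best.nfev}


def _ols_neg2_reml(prob: _RemlProblem) -> float:
    beta = np.linalg.solve(prob.XtX, prob.Xty)
    ypy = max(prob.yty - prob.Xty @ beta, 1e-300)
    df = prob.n - prob.p
    sigma2 = ypy / df
    _, logdet_x = np.linalg.slogdet(prob.XtX)
    return df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_x


def _fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    z_terms: Sequence[tuple[str, sp.csc_matrix]],
) -> dict:
    """Fit the profiled-REML model and return estimates and BLUPs."""
    n, p = X.shape
    if n <= p:
        raise DesignError("more fixed-effect parameters than observations")
    if z_terms:
        Z = sp.hstack([z for _, z in z_terms], format="csc")
        ZtZ = (Z.T @ Z).toarray()
        ZtX = Z.T @ X
        Zty = Z.T @ y
    else:
        ZtZ = np.zeros((0, 0))
        ZtX = np.zeros((0, p))
        Zty = np.zeros(0)
    prob = _RemlProblem(
        n=n, p=p,
        XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
        ZtZ=ZtZ, ZtX=np.asarray(ZtX), Zty=np.asarray(Zty),
        sizes=tuple(z.shape[1] for _, z in z_terms),
        term_names=tuple(name for name, _ in z_terms),
    )
    gamma, info = _reml_optimize(prob)
    if z_terms:
        n2ll, beta, sigma2, u = prob.neg2_reml(gamma, want_fit=True)
    else:
        n2ll = info["n2ll"]
        beta = np.linalg.solve(prob.XtX, prob.Xty)
        sigma2 = max(prob.yty - prob.Xty @ beta, 0.0) / (n - p)
        u = np.zeros(0)
    comps = {name: float(g * sigma2) for name, g in zip(prob.term_names, gamma)}
    blups: dict[str, np.ndarray] = {}
    off = 0
    for (name, z) in z_terms:
        blups[name] = u[off: off + z.shape[1]]
        off += z.shape[1]
    return {
        "loglik": -0.5 * float(n2ll),
        "beta": beta,
        "sigma2_e": float(sigma2),
        "components": comps,
        "blups": blups,
        "n_obs": n,
        "gamma": gamma,
        "info": info,
    }


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SiteFit:
    """Per-site REML fit of one trait."""

    trait: str
    site: str
    v_p: float
    v_pb: float
    v_r: float
    fixed_effects: pd.Series        # intercept + block contrasts
    loglik: float
    blups: pd.Series                # provenance BLUPs
    n_obs: int
    fixed_mean: float               # mean of X beta over the observations
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _terms: tuple[tuple[str, slice], ...] = ()

    @property
    def predicted_means(self) -> pd.Series:
        """BLUP-based provenance means: average fixed value + BLUP."""
        return self.fixed_mean + self.blups


@dataclass
class MetFit:
    """Across-site REML fit of one trait."""

    trait: str
    v_p: float
    v_ge: float
    v_r: float
    fixed_effects: pd.Series
    loglik: float
    blups: pd.Series
    interaction_blups: pd.DataFrame  # provenances x sites (theta)
    n_obs: int
    fixed_mean: float
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _terms: tuple[tuple[str, slice], ...] = ()

    @property
    def predicted_means(self) -> pd.Series:
        return self.fixed_mean + self.blups


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    term: str

    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class FixedAnova:
    """Sequential (type I) mean squares for the fixed terms of a fit."""

    table: pd.DataFrame  # index: term; columns: df, ms, f, p_value, stars


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _complete_records(data: TrialDataset, trait: str) -> pd.DataFrame:
    if trait not in data.traits:
        raise ParameterError(f"unknown trait {trait!r}")
    df = data.data
    return df[df[trait].notna()].reset_index(drop=True)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummies dropping the first level."""
    out = np.zeros((codes.shape[0], n_levels - 1))
    for lv in range(1, n_levels):
        out[codes == lv, lv - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_site_model(
    data: TrialDataset,
    trait: str,
    exclude: Sequence[str] = (),
) -> SiteFit:
    """Fit the within-site model for one trait.

    ``exclude`` drops named random terms ("provenance", "provenance:block")
    for likelihood-ratio testing; the fixed part is unchanged.
    """
    df = _complete_records(data, trait)
    sites = pd.unique(df["site"])
    if len(sites) != 1:
        raise DesignError(
            f"fit_site_model needs data from a single site, got {list(sites)}"
        )
    site = str(sites[0])
    prov_codes, prov_levels = pd.factorize(df["provenance"], sort=True)
    block_codes, block_levels = pd.factorize(df["block"], sort=True)
    if len(prov_levels) < 2:
        raise DesignError("at least 2 provenances are required")
    if len(block_levels) < 2:
        raise DesignError("at least 2 blocks are required")

    y = df[trait].to_numpy(float)
    n = len(y)
    Xb = _dummies(block_codes, len(block_levels))
    X = np.column_stack([np.ones(n), Xb])
    terms = (("intercept", slice(0, 1)), ("block", slice(1, X.shape[1])))

    pb_codes = prov_codes * len(block_levels) + block_codes
    z_terms = []
    if "provenance" not in exclude:
        z_terms.append(("provenance", _indicator(prov_codes, len(prov_levels))))
    if "provenance:block" not in exclude:
        z_terms.append(
            ("provenance:block",
             _indicator(pb_codes, len(prov_levels) * len(block_levels)))
        )
    fit = _fit_reml(y, X, z_terms)
    blups = pd.Series(
        fit["blups"].get("provenance", np.zeros(len(prov_levels))),
        index=list(prov_levels), name=trait,
    )
    fixed_names = ["intercept"] + [f"block[{b}]" for b in block_levels[1:]]
    logger.info(
        "fit_site_model site=%s trait=%s n=%d converged=%s",
        site, trait, n, fit["info"]["converged"],
    )
    return SiteFit(
        trait=trait, site=site,
        v_p=fit["components"].get("provenance", 0.0),
        v_pb=fit["components"].get("provenance:block", 0.0),
        v_r=fit["sigma2_e"],
        fixed_effects=pd.Series(fit["beta"], index=fixed_names),
        loglik=fit["loglik"],
        blups=blups,
        n_obs=n,
        fixed_mean=float(np.mean(X @ fit["beta"])),
        _X=X, _y=y, _terms=terms,
    )


def fit_met_model(
    data: TrialDataset,
    trait: str,
    analysis_set: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> MetFit:
    """Fit the across-site model for one trait.

    ``analysis_set`` restricts the fit to a provenance subset; the default is
    the set of provenances present at every site (the common-garden
    convention).  The interaction-BLUP matrix has one row per provenance in
    the analysis set and one column per site; provenance-site pairs absent
    from the data keep the BLUP of an unobserved effect, exactly 0.
    """
    df = _complete_records(data, trait)
    all_sites = sorted(pd.unique(df["site"]))
    if len(all_sites) < 2:
        raise DesignError("across-site model needs at least 2 sites")
    if analysis_set is None:
        by_site = df.groupby("site")["provenance"].agg(set)
        analysis_set = sorted(set.intersection(*by_site.tolist()))
    else:
        analysis_set = sorted(set(analysis_set))
    if not analysis_set:
        raise ParameterError("analysis_set is empty")
    df = df[df["provenance"].isin(set(analysis_set))].reset_index(drop=True)
    if df.empty:
        raise ParameterError("no records for the requested analysis set")
    presence = df.groupby("provenance")["site"].nunique()
    lonely = presence[presence < 2]
    if len(lonely):
        logger.warning(
            "fit_met_model: %d provenances observed at a single site: %s",
            len(lonely), list(lonely.index),
        )

    prov_levels = list(analysis_set)
    prov_codes = pd.Categorical(
        df["provenance"], categories=prov_levels
    ).codes.astype(np.int64)
    site_codes, site_levels = pd.factorize(df["site"], sort=True)
    sb = df["site"].astype(str) + "/" + df["block"].astype(str)
    sb_codes, sb_levels = pd.factorize(sb, sort=True)

    y = df[trait].to_numpy(float)
    n = len(y)
    Xs = _dummies(site_codes, len(site_levels))
    # block-within-site: drop the first block of each site
    first_sb = {s: min(l for l in sb_levels if l.startswith(f"{s}/"))
                for s in site_levels}
    keep_sb = [i for i, l in enumerate(sb_levels) if l not in first_sb.values()]
    Xsb = np.zeros((n, len(keep_sb)))
    for j, i in enumerate(keep_sb):
        Xsb[sb_codes == i, j] = 1.0
    X = np.column_stack([np.ones(n), Xs, Xsb])
    terms = (
        ("intercept", slice(0, 1)),
        ("site", slice(1, 1 + Xs.shape[1])),
        ("block(site)", slice(1 + Xs.shape[1], X.shape[1])),
    )

    # interaction term: only observed provenance-site cells get a column
    pair = prov_codes * len(site_levels) + site_codes
    obs_pairs = np.unique(pair)
    pair_pos = {p: i for i, p in enumerate(obs_pairs)}
    pair_codes = np.array([pair_pos[p] for p in pair])
    z_terms = []
    if "provenance" not in exclude:
        z_terms.append(("provenance", _indicator(prov_codes, len(prov_levels))))
    if "provenance:site" not in exclude:
        z_terms.append(
            ("provenance:site", _indicator(pair_codes, len(obs_pairs)))
        )
    fit = _fit_reml(y, X, z_terms)

    blups = pd.Series(
        fit["blups"].get("provenance", np.zeros(len(prov_levels))),
        index=prov_levels, name=trait,
    )
    theta = pd.DataFrame(
        0.0, index=prov_levels, columns=list(site_levels)
    )
    if "provenance:site" in fit["blups"]:
        u = fit["blups"]["provenance:site"]
        for p, i in pair_pos.items():
            theta.iloc[p // len(site_levels), p % len(site_levels)] = u[i]
    fixed_names = (
        ["intercept"]
        + [f"site[{s}]" for s in site_levels[1:]]
        + [f"block[{sb_levels[i]}]" for i in keep_sb]
    )
    logger.info(
        "fit_met_model trait=%s n=%d n_prov=%d converged=%s",
        trait, n, len(prov_levels), fit["info"]["converged"],
    )
    return MetFit(
        trait=trait,
        v_p=fit["components"].get("provenance", 0.0),
        v_ge=fit["components"].get("provenance:site", 0.0),
        v_r=fit["sigma2_e"],
        fixed_effects=pd.Series(fit["beta"], index=fixed_names),
        loglik=fit["loglik"],
        blups=blups,
        interaction_blups=theta,
        n_obs=n,
        fixed_mean=float(np.mean(X @ fit["beta"])),
        _X=X, _y=y, _terms=terms,
    )


# ---------------------------------------------------------------------------
# Tests and summaries
# ---------------------------------------------------------------------------

def lrt_random_effect(
    full_loglik: float, reduced_loglik: float, df: int, term: str = ""
) -> LrtResult:
    """Likelihood-ratio test for a random term from two REML log-likelihoods.

    The statistic is clipped at zero (the full model can only lose likelihood
    by numerical noise); the reference distribution is a chi-square with
    ``df`` degrees of freedom.
    """
    if df < 1:
        raise ParameterError("df must be >= 1")
    tol = 1e-6 * max(1.0, abs(reduced_loglik))
    if full_loglik < reduced_loglik - tol:
        logger.warning(
            "lrt_random_effect: full log-likelihood %.6g below reduced %.6g",
            full_loglik, reduced_loglik,
        )
    stat = max(0.0, 2.0 * (full_loglik - reduced_loglik))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(statistic=stat, df=df, p_value=p, term=term)


def variance_proportions(fit: SiteFit | MetFit) -> dict[str, float]:
    """Share of each reported random component in the total variance.

    Within a site the total is V_p + V_r (the provenance-by-block component
    is excluded from the denominator, matching how per-site proportions are
    conventionally reported for these trials); across sites it is
    V_p + V_ge + V_r.
    """
    if isinstance(fit, SiteFit):
        parts = {"provenance": fit.v_p, "residual": fit.v_r}
    else:
        parts = {"provenance": fit.v_p, "provenance:site": fit.v_ge,
                 "residual": fit.v_r}
    total = sum(parts.values())
    if total <= 0:
        raise ParameterError("all variance components are zero; "
                             "proportions undefined")
    return {k: v / total for k, v in parts.items()}


def anova_fixed(fit: SiteFit | MetFit) -> FixedAnova:
    """Sequential (type I) mean squares for the fixed terms of a fit.

    Each term's sum of squares is the drop in residual SS when its columns
    enter after all preceding terms; the F statistic tests the mean square
    against the REML residual variance.
    """
    if fit._X is None or fit._y is None:
        raise ParameterError("fit does not carry its design matrix")
    X, y = fit._X, fit._y
    n = len(y)
    rows = []
    rss_prev = float(y @ y)
    cols_so_far = 0
    rank_prev = 0
    for name, sl in fit._terms:
        cols_so_far = sl.stop
        Xc = X[:, :cols_so_far]
        beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
        rss = float(y @ y - y @ (Xc @ beta))
        ss = max(rss_prev - rss, 0.0)
        df_term = rank - rank_prev
        rss_prev, rank_prev = rss, rank
        if name == "intercept":
            continue
        if df_term < 1:
            raise ParameterError(f"fixed term {name!r} adds no rank")
        ms = ss / df_term
        df_resid = n - X.shape[1]
        f = ms / fit.v_r if fit.v_r > 0 else np.inf
        p = float(stats.f.sf(f, df_term, df_resid))
        rows.append((name, df_term, ms, f, p, significance_stars(p)))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ms", "f", "p_value", "stars"]
    ).set_index("term")
    return FixedAnova(table=table)
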