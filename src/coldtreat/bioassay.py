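"""Beta-binomial time-mortality models for cold-treatment bioassays.

The observational unit is a treated box (or lot) of infested fruit: after a
cold treatment of ``t`` days, ``pupae_count`` insects survived to pupation out
of an estimated ``treated_estimate`` that would have pupated untreated.  The
probability of death is modelled on a link scale (probit or logit) as a
stage-specific intercept plus a stage-specific slope in treatment time, with a
beta-binomial observation model whose intraclass correlation ``rho`` has its
own submodel (per-stage intercepts and, optionally, a slope in time).
Replicate-level Gaussian random intercepts are integrated out by a Laplace
approximation with an adaptive Gauss-Hermite fallback.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "STAGE_ORDER",
    "TreatmentObservation",
    "ModelSpec",
    "ModelFit",
    "DispersionCheck",
    "link_transform",
    "link_inverse",
    "betabinom_loglik",
    "betabinom_rvs",
    "fit_fixed",
    "fit_mixed",
    "select_link",
    "dispersion_check",
    "read_observations",
    "observations_to_frame",
]

#: Canonical ordering of the immature life stages (egg, then larval instars).
STAGE_ORDER = ("egg", "L1", "L2", "L3")

_LINKS = ("probit", "logit")

# Below this intraclass correlation the beta-binomial pmf is numerically
# indistinguishable from (and less accurate than) the plain binomial.
_RHO_BINOMIAL_EPS = 1e-8
_MU_EPS = 1e-12


# ---------------------------------------------------------------------------
# link functions


def link_transform(p, link: str):
    """Map a probability to the link scale (probit or logit).

    Raises ``ValueError`` for probabilities outside the open interval (0, 1).
    """
    _check_link(link)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probabilities must lie strictly between 0 and 1")
    out = stats.norm.ppf(p) if link == "probit" else special.logit(p)
    return float(out) if out.ndim == 0 else out

def link_inverse(x, link: str):
    """Inverse link: map a real number back to a probability."""
    _check_link(link)
    x = np.asarray(x, dtype=float)
    out = stats.norm.cdf(x) if link == "probit" else special.expit(x)
    return float(out) if out.ndim == 0 else out

def _check_link(link: str) -> None:
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}; expected one of {_LINKS}")


# ---------------------------------------------------------------------------
# beta-binomial pmf


def _bb_ab(mu, rho):
    # mean/intraclass-correlation -> standard (a, b) parameters
    s = (1.0 - rho) / rho
    return mu * s, (1.0 - mu) * s

def _log_choose(n, k):
    return special.gammaln(n + 1.0) - special.gammaln(k + 1.0) - special.gammaln(n - k + 1.0)

def _bb_logpmf_core(k, n, mu, rho):
    """Unvalidated vectorized log-pmf used by the likelihood hot path.

    Evaluates the binomial branch where rho is numerically negligible and
    the beta-function form elsewhere, via gammaln directly (much faster than
    the frozen-distribution machinery).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu, rho = np.broadcast_arrays(np.asarray(mu, dtype=float), np.asarray(rho, dtype=float))
    k, n, mu, rho = np.broadcast_arrays(k, n, mu, rho)
    out = np.empty(k.shape, dtype=float)
    tiny = rho < _RHO_BINOMIAL_EPS
    if np.any(tiny):
        kt, nt, mt = k[tiny], n[tiny], mu[tiny]
        out[tiny] = _log_choose(nt, kt) + special.xlogy(kt, mt) + special.xlog1py(nt - kt, -mt)
    if np.any(~tiny):
        kb, nb = k[~tiny], n[~tiny]
        a, b = _bb_ab(mu[~tiny], rho[~tiny])
        out[~tiny] = (
            _log_choose(nb, kb)
            + special.betaln(kb + a, nb - kb + b)
            - special.betaln(a, b)
        )
    return out

def betabinom_loglik(k, n, mu, rho):
    """Log pmf of the beta-binomial with mean ``mu`` and intraclass
    correlation ``rho`` in [0, 1).

    ``rho -> 0`` recovers the binomial; values below 1e-8 are evaluated on the
    binomial branch, where the beta-function form loses precision.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(n < 1):
        raise ValueError("require n >= 1")
    if np.any((rho < 0.0) | (rho >= 1.0)):
        raise ValueError("rho must lie in [0, 1)")
    if np.any((mu <= 0.0) | (mu >= 1.0)):
        raise ValueError("mu must lie strictly between 0 and 1")

    out = _bb_logpmf_core(k, n, mu, rho)
    return float(out) if out.ndim == 0 else out

def betabinom_rvs(n, mu, rho, rng: np.random.Generator):
    """Draw beta-binomial variates (binomial when rho ~ 0)."""
    n = np.asarray(n)
    mu, rho = np.broadcast_arrays(
        np.asarray(mu, dtype=float), np.asarray(rho, dtype=float)
    )
    n, mu, rho = np.broadcast_arrays(n, mu, rho)
    out = np.empty(n.shape, dtype=np.int64)
    tiny = rho < _RHO_BINOMIAL_EPS
    if np.any(tiny):
        out[tiny] = rng.binomial(n[tiny], mu[tiny])
    if np.any(~tiny):
        a, b = _bb_ab(mu[~tiny], rho[~tiny])
        p = rng.beta(a, b)
        out[~tiny] = rng.binomial(n[~tiny], p)
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TreatmentObservation:
    """One treated box/lot of infested fruit."""

    year: str
    cultivar: str
    life_stage: str
    replicate: str
    duration_days: float
    unit_id: str
    pupae_count: int
    treated_estimate: float

    def __post_init__(self):
        if self.pupae_count < 0:
            raise ValueError("pupae_count must be non-negative")
        if self.treated_estimate <= 0:
            raise ValueError("treated_estimate must be positive")
        if self.duration_days < 0:
            raise ValueError("duration_days must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """Mean, dispersion and random-effect structure of the mortality model.

    ``family='binomial'`` drops the dispersion submodel entirely (used to
    demonstrate that extra-binomial variation must be modelled).
    ``disp_slope`` controls the time slope of the transformed intraclass
    correlation: 'shared' (one slope across stages, the default minimal
    structure), 'per_stage', or 'none'.
    """

    link: str = "logit"
    family: str = "betabinom"
    disp_slope: str = "shared"
    random: str | None = None  # None | 'replicate' | 'replicate_cultivar'

    def __post_init__(self):
        _check_link(self.link)
        if self.family not in ("betabinom", "binomial"):
            raise ValueError("family must be 'betabinom' or 'binomial'")
        if self.disp_slope not in ("shared", "per_stage", "none"):
            raise ValueError("disp_slope must be 'shared', 'per_stage' or 'none'")
        if self.random not in (None, "replicate", "replicate_cultivar"):
            raise ValueError("random must be None, 'replicate' or 'replicate_cultivar'")


@dataclass
class ModelFit:
    """Maximum-likelihood fit of a :class:`ModelSpec`."""

    spec: ModelSpec
    stages: tuple[str, ...]
    param_names: tuple[str, ...]
    params: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    warnings: tuple[str, ...] = ()
    sigma_u: float | None = None

    # -- parameter accessors -------------------------------------------------

    def _idx(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"no parameter {name!r} in fit") from None

    def alpha(self, stage: str) -> float:
        return float(self.params[self._idx(f"alpha[{stage}]")])

    def beta(self, stage: str) -> float:
        return float(self.params[self._idx(f"beta[{stage}]")])

    def ab_covariance(self, stage: str) -> np.ndarray:
        """2x2 covariance block of (alpha_stage, beta_stage)."""
        i = self._idx(f"alpha[{stage}]")
        j = self._idx(f"beta[{stage}]")
        return self.covariance[np.ix_([i, j], [i, j])]

    def rho(self, stage: str, t) -> np.ndarray:
        """Fitted intraclass correlation at treatment time t."""
        if self.spec.family == "binomial":
            return np.zeros_like(np.asarray(t, dtype=float))
        d = self.params[self._idx(f"d[{stage}]")]
        if self.spec.disp_slope == "shared":
            e = self.params[self._idx("e")]
        elif self.spec.disp_slope == "per_stage":
            e = self.params[self._idx(f"e[{stage}]")]
        else:
            e = 0.0
        return special.expit(d + e * np.asarray(t, dtype=float))

    def predict_mortality(self, stage: str, t) -> np.ndarray:
        """Fitted probability of death at treatment time t (fixed effects)."""
        eta = self.alpha(stage) + self.beta(stage) * np.asarray(t, dtype=float)
        return link_inverse(eta, self.spec.link)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    # -- serialization -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "spec": asdict(self.spec),
            "stages": list(self.stages),
            "param_names": list(self.param_names),
            "params": self.params.tolist(),
            "covariance": self.covariance.ravel().tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "warnings": list(self.warnings),
            "sigma_u": self.sigma_u,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ModelFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        k = len(payload["param_names"])
        return cls(
            spec=ModelSpec(**payload["spec"]),
            stages=tuple(payload["stages"]),
            param_names=tuple(payload["param_names"]),
            params=np.asarray(payload["params"], dtype=float),
            covariance=np.asarray(payload["covariance"], dtype=float).reshape(k, k),
            loglik=payload["loglik"],
            converged=payload["converged"],
            n_obs=payload["n_obs"],
            warnings=tuple(payload["warnings"]),
            sigma_u=payload["sigma_u"],
        )


@dataclass(frozen=True)
class DispersionCheck:
    """Simulation-based check of the fitted dispersion structure."""

    n_sim: int
    seed: int
    dispersion_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# data handling


_COLUMNS = (
    "year",
    "cultivar",
    "life_stage",
    "replicate",
    "duration_days",
    "unit_id",
    "pupae_count",
    "treated_estimate",
)

def observations_to_frame(data) -> pd.DataFrame:
    """Normalize observations (records or DataFrame) to a DataFrame.

    Only ``life_stage``, ``duration_days``, ``pupae_count`` and
    ``treated_estimate`` are required; missing grouping columns are filled
    with a single level.
    """
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame([asdict(o) for o in data])
    for col in ("life_stage", "duration_days", "pupae_count", "treated_estimate"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = "all"
    if (df["treated_estimate"] <= 0).any():
        raise ValueError("treated_estimate must be positive")
    if (df["pupae_count"] < 0).any():
        raise ValueError("pupae_count must be non-negative")
    return df

def read_observations(path) -> pd.DataFrame:
    """Read box-level observations from a comma-separated file."""
    return observations_to_frame(pd.read_csv(path))

def sort_stages(stages: Iterable[str]) -> tuple[str, ...]:
    """Canonical stage ordering: egg, L1, L2, L3 first, then alphabetical."""
    def key(s):
        return (STAGE_ORDER.index(s), "") if s in STAGE_ORDER else (len(STAGE_ORDER), s)
    return tuple(sorted(set(stages), key=key))


# ---------------------------------------------------------------------------
# likelihood machinery


class _Prepared:
    """Design arrays shared by the fixed and mixed likelihoods."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.stages = sort_stages(df["life_stage"])
        for s in self.stages:
            sub = df[df["life_stage"] == s]
            if sub["duration_days"].nunique() < 2:
                raise ValueError(
                    f"stage {s!r} has fewer than 2 distinct durations; "
                    "the time slope is not identifiable"
                )
        smap = {s: i for i, s in enumerate(self.stages)}
        self.sidx = df["life_stage"].map(smap).to_numpy()
        self.t = df["duration_days"].to_numpy(dtype=float)
        ntot = np.rint(df["treated_estimate"].to_numpy(dtype=float)).astype(np.int64)
        ntot = np.maximum(ntot, 1)
        dead = ntot - np.rint(df["pupae_count"].to_numpy(dtype=float)).astype(np.int64)
        self.dead = np.clip(dead, 0, ntot)
        self.ntot = ntot
        self.n_obs = len(df)

        S = len(self.stages)
        self.n_mean = 2 * S
        if spec.family == "binomial":
            self.n_disp = 0
        elif spec.disp_slope == "shared":
            self.n_disp = S + 1
        elif spec.disp_slope == "per_stage":
            self.n_disp = 2 * S
        else:
            self.n_disp = S
        names = [f"alpha[{s}]" for s in self.stages] + [f"beta[{s}]" for s in self.stages]
        if spec.family == "betabinom":
            names += [f"d[{s}]" for s in self.stages]
            if spec.disp_slope == "shared":
                names += ["e"]
            elif spec.disp_slope == "per_stage":
                names += [f"e[{s}]" for s in self.stages]
        self.param_names = tuple(names)

        # random-effect grouping
        if spec.random is None:
            self.gidx = None
            self.n_groups = 0
        else:
            if spec.random == "replicate":
                keys = df["replicate"].astype(str)
            else:
                keys = df["replicate"].astype(str) + "//" + df["cultivar"].astype(str)
            levels = sorted(keys.unique())
            if len(levels) < 2:
                raise ValueError("random intercepts need at least 2 group levels")
            gmap = {g: i for i, g in enumerate(levels)}
            self.gidx = keys.map(gmap).to_numpy()
            self.n_groups = len(levels)
            self.groups = tuple(levels)

    # -- per-row log-likelihood ---------------------------------------------

    def mu_rho(self, theta: np.ndarray, u_row: np.ndarray | float = 0.0):
        S = len(self.stages)
        alpha = theta[:S][self.sidx]
        beta = theta[S : 2 * S][self.sidx]
        eta = alpha + beta * self.t + u_row
        mu = special.ndtr(eta) if self.spec.link == "probit" else special.expit(eta)
        mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
        if self.spec.family == "binomial":
            rho = np.zeros_like(mu)
        else:
            d = theta[2 * S : 3 * S][self.sidx]
            if self.spec.disp_slope == "shared":
                zeta = d + theta[3 * S] * self.t
            elif self.spec.disp_slope == "per_stage":
                zeta = d + theta[3 * S : 4 * S][self.sidx] * self.t
            else:
                zeta = d
            rho = special.expit(np.clip(zeta, -34.0, 34.0))
        return mu, rho

    def row_loglik(self, theta: np.ndarray, u_row: np.ndarray | float = 0.0):
        mu, rho = self.mu_rho(theta, u_row)
        return _bb_logpmf_core(self.dead, self.ntot, mu, rho)

    def start_values(self) -> np.ndarray:
        S = len(self.stages)
        alpha0 = np.zeros(S)
        beta0 = np.zeros(S)
        padj = (self.dead + 0.5) / (self.ntot + 1.0)
        y = link_transform(padj, self.spec.link)
        for i in range(S):
            m = self.sidx == i
            b, a = np.polyfit(self.t[m], y[m], 1)
            alpha0[i], beta0[i] = a, b
        theta0 = np.concatenate([alpha0, beta0])
        if self.spec.family == "betabinom":
            d0 = np.full(S, special.logit(0.05))
            theta0 = np.concatenate([theta0, d0])
            if self.spec.disp_slope == "shared":
                theta0 = np.concatenate([theta0, [0.0]])
            elif self.spec.disp_slope == "per_stage":
                theta0 = np.concatenate([theta0, np.zeros(S)])
        return theta0

    def separation_warnings(self) -> list[str]:
        out = []
        for i, s in enumerate(self.stages):
            m = self.sidx == i
            interior = (self.dead[m] > 0) & (self.dead[m] < self.ntot[m])
            if not interior.any():
                out.append(
                    f"possible complete separation for stage {s!r}: "
                    "no box with partial mortality"
                )
        return out


def _covariance_from_hessian(nll, theta_hat, warnings_list):
    H = approx_hess(theta_hat, nll)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.linalg.eigvalsh(cov) > -1e-8):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        warnings_list.append(
            "observed information is singular or indefinite; "
            "covariance computed by pseudo-inverse"
        )
    cov = 0.5 * (cov + cov.T)
    return cov

def _minimize(nll, theta0, light=False):
    """Deterministic optimisation: quasi-Newton start, simplex polish with a
    restart, then a scaled-gradient convergence check.

    ``light=True`` (marginal likelihoods, where each evaluation is costly)
    uses a single polish with looser simplex tolerances.
    """
    lbfgs = {"maxiter": 200, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5} \
        if light else {"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-7}
    best = optimize.minimize(nll, theta0, method="L-BFGS-B", options=lbfgs)
    polish = {"maxiter": 2000, "maxfev": 2000, "xatol": 1e-5, "fatol": 1e-7} \
        if light else {"maxiter": 20000, "maxfev": 20000, "xatol": 1e-8, "fatol": 1e-10}
    for _ in range(1 if light else 2):
        res = optimize.minimize(nll, best.x, method="Nelder-Mead", options=polish)
        if res.fun <= best.fun:
            best = res
    # coarse central differences: near the rho -> 0 boundary the likelihood
    # carries ~1e-7-level branch noise that a fine step would amplify
    grad = np.array([
        (nll(best.x + e) - nll(best.x - e)) / 2e-3
        for e in 1e-3 * np.eye(len(best.x))
    ])
    gtol = 1e-2 if light else 1e-3
    rel_grad = float(np.max(np.abs(grad))) / max(abs(best.fun), 1.0)
    converged = bool(np.isfinite(best.fun) and rel_grad < gtol)
    return best.x, -best.fun, converged


# ---------------------------------------------------------------------------
# fitting


def fit_fixed(data, spec: ModelSpec | None = None) -> ModelFit:
    """Maximum-likelihood fit of the fixed-effects time-mortality model.

    The response is the number dead, ``round(treated_estimate) -
    pupae_count`` (clipped at zero), out of ``round(treated_estimate)``.
    Controls (duration 0) are ordinary data points.
    """
    spec = spec or ModelSpec()
    if spec.random is not None:
        raise ValueError("fit_fixed requires a spec without random terms")
    df = observations_to_frame(data)
    prep = _Prepared(df, spec)

    def nll(theta):
        ll = prep.row_loglik(theta)
        return -np.sum(ll)

    theta0 = prep.start_values()
    theta_hat, loglik, converged = _minimize(nll, theta0)
    warns = prep.separation_warnings()
    cov = _covariance_from_hessian(nll, theta_hat, warns)
    return ModelFit(
        spec=spec,
        stages=prep.stages,
        param_names=prep.param_names,
        params=np.asarray(theta_hat, dtype=float),
        covariance=cov,
        loglik=float(loglik),
        converged=converged,
        n_obs=prep.n_obs,
        warnings=tuple(warns),
    )


def _laplace_group_logliks(prep: _Prepared, theta, log_sigma, n_agq=9):
    """Vectorized per-group Laplace (AGQ fallback) marginal log-likelihoods.

    The conditional mode of each group's random intercept is found by a
    safeguarded (backtracking, monotone-ascent) Newton iteration on
    finite-difference derivatives, started from the prior mode.
    """
    # clamp sigma away from 0: the Laplace integral degenerates smoothly to
    # the fixed-effects likelihood there, so the floor only caps exploration
    sigma2 = math.exp(2.0 * max(log_sigma, -7.0))
    sigma = math.sqrt(sigma2)
    G = prep.n_groups
    u = np.zeros(G)
    fd = 1e-4

    def group_ll(u_vec):
        ll = prep.row_loglik(theta, u_vec[prep.gidx])
        return np.bincount(prep.gidx, weights=ll, minlength=G)

    def h_of(u_vec):
        return group_ll(u_vec) - u_vec**2 / (2.0 * sigma2)

    def derivs(u_vec):
        f0 = group_ll(u_vec)
        fp = group_ll(u_vec + fd)
        fm = group_ll(u_vec - fd)
        h = f0 - u_vec**2 / (2.0 * sigma2)
        h1 = (fp - fm) / (2.0 * fd) - u_vec / sigma2
        h2 = (fp - 2.0 * f0 + fm) / fd**2 - 1.0 / sigma2
        return h, h1, h2

    h, h1, h2 = derivs(u)
    for _ in range(40):
        if np.max(np.abs(h1)) < 1e-8:
            break
        curv = np.where(h2 < -1e-8, h2, -1e-8)
        delta = np.clip(h1 / curv, -3.0, 3.0)
        step = np.ones(G)
        for _ in range(10):  # backtrack where the step does not ascend
            h_try = h_of(u - step * delta)
            bad = h_try < h - 1e-12
            if not np.any(bad):
                break
            step = np.where(bad, step / 2.0, step)
        u = u - step * delta
        h, h1, h2 = derivs(u)

    neg_curv = -h2
    laplace = h + 0.5 * math.log(2.0 * math.pi) - 0.5 * np.log(np.maximum(neg_curv, 1e-300))
    # include the Gaussian prior normalisation
    laplace = laplace - 0.5 * math.log(2.0 * math.pi * sigma2)

    ill = (neg_curv < 1e-6) | ~np.isfinite(laplace)
    if np.any(ill):
        # adaptive Gauss-Hermite on the ill-conditioned groups; the proposal
        # spread is capped at a few prior standard deviations
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_agq)
        sd = np.minimum(1.0 / np.sqrt(np.maximum(neg_curv, 1e-6)), 3.0 * sigma)
        vals = np.full((n_agq, G), -np.inf)
        for i, (x, w) in enumerate(zip(nodes, weights)):
            u_i = u + sd * x
            ll = h_of(u_i) - 0.5 * math.log(2.0 * math.pi * sigma2)
            vals[i] = ll + math.log(w) + 0.5 * x**2 + np.log(sd)
        agq = special.logsumexp(vals, axis=0)
        laplace = np.where(ill, agq, laplace)
    return laplace, u

def fit_mixed(data, spec: ModelSpec) -> ModelFit:
    """Fit with Gaussian random intercepts integrated out (Laplace / AGQ).

    With ``spec.random`` unset this reduces exactly to :func:`fit_fixed`.
    """
    if spec.random is None:
        return fit_fixed(data, spec)
    df = observations_to_frame(data)
    prep = _Prepared(df, spec)

    def nll(psi):
        theta, log_sigma = psi[:-1], psi[-1]
        lg, _ = _laplace_group_logliks(prep, theta, log_sigma)
        return -np.sum(lg)

    fixed_start = fit_fixed(df, ModelSpec(
        link=spec.link, family=spec.family, disp_slope=spec.disp_slope
    ))
    # two starts: a moderate variance and the sigma -> 0 boundary (where the
    # marginal likelihood equals the fixed-effects fit); the profile in
    # log sigma is flat enough near the boundary that a single start stalls
    psi_hat, loglik, converged = None, -np.inf, False
    for ls0 in (math.log(0.3), -7.0):
        psi0 = np.concatenate([fixed_start.params, [ls0]])
        cand, cand_ll, cand_conv = _minimize(nll, psi0, light=True)
        if cand_ll > loglik:
            psi_hat, loglik, converged = cand, cand_ll, cand_conv
    sigma_u = float(math.exp(psi_hat[-1]))
    warns = prep.separation_warnings()
    if sigma_u < 1e-3:
        warns.append("random-intercept variance estimated at the zero boundary")
    cov_full = _covariance_from_hessian(nll, psi_hat, warns)
    k = len(prep.param_names)
    return ModelFit(
        spec=spec,
        stages=prep.stages,
        param_names=prep.param_names,
        params=np.asarray(psi_hat[:-1], dtype=float),
        covariance=cov_full[:k, :k],
        loglik=float(loglik),
        converged=converged,
        n_obs=prep.n_obs,
        warnings=tuple(warns),
        sigma_u=sigma_u,
    )


def select_link(data, spec: ModelSpec | None = None) -> ModelFit:
    """Fit under both links and keep the smaller-AIC model."""
    spec = spec or ModelSpec()
    fits = []
    for link in _LINKS:
        s = ModelSpec(link=link, family=spec.family,
                      disp_slope=spec.disp_slope, random=spec.random)
        fits.append(fit_mixed(data, s) if s.random else fit_fixed(data, s))
    return min(fits, key=lambda f: f.aic)


# ---------------------------------------------------------------------------
# dispersion diagnostics


def dispersion_check(fit: ModelFit, data, n_sim: int = 200, seed: int = 0) -> DispersionCheck:
    """Simulation-based test of the fitted dispersion structure.

    Simulates ``n_sim`` datasets from the fitted (fixed-effect) model and
    compares the observed mean squared Pearson residual with the simulated
    distribution.  The statistic is the ratio of observed to mean simulated
    residual variance; the p-value is the upper-tail simulation rank, small
    when the data are more dispersed than the model allows.
    """
    if not fit.converged:
        raise ValueError("dispersion_check requires a converged fit")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    df = observations_to_frame(data)
    prep = _Prepared(df, fit.spec if fit.spec.random is None else ModelSpec(
        link=fit.spec.link, family=fit.spec.family, disp_slope=fit.spec.disp_slope
    ))
    mu, rho = prep.mu_rho(fit.params)
    var = prep.ntot * mu * (1.0 - mu) * (1.0 + (prep.ntot - 1.0) * rho)
    obs_stat = float(np.mean((prep.dead - prep.ntot * mu) ** 2 / var))

    rng = np.random.default_rng(seed)
    sim_stats = np.empty(n_sim)
    for j in range(n_sim):
        k = betabinom_rvs(prep.ntot, mu, rho, rng)
        sim_stats[j] = np.mean((k - prep.ntot * mu) ** 2 / var)
    statistic = obs_stat / float(np.mean(sim_stats))
    p = (1.0 + np.sum(sim_stats >= obs_stat)) / (n_sim + 1.0)
    return DispersionCheck(
        n_sim=n_sim, seed=seed,
        dispersion_statistic=statistic, p_value=float(p),
    )
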