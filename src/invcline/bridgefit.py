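"""Suspension-bridge F_ST landscape: expectation, Bayesian fit, outliers.

Differentiation between the two arrangements of a polymorphic inversion is
expected to peak near the breakpoints (where recombination in
heterokaryotypes is most strongly suppressed) and sag in the middle (gene
flux via double crossovers and gene conversion).  The landscape along a
linkage group is modelled piecewise: background level ``m`` with exponential
decay toward the inversion on both flanks, and a parabola inside:

    F(p) = m + a0 * exp(l (p - b))                    p <  b
    F(p) = m + a0 + a1 (p - b) + a2 (p - b)^2         b <= p <= b + k
    F(p) = m + h  * exp(r (b + k - p))                p >  b + k

with ``h = a0 + a1 k + a2 k^2`` the elevation at the right peak, so the
curve is continuous at both junctions.  Contig-mean F_ST values are
logit-transformed and fitted with Gaussian residuals of constant SD ``s``
by MCMC (affine-invariant ensemble sampler).  A bridge is declared present
when the central 95% posterior intervals for a0, a1 and a2 all exclude
zero; contigs more than 3 posterior-mean residual SDs *above* the fitted
curve are flagged as outliers (candidate direct targets of selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

__all__ = [
    "BridgeParams",
    "BridgeFit",
    "bridge_expectation",
    "contig_mean_logit_fst",
    "fit_bridge",
    "detect_outliers",
]

_LOGIT_EPS = 1e-4

_PARAM_NAMES = ["m", "a0", "a1", "a2", "b", "k", "l", "r", "s"]


@dataclass
class BridgeParams:
    m: float  # background F_ST outside the inversion
    a0: float  # elevation at the left peak
    a1: float  # parabola linear coefficient (per cM)
    a2: float  # parabola quadratic coefficient (per cM^2)
    b: float  # left peak position (cM)
    k: float  # inversion span (cM)
    l: float = 1.0  # left flank decay rate (per cM)
    r: float = 1.0  # right flank decay rate (per cM)
    s: float = 0.0  # residual SD on the logit scale

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.l <= 0 or self.r <= 0:
            raise ValueError("decay rates must be positive")
        if not (0.0 < self.m < 1.0):
            raise ValueError("m must be in (0, 1)")

    @property
    def h(self) -> float:
        """Elevation at the right peak, a0 + a1 k + a2 k^2."""
        return self.a0 + self.a1 * self.k + self.a2 * self.k**2

    def to_array(self) -> np.ndarray:
        return np.array([self.m, self.a0, self.a1, self.a2, self.b, self.k,
                         self.l, self.r, self.s])


def bridge_expectation(p, params: BridgeParams) -> np.ndarray:
    """Expected F_ST at map position(s) ``p`` (cM)."""
    p = np.asarray(p, dtype=float)
    m, a0, a1, a2 = params.m, params.a0, params.a1, params.a2
    b, k, l, r = params.b, params.k, params.l, params.r
    h = params.h
    t = p - b
    inside = m + a0 + a1 * t + a2 * t**2
    with np.errstate(over="ignore"):
        left = m + a0 * np.exp(l * t)
        right = m + h * np.exp(r * (b + k - p))
    return np.where(p < b, left, np.where(p > b + k, right, inside))


def _expectation_range_ok(theta: np.ndarray, positions: np.ndarray) -> bool:
    """All expectations in (0,1), including the parabola vertex if interior."""
    m, a0, a1, a2, b, k = theta[:6]
    vals = [m, m + a0, m + a0 + a1 * k + a2 * k**2]
    if abs(a2) > 1e-12:
        tv = -a1 / (2.0 * a2)
        if 0.0 < tv < k:
            vals.append(m + a0 + a1 * tv + a2 * tv**2)
    if min(vals) <= 0.0 or max(vals) >= 1.0:
        return False
    return True


def contig_mean_logit_fst(
    per_snp_fst: pd.DataFrame,
    fst_col: str = "fst",
    contig_col: str = "contig",
    cm_col: str = "cM",
) -> pd.DataFrame:
    """Average per-SNP F_ST within contigs on the natural scale, then logit.

    Returns one row per contig with its mean cM position, the natural-scale
    mean (clamped to [eps, 1-eps] before the logit) and the logit value;
    contigs without any defined F_ST are dropped.
    """
    df = per_snp_fst[[contig_col, cm_col, fst_col]].dropna(subset=[fst_col])
    if df.empty:
        raise ValueError("no defined F_ST values")
    agg = df.groupby(contig_col, sort=True).agg(
        cM=(cm_col, "mean"), mean_fst=(fst_col, "mean"),
        n_snps=(fst_col, "size"))
    clamped = agg["mean_fst"].clip(_LOGIT_EPS, 1.0 - _LOGIT_EPS)
    agg["logit_fst"] = np.log(clamped / (1.0 - clamped))
    return agg.reset_index().rename(columns={contig_col: "contig"})


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------


def _log_prior(theta: np.ndarray, lg_length: float) -> float:
    m, a0, a1, a2, b, k, l, r, s = theta
    if not (0.0 < m < 1.0) or a0 < 0 or l <= 0 or r <= 0 or s <= 0:
        return -np.inf
    if not (0.0 <= b <= lg_length and 0.0 < k <= lg_length - b):
        return -np.inf
    logit_m = math.log(m / (1.0 - m))
    lp = -0.5 * ((logit_m + 4.0) / 2.0) ** 2
    lp += -0.5 * (a0 / 1.0) ** 2  # half-normal(1)
    lp += -0.5 * (a1 / 0.1) ** 2
    lp += -0.5 * (a2 / 0.01) ** 2
    lp += -l - r  # exponential(mean 1)
    lp += -0.5 * (s / 2.0) ** 2  # half-normal(2)
    return lp


def _log_prob(theta, positions, logit_obs, lg_length):
    lp = _log_prior(theta, lg_length)
    if not np.isfinite(lp):
        return -np.inf
    if not _expectation_range_ok(theta, positions):
        return -np.inf
    params = BridgeParams(*theta)
    mu = bridge_expectation(positions, params)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        return -np.inf
    logit_mu = np.log(mu / (1.0 - mu))
    s = theta[8]
    resid = logit_obs - logit_mu
    return lp - 0.5 * np.sum((resid / s) ** 2) - len(resid) * math.log(s)


@dataclass
class BridgeFit:
    """Posterior summary of a suspension-bridge fit."""

    samples: pd.DataFrame  # post-burn posterior draws, one column per param
    summary: pd.DataFrame  # mean, sd, q2.5, q97.5 per parameter
    rhat: dict[str, float]
    converged: bool
    verdict: bool  # bridge present: 95% intervals of a0,a1,a2 exclude zero
    positions: np.ndarray
    logit_obs: np.ndarray
    fitted_logit: np.ndarray  # at posterior-mean parameters
    std_residuals: np.ndarray
    lg_length: float
    contigs: np.ndarray | None = None

    @property
    def posterior_mean(self) -> BridgeParams:
        m = self.summary["mean"]
        return BridgeParams(*[float(m[n]) for n in _PARAM_NAMES])


def _split_rhat(chains: np.ndarray) -> float:
    """Classic split-R-hat for an (n_steps, n_chains) array."""
    n, c = chains.shape
    half = n // 2
    seq = np.concatenate([chains[:half], chains[half:2 * half]], axis=1)
    n, c = seq.shape
    means = seq.mean(axis=0)
    W = seq.var(axis=0, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def _initial_guess(positions, logit_obs, lg_length):
    """Moment-based starting point: background from the flank-level quantile,
    peak span from where observations exceed the midpoint level."""
    obs_f = 1.0 / (1.0 + np.exp(-logit_obs))
    lo = np.quantile(obs_f, 0.2)
    hi = np.quantile(obs_f, 0.9)
    m0 = min(max(lo, 1e-3), 0.5)
    thresh = 0.5 * (lo + hi)
    elevated = positions[obs_f > thresh]
    if len(elevated) >= 2:
        b0 = float(elevated.min())
        k0 = float(max(elevated.max() - b0, 1.0))
    else:
        b0, k0 = 0.25 * lg_length, 0.5 * lg_length
    a0 = max(hi - m0, 0.05)
    # start with a gentle sag: center elevation ~80% of the peak elevation
    sag = 0.2 * a0
    a1 = -4.0 * sag / k0
    a2 = 4.0 * sag / k0**2
    return np.array([m0, a0, a1, a2, b0, k0, 1.0, 1.0, 0.5])


def fit_bridge(
    positions,
    logit_means,
    lg_length: float,
    n_walkers: int = 32,
    n_steps: int = 8000,
    n_burn: int = 3000,
    seed: int = 0,
    contigs=None,
) -> BridgeFit:
    """Fit the bridge model to contig-level logit mean F_ST values by MCMC.

    The likelihood is ``logit(F_obs_j) ~ Normal(logit(F(p_j)), s)``.  Priors
    are weakly informative and scale-matched to cM units: logit(m) ~
    N(-4, 2), a0 ~ HalfNormal(1), a1 ~ N(0, 0.1), a2 ~ N(0, 0.01), b ~
    U(0, L), k ~ U(0, L - b), l, r ~ Exp(1), s ~ HalfNormal(2); parameter
    sets driving F outside (0, 1) are rejected.  Walkers are split into four
    groups for the split R-hat diagnostic; R-hat >= 1.05 on any parameter
    flags non-convergence (the fit is still returned, flagged).
    """
    positions = np.asarray(positions, dtype=float)
    logit_obs = np.asarray(logit_means, dtype=float)
    if len(positions) < 20:
        raise ValueError("need at least 20 contigs spanning the linkage group")
    rng = np.random.default_rng(seed)
    center = _initial_guess(positions, logit_obs, lg_length)
    scale = np.array([0.005, 0.05, 0.01, 0.001, 2.0, 3.0, 0.3, 0.3, 0.1])
    p0 = np.empty((n_walkers, 9))
    i = 0
    while i < n_walkers:
        cand = center + scale * rng.standard_normal(9)
        cand[0] = min(max(cand[0], 1e-4), 0.8)
        cand[1] = abs(cand[1])
        cand[4] = min(max(cand[4], 0.0), lg_length - 1.0)
        cand[5] = min(max(cand[5], 1.0), lg_length - cand[4])
        cand[6] = max(cand[6], 0.05)
        cand[7] = max(cand[7], 0.05)
        cand[8] = max(cand[8], 0.05)
        if np.isfinite(_log_prob(cand, positions, logit_obs, lg_length)):
            p0[i] = cand
            i += 1
    sampler = emcee.EnsembleSampler(
        n_walkers, 9, _log_prob, args=(positions, logit_obs, lg_length))
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain()[n_burn:]  # (steps, walkers, 9)
    rhat = {}
    for j, name in enumerate(_PARAM_NAMES):
        # four chain groups of walkers
        groups = np.array_split(np.arange(n_walkers), 4)
        grouped = np.stack([chain[:, g, j].mean(axis=1) for g in groups], axis=1)
        rhat[name] = _split_rhat(grouped)
    converged = all(v < 1.05 for v in rhat.values())
    flat = chain.reshape(-1, 9)
    samples = pd.DataFrame(flat, columns=_PARAM_NAMES)
    q = samples.quantile([0.025, 0.975])
    summary = pd.DataFrame({
        "mean": samples.mean(),
        "sd": samples.std(ddof=1),
        "q2.5": q.loc[0.025],
        "q97.5": q.loc[0.975],
    })
    summary.index.name = "param"
    verdict = all(
        not (summary.loc[nm, "q2.5"] <= 0.0 <= summary.loc[nm, "q97.5"])
        for nm in ("a0", "a1", "a2")
    )
    pm = BridgeParams(*[float(summary.loc[n, "mean"]) for n in _PARAM_NAMES])
    mu = np.clip(bridge_expectation(positions, pm), _LOGIT_EPS, 1 - _LOGIT_EPS)
    fitted_logit = np.log(mu / (1.0 - mu))
    s_hat = float(summary.loc["s", "mean"])
    std_resid = (logit_obs - fitted_logit) / s_hat
    return BridgeFit(
        samples=samples, summary=summary, rhat=rhat, converged=converged,
        verdict=verdict, positions=positions, logit_obs=logit_obs,
        fitted_logit=fitted_logit, std_residuals=std_resid,
        lg_length=float(lg_length),
        contigs=None if contigs is None else np.asarray(contigs),
    )


def detect_outliers(fit: BridgeFit, threshold: float = 3.0) -> np.ndarray:
    """Indices (or contig names when known) of contigs whose standardized
    residual exceeds ``threshold`` *above* the fitted curve (one-sided:
    elevated differentiation is the signature of a direct selection target).
    """
    flagged = np.flatnonzero(fit.std_residuals > threshold)
    if fit.contigs is not None:
        return fit.contigs[flagged]
    return flagged
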