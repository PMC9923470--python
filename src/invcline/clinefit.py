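"""Geographic cline models, ML fitting with AIC model competition, per-SNP
cline scans, phenotype clines, cline-based heterozygote deficits and the
cline-width selection estimate.

The frequency model is the stepped-cline family used throughout hybrid-zone
work: a central sigmoid ``f(x) = 1/(1 + exp(-4 (x - c)/w))`` with center *c*
(the position of steepest change) and width *w* (inverse of the maximum
slope), scaled between end frequencies ``pmin`` and ``pmax``, optionally
extended with exponential introgression tails beyond distances ``delta`` on
either side with tail-slope parameters ``tau`` in (0, 1].  With ``tau = 1``
the tail attaches with a continuous first derivative.

Model competition follows the conventional rule that a richer model must
improve AIC by more than 4 over a simpler one, otherwise the simpler model is
retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ClineParams",
    "ClineFit",
    "FisResult",
    "SelectionEstimate",
    "SHAPES",
    "cline_frequency",
    "fit_frequency_cline",
    "fit_size_cline",
    "scan_snp_clines",
    "fis_by_bins",
    "fis_by_bins_multiallelic",
    "project_to_path",
    "map_legacy_sites",
    "selection_from_width",
]

SHAPES = (
    "constant",
    "linear",
    "sigmoid",
    "sigmoid_left",
    "sigmoid_right",
    "sigmoid_both",
    "sigmoid_indep",
)

_EPS = 1e-9


@dataclass
class ClineParams:
    """Natural-scale cline parameters; unused fields stay at their defaults."""

    shape: str = "sigmoid"
    center: float = 0.0  # c, meters
    width: float = 1.0  # w, meters
    pmin: float = 0.0
    pmax: float = 1.0
    delta_l: float = 0.0  # left tail distance (m)
    tau_l: float = 1.0  # left tail slope, (0, 1]
    delta_r: float = 0.0
    tau_r: float = 1.0
    intercept: float = 0.0  # linear model only
    slope: float = 0.0  # linear model only, per meter
    mu_min: float = 0.0  # phenotype clines, mm
    mu_max: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (0.0 < self.tau_l <= 1.0 and 0.0 < self.tau_r <= 1.0):
            raise ValueError("tail slopes must be in (0, 1]")
        if self.delta_l < 0 or self.delta_r < 0:
            raise ValueError("tail distances must be nonnegative")


def _sigmoid_fraction(x: np.ndarray, p: ClineParams) -> np.ndarray:
    """The 0..1 cline fraction f(x), including any tails."""
    c, w = p.center, p.width
    z = np.asarray(x, dtype=float) - c
    f = expit(4.0 * z / w)
    has_left = p.shape in ("sigmoid_left", "sigmoid_both", "sigmoid_indep")
    has_right = p.shape in ("sigmoid_right", "sigmoid_both", "sigmoid_indep")
    if has_left and p.delta_l > 0:
        dl, tl = p.delta_l, p.tau_l
        f0 = float(expit(-4.0 * dl / w))
        denom = w * (1.0 + math.exp(-4.0 * dl / w))
        left = z < -dl
        arg = np.where(left, 4.0 * tl * (z + dl) / denom, 0.0)  # arg <= 0
        f = np.where(left, f0 * np.exp(arg), f)
    if has_right and p.delta_r > 0:
        dr, tr = p.delta_r, p.tau_r
        f1 = float(expit(4.0 * dr / w))
        denom = w * (1.0 + math.exp(-4.0 * dr / w))
        right = z > dr
        arg = np.where(right, -4.0 * tr * (z - dr) / denom, 0.0)  # arg <= 0
        f = np.where(right, 1.0 - (1.0 - f1) * np.exp(arg), f)
    return f


def cline_frequency(x, params: ClineParams) -> np.ndarray:
    """Allele/arrangement frequency p(x) under ``params``.

    Monotone nondecreasing in x whenever ``pmax > pmin``; continuous at the
    tail junctions, and continuously differentiable there when ``tau = 1``.
    """
    x = np.asarray(x, dtype=float)
    if params.shape == "constant":
        return np.full(x.shape, params.pmin)
    if params.shape == "linear":
        return np.clip(params.intercept + params.slope * x, 0.0, 1.0)
    f = _sigmoid_fraction(x, params)
    return params.pmin + (params.pmax - params.pmin) * f


# ---------------------------------------------------------------------------
# transformed parameterizations for fitting
# ---------------------------------------------------------------------------


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


_expit = expit


_N_PARAMS = {
    "constant": 1,
    "linear": 2,
    "sigmoid": 4,
    "sigmoid_left": 6,
    "sigmoid_right": 6,
    "sigmoid_both": 6,
    "sigmoid_indep": 8,
}

_PARAM_NAMES = {
    "constant": ["logit_p"],
    "linear": ["intercept", "slope"],
    "sigmoid": ["c", "log_w", "logit_pmin", "logit_pmax"],
    "sigmoid_left": ["c", "log_w", "logit_pmin", "logit_pmax", "log_dl", "logit_tl"],
    "sigmoid_right": ["c", "log_w", "logit_pmin", "logit_pmax", "log_dr", "logit_tr"],
    "sigmoid_both": ["c", "log_w", "logit_pmin", "logit_pmax", "log_d", "logit_t"],
    "sigmoid_indep": [
        "c", "log_w", "logit_pmin", "logit_pmax",
        "log_dl", "logit_tl", "log_dr", "logit_tr",
    ],
}


def _theta_to_params(theta: np.ndarray, shape: str) -> ClineParams:
    if shape == "constant":
        return ClineParams(shape="constant", pmin=float(_expit(theta[0])),
                           pmax=float(_expit(theta[0])))
    if shape == "linear":
        return ClineParams(shape="linear", intercept=float(theta[0]),
                           slope=float(theta[1]))
    c, log_w, lo, hi = theta[:4]
    kw = dict(shape=shape, center=float(c), width=float(np.exp(log_w)),
              pmin=float(_expit(lo)), pmax=float(_expit(hi)))
    if shape == "sigmoid_left":
        kw.update(delta_l=float(np.exp(theta[4])), tau_l=float(_expit(theta[5])))
    elif shape == "sigmoid_right":
        kw.update(delta_r=float(np.exp(theta[4])), tau_r=float(_expit(theta[5])))
    elif shape == "sigmoid_both":
        d, t = float(np.exp(theta[4])), float(_expit(theta[5]))
        kw.update(delta_l=d, tau_l=t, delta_r=d, tau_r=t)
    elif shape == "sigmoid_indep":
        kw.update(delta_l=float(np.exp(theta[4])), tau_l=float(_expit(theta[5])),
                  delta_r=float(np.exp(theta[6])), tau_r=float(_expit(theta[7])))
    return ClineParams(**kw)


@dataclass
class ModelFit:
    shape: str
    theta: np.ndarray
    params: ClineParams
    loglik: float
    aic: float
    n_params: int
    success: bool


@dataclass
class ClineFit:
    """Result of fitting one or more cline shapes to one set of observations."""

    models: dict[str, ModelFit]
    selected: str
    gof: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    note: str = ""

    @property
    def params(self) -> ClineParams:
        return self.models[self.selected].params

    @property
    def loglik(self) -> float:
        return self.models[self.selected].loglik

    @property
    def aic(self) -> float:
        return self.models[self.selected].aic

    def aic_table(self) -> pd.DataFrame:
        rows = [
            (m.shape, m.n_params, m.loglik, m.aic, m.shape == self.selected)
            for m in self.models.values()
        ]
        return pd.DataFrame(rows, columns=["shape", "n_params", "loglik", "aic",
                                           "selected"]).sort_values("aic",
                                                                    ignore_index=True)


def _select_model(models: dict[str, ModelFit], delta: float = 4.0) -> str:
    """Minimum-AIC winner unless a simpler model is within ``delta`` AIC."""
    best_aic = min(m.aic for m in models.values())
    eligible = [m for m in models.values() if m.aic <= best_aic + delta]
    eligible.sort(key=lambda m: (m.n_params, m.aic))
    return eligible[0].shape


def _binom_nll(theta, shape, x, g, n):
    p = cline_frequency(x, _theta_to_params(theta, shape))
    penalty = 0.0
    if shape == "linear":
        # a genuinely straight trend: the line must stay inside [0,1] over
        # the observed range, otherwise it degenerates into a ramp-shaped
        # cline mimic; endpoint checks suffice for a linear function
        ends = theta[0] + theta[1] * np.array([np.min(x), np.max(x)])
        excess = np.maximum(ends - 1.0, 0.0) + np.maximum(-ends, 0.0)
        penalty = 1e4 * float(np.sum(excess) ** 2) * len(x)
    p = np.clip(p, _EPS, 1 - _EPS)
    return -np.sum(g * np.log(p) + (n - g) * np.log1p(-p)) + penalty


def _bounds_for(shape: str, x: np.ndarray) -> list[tuple[float, float]]:
    xmin, xmax = float(np.min(x)), float(np.max(x))
    span = max(xmax - xmin, 1.0)
    b_c = (xmin - 0.5 * span, xmax + 0.5 * span)
    b_lw = (math.log(0.1), math.log(10.0 * span))
    b_lp = (-12.0, 12.0)
    b_ld = (math.log(0.01), math.log(4.0 * span))
    b_lt = (-8.0, 8.0)
    if shape == "constant":
        return [b_lp]
    if shape == "linear":
        return [(-2.0, 3.0), (-1.0, 1.0)]
    out = [b_c, b_lw, b_lp, b_lp]
    extra = (_N_PARAMS[shape] - 4) // 2
    for _ in range(extra):
        out += [b_ld, b_lt]
    return out


def _heuristic_start(shape, x, g, n, span):
    """Data-driven start: terminal-window frequencies and mid-crossing."""
    xmin, xmax = float(np.min(x)), float(np.max(x))
    lo_m = (x <= xmin + 0.2 * span)
    hi_m = (x >= xmax - 0.2 * span)
    p_lo = g[lo_m].sum() / max(n[lo_m].sum(), 1)
    p_hi = g[hi_m].sum() / max(n[hi_m].sum(), 1)
    pbar = g.sum() / max(n.sum(), 1)
    if shape == "constant":
        return np.array([_logit(pbar)])
    if shape == "linear":
        return np.array([p_lo, (p_hi - p_lo) / span])
    if p_lo > p_hi:  # fitting handles either orientation via pmin/pmax order
        p_lo, p_hi = p_hi, p_lo
    start = [0.5 * (xmin + xmax), math.log(span / 3.0), _logit(p_lo), _logit(p_hi)]
    extra = (_N_PARAMS[shape] - 4) // 2
    for _ in range(extra):
        start += [math.log(2.0 * span), 0.0]  # tail far outside data = no tail
    return np.array(start)


def _fit_one_shape(shape, x, g, n, n_restarts, rng, parent: ModelFit | None):
    bounds = _bounds_for(shape, x)
    span = max(float(np.max(x) - np.min(x)), 1.0)
    starts = [_heuristic_start(shape, x, g, n, span)]
    if parent is not None and shape.startswith("sigmoid_"):
        # nested start: parent sigmoid optimum with tails pushed out of range,
        # which reproduces the parent likelihood exactly
        base = list(parent.theta[:4])
        extra = (_N_PARAMS[shape] - 4) // 2
        starts.append(np.array(base + [math.log(2.0 * span), 0.0] * extra))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(n_restarts):
        starts.append(lo + (hi - lo) * rng.random(len(bounds)))
    best = None
    for s in starts:
        s = np.clip(s, lo, hi)
        res = minimize(_binom_nll, s, args=(shape, x, g, n), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(best.x, shape)
    ll = -float(best.fun)
    k = _N_PARAMS[shape]
    return ModelFit(shape, np.asarray(best.x), params, ll, 2.0 * k - 2.0 * ll, k,
                    bool(best.success))


def _wald_ci(nll, theta, args, names):
    """95% intervals from a central-difference Hessian on the working scale."""
    k = len(theta)
    h = np.maximum(1e-4, 1e-4 * np.abs(theta))
    H = np.zeros((k, k))
    f0 = nll(theta, *args)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(theta + ei + ej, *args)
            fpm = nll(theta + ei - ej, *args)
            fmp = nll(theta - ei + ej, *args)
            fmm = nll(theta - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return {nm: (float(t - 1.96 * s), float(t + 1.96 * s))
            for nm, t, s in zip(names, theta, se)}


def fit_frequency_cline(
    positions,
    counts,
    n_trials=2,
    shapes: tuple[str, ...] = SHAPES,
    n_restarts: int = 8,
    seed: int = 0,
    compute_ci: bool = True,
) -> ClineFit:
    """Maximum-likelihood cline fit with AIC competition across ``shapes``.

    ``counts`` are per-observation successes (e.g. copies of the focal
    arrangement per diploid snail, so 0..2) and ``n_trials`` the per-
    observation totals (scalar or array).  The likelihood is binomial with
    p(x) from the shape under test; optimization runs on transformed scales
    (log width, logit end frequencies, log tail distance, logit tail slope)
    with seeded multi-start L-BFGS-B.
    """
    x = np.asarray(positions, dtype=float)
    g = np.asarray(counts, dtype=float)
    n = np.broadcast_to(np.asarray(n_trials, dtype=float), g.shape).copy()
    if x.shape != g.shape:
        raise ValueError("positions and counts must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct positions")
    if np.any(g < 0) or np.any(g > n):
        raise ValueError("counts must lie in [0, n_trials]")
    rng = np.random.default_rng(seed)
    note = ""
    if g.sum() == 0 or g.sum() == n.sum():
        # monomorphic: only the constant model is identified
        mono = _fit_one_shape("constant", x, g, n, 2, rng, None)
        fit = ClineFit(models={"constant": mono}, selected="constant",
                       note="monomorphic data; constant model returned")
        return fit
    models: dict[str, ModelFit] = {}
    parent = None
    for shape in shapes:
        m = _fit_one_shape(shape, x, g, n, n_restarts, rng, parent)
        models[shape] = m
        if shape == "sigmoid":
            parent = m
    selected = _select_model(models)
    fit = ClineFit(models=models, selected=selected, note=note)
    fit.gof = _binomial_gof(x, g, n, fit)
    if compute_ci:
        m = models[selected]
        fit.ci = _wald_ci(_binom_nll, m.theta, (selected, x, g, n),
                          _PARAM_NAMES[selected])
    return fit


def _binomial_gof(x, g, n, fit: ClineFit) -> float:
    """Deviance pseudo-R^2 from a binomial regression of the observed counts
    on the fitted logit frequency (1 - residual/null deviance)."""
    p_hat = np.clip(cline_frequency(x, fit.params), 1e-9, 1 - 1e-9)
    eta = _logit(p_hat)
    if np.std(eta) < 1e-9:
        return 0.0

    def nll_glm(beta):
        p = np.clip(_expit(beta[0] + beta[1] * eta), _EPS, 1 - _EPS)
        return -np.sum(g * np.log(p) + (n - g) * np.log1p(-p))

    res = minimize(nll_glm, np.array([0.0, 1.0]), method="BFGS")
    pbar = g.sum() / n.sum()
    ll_null = np.sum(g * np.log(max(pbar, _EPS))
                     + (n - g) * np.log(max(1 - pbar, _EPS)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ghat = np.clip(g / n, _EPS, 1 - _EPS)
    ll_sat = np.sum(g * np.log(ghat) + (n - g) * np.log1p(-ghat))
    dev_res = 2.0 * (ll_sat + res.fun)
    dev_null = 2.0 * (ll_sat - ll_null)
    if dev_null <= 0:
        return 0.0
    return float(1.0 - dev_res / dev_null)


# ---------------------------------------------------------------------------
# phenotype (size) cline
# ---------------------------------------------------------------------------


def _gauss_nll(theta, x, y):
    c, log_w, mu_min, mu_max, log_sd = theta
    p = ClineParams(shape="sigmoid", center=c, width=float(np.exp(log_w)))
    f = _sigmoid_fraction(x, p)
    mu = mu_min + (mu_max - mu_min) * f
    sd = float(np.exp(log_sd))
    return 0.5 * np.sum(((y - mu) / sd) ** 2) + len(y) * (log_sd
                                                          + 0.5 * math.log(2 * math.pi))


def fit_size_cline(positions, sizes, n_restarts: int = 8, seed: int = 0) -> ClineFit:
    """Fit a simple symmetric sigmoid cline to a quantitative trait (mm).

    Gaussian likelihood with mean mu(x) = mu_min + (mu_max - mu_min) f(x) and
    constant residual SD.  Returns center/width/end means with Wald CIs on the
    working scales.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 individuals")
    if np.std(y) < 1e-12:
        raise ValueError("zero size variance; cline unidentifiable")
    xmin, xmax = float(x.min()), float(x.max())
    span = max(xmax - xmin, 1.0)
    ylo, yhi = float(np.min(y)), float(np.max(y))
    yr = max(yhi - ylo, 1e-6)
    bounds = [(xmin - 0.5 * span, xmax + 0.5 * span),
              (math.log(0.1), math.log(10 * span)),
              (ylo - yr, yhi + yr), (ylo - yr, yhi + yr),
              (math.log(1e-3 * yr), math.log(10 * yr))]
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds]); hi = np.array([b[1] for b in bounds])
    # orient using the ends of the transect
    y_lo_end = y[x <= xmin + 0.25 * span].mean()
    y_hi_end = y[x >= xmax - 0.25 * span].mean()
    starts = [np.array([0.5 * (xmin + xmax), math.log(span / 3),
                        y_lo_end, y_hi_end, math.log(max(np.std(y) / 2, 1e-3))])]
    for _ in range(n_restarts):
        starts.append(lo + (hi - lo) * rng.random(len(bounds)))
    best = None
    for s in starts:
        res = minimize(_gauss_nll, np.clip(s, lo, hi), args=(x, y),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    c, log_w, mu_min, mu_max, log_sd = best.x
    params = ClineParams(shape="sigmoid", center=float(c),
                         width=float(np.exp(log_w)), mu_min=float(mu_min),
                         mu_max=float(mu_max), sd=float(np.exp(log_sd)))
    ll = -float(best.fun)
    m = ModelFit("sigmoid", np.asarray(best.x), params, ll, 2 * 5 - 2 * ll, 5,
                 bool(best.success))
    names = ["c", "log_w", "mu_min", "mu_max", "log_sd"]
    ci = _wald_ci(_gauss_nll, m.theta, (x, y), names)
    note = ""
    se_lw = (ci["log_w"][1] - ci["log_w"][0]) / (2 * 1.96)
    # a trait step smaller than ~2 residual SDs cannot pin down the width
    if (not np.isfinite(se_lw) or se_lw > 3.0
            or abs(mu_max - mu_min) < 2.0 * params.sd):
        note = "width unidentifiable (flat trait profile)"
    return ClineFit(models={"sigmoid": m}, selected="sigmoid", ci=ci, note=note)


# ---------------------------------------------------------------------------
# per-SNP cline scan
# ---------------------------------------------------------------------------


def scan_snp_clines(
    g,
    samples: pd.DataFrame,
    min_end_diff: float = 0.10,
    end_window_m: float = 25.0,
    shapes: tuple[str, ...] = ("constant", "linear", "sigmoid"),
    n_restarts: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP, per-transect cline scan.

    SNPs whose allele-frequency difference between the terminal
    ``end_window_m`` windows is below ``min_end_diff`` are skipped.  Retained
    SNPs get the three-model AIC competition; a SNP is flagged ``clinal``
    when the sigmoid beats both the constant and the linear model by more
    than 4 AIC units.  The reported center/width/end frequencies and slope
    ``(pmax - pmin)/w`` come from the sigmoid fit.
    """
    rows = []
    order = samples.reset_index(drop=True)
    id_to_col = {s: i for i, s in enumerate(g.samples)}
    for transect, sub in order.groupby("transect", sort=True):
        cols = np.array([id_to_col[s] for s in sub["id"]])
        x = sub["path_pos_m"].to_numpy(float)
        xmin, xmax = x.min(), x.max()
        lo_m = x <= xmin + end_window_m
        hi_m = x >= xmax - end_window_m
        dos = g.dosages[:, cols]
        called = dos != -1
        dosf = np.where(called, dos, 0).astype(float)

        def _end_freq(mask):
            n = (called[:, mask]).sum(axis=1) * 2.0
            alt = dosf[:, mask].sum(axis=1)
            with np.errstate(invalid="ignore"):
                return np.where(n > 0, alt / n, np.nan)

        p_lo, p_hi = _end_freq(lo_m), _end_freq(hi_m)
        end_diff = np.abs(p_hi - p_lo)
        for j in np.flatnonzero(end_diff >= min_end_diff):
            m = called[j]
            fit = fit_frequency_cline(x[m], dosf[j, m], 2, shapes=shapes,
                                      n_restarts=n_restarts, seed=seed,
                                      compute_ci=False)
            sig = fit.models.get("sigmoid")
            clinal = False
            if sig is not None:
                others = [fit.models[s].aic for s in ("constant", "linear")
                          if s in fit.models]
                clinal = bool(others) and all(sig.aic < a - 4.0 for a in others)
            p = sig.params if sig is not None else fit.params
            rows.append({
                "transect": transect,
                "site": j,
                "contig": g.sites["contig"].iloc[j],
                "pos": g.sites["pos"].iloc[j],
                "cM": g.sites["cM"].iloc[j] if "cM" in g.sites else np.nan,
                "p_end_low": p_lo[j],
                "p_end_high": p_hi[j],
                "end_diff": end_diff[j],
                "selected": fit.selected,
                "center": p.center,
                "width": p.width,
                "pmin": p.pmin,
                "pmax": p.pmax,
                "slope": (p.pmax - p.pmin) / p.width,
                "clinal": clinal,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_IS in distance bins
# ---------------------------------------------------------------------------


@dataclass
class FisResult:
    """Per-bin heterozygote-deficit table and bootstrap p-values."""

    table: pd.DataFrame  # bin, x_lo, x_hi, n, h_obs, h_exp, fis, p, p_bonferroni
    bin_edges: np.ndarray
    n_boot: int


def _fis_core(het_obs, het_prob, positions, nbins, n_boot, rng):
    x = np.asarray(positions, dtype=float)
    edges = np.linspace(x.min(), x.max(), nbins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, nbins - 1)
    rows = []
    for b in range(nbins):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            rows.append((b, edges[b], edges[b + 1], 0, np.nan, np.nan, np.nan,
                         np.nan))
            continue
        hexp = float(het_prob[m].sum())
        hobs = float(het_obs[m].sum())
        if hexp <= 0:
            rows.append((b, edges[b], edges[b + 1], n, hobs, hexp, np.nan,
                         np.nan))
            continue
        fis = 1.0 - hobs / hexp
        draws = (rng.random((n_boot, n)) < het_prob[m]).sum(axis=1)
        # mid-p two-sided bootstrap p-value: ties at the observed count are
        # counted half so the p-value stays ~uniform despite discreteness
        ge = np.count_nonzero(draws > hobs) + 0.5 * np.count_nonzero(draws == hobs)
        le = np.count_nonzero(draws < hobs) + 0.5 * np.count_nonzero(draws == hobs)
        p = min(1.0, 2.0 * min(ge, le) / n_boot)
        rows.append((b, edges[b], edges[b + 1], n, hobs, hexp, fis, p))
    df = pd.DataFrame(rows, columns=["bin", "x_lo", "x_hi", "n", "h_obs",
                                     "h_exp", "fis", "p"])
    n_valid = int(df["p"].notna().sum())
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * max(n_valid, 1))
    return FisResult(df, edges, n_boot)


def fis_by_bins(
    genotypes,
    positions,
    fit: ClineFit,
    nbins: int = 7,
    n_boot: int = 10000,
    seed: int = 0,
) -> FisResult:
    """Heterozygote deficit F_IS = 1 - Hobs/Hexp in equal-distance bins.

    Expected heterozygote counts come from the fitted cline: for individual i
    at x_i the heterozygote probability is 2 p(x_i) (1 - p(x_i)).  The
    two-sided p-value is a parametric bootstrap drawing genotypes from
    Binomial(2, p(x_i)); Bonferroni correction runs over the non-empty bins.
    """
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be diploid counts 0/1/2")
    x = np.asarray(positions, dtype=float)
    p = np.clip(cline_frequency(x, fit.params), 0.0, 1.0)
    het_prob = 2.0 * p * (1.0 - p)
    rng = np.random.default_rng(seed)
    return _fis_core((g == 1).astype(float), het_prob, x, nbins, n_boot, rng)


def fis_by_bins_multiallelic(
    allele_pairs,
    positions,
    fits: list[ClineFit],
    nbins: int = 7,
    n_boot: int = 10000,
    seed: int = 0,
) -> FisResult:
    """Multi-allelic variant: Hexp_i = 1 - sum_a p_a(x_i)^2 with the
    per-allele fitted clines renormalized to sum to one at each position."""
    pairs = np.asarray(allele_pairs)
    x = np.asarray(positions, dtype=float)
    P = np.stack([np.clip(cline_frequency(x, f.params), 1e-12, 1.0)
                  for f in fits], axis=0)
    P /= P.sum(axis=0, keepdims=True)
    het_prob = 1.0 - np.sum(P**2, axis=0)
    het_obs = (pairs[:, 0] != pairs[:, 1]).astype(float)
    rng = np.random.default_rng(seed)
    return _fis_core(het_obs, het_prob, x, nbins, n_boot, rng)


# ---------------------------------------------------------------------------
# path projection and legacy-site remapping
# ---------------------------------------------------------------------------


def project_to_path(coords, waypoints) -> np.ndarray:
    """Project points onto a piecewise-linear path; return arc-length (m).

    Each point maps to its nearest point on the path; ties between segments
    resolve to the lower arc length.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    wp = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if wp.shape[0] < 2:
        raise ValueError("need at least 2 waypoints")
    seg = np.diff(wp, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen < 1e-12):
        raise ValueError("degenerate (repeated) waypoints")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    best_d = np.full(len(pts), np.inf)
    best_arc = np.zeros(len(pts))
    for i in range(len(seg)):
        rel = pts - wp[i]
        t = np.clip(rel @ seg[i] / seglen[i] ** 2, 0.0, 1.0)
        foot = wp[i] + t[:, None] * seg[i]
        d = np.linalg.norm(pts - foot, axis=1)
        better = d < best_d - 1e-12  # ties keep the earlier (lower) arc length
        best_arc[better] = cum[i] + t[better] * seglen[i]
        best_d[better] = d[better]
    return best_arc


def map_legacy_sites(site_coords, snail_coords, snail_path_pos) -> np.ndarray:
    """Assign each legacy sampling site the path position of its nearest
    current snail (Euclidean); ties resolve to the smaller path position."""
    sites = np.atleast_2d(np.asarray(site_coords, dtype=float))
    snails = np.atleast_2d(np.asarray(snail_coords, dtype=float))
    pos = np.asarray(snail_path_pos, dtype=float)
    if len(snails) == 0:
        raise ValueError("empty snail set")
    out = np.empty(len(sites))
    for i, s in enumerate(sites):
        d = np.linalg.norm(snails - s, axis=1)
        tied = np.flatnonzero(d <= d.min() + 1e-12)
        out[i] = pos[tied].min()
    return out


# ---------------------------------------------------------------------------
# selection from cline width
# ---------------------------------------------------------------------------


@dataclass
class SelectionEstimate:
    """Selection implied by a cline of width w under dispersal sigma.

    Uses the abrupt-habitat-change, no-dominance relation
    ``width = 1.732 sigma / sqrt(s*)`` so ``s* = (1.732 sigma / w)^2``.
    """

    sigma: float
    width: float
    s_star: float


def selection_from_width(width: float, sigma: float) -> SelectionEstimate:
    if width <= 0 or sigma <= 0:
        raise ValueError("width and sigma must be positive")
    s = (1.732 * sigma / width) ** 2
    return SelectionEstimate(sigma=float(sigma), width=float(width),
                             s_star=float(s))
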