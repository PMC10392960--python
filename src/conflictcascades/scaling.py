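"""Heavy-tail scaling analysis of avalanche properties.

Avalanche properties — fatalities F, reports R (event count), duration T
(bins spanned), sites N (distinct cells), diameter L (max pairwise
great-circle distance, km), area A (summed cell areas, km^2) — are fit
with power-law tails P(X) ~ X^(-alpha) above a lower cutoff X_min using
maximum likelihood with a Kolmogorov-Smirnov scan for X_min, a
semiparametric bootstrap goodness-of-fit p-value (p > 0.1 counts as a
plausible power law), nonparametric bootstrap exponent errors, and a
normalized (Vuong) likelihood-ratio comparison against a lognormal on the
common tail.

Dynamical scaling links duration to the size measures, X ~ T^gamma; with
P(T) ~ T^(-alpha) a change of variables gives the exponent relation for
the size tail P(X) ~ X^(-tau):

    tau - 1 = (alpha - 1) / gamma.

(The relation's orientation — gamma dividing rather than multiplying — is
pinned down by a synthetic change-of-variables test in the suite.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

from ._geo import haversine_km

ALPHA_MAX = 10.0


# ---------------------------------------------------------------- properties

def avalanche_properties(avalanches, events: pd.DataFrame, tess) -> pd.DataFrame:
    """One row of (F, R, T, N, L, A) per avalanche with at least one event.

    Duration T is the inclusive bin span; L the max pairwise great-circle
    distance between member event locations; A the summed area of the
    distinct member cells.
    """
    by_event = events.set_index("event_id")
    areas = tess.cell_areas_km2
    rows = []
    for av in avalanches:
        if not av.event_ids:
            continue
        sub = by_event.loc[sorted(av.event_ids)]
        lon = sub["lon"].to_numpy()
        lat = sub["lat"].to_numpy()
        if len(lon) > 1:
            i, j = np.triu_indices(len(lon), k=1)
            L = float(haversine_km(lon[i], lat[i], lon[j], lat[j]).max())
        else:
            L = 0.0
        rows.append({
            "avalanche_id": av.avalanche_id,
            "F": int(sub["fatalities"].sum()),
            "R": int(len(sub)),
            "T": int(av.end_bin - av.start_bin + 1),
            "N": int(len(av.cells)),
            "L": L,
            "A": float(areas[sorted(av.cells)].sum()),
            "is_singleton": av.is_singleton,
        })
    return pd.DataFrame(rows, columns=["avalanche_id", "F", "R", "T", "N", "L",
                                       "A", "is_singleton"])


# ------------------------------------------------------------ power-law MLE

def _alpha_mle_continuous(x: np.ndarray, xmin: float) -> float:
    return 1.0 + x.size / np.sum(np.log(x / xmin))


def _discrete_negll(alpha: float, logsum: float, n: int, xmin: float) -> float:
    return n * np.log(special.zeta(alpha, xmin)) + alpha * logsum


def _alpha_mle_discrete(x: np.ndarray, xmin: float) -> float:
    logsum = float(np.sum(np.log(x)))
    res = optimize.minimize_scalar(
        _discrete_negll, bounds=(1.0 + 1e-6, ALPHA_MAX), method="bounded",
        args=(logsum, x.size, xmin))
    return float(res.x)


def _ks_continuous(x: np.ndarray, alpha: float, xmin: float) -> float:
    xs = np.sort(x)
    cdf = 1.0 - (xs / xmin) ** (1.0 - alpha)
    emp_hi = np.arange(1, xs.size + 1) / xs.size
    emp_lo = np.arange(0, xs.size) / xs.size
    return float(max(np.abs(emp_hi - cdf).max(), np.abs(emp_lo - cdf).max()))


def _discrete_cdf(values: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """CDF P(X <= v) of the discrete power law at the given integer values."""
    hi = int(values.max())
    ks = np.arange(int(xmin), hi + 1, dtype=float)
    pmf = ks ** (-alpha) / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    return cdf[(values - int(xmin)).astype(int)]


def _ks_discrete(x: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.sort(x).astype(int)
    uniq, counts = np.unique(xs, return_counts=True)
    emp = np.cumsum(counts) / xs.size
    model = _discrete_cdf(uniq, alpha, xmin)
    emp_lo = np.concatenate([[0.0], emp[:-1]])
    model_lo = np.concatenate([[0.0], model[:-1]])
    return float(max(np.abs(emp - model).max(), np.abs(emp_lo - model_lo).max()))


def _xmin_candidates(x: np.ndarray, max_candidates: int = 100) -> np.ndarray:
    uniq = np.unique(x)
    uniq = uniq[:-1] if uniq.size > 1 else uniq  # need data strictly above
    if uniq.size > max_candidates:
        idx = np.unique(np.linspace(0, uniq.size - 1, max_candidates).astype(int))
        uniq = uniq[idx]
    return uniq


def _fit_tail(x: np.ndarray, discrete: bool, xmin_fixed=None,
              min_tail: int = 10) -> tuple[float, float, float, int]:
    """Scan xmin by KS distance; return (alpha, xmin, ks, n_tail)."""
    best = None
    candidates = ([xmin_fixed] if xmin_fixed is not None
                  else _xmin_candidates(x))
    for xmin in candidates:
        tail = x[x >= xmin]
        if tail.size < min_tail or np.unique(tail).size < 2:
            continue
        if discrete:
            alpha = _alpha_mle_discrete(tail, int(xmin))
            ks = _ks_discrete(tail, alpha, int(xmin))
        else:
            alpha = _alpha_mle_continuous(tail, float(xmin))
            ks = _ks_continuous(tail, alpha, float(xmin))
        if best is None or ks < best[2]:
            best = (float(alpha), float(xmin), float(ks), int(tail.size))
    if best is None:
        raise ValueError("no viable lower cutoff (too few samples above any xmin)")
    return best


def _sample_powerlaw(n: int, alpha: float, xmin, discrete: bool,
                     rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    if discrete:
        # standard continuous-approximation sampler for the discrete law
        return np.floor((xmin - 0.5) * (1.0 - u) ** (-1.0 / (alpha - 1.0)) + 0.5)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def _lognormal_tail_negll(params, logx: np.ndarray, log_xmin: float) -> float:
    mu, sigma = params
    if sigma <= 0:
        return np.inf
    z = (logx - mu) / sigma
    z_min = (log_xmin - mu) / sigma
    # density of log x truncated to log x >= log xmin
    log_tail = special.log_ndtr(-z_min)
    return float(np.sum(0.5 * z**2 + np.log(sigma) + 0.5 * np.log(2 * np.pi)
                        + logx + log_tail))


def _lognormal_tail_ll(x: np.ndarray, xmin: float) -> tuple[np.ndarray, tuple]:
    """Pointwise log-likelihoods of the xmin-truncated lognormal MLE fit."""
    logx = np.log(x)
    log_xmin = np.log(xmin)
    x0 = np.array([logx.mean(), max(logx.std(), 0.1)])
    res = optimize.minimize(_lognormal_tail_negll, x0, args=(logx, log_xmin),
                            method="Nelder-Mead")
    mu, sigma = res.x
    z = (logx - mu) / sigma
    z_min = (log_xmin - mu) / sigma
    ll = (-0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi) - logx
          - special.log_ndtr(-z_min))
    return ll, (float(mu), float(sigma))


def _powerlaw_tail_ll(x: np.ndarray, alpha: float, xmin, discrete: bool) -> np.ndarray:
    if discrete:
        return -alpha * np.log(x) - np.log(special.zeta(alpha, xmin))
    return np.log(alpha - 1.0) - np.log(xmin) - alpha * np.log(x / xmin)


class PowerLawFit(BaseEstimator):
    """MLE power-law tail fit with KS cutoff scan (Clauset-style procedure).

    Parameters
    ----------
    discrete : bool, default False
        Use the zeta-normalized discrete law (for counts) instead of the
        continuous Pareto form.
    xmin : number, optional
        Fix the lower cutoff instead of scanning.
    n_bootstrap : int, default 1000
        Nonparametric resamples for the exponent standard deviation.
    n_gof : int, default 100
        Semiparametric surrogates for the goodness-of-fit p-value.
    random_state : int, default 0

    Attributes
    ----------
    alpha_, xmin_, ks_, n_tail_ : tail fit
    alpha_sd_ : bootstrap SD of alpha
    gof_p_ : fraction of surrogate KS distances >= observed (> 0.1 counts
        as a plausible power law)
    lr_lognormal_, lr_p_ : signed log-likelihood ratio vs a truncated
        lognormal on the same tail and its Vuong-normalized p-value
        (positive ratio favors the power law)
    """

    def __init__(self, discrete: bool = False, xmin=None, n_bootstrap: int = 1000,
                 n_gof: int = 100, random_state: int = 0):
        self.discrete = discrete
        self.xmin = xmin
        self.n_bootstrap = n_bootstrap
        self.n_gof = n_gof
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x) & (x > 0)]
        if x.size < 10:
            raise ValueError("need at least 10 positive samples")
        if np.unique(x).size < 2:
            raise ValueError("degenerate input: all samples equal")
        rng = np.random.default_rng(self.random_state)

        self.alpha_, self.xmin_, self.ks_, self.n_tail_ = _fit_tail(
            x, self.discrete, xmin_fixed=self.xmin)

        # bootstrap SD of alpha (full refit incl. cutoff scan per resample)
        alphas = []
        for _ in range(self.n_bootstrap):
            xb = rng.choice(x, size=x.size, replace=True)
            try:
                a, *_ = _fit_tail(xb, self.discrete, xmin_fixed=self.xmin)
                alphas.append(a)
            except ValueError:
                continue
        self.alpha_sd_ = float(np.std(alphas)) if len(alphas) > 1 else float("nan")

        # semiparametric goodness-of-fit bootstrap
        body = x[x < self.xmin_]
        p_tail = self.n_tail_ / x.size
        exceed = 0
        for _ in range(self.n_gof):
            from_tail = rng.random(x.size) < p_tail
            n_t = int(from_tail.sum())
            synth = np.concatenate([
                _sample_powerlaw(n_t, self.alpha_, self.xmin_, self.discrete, rng),
                rng.choice(body, size=x.size - n_t, replace=True) if body.size
                else _sample_powerlaw(x.size - n_t, self.alpha_, self.xmin_,
                                      self.discrete, rng),
            ])
            try:
                _, _, ks, _ = _fit_tail(synth, self.discrete, xmin_fixed=self.xmin)
            except ValueError:
                continue
            if ks >= self.ks_:
                exceed += 1
        self.gof_p_ = exceed / self.n_gof if self.n_gof else float("nan")

        # Vuong-normalized likelihood ratio vs lognormal on the common tail
        tail = x[x >= self.xmin_]
        ll_pl = _powerlaw_tail_ll(tail, self.alpha_, self.xmin_, self.discrete)
        ll_ln, self.lognormal_params_ = _lognormal_tail_ll(tail, self.xmin_)
        diff = ll_pl - ll_ln
        self.lr_lognormal_ = float(diff.sum())
        sd = diff.std()
        if sd > 0:
            self.lr_p_ = float(special.erfc(abs(self.lr_lognormal_)
                                            / (sd * np.sqrt(2.0 * tail.size))))
        else:
            self.lr_p_ = 1.0
        return self

    @property
    def plausible_power_law_(self) -> bool:
        return self.gof_p_ > 0.1


def fit_power_law(samples, discrete: bool = False, n_bootstrap: int = 1000,
                  n_gof: int = 100, rng: int = 0, xmin=None) -> PowerLawFit:
    """Functional wrapper around :class:`PowerLawFit`."""
    return PowerLawFit(discrete=discrete, xmin=xmin, n_bootstrap=n_bootstrap,
                       n_gof=n_gof, random_state=rng).fit(samples)


# -------------------------------------------------------- dynamical scaling

class DynamicalScalingFit(BaseEstimator):
    """Fit X ~ T^gamma on avalanches above both lower cutoffs.

    Durations are geometrically binned (default 8 bins per decade) and the
    slope of mean log X per bin against log T is taken by least squares —
    binning stops the abundant short avalanches from dominating the fit.

    Attributes: ``gamma_`` (the scaling exponent, e.g. dF/z for fatalities
    vs duration), ``intercept_``, ``gamma_se_``, ``n_bins_``, ``n_pairs_``.
    """

    def __init__(self, t_min: float = 1.0, x_min: float = 1.0,
                 bins_per_decade: int = 8):
        self.t_min = t_min
        self.x_min = x_min
        self.bins_per_decade = bins_per_decade

    def fit(self, T, X=None):
        if X is None:  # allow fit([(t, x), ...])
            arr = np.asarray(T, dtype=float)
            T, X = arr[:, 0], arr[:, 1]
        T = np.asarray(T, dtype=float).ravel()
        X = np.asarray(X, dtype=float).ravel()
        keep = (T >= self.t_min) & (X >= self.x_min) & (T > 0) & (X > 0)
        T, X = T[keep], X[keep]
        if T.size == 0:
            raise ValueError("no pairs above the lower cutoffs")
        logt, logx = np.log10(T), np.log10(X)
        lo, hi = logt.min(), logt.max()
        n_edges = max(int(np.ceil((hi - lo) * self.bins_per_decade)) + 1, 2)
        edges = np.linspace(lo, hi + 1e-12, n_edges)
        which = np.clip(np.digitize(logt, edges) - 1, 0, n_edges - 2)
        bt, bx = [], []
        for k in range(n_edges - 1):
            m = which == k
            if m.any():
                bt.append(logt[m].mean())
                bx.append(logx[m].mean())
        if len(bt) < 3:
            raise ValueError(f"only {len(bt)} usable duration bins; need >= 3")
        bt, bx = np.asarray(bt), np.asarray(bx)
        A = np.vander(bt, 2)
        coef, res, *_ = np.linalg.lstsq(A, bx, rcond=None)
        self.gamma_ = float(coef[0])
        self.intercept_ = float(coef[1])
        resid = bx - A @ coef
        dof = max(len(bt) - 2, 1)
        sxx = np.sum((bt - bt.mean()) ** 2)
        self.gamma_se_ = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if sxx > 0 else float("nan")
        self.n_bins_ = len(bt)
        self.n_pairs_ = int(T.size)
        return self


def fit_dynamical_scaling(pairs, t_min: float = 1.0, x_min: float = 1.0,
                          bins_per_decade: int = 8) -> DynamicalScalingFit:
    """Functional wrapper around :class:`DynamicalScalingFit`."""
    return DynamicalScalingFit(t_min=t_min, x_min=x_min,
                               bins_per_decade=bins_per_decade).fit(pairs)


# -------------------------------------------------------- exponent relation

@dataclass
class ExponentRelation:
    measured: float    # tau - 1 from the size-tail fit
    predicted: float   # (alpha - 1) / gamma from duration tail + scaling fit
    combined_sd: float
    compatible: bool


def check_exponent_relation(size_fit: PowerLawFit, duration_fit: PowerLawFit,
                            dyn_fit: DynamicalScalingFit) -> ExponentRelation:
    """Test tau - 1 = (alpha - 1) / gamma between independent fits.

    ``size_fit`` gives tau (tail of the size measure), ``duration_fit``
    gives alpha (tail of durations), ``dyn_fit`` gives gamma (size vs
    duration). Compatibility: |measured - predicted| <= 2 x combined SD,
    with the prediction's SD propagated from the alpha and gamma errors.
    """
    gamma = dyn_fit.gamma_
    measured = size_fit.alpha_ - 1.0
    predicted = (duration_fit.alpha_ - 1.0) / gamma
    var = size_fit.alpha_sd_**2 + (duration_fit.alpha_sd_ / gamma) ** 2
    if np.isfinite(dyn_fit.gamma_se_):
        var += ((duration_fit.alpha_ - 1.0) / gamma**2 * dyn_fit.gamma_se_) ** 2
    sd = float(np.sqrt(var))
    return ExponentRelation(measured=float(measured), predicted=float(predicted),
                            combined_sd=sd,
                            compatible=bool(abs(measured - predicted) <= 2 * sd))
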