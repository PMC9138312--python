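"""Inference of fragmentation kinetics from length-distribution decays.

Under pure fragmentation with rate law ``B(x) = (alpha*x)**gamma``, the
mean fibril length enters a self-similar regime in which

    mu(t) = C * t**(-1/gamma)        for t > t_s,

with a plateau at earlier times where the asymptote is not yet reached.
``gamma`` and ``C`` are obtained by straight-line regression in log-log
coordinates over the post-plateau points, with the plateau time ``t_s``
selected on the observed time grid by residual minimisation. Given
``gamma``, each post-plateau length distribution yields a moment
estimate of the rate scale

    alpha_t = (gamma * t * M_gamma(t)) ** (-1/gamma),
    M_gamma(t) = int x**gamma f(t, x) dx,

which is time-constant under exact self-similar decay; ``alpha`` is
their arithmetic mean. Standard errors come from delete-one jackknife
over time points. Fitted rate laws for different fibril polymorphs are
compared through their B(x) curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import LengthSample
from .simulate import FragmentationParams, division_rate

__all__ = [
    "DecaySeries",
    "FragmentationFit",
    "mean_length_model",
    "fit_length_decay",
    "estimate_alpha",
    "jackknife_se",
    "fit_fragmentation",
    "compare_fits",
    "rate_law_crossing",
]

#: Minimum particle count for a time point to enter the decay fit.
MIN_COUNT_PER_TIMEPOINT = 10


@dataclass
class DecaySeries:
    """Mean-length decay data: mu(t) at strictly increasing times (s)."""

    times: np.ndarray
    mean_lengths: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_lengths = np.asarray(self.mean_lengths, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        if self.times.shape != self.mean_lengths.shape:
            raise ValueError("times and mean_lengths must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_lengths <= 0):
            raise ValueError("mean lengths must be > 0")


@dataclass
class FragmentationFit:
    """Best-fit pure-fragmentation model for one fibril type."""

    params: FragmentationParams
    se_gamma: float
    se_log10_alpha: float
    alpha_t: dict[float, float]
    residual_sd: float
    times_used: np.ndarray
    name: str = ""

    def rate(self, x):
        """Fitted B(x) = (alpha*x)**gamma in 1/s."""
        return division_rate(x, self.params)

    @property
    def b100(self) -> float:
        return float(self.rate(100.0))

    def to_dict(self) -> dict:
        p = self.params
        return {
            "name": self.name,
            "gamma": p.gamma,
            "se_gamma": self.se_gamma,
            "alpha": p.alpha,
            "log10_alpha": float(np.log10(p.alpha)),
            "se_log10_alpha": self.se_log10_alpha,
            "C": p.C,
            "t_s": p.t_s,
            "alpha_t": {str(t): a for t, a in self.alpha_t.items()},
            "B100": self.b100,
            "log10_B100": float(np.log10(self.b100)),
            "residual_sd": self.residual_sd,
            "times_used": list(map(float, self.times_used)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def mean_length_model(t, params: FragmentationParams):
    """Piecewise mean-length decay: C * t**(-1/gamma) beyond the plateau.

    For t <= t_s the value is held at the plateau level C * t_s**(-1/gamma),
    so the curve is continuous at t_s. Requires fitted C and t_s on
    ``params``. Vectorised over t.
    """
    if params.C is None or params.t_s is None:
        raise ValueError("params must carry fitted C and t_s")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.t_s == 0 and np.any(t == 0):
        raise ValueError("mu(0) is undefined when t_s = 0 (no plateau)")
    inv_g = 1.0 / params.gamma
    plateau = params.C * params.t_s**-inv_g if params.t_s > 0 else np.inf
    with np.errstate(divide="ignore"):
        decay = params.C * np.where(t > 0, t, np.nan) ** -inv_g
    out = np.where(t > params.t_s, decay, plateau)
    return float(out) if out.ndim == 0 else out


def fit_length_decay(series: DecaySeries, min_points: int = 3):
    """Fit the power-law decay, selecting the plateau time on the grid.

    For every candidate t_s (0, meaning no plateau, or an observed time
    leaving at least ``min_points`` later points), a least-squares line
    in (log10 t, log10 mu) over t > t_s gives slope -1/gamma and
    intercept log10 C. Candidates are scored by the residual standard
    deviation per degree of freedom of the full piecewise model —
    plateau branch included — over all usable points, so a true plateau
    is identified rather than merely ignored; the winner must have a
    negative slope, and ties go to the smaller t_s (more fitted data).
    Time points with fewer than 10 particles are excluded with a warning.

    Returns
    -------
    (gamma, C, t_s, residuals) where residuals are in log10 space over
    the fitted points.

    Raises
    ------
    ValueError
        If fewer than 4 usable points exist or no candidate shows decay.
    """
    t = series.times
    mu = series.mean_lengths
    use = t > 0
    if series.counts is not None:
        low = use & (np.asarray(series.counts) < MIN_COUNT_PER_TIMEPOINT)
        if low.any():
            warnings.warn(
                f"excluding {int(low.sum())} time point(s) with fewer than "
                f"{MIN_COUNT_PER_TIMEPOINT} particles from the decay fit",
                stacklevel=2,
            )
        use &= ~low
    t, mu = t[use], mu[use]
    if t.size < 4:
        raise ValueError("need at least 4 positive-time points with enough particles")

    candidates = [0.0] + [float(ts) for ts in t if np.sum(t > ts) >= min_points]
    dof = max(1, t.size - 3)  # gamma, C and t_s are all estimated
    best = None
    for ts in candidates:
        sel = t > ts
        lt, lm = np.log10(t[sel]), np.log10(mu[sel])
        res = stats.linregress(lt, lm)
        if res.slope >= 0:
            continue
        # Full-model residuals in log space: line beyond ts, constant
        # plateau (the line's value at ts) before it.
        pred = res.intercept + res.slope * np.log10(np.where(t > ts, t, max(ts, t[0])))
        if ts > 0:
            pred[t <= ts] = res.intercept + res.slope * np.log10(ts)
        resid_all = np.log10(mu) - pred
        score = float(np.sqrt(np.sum(resid_all**2) / dof))
        if best is None or score < best[0] - 1e-12:
            best = (score, ts, res, resid_all)
    if best is None:
        raise ValueError("no decay detected: no candidate plateau gives a negative slope")
    score, ts, res, resid = best
    gamma = -1.0 / res.slope
    C = 10.0**res.intercept
    return gamma, C, ts, resid


def estimate_alpha(
    samples: list[LengthSample],
    gamma: float,
    t_s: float,
) -> tuple[float, dict[float, float]]:
    """Moment estimate of the rate scale alpha from post-plateau samples.

    For each sample with t > t_s, computes the gamma-moment
    ``M_gamma(t) = sum(w x^gamma) / sum(w)`` of the bias-weighted
    normalised length distribution and sets
    ``alpha_t = (gamma * t * M_gamma)**(-1/gamma)``; alpha is the
    arithmetic mean of the per-time values, which are time-constant under
    exact self-similar decay.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    alpha_t: dict[float, float] = {}
    for s in samples:
        if s.time <= t_s:
            warnings.warn(
                f"sample at t = {s.time} s <= t_s = {t_s} s excluded from alpha estimation",
                stacklevel=2,
            )
            continue
        mg = s.moment(gamma)
        alpha_t[float(s.time)] = float((gamma * s.time * mg) ** (-1.0 / gamma))
    if not alpha_t:
        raise ValueError("no samples beyond t_s; cannot estimate alpha")
    return float(np.mean(list(alpha_t.values()))), alpha_t


def jackknife_se(data, estimator) -> float:
    """Delete-one jackknife standard error of ``estimator(data)``.

    ``data`` is an indexable collection of exchangeable units (here:
    time points); ``estimator`` reduces such a collection to a scalar.
    """
    n = len(data)
    if n < 3:
        raise ValueError("jackknife needs at least 3 units")
    thetas = []
    for i in range(n):
        subset = [d for j, d in enumerate(data) if j != i]
        try:
            thetas.append(float(estimator(subset)))
        except Exception as exc:
            raise RuntimeError(f"estimator failed on leave-one-out subset {i}: {exc}") from exc
    thetas = np.asarray(thetas)
    return float(np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)))


def fit_fragmentation(
    samples: list[LengthSample],
    name: str = "",
    counts: np.ndarray | None = None,
) -> FragmentationFit:
    """Full inference for one fibril type: gamma, C, t_s, alpha, and SEs.

    Builds the mean-length decay from the bias-weighted samples, fits the
    power law, estimates alpha from the post-plateau gamma-moments, and
    attaches delete-one jackknife standard errors over time points
    (refitting gamma, then alpha, on every leave-one-out subset).
    """
    samples = sorted((s for s in samples if s.time > 0), key=lambda s: s.time)

    def _series(subset):
        return DecaySeries(
            times=np.array([s.time for s in subset]),
            mean_lengths=np.array([s.weighted_mean_length for s in subset]),
            counts=np.array([s.lengths.size for s in subset]),
        )

    gamma, C, t_s, resid = fit_length_decay(_series(samples))
    alpha, alpha_t = estimate_alpha(samples, gamma, t_s)

    def _gamma_of(subset):
        g, *_ = fit_length_decay(_series(subset))
        return g

    def _log_alpha_of(subset):
        g, _, ts_i, _ = fit_length_decay(_series(subset))
        a, _ = estimate_alpha(subset, g, ts_i)
        return np.log10(a)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_gamma = jackknife_se(samples, _gamma_of)
        se_log_alpha = jackknife_se(samples, _log_alpha_of)

    params = FragmentationParams(gamma=gamma, alpha=alpha, C=C, t_s=t_s)
    return FragmentationFit(
        params=params,
        se_gamma=se_gamma,
        se_log10_alpha=se_log_alpha,
        alpha_t=alpha_t,
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        times_used=np.array([s.time for s in samples if s.time > t_s]),
        name=name,
    )


def rate_law_crossing(p1: FragmentationParams, p2: FragmentationParams) -> float | None:
    """Length (nm) where two fitted rate laws cross, if gamma differs.

    Solves (a1 x)^g1 = (a2 x)^g2 in closed form:
    ln x = (g1 ln a1 - g2 ln a2) / (g2 - g1). Returns None for equal
    gamma (parallel laws in log-log).
    """
    if np.isclose(p1.gamma, p2.gamma):
        return None
    lx = (p1.gamma * np.log(p1.alpha) - p2.gamma * np.log(p2.alpha)) / (p2.gamma - p1.gamma)
    return float(np.exp(lx))


def compare_fits(
    fits: dict[str, FragmentationFit | FragmentationParams],
    x_range: tuple[float, float] = (10.0, 1000.0),
    n_grid: int = 50,
) -> dict:
    """Compare fitted rate laws across fibril types.

    Tabulates B(x) on a log-spaced grid over ``x_range``, the rank order
    at each grid point (power laws with different gamma cross, so the
    order may change along x), B at 100 nm, pairwise log10 rate ratios at
    100 nm, and all pairwise crossing lengths.

    Returns a dict with 'table' (DataFrame of B(x) and ranks), 'summary'
    (DataFrame of gamma/alpha/B100 with SEs where available), 'ratios'
    (DataFrame of pairwise log10 B100 ratios) and 'crossings'.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    names = list(fits)
    par = {
        k: (v.params if isinstance(v, FragmentationFit) else v) for k, v in fits.items()
    }
    x = np.geomspace(x_range[0], x_range[1], n_grid)
    tab = pd.DataFrame({"x_nm": x})
    for k in names:
        tab[f"B_{k}"] = division_rate(x, par[k])
    Bmat = tab[[f"B_{k}" for k in names]].to_numpy()
    order = np.argsort(-Bmat, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(order.shape[0])[:, None]
    ranks[rows, order] = np.arange(len(names))[None, :] + 1
    for j, k in enumerate(names):
        tab[f"rank_{k}"] = ranks[:, j]

    summary = []
    for k in names:
        p = par[k]
        f = fits[k] if isinstance(fits[k], FragmentationFit) else None
        b100 = division_rate(100.0, p)
        summary.append(
            {
                "name": k,
                "gamma": p.gamma,
                "se_gamma": f.se_gamma if f else np.nan,
                "alpha": p.alpha,
                "log10_alpha": np.log10(p.alpha),
                "se_log10_alpha": f.se_log10_alpha if f else np.nan,
                "B100": b100,
                "log10_B100": np.log10(b100),
            }
        )
    summary = pd.DataFrame(summary).set_index("name")

    ratio_rows = []
    crossings = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = np.log10(division_rate(100.0, par[a]) / division_rate(100.0, par[b]))
            ratio_rows.append({"pair": f"{a}/{b}", "log10_ratio_at_100nm": float(r)})
            crossings[f"{a}/{b}"] = rate_law_crossing(par[a], par[b])
    return {
        "table": tab,
        "summary": summary,
        "ratios": pd.DataFrame(ratio_rows),
        "crossings": crossings,
    }
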