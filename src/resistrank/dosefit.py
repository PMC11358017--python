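"""Calcium dose-response quantification and Hill-equation fitting.

A Fura-2 trace is reduced to a single normalized peak response,

    delta_ratio_norm = (max post-stimulus ratio - mean pre-stimulus ratio)
                       / ionomycin amplitude,

so responses from different wells are comparable on a 0..1 scale where 1 is
the ionophore (maximal) response. Normalized peaks at several agonist
concentrations are then fit with the Hill function

    y(c) = baseline + Emax * c^h / (EC50^h + c^h),

with EC50 optimized on the log10 scale from a multi-start grid. By default
the baseline is fixed at 0 (responses are already baseline-subtracted) and
the Hill coefficient h is free within [0.3, 4]; both can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HillParams",
    "HillFit",
    "CalciumTrace",
    "hill_curve",
    "peak_delta_ratio",
    "fit_hill",
    "compare_potency",
]

H_BOUNDS = (0.3, 4.0)


@dataclass(frozen=True)
class HillParams:
    """Hill-curve parameters: EC50 (M), slope h, maximal response, baseline."""

    ec50: float
    h: float = 1.0
    emax: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError("EC50 must be > 0")
        if not self.h > 0:
            raise ValueError("Hill coefficient must be > 0")
        if not 0 <= self.emax <= 1.5:
            raise ValueError("Emax must lie in [0, 1.5] (fraction of the ionomycin response)")


def hill_curve(conc: np.ndarray | float, params: HillParams) -> np.ndarray | float:
    """Hill function y(c) = baseline + Emax * c^h / (EC50^h + c^h); y(0) = baseline."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, c**params.h / (params.ec50**params.h + c**params.h), 0.0)
    out = params.baseline + params.emax * frac
    return float(out) if np.isscalar(conc) else out


@dataclass
class CalciumTrace:
    """One Fura-2 F340/F380 time course with its plate's ionomycin amplitude."""

    time: np.ndarray
    ratio: np.ndarray
    stimulus_time: float
    ionomycin_amplitude: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.shape != self.ratio.shape:
            raise ValueError("time and ratio vectors must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValueError("fluorescence ratios must be positive")
        if not (self.time[0] <= self.stimulus_time <= self.time[-1]):
            raise ValueError("stimulus time outside the recording")


def peak_delta_ratio(trace: CalciumTrace) -> float:
    """Normalized peak response: (post-stimulus max - pre-stimulus mean) / ionomycin."""
    if trace.ionomycin_amplitude <= 0:
        raise ValueError("ionomycin amplitude must be > 0")
    pre = trace.ratio[trace.time < trace.stimulus_time]
    post = trace.ratio[trace.time >= trace.stimulus_time]
    if pre.size < 5:
        raise ValueError("need >= 5 pre-stimulus samples for a stable baseline")
    if post.size == 0:
        raise ValueError("no post-stimulus samples")
    return float((post.max() - pre.mean()) / trace.ionomycin_amplitude)


@dataclass
class HillFit:
    """Result of a Hill least-squares fit.

    ``se`` holds asymptotic standard errors keyed like the parameters
    (``se["log10_ec50"]`` is on the log10 scale; ``se["ec50"]`` is the
    delta-method linear-scale error). Flags: ``converged`` from the
    optimizer, ``extrapolated`` when EC50 falls more than one log unit
    outside the fitted concentration range, ``identifiable`` False when
    SE(EC50)/EC50 > 1 (e.g. flat, response-free data).
    """

    params: HillParams
    se: dict[str, float]
    rss: float
    n_obs: int
    converged: bool
    extrapolated: bool
    identifiable: bool
    method: str = "least_squares_multistart"

    @property
    def ec50(self) -> float:
        return self.params.ec50


def _prepare_dose_response(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    conc = data["concentration_M"].to_numpy(dtype=float)
    resp = data["response"].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    pos = np.unique(conc[conc > 0])
    if pos.size < 4:
        raise ValueError("need >= 4 distinct positive concentrations to fit")
    return conc, resp


def fit_hill(
    data: pd.DataFrame,
    fix_baseline: bool = True,
    fix_h: float | None = None,
    fit_on_means: bool = False,
    n_starts: int = 7,
) -> HillFit:
    """Least-squares Hill fit to a (concentration_M, replicate, response) table.

    EC50 is parameterized as log10(EC50) and started from ``n_starts``
    log-spaced points spanning the observed concentration range; the best
    converged candidate (lowest residual sum of squares) is returned.
    With ``fit_on_means`` the fit uses per-concentration replicate means.
    """
    conc, resp = _prepare_dose_response(data)
    if fit_on_means:
        g = pd.DataFrame({"c": conc, "y": resp}).groupby("c", as_index=False).mean()
        conc, resp = g["c"].to_numpy(), g["y"].to_numpy()

    pos = conc[conc > 0]
    lo, hi = math.log10(pos.min()), math.log10(pos.max())
    resp_span = float(resp.max() - resp.min())

    # free parameters: log10_ec50, [h], emax, [baseline]
    names = ["log10_ec50"]
    lower = [lo - 3.0]
    upper = [hi + 3.0]
    if fix_h is None:
        names.append("h")
        lower.append(H_BOUNDS[0])
        upper.append(H_BOUNDS[1])
    names.append("emax")
    lower.append(0.0)
    upper.append(1.5)
    if not fix_baseline:
        names.append("baseline")
        lower.append(-0.5)
        upper.append(1.5)

    def unpack(theta: np.ndarray) -> HillParams:
        vals = dict(zip(names, theta))
        return HillParams(
            ec50=10.0 ** vals["log10_ec50"],
            h=vals.get("h", fix_h if fix_h is not None else 1.0),
            emax=min(max(vals["emax"], 0.0), 1.5),
            baseline=vals.get("baseline", 0.0),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return hill_curve(conc, unpack(theta)) - resp

    emax0 = min(max(resp_span, 1e-6), 1.5)
    best = None
    for start in np.linspace(lo - 0.5, hi + 0.5, n_starts):
        theta0 = [start]
        if fix_h is None:
            theta0.append(1.0)
        theta0.append(emax0)
        if not fix_baseline:
            theta0.append(float(resp.min()))
        sol = optimize.least_squares(
            residuals, theta0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    params = unpack(best.x)
    rss = float(2.0 * best.cost)
    n_obs = conc.size
    dof = max(n_obs - best.x.size, 1)
    sigma2 = rss / dof
    jtj = best.jac.T @ best.jac
    se = {name: math.nan for name in names}
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        for i, name in enumerate(names):
            se[name] = float(math.sqrt(max(cov[i, i], 0.0)))
    except np.linalg.LinAlgError:
        pass
    # delta method: SE(EC50) = EC50 * ln(10) * SE(log10 EC50)
    se["ec50"] = params.ec50 * math.log(10.0) * se["log10_ec50"] if math.isfinite(
        se["log10_ec50"]
    ) else math.nan

    log_ec50 = math.log10(params.ec50)
    extrapolated = bool(not (lo - 1.0 <= log_ec50 <= hi + 1.0))
    identifiable = bool(
        math.isfinite(se["ec50"]) and params.ec50 > 0 and se["ec50"] / params.ec50 <= 1.0
    )
    return HillFit(
        params=params,
        se=se,
        rss=rss,
        n_obs=n_obs,
        converged=bool(best.success),
        extrapolated=extrapolated,
        identifiable=identifiable,
    )


def compare_potency(fit_a: HillFit, fit_b: HillFit, level: float = 0.95) -> dict[str, float]:
    """EC50 ratio B/A with a log-scale error-propagation confidence interval.

    The ratio of half-maximal concentrations is the relative potency of the
    two agonists (ratio > 1: A is the more potent). The CI combines the two
    fits' log-scale standard errors in quadrature.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    from scipy import stats as _stats

    ratio = fit_b.ec50 / fit_a.ec50
    se_log = math.sqrt(
        (math.log(10.0) * fit_a.se["log10_ec50"]) ** 2
        + (math.log(10.0) * fit_b.se["log10_ec50"]) ** 2
    )
    z = float(_stats.norm.ppf(0.5 + level / 2.0))
    return {
        "ratio": ratio,
        "ci_low": ratio * math.exp(-z * se_log),
        "ci_high": ratio * math.exp(z * se_log),
        "level": level,
    }
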