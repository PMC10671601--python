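"""Flexible-logistic velocity profile, REGR profile and kinematic traits.

The axial velocity of root material relative to the quiescent center is
consistently sigmoidal in a steadily growing root: near zero in the
meristem, accelerating through the elongation zone, saturating at the
final elongation rate in mature tissue.  The four-parameter flexible
logistic of Morris & Silk,

    v(x) = v_f * [1 + exp(-k (x - x0))]**(-1/n),

captures this shape with final velocity ``v_f`` (mm/h), steepness ``k``
(mm^-1), reference position ``x0`` (mm from the QC) and asymmetry
exponent ``n``.  Its spatial derivative is the bell-shaped relative
elemental growth rate (REGR) profile, reported in % h^-1:

    REGR(x) = 100 * (v_f k / n) * u * (1 + u)**(-1/n - 1),   u = exp(-k (x - x0)),

whose peak sits at ``x0 - ln(n)/k``.  Four traits summarize the growth
zone: the maximum REGR, its axial position, the elongation-zone length
(where REGR exceeds 20% of its maximum), and the average growth rate,
which equals ``v_f``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "LogisticParams",
    "KinematicTraits",
    "FitResult",
    "FitError",
    "velocity_model",
    "regr_profile",
    "fit_flexible_logistic",
    "extract_traits",
]


class FitError(RuntimeError):
    """Raised when the velocity-profile fit fails to converge."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the flexible logistic velocity profile."""

    v_f: float  # final / average elongation rate, mm/h
    k: float  # steepness, mm^-1
    x0: float  # inflection reference position, mm from the QC
    n: float  # asymmetry exponent, dimensionless

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.v_f, self.k, self.x0, self.n)


@dataclass(frozen=True)
class KinematicTraits:
    """The four kinematic traits of the elongation zone."""

    max_regr: float  # % h^-1
    max_regr_position: float  # mm from the QC
    zone_length: float  # mm
    avg_growth_rate: float  # mm/h; equals the fitted v_f
    zone_apical_mm: float = np.nan
    zone_basal_mm: float = np.nan
    apical_clipped: bool = False


def velocity_model(params: LogisticParams, x) -> np.ndarray:
    """Evaluate the flexible logistic velocity profile at positions x (mm).

    Overflow-safe for large ``|k (x - x0)|`` via log-space evaluation.
    """
    x = np.asarray(x, dtype=float)
    z = -params.k * (x - params.x0)
    return params.v_f * np.exp(-np.logaddexp(0.0, z) / params.n)


def regr_profile(params: LogisticParams, x) -> np.ndarray:
    """REGR profile in % h^-1: the analytic derivative 100 * dv/dx."""
    x = np.asarray(x, dtype=float)
    z = -params.k * (x - params.x0)
    # log of u * (1 + u)^(-1/n - 1), with u = e^z
    log_shape = z - (1.0 / params.n + 1.0) * np.logaddexp(0.0, z)
    return 100.0 * (params.v_f * params.k / params.n) * np.exp(log_shape)


def _moving_median(x: np.ndarray, v: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x, kind="stable")
    xs, vs = x[order], v[order]
    half = window // 2
    med = np.array(
        [np.median(vs[max(0, i - half): i + half + 1]) for i in range(len(vs))]
    )
    return xs, med


def _initial_guess(x: np.ndarray, v: np.ndarray) -> LogisticParams:
    """Data-driven starting point: plateau from the upper percentile, x0 from
    the half-rise of a moving median, k from the local slope there."""
    v_f0 = max(float(np.percentile(v, 95)), 1e-6)
    window = max(11, len(x) // 20)
    xs, med = _moving_median(x, v, window)
    above = np.nonzero(med > v_f0 / 2.0)[0]
    if len(above):
        i0 = above[0]
        x0 = float(xs[i0])
    else:
        i0 = len(xs) // 2
        x0 = float(np.median(xs))
    lo, hi = max(0, i0 - window), min(len(xs), i0 + window)
    if hi - lo >= 2 and np.ptp(xs[lo:hi]) > 0:
        slope = float(np.polyfit(xs[lo:hi], med[lo:hi], 1)[0])
    else:
        slope = 0.0
    k0 = max(4.0 * slope / v_f0, 0.5)
    return LogisticParams(v_f=v_f0, k=k0, x0=x0, n=1.0)


@dataclass
class FitResult:
    params: LogisticParams
    sse: float
    converged: bool
    n_samples: int
    degenerate: bool = False
    message: str = ""


def fit_flexible_logistic(
    x,
    v,
    init: LogisticParams | None = None,
    *,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 5000,
    qc_referenced: bool = False,
) -> FitResult:
    """Fit the flexible logistic to a velocity point cloud by Nelder-Mead.

    Minimizes the unweighted sum of squared residuals over
    ``(v_f, k, x0, n)``; the positive parameters are optimized on a log
    scale.  ``restarts`` simplex runs are started from the data-driven
    initial guess plus seeded jitter, and the best SSE wins.

    Parameters
    ----------
    x, v : arrays of positions (mm) and axial velocities (mm/h), one entry
        per velocity sample.  Sample order is irrelevant.
    init : optional explicit starting parameters.
    qc_referenced : fit the relative-velocity prediction
        ``v(x) - v(0)`` instead of ``v(x)``.  Tracked velocities are
        measured relative to the QC disk, so when the profile's apical
        tail has not fully vanished at the QC the cloud is shifted down by
        ``v(0)``; modelling the shift keeps the underlying parameters
        unbiased.  (For profiles with a negligible tail at the QC the two
        fits coincide.)

    Returns
    -------
    FitResult with fitted parameters, residual SSE and diagnostics.  A
    cloud with (near-)zero velocity spread takes a degenerate path that
    returns ``v_f ~ mean(v)`` with a warning instead of optimizing.
    """
    x = np.asarray(x, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if x.shape != v.shape or x.size < 4:
        raise ValueError("x and v must be equal-length arrays with >= 4 samples")
    # canonical ordering makes the fit exactly invariant to input shuffling
    order = np.lexsort((v, x))
    x, v = x[order], v[order]

    spread = float(np.ptp(v))
    scale = max(float(np.max(np.abs(v))), 1e-30)
    if spread < 1e-9 * scale or np.max(np.abs(v)) < 1e-12:
        warnings.warn("velocity cloud has no spread; degenerate fit")
        vf = max(float(np.mean(v)), 0.0)
        params = LogisticParams(v_f=vf, k=1.0, x0=float(np.median(x)), n=1.0)
        sse = float(np.sum((v - velocity_model(params, x)) ** 2))
        return FitResult(params, sse, True, x.size, degenerate=True,
                         message="zero velocity spread")

    p0 = init if init is not None else _initial_guess(x, v)
    theta0 = np.array(
        [np.log(max(p0.v_f, 1e-9)), np.log(max(p0.k, 1e-9)), p0.x0,
         np.log(max(p0.n, 1e-9))]
    )

    def unpack(theta: np.ndarray) -> LogisticParams:
        return LogisticParams(
            v_f=float(np.exp(theta[0])), k=float(np.exp(theta[1])),
            x0=float(theta[2]), n=float(np.exp(theta[3])),
        )

    def loss(theta: np.ndarray) -> float:
        p = unpack(theta)
        pred = velocity_model(p, x)
        if qc_referenced:
            pred = pred - velocity_model(p, 0.0)
        r = v - pred
        return float(r @ r)

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for trial in range(max(restarts, 1)):
        start = theta0 if trial == 0 else theta0 + rng.normal(0.0, 0.2, 4)
        res = optimize.minimize(
            loss, start, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14,
                     "adaptive": True},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("flexible-logistic fit failed on all restarts")
    if not any_converged:
        raise FitError(
            f"Nelder-Mead did not converge after {restarts} restarts: "
            f"{best.message}"
        )
    return FitResult(
        params=unpack(best.x), sse=float(best.fun), converged=True,
        n_samples=x.size, message=str(best.message),
    )


def extract_traits(params: LogisticParams) -> KinematicTraits:
    """Derive the four kinematic traits from fitted profile parameters.

    The REGR peak sits at ``x0 - ln(n)/k`` (clipped at the QC if negative).
    The elongation zone is bounded by the two positions where REGR falls to
    20% of its maximum, found by bracketed root-finding on each side of the
    peak; the apical bound is clipped at x = 0 when the profile is still
    above threshold at the QC.  The average growth rate is ``v_f`` itself
    (the area under the REGR curve).
    """
    if not (params.v_f > 0 and params.k > 0 and params.n > 0):
        raise ValueError("extract_traits requires v_f, k, n > 0")
    peak = params.x0 - np.log(params.n) / params.k
    position = max(peak, 0.0)
    max_regr = float(regr_profile(params, position))
    thr = 0.2 * max_regr

    def f(x: float) -> float:
        return float(regr_profile(params, x)) - thr

    # basal (shootward) bound: REGR decays to the threshold past the peak
    hi = position + 20.0 / params.k
    while f(hi) >= 0:
        hi += 20.0 / params.k
    basal = optimize.brentq(f, position, hi, xtol=1e-12)

    # apical (rootward) bound, clipped at the QC
    apical_clipped = False
    if f(0.0) >= 0 or position == 0.0:
        apical = 0.0
        apical_clipped = True
    else:
        lo = max(position - 20.0 / params.k, 0.0)
        if f(lo) >= 0:
            lo = 0.0
        apical = optimize.brentq(f, lo, position, xtol=1e-12)

    return KinematicTraits(
        max_regr=max_regr,
        max_regr_position=position,
        zone_length=float(basal - apical),
        avg_growth_rate=params.v_f,
        zone_apical_mm=float(apical),
        zone_basal_mm=float(basal),
        apical_clipped=apical_clipped,
    )
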