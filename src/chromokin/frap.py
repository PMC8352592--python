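"""FRAP/FLIP curve normalization and kinetic fitting.

The analysis chain mirrors standard confocal FRAP practice: background
correction, double normalization of the ROI trace against the
whole-nucleus trace (which corrects for acquisition bleaching), a
full-scale rescale so the pre-bleach mean maps to 1 and the first
post-bleach frame to 0, and a least-squares double-exponential fit

    F(t) = a (1 - e^{-k1 t}) + b (1 - e^{-k2 t})

from which the mobile fraction (a + b) and the half-time of recovery
(the t solving F(t) = (a + b) / 2) are derived.  Half-nucleus FLIP-FRAP
pairs are expressed as percent of their own pre-bleach means and
summarized by an equilibration half-time and a gain/loss balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .curves import NormalizedCurve, TimeSeriesCurve
from .errors import AnalysisError, ValidationError

log = logging.getLogger(__name__)

_DEGENERATE_RATE_TOL = 1e-3
_DEGENERATE_AMP_TOL = 1e-3
_N_RESTARTS = 5
_AMP_BOUND = 1.2  # amplitudes are physical fractions; small noise headroom
_JITTER_SEED = 1811  # fixed: restarts must be reproducible


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def background_correct(curve: TimeSeriesCurve) -> TimeSeriesCurve:
    """Subtract the background channel from ROI and whole-nucleus traces.

    Values are floored at zero; flooring events are logged and recorded
    in ``meta['floored']``.
    """
    roi = curve.roi - curve.background
    whole = curve.whole - curve.background
    floored = bool((roi < 0).any() or (whole < 0).any())
    if floored:
        log.warning(
            "background correction floored %d ROI and %d whole-nucleus samples at 0",
            int((roi < 0).sum()),
            int((whole < 0).sum()),
        )
    meta = dict(curve.meta)
    meta["floored"] = floored
    return TimeSeriesCurve(
        time=curve.time,
        roi=np.clip(roi, 0.0, None),
        whole=np.clip(whole, 0.0, None),
        background=np.zeros_like(curve.background),
        n_pre=curve.n_pre,
        meta=meta,
    )


def full_scale_normalize(curve: TimeSeriesCurve) -> NormalizedCurve:
    """Double-normalize then full-scale rescale a background-corrected trace.

    Double normalization ``I_dn(t) = [roi(t)/mean(roi_pre)] /
    [whole(t)/mean(whole_pre)]`` cancels acquisition bleaching; the
    full-scale step ``F(t) = (I_dn(t) - I_dn(t0)) / (1 - I_dn(t0))``
    pins the first post-bleach sample ``t0`` to exactly 0.

    Raises
    ------
    AnalysisError
        If ``I_dn(t0) >= 1`` (no bleach detected).
    """
    n_pre = curve.n_pre
    roi_pre = curve.roi[:n_pre].mean()
    whole_pre = curve.whole[:n_pre].mean()
    if roi_pre <= 0 or whole_pre <= 0:
        raise ValidationError("pre-bleach mean must be positive in roi and whole")
    with np.errstate(divide="ignore", invalid="ignore"):
        i_dn = (curve.roi / roi_pre) / (curve.whole / whole_pre)
    if not np.all(np.isfinite(i_dn)):
        raise ValidationError("whole channel contains zeros; cannot normalize")
    i0 = i_dn[n_pre]
    if i0 >= 1.0:
        raise AnalysisError("no bleach detected: first post-bleach sample >= pre-bleach level")
    value = (i_dn - i0) / (1.0 - i0)
    t_bleach = curve.time[n_pre]
    return NormalizedCurve(
        time=curve.time - t_bleach,
        value=value,
        n_pre=n_pre,
        meta=dict(curve.meta),
    )


# ---------------------------------------------------------------------------
# Double-exponential fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoubleExpFit:
    """Fitted double-exponential recovery and derived kinetic readouts."""

    a: float
    b: float
    k1: float
    k2: float
    mobile_fraction: float
    mobile_fraction_raw: float
    t_half: float
    residual_sse: float
    converged: bool
    model: str = "double"
    meta: dict = field(default_factory=dict, compare=False)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * -np.expm1(-self.k1 * t) + self.b * -np.expm1(-self.k2 * t)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "k1": self.k1,
            "k2": self.k2,
            "mobile_fraction": self.mobile_fraction,
            "t_half_s": self.t_half,
            "sse": self.residual_sse,
            "converged": self.converged,
            "model": self.model,
        }


def _model(t, a, b, k1, k2):
    return a * -np.expm1(-k1 * t) + b * -np.expm1(-k2 * t)


def solve_t_half(fit) -> float:
    """Time at which the fitted recovery reaches half its plateau.

    Accepts anything with ``a, b, k1, k2`` attributes.  The recovery is
    strictly increasing for non-negative parameters, so the root of
    ``F(t) - (a+b)/2`` is unique; it is found by bracketed root-finding.
    """
    a, b, k1, k2 = fit.a, fit.b, fit.k1, fit.k2
    mobile = a + b
    if mobile <= 0:
        raise AnalysisError("t_half undefined: mobile fraction is zero")
    # Components with zero rate never recover; fold them out.
    if k1 <= 0:
        raise AnalysisError("t_half undefined: no recovering component")
    if b <= 0 or k2 == k1:
        return math.log(2.0) / k1
    if k2 <= 0:
        # Only the fast component recovers; the target (a+b)/2 may sit
        # above its plateau a.
        target = mobile / 2.0
        if target >= a:
            raise AnalysisError(
                "t_half undefined: half-plateau exceeds the recovering amplitude"
            )
        return -math.log(1.0 - target / a) / k1

    def g(t):
        return _model(t, a, b, k1, k2) - mobile / 2.0

    hi = math.log(2.0) / k2  # slow-only bound; recovery is at least this fast
    while g(hi) < 0:
        hi *= 2.0
    return brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-14)


def _initial_guesses(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Plateau and fast-rate starting values from the data shape."""
    n = len(f)
    plateau = float(f[max(n - max(n // 4, 1), 0) :].mean())
    plateau = min(max(plateau, 1e-3), 1.0)
    half_level = plateau / 2.0
    above = np.nonzero(f >= half_level)[0]
    if len(above) and t[above[0]] > 0:
        k1 = math.log(2.0) / t[above[0]]
    else:
        k1 = 1.0 / max(t[-1] / 10.0, 1e-6)
    return plateau, k1


def _fit_single(t: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, float]:
    plateau, k1 = _initial_guesses(t, f)

    def resid(p):
        return p[0] * -np.expm1(-p[1] * t) - f

    sol = least_squares(
        resid,
        x0=[plateau, k1],
        bounds=([0.0, 0.0], [_AMP_BOUND, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return sol.x, float(np.sum(sol.fun**2))


def fit_double_exponential(
    curve: NormalizedCurve, model: str = "double"
) -> DoubleExpFit:
    """Least-squares fit of the double-exponential recovery model.

    All post-bleach frames are fitted (no truncation).  Initialization
    follows the curve shape (k1 from the time to half the late plateau,
    k2 = k1/10, amplitudes split evenly) with five jittered multi-start
    restarts; the lowest-SSE solution wins.  When the two rates are
    indistinguishable or one amplitude vanishes, the fit falls back to a
    single exponential.  The mobile fraction is clipped to [0, 1]; the
    raw value is kept in ``mobile_fraction_raw``.
    """
    t = curve.post_time
    f = curve.post_value
    if len(t) < 10:
        raise ValidationError("need at least 10 post-bleach samples to fit")
    if model not in ("double", "single"):
        raise ValidationError("model must be 'double' or 'single'")

    if model == "single":
        (amp, k), sse = _fit_single(t, f)
        return _package_fit(amp, 0.0, k, 0.0, sse, True, "single")

    plateau, k1_init = _initial_guesses(t, f)
    rng = np.random.default_rng(_JITTER_SEED)

    def resid(p):
        return _model(t, *p) - f

    best = None
    best_sse = np.inf
    converged = False
    for i in range(_N_RESTARTS):
        jitter = np.ones(4) if i == 0 else np.exp(rng.normal(0.0, 0.4, size=4))
        x0 = np.array(
            [plateau / 2.0, plateau / 2.0, k1_init, k1_init / 10.0]
        ) * jitter
        x0[:2] = np.clip(x0[:2], 1e-6, 1.0)
        try:
            sol = least_squares(
                resid,
                x0=x0,
                bounds=([0.0, 0.0, 0.0, 0.0], [_AMP_BOUND, _AMP_BOUND, np.inf, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # pragma: no cover - scipy failures are rare
            continue
        sse = float(np.sum(sol.fun**2))
        if sse < best_sse:
            best, best_sse = sol.x, sse
            converged = bool(sol.status > 0)
    if best is None:
        raise AnalysisError("double-exponential fit failed on all restarts")

    a, b, k1, k2 = best
    if k1 < k2:  # canonical ordering: k1 is the fast rate
        a, b, k1, k2 = b, a, k2, k1

    degenerate = (
        min(a, b) < _DEGENERATE_AMP_TOL
        or (k1 > 0 and abs(k1 - k2) / k1 < _DEGENERATE_RATE_TOL)
    )
    if degenerate:
        (amp, k), sse_s = _fit_single(t, f)
        return _package_fit(amp, 0.0, k, 0.0, sse_s, converged, "single")
    return _package_fit(a, b, k1, k2, best_sse, converged, "double")


def _package_fit(a, b, k1, k2, sse, converged, model) -> DoubleExpFit:
    raw_mobile = float(a + b)
    mobile = min(max(raw_mobile, 0.0), 1.0)
    if raw_mobile != mobile:
        log.info("mobile fraction %.4f clipped to [0, 1]", raw_mobile)

    class _P:  # minimal parameter view for solve_t_half
        pass

    p = _P()
    p.a, p.b, p.k1, p.k2 = a, b, k1, k2
    try:
        t_half = solve_t_half(p)
    except AnalysisError:
        t_half = math.nan
    return DoubleExpFit(
        a=float(a),
        b=float(b),
        k1=float(k1),
        k2=float(k2),
        mobile_fraction=mobile,
        mobile_fraction_raw=raw_mobile,
        t_half=float(t_half),
        residual_sse=float(sse),
        converged=bool(converged),
        model=model,
    )


# ---------------------------------------------------------------------------
# Biphasic fit (exponential burst + linear ramp)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiphasicFit:
    """Exponential-plus-ramp recovery fit for polymerase-like curves."""

    fast_amp: float
    fast_k: float
    slope: float
    residual_sse: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.fast_amp * -np.expm1(-self.fast_k * t) + self.slope * t


def fit_biphasic(curve: NormalizedCurve) -> BiphasicFit:
    """Fit ``fast_amp (1 - e^{-fast_k t}) + slope t`` with slope >= 0.

    Captures an initial rapid exchange phase followed by a prolonged
    linear phase of recovery.
    """
    t = curve.post_time
    f = curve.post_value
    if len(t) < 20:
        raise ValidationError("need at least 20 post-bleach samples to fit")

    # Initialize the ramp from the late half of the curve, the burst
    # from what the ramp leaves unexplained.
    half = len(t) // 2
    slope0, intercept0 = np.polyfit(t[half:], f[half:], 1)
    slope0 = max(float(slope0), 0.0)
    amp0 = min(max(float(intercept0), 1e-3), 1.0)
    _, k0 = _initial_guesses(t, np.clip(f - slope0 * t, 0.0, None))

    def resid(p):
        return p[0] * -np.expm1(-p[1] * t) + p[2] * t - f

    sol = least_squares(
        resid,
        x0=[amp0, k0, slope0],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return BiphasicFit(
        fast_amp=float(sol.x[0]),
        fast_k=float(sol.x[1]),
        slope=float(sol.x[2]),
        residual_sse=float(np.sum(sol.fun**2)),
        converged=bool(sol.status > 0),
    )


# ---------------------------------------------------------------------------
# FLIP-FRAP and scalar readouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlipFrapResult:
    """Half-nucleus FLIP-FRAP summary.

    Curves are percent of each half's own pre-bleach mean; the
    equilibration half-time tracks the bleached-half rise, and
    ``gain_loss_balance`` is the ratio of bleached-half gain to
    unbleached-half loss over the post-bleach window (≈1 when total
    fluorescence is conserved).
    """

    time: np.ndarray
    bleached_percent: np.ndarray
    unbleached_percent: np.ndarray
    n_pre: int
    equilibration_t_half: float
    gain_loss_balance: float
    bleached_recovery_percent: float


def _percent_of_prebleach(curve: TimeSeriesCurve) -> np.ndarray:
    corrected = background_correct(curve)
    pre = corrected.roi[: curve.n_pre].mean()
    if pre <= 0:
        raise ValidationError("pre-bleach mean must be positive in roi")
    return 100.0 * corrected.roi / pre


def analyze_flip_frap(
    bleached: TimeSeriesCurve, unbleached: TimeSeriesCurve
) -> FlipFrapResult:
    """Summarize a half-nucleus FLIP-FRAP pair.

    Raises
    ------
    AnalysisError
        If neither half changes after the bleach ("no exchange detected").
    """
    if bleached.n_pre != unbleached.n_pre or len(bleached) != len(unbleached):
        raise ValidationError("curves must share time base and n_pre")
    if not np.allclose(bleached.time, unbleached.time):
        raise ValidationError("curves must share time base and n_pre")
    n_pre = bleached.n_pre
    pb = _percent_of_prebleach(bleached)
    pu = _percent_of_prebleach(unbleached)

    post_b = pb[n_pre:]
    post_u = pu[n_pre:]
    tail = max(len(post_b) // 10, 1)
    b_start, b_end = post_b[0], post_b[-tail:].mean()
    u_start, u_end = post_u[0], post_u[-tail:].mean()
    gain = b_end - b_start
    loss = u_start - u_end
    if abs(gain) < 1e-9 and abs(loss) < 1e-9:
        raise AnalysisError("no exchange detected")
    balance = gain / loss if loss != 0 else math.inf

    # Equilibration half-time: first crossing of the midpoint of the
    # bleached-half rise, linearly interpolated.
    t_post = bleached.post_time
    target = b_start + gain / 2.0
    t_half = math.nan
    if gain > 0:
        above = np.nonzero(post_b >= target)[0]
        if len(above):
            i = above[0]
            if i == 0:
                t_half = float(t_post[0])
            else:
                f0, f1 = post_b[i - 1], post_b[i]
                frac = (target - f0) / (f1 - f0) if f1 != f0 else 0.0
                t_half = float(t_post[i - 1] + frac * (t_post[i] - t_post[i - 1]))
    return FlipFrapResult(
        time=bleached.time,
        bleached_percent=pb,
        unbleached_percent=pu,
        n_pre=n_pre,
        equilibration_t_half=t_half,
        gain_loss_balance=float(balance),
        bleached_recovery_percent=float(gain),
    )


def percent_recovery_at(
    curve: NormalizedCurve, t: float, window: float = 0.0
) -> float:
    """Mean normalized recovery in a window centered at time ``t``.

    Returns a fraction (0.18 means 18 % recovery).  ``window`` is the
    full window width in seconds; 0 picks the nearest sample.
    """
    t_post = curve.post_time
    if not (t_post[0] <= t <= t_post[-1]):
        raise AnalysisError(
            f"query time {t} s outside sampled range "
            f"[{t_post[0]}, {t_post[-1]}] s"
        )
    if window <= 0:
        idx = int(np.argmin(np.abs(t_post - t)))
        return float(curve.post_value[idx])
    sel = (t_post >= t - window / 2.0) & (t_post <= t + window / 2.0)
    return float(curve.post_value[sel].mean())


@dataclass(frozen=True)
class THalfComparison:
    ratio: float
    description: str


def compare_t_half(fit_a: DoubleExpFit, fit_b: DoubleExpFit) -> THalfComparison:
    """Ratio of half-times t½(a) / t½(b), with a qualitative fold label."""
    if not (fit_a.converged and fit_b.converged):
        raise AnalysisError("both fits must have converged to compare t_half")
    ratio = fit_a.t_half / fit_b.t_half
    fold = max(ratio, 1.0 / ratio) if ratio > 0 else math.nan
    slower = "a" if ratio > 1 else "b"
    description = (
        "equal half-times"
        if abs(ratio - 1.0) < 0.05
        else f"curve {slower} is ~{fold:.1f}-fold slower"
    )
    return THalfComparison(ratio=float(ratio), description=description)
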