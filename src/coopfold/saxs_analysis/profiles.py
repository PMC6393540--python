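"""Scattering-profile analysis: Guinier fitting, the dimensionless Kratky
transform with its analytic globular/random-coil reference laws, peak
location and foldedness classification, chi^2 model comparison and Porod
volume / molecular-weight estimation.

The dimensionless Kratky plot shows (qRg)^2 I(q)/I(0) against x = qRg.
A globular (Guinier-law) scatterer peaks at (sqrt(3), 3/e = 1.104); an
ideal random coil (Debye law) increases monotonically towards 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "ScatteringProfile",
    "GuinierResult",
    "KratkyCurve",
    "guinier_fit",
    "dimensionless_kratky",
    "theoretical_kratky_globular",
    "theoretical_kratky_debye",
    "find_kratky_maximum",
    "classify_foldedness",
    "chi2_with_scale",
    "porod_mw_estimates",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringProfile:
    """One scattering curve: q (A^-1, strictly increasing, > 0), I, sigma."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.i, dtype=float)
        if q.ndim != 1 or q.shape != i.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if q.size == 0:
            raise ValueError("empty profile")
        if np.any(q <= 0):
            raise ValueError("q must be > 0")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("I must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "i", i)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s <= 0):
                raise ValueError("sigma must be > 0 where present")
            object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size

    def sigma_or_default(self, fraction: float = 0.01) -> np.ndarray:
        """sigma, synthesizing ``fraction * |I|`` where absent."""
        if self.sigma is not None:
            return self.sigma
        s = fraction * np.abs(self.i)
        floor = fraction * float(np.max(np.abs(self.i)))
        return np.maximum(s, 1e-6 * floor if floor > 0 else 1e-12)


@dataclass(frozen=True)
class GuinierResult:
    """Rg/I0 from a Guinier fit, with the fit window actually used."""

    rg: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("Rg must be > 0")
        if self.i0 <= 0:
            raise ValueError("I0 must be > 0")


@dataclass(frozen=True)
class KratkyCurve:
    """Dimensionless Kratky curve: x = qRg, y = (qRg)^2 I(q)/I(0)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be ascending")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

def guinier_fit(
    profile: ScatteringProfile,
    qrg_limit: float = 1.3,
    min_points: int = 8,
    max_iter: int = 100,
) -> GuinierResult:
    """Iterative Guinier fit of ln I vs q^2 on the low-q window.

    Starting from the ``min_points`` lowest-q points, fits a line, derives
    Rg = sqrt(-3 slope), then re-selects the window {q : q Rg <= qrg_limit}
    and repeats until the window is a fixed point.

    Raises
    ------
    ValueError
        If fewer than ``min_points`` usable points exist in the window or
        the fitted slope is >= 0 (no Guinier region, aggregation-like).
    """
    q, i = profile.q, profile.i
    positive = i > 0
    if np.count_nonzero(positive) < min_points:
        raise ValueError("too few points with positive intensity for Guinier fit")

    n_window = min_points
    prev_n = -1
    slope = intercept = float("nan")
    for _ in range(max_iter):
        idx = np.flatnonzero(positive)[:n_window]
        if idx.size < min_points:
            raise ValueError("too few points in Guinier window")
        x = q[idx] ** 2
        y = np.log(i[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise ValueError(
                "no Guinier region: ln I vs q^2 slope is non-negative "
                "(aggregation-like profile)"
            )
        rg = math.sqrt(-3.0 * slope)
        within = np.flatnonzero(positive & (q * rg <= qrg_limit))
        new_n = max(int(within.size), min_points)
        if new_n == prev_n or new_n == n_window:
            n_window = new_n
            break
        prev_n = n_window
        n_window = new_n

    idx = np.flatnonzero(positive)[:n_window]
    x = q[idx] ** 2
    y = np.log(i[idx])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("no Guinier region after window refinement")
    rg = math.sqrt(-3.0 * slope)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(
        rg=rg,
        i0=math.exp(intercept),
        q_min=float(q[idx[0]]),
        q_max=float(q[idx[-1]]),
        n_points=int(idx.size),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Dimensionless Kratky transform and reference laws
# ---------------------------------------------------------------------------

def dimensionless_kratky(
    profile: ScatteringProfile, rg: float, i0: float
) -> KratkyCurve:
    """x = q Rg, y = x^2 I(q)/I0.  No smoothing is applied here."""
    if rg <= 0:
        raise ValueError("Rg must be > 0")
    if i0 <= 0:
        raise ValueError("I0 must be > 0")
    x = profile.q * rg
    y = x * x * profile.i / i0
    return KratkyCurve(x=x, y=y)


def theoretical_kratky_globular(x) -> np.ndarray:
    """Reference Kratky curve of a Guinier-law (globular) scatterer.

    y = x^2 exp(-x^2/3); maximum 3/e at x = sqrt(3).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    return x * x * np.exp(-x * x / 3.0)


def theoretical_kratky_debye(x) -> np.ndarray:
    """Reference Kratky curve of an ideal random coil (Debye law).

    The Debye form factor is I(q)/I(0) = 2 (exp(-x^2) - 1 + x^2) / x^4 with
    x = qRg, so the Kratky transform is y = 2 (exp(-x^2) - 1 + x^2) / x^2:
    monotone increasing with asymptote 2, and y(0) = 0 by limit.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    u = x * x
    out = np.empty_like(u)
    small = u < 1e-8
    # Series 2(e^-u - 1 + u)/u = u - u^2/3 + u^3/12 - ... near zero.
    out[small] = u[small] - u[small] ** 2 / 3.0
    us = u[~small]
    out[~small] = 2.0 * (np.expm1(-us) + us) / us
    return out


def find_kratky_maximum(
    curve: KratkyCurve,
    smooth_window: int = 7,
    polyorder: int = 2,
    x_max: float = 4.0,
) -> tuple[float, float] | None:
    """Locate the Kratky maximum on a smoothed curve, restricted to x <= x_max.

    Uses Savitzky-Golay smoothing (local polynomial) before taking the
    argmax.  Returns ``None`` when the smoothed curve is monotone
    increasing over the range (random-coil-like), i.e. the maximum sits on
    the right edge.
    """
    mask = curve.x <= x_max
    x = curve.x[mask]
    y = curve.y[mask]
    if x.size < smooth_window:
        raise ValueError(
            f"need at least smooth_window={smooth_window} points with x <= {x_max}"
        )
    window = smooth_window
    if window % 2 == 0:
        window += 1
    window = min(window, x.size if x.size % 2 == 1 else x.size - 1)
    if window <= polyorder:
        ys = y
    else:
        ys = savgol_filter(y, window_length=window, polyorder=polyorder)
    k = int(np.argmax(ys))
    if k >= x.size - 1:
        return None  # edge maximum: monotone increasing over the range
    return float(x[k]), float(ys[k])


def classify_foldedness(
    peak: tuple[float, float] | None,
    x_threshold: float = 1.9,
    y_threshold: float = 1.17,
) -> str:
    """Classify a Kratky peak as globular / partially_disordered / disordered.

    No peak (monotone curve) means disordered.  A peak at or below both
    thresholds is globular; anything else is partially disordered.  Default
    thresholds sit midway between the analytic globular peak (1.73, 1.104)
    and a typical partially-disordered peak near (2.0, 1.22).
    """
    if peak is None:
        return "disordered"
    x_star, y_star = peak
    if x_star <= x_threshold and y_star <= y_threshold:
        return "globular"
    return "partially_disordered"


# ---------------------------------------------------------------------------
# chi^2 model comparison
# ---------------------------------------------------------------------------

def chi2_with_scale(
    exp: ScatteringProfile, model: ScatteringProfile
) -> tuple[float, float]:
    """Optimal scale c and reduced chi^2 between experiment and model.

    c = sum(I_exp I_mod / s^2) / sum(I_mod^2 / s^2) analytically, then
    chi2 = (1/M) sum((I_exp - c I_mod)/s)^2.  The model is resampled onto
    the experimental grid by linear interpolation when grids differ (no
    extrapolation: experimental points outside the model range are an
    error).
    """
    if exp.sigma is None:
        raise ValueError("experimental profile needs sigma for chi^2")
    if np.any(exp.sigma == 0):
        raise ValueError("sigma must be non-zero")
    if model.q.shape == exp.q.shape and np.allclose(model.q, exp.q):
        i_mod = model.i
    else:
        if exp.q[0] < model.q[0] - 1e-12 or exp.q[-1] > model.q[-1] + 1e-12:
            raise ValueError("model q range does not cover experimental range")
        i_mod = np.interp(exp.q, model.q, model.i)
    w = 1.0 / (exp.sigma * exp.sigma)
    denom = float(np.sum(i_mod * i_mod * w))
    if denom == 0:
        raise ValueError("model intensity is identically zero")
    c = float(np.sum(exp.i * i_mod * w)) / denom
    resid = (exp.i - c * i_mod) / exp.sigma
    chi2 = float(np.mean(resid * resid))
    return c, chi2


# ---------------------------------------------------------------------------
# Porod volume / molecular weight
# ---------------------------------------------------------------------------

def porod_mw_estimates(
    profile: ScatteringProfile,
    guinier: GuinierResult,
    volume_per_dalton: float = 1.66,
    background_fraction: float = 0.2,
) -> dict[str, float]:
    """Porod volume V_p = 2 pi^2 I0 / Q and the derived MW estimate.

    The Porod invariant Q = int q^2 I(q) dq is computed by trapezoid after
    subtracting a constant background chosen so q^4 I flattens at high q
    (linear fit of q^4 I vs q^4 over the top ``background_fraction`` of the
    q range).  The integral is extended analytically below q_min with the
    Guinier form and above q_max with the fitted Porod tail A/q^4.

    MW is V_p / ``volume_per_dalton`` (default 1.66 A^3/Da), returned in kDa.
    """
    q, i = profile.q, profile.i
    if q[-1] * guinier.rg < 5.0:
        raise ValueError(
            "profile q range insufficient for Porod analysis "
            f"(q_max*Rg = {q[-1] * guinier.rg:.2f} < 5)"
        )
    # Background: I(q) ~ B + A/q^4 at high q  =>  q^4 I = A + B q^4.
    n_hi = max(int(background_fraction * q.size), 5)
    qh = q[-n_hi:]
    ih = i[-n_hi:]
    q4 = qh**4
    bgr = np.polyfit(q4, q4 * ih, 1)[0]  # slope = B
    # a physical background cannot exceed the smallest observed intensity
    bgr = float(np.clip(bgr, 0.0, np.min(i)))
    # Porod constant from the windowed mean (robust to form-factor ripple)
    porod_a = max(float(np.mean(q4 * (ih - bgr))), 0.0)
    i_sub = np.clip(i - bgr, 0.0, None)
    q_invariant = float(np.trapezoid(q * q * i_sub, q))
    # Low-q extension from the Guinier form (exact integral unavailable in
    # closed form cheaply; fine trapezoid on [0, q_min] is ample).
    q_lo = np.linspace(0.0, q[0], 64)
    i_lo = guinier.i0 * np.exp(-(q_lo * guinier.rg) ** 2 / 3.0)
    q_invariant += float(np.trapezoid(q_lo * q_lo * i_lo, q_lo))
    # High-q Porod tail: int_{qmax}^inf q^2 (A/q^4) dq = A / qmax.
    q_invariant += porod_a / q[-1]
    if q_invariant <= 0:
        raise ValueError("non-positive Porod invariant")
    v_p = 2.0 * math.pi**2 * guinier.i0 / q_invariant
    return {
        "porod_volume_A3": v_p,
        "mw_from_vp_kda": v_p / volume_per_dalton / 1000.0,
        "porod_invariant": q_invariant,
        "background": float(bgr),
    }
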