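"""Tri-molecular cooperative binding model for ITC data.

The model describes two protein dimers (A) binding a DNA duplex (D) in a
single cooperative step,

    2 A + D  <=>  C,      K_A = [C] / ([A]^2 [D])   (M^-2)

with no populated intermediate.  The module solves the speciation problem,
simulates closed-cell titrations with perfusion dilution, and fits
isotherms by least squares on (log10 K_A, dH, offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "BindingParameters",
    "TitrationProtocol",
    "TitrationExperiment",
    "SpeciationState",
    "IsothermFit",
    "solve_trimolecular_equilibrium",
    "speciation_curve",
    "sequential_two_site_speciation",
    "max_intermediate_fraction",
    "simulate_isotherm",
    "model_ndh",
    "fit_isotherm",
    "delta_g_from_ka",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425864083e-3
#: Reference temperature (25 C) for reported free energies.
STANDARD_TEMPERATURE_K = 298.15


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParameters:
    """Macroscopic parameters of the cooperative 2:1 binding reaction.

    Parameters
    ----------
    ka : float
        Macroscopic association constant, M^-2.  Non-negative.
    dh : float
        Molar enthalpy of complex formation, kcal per mol of duplex
        incorporated (one duplex per complex).
    offset : float
        Constant per-injection background heat, kcal per mol of injectant.
    """

    ka: float
    dh: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.ka) or self.ka < 0:
            raise ValueError(f"ka must be finite and >= 0, got {self.ka!r}")
        if not math.isfinite(self.dh):
            raise ValueError(f"dh must be finite, got {self.dh!r}")
        if not math.isfinite(self.offset):
            raise ValueError(f"offset must be finite, got {self.offset!r}")

    @property
    def dg(self) -> float:
        """Free energy -RT ln K_A at 25 C, kcal/mol (-inf when ka == 0)."""
        return delta_g_from_ka(self.ka)


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule of a closed-cell (perfusion) titration.

    The cell holds the protein dimer (or TA heterotetramer); the syringe
    holds the DNA duplex.  Volumes in microlitres, concentrations in M.
    """

    cell_volume_ul: float = 200.0
    cell_conc: float = 20e-6
    syringe_conc: float = 90e-6
    injection_volumes_ul: tuple[float, ...] = field(
        default_factory=lambda: (2.0,) * 20
    )
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0:
            raise ValueError("cell_volume_ul must be > 0")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be > 0")
        vols = tuple(float(v) for v in self.injection_volumes_ul)
        if not vols:
            raise ValueError("injection_volumes_ul must be non-empty")
        if any(v <= 0 for v in vols):
            raise ValueError("all injection volumes must be > 0")
        object.__setattr__(self, "injection_volumes_ul", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass(frozen=True)
class TitrationExperiment:
    """Per-injection normalized heats of one titration.

    ``ndh`` is the heat per mole of injected duplex (kcal/mol), dilution
    corrected.  ``molar_ratio`` is the cumulative injectant:cell-species
    molar ratio inside the cell after each injection.
    """

    protocol: TitrationProtocol
    ndh: tuple[float, ...]
    sigma: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ndh = tuple(float(x) for x in self.ndh)
        if len(ndh) != self.protocol.n_injections:
            raise ValueError(
                f"len(ndh)={len(ndh)} does not match "
                f"{self.protocol.n_injections} injections"
            )
        object.__setattr__(self, "ndh", ndh)
        if self.sigma is not None:
            sig = tuple(float(s) for s in self.sigma)
            if len(sig) != len(ndh):
                raise ValueError("sigma length must match ndh length")
            if any(s <= 0 for s in sig):
                raise ValueError("sigma values must be > 0")
            object.__setattr__(self, "sigma", sig)

    @property
    def molar_ratio(self) -> np.ndarray:
        """Cumulative duplex:dimer molar ratio in the cell (derived)."""
        totals = _cell_totals(self.protocol)
        return totals[1] / totals[0]


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations (M) of the tri-molecular system."""

    free_dimer: float
    free_duplex: float
    complex: float

    def __post_init__(self) -> None:
        for name in ("free_dimer", "free_duplex", "complex"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < -1e-15:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def dimer_total(self) -> float:
        return self.free_dimer + 2.0 * self.complex

    @property
    def duplex_total(self) -> float:
        return self.free_duplex + self.complex

    def bound_duplex_fraction(self) -> float:
        tot = self.duplex_total
        return self.complex / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# Equilibrium solvers
# ---------------------------------------------------------------------------

def solve_trimolecular_equilibrium(
    ka: float, dimer_total: float, duplex_total: float
) -> SpeciationState:
    """Solve 2A + D <=> C for the complex concentration.

    Finds the unique root C in [0, min(dimer_total/2, duplex_total)] of

        K_A (A_t - 2C)^2 (D_t - C) - C = 0,

    which is strictly decreasing on that interval, by Brent bracketing
    followed by a Newton polish.

    Returns
    -------
    SpeciationState
        Free dimer, free duplex and complex concentrations in M.
    """
    if not math.isfinite(ka):
        raise ValueError("ka must be finite")
    if ka < 0 or dimer_total < 0 or duplex_total < 0:
        raise ValueError("ka and totals must be >= 0")

    c_max = min(dimer_total / 2.0, duplex_total)
    if ka == 0.0 or c_max == 0.0:
        return SpeciationState(dimer_total, duplex_total, 0.0)

    def f(c: float) -> float:
        return ka * (dimer_total - 2.0 * c) ** 2 * (duplex_total - c) - c

    # f(0) > 0 and f(c_max) = -c_max < 0, so the bracket is guaranteed.
    c = optimize.brentq(f, 0.0, c_max, xtol=1e-30, rtol=4 * np.finfo(float).eps)

    # One Newton step sharpens the residual near saturation.
    a = dimer_total - 2.0 * c
    d = duplex_total - c
    fprime = ka * (-4.0 * a * d - a * a) - 1.0
    if fprime != 0.0:
        step = f(c) / fprime
        c_new = c - step
        if 0.0 <= c_new <= c_max:
            c = c_new

    return SpeciationState(dimer_total - 2.0 * c, duplex_total - c, c)


def speciation_curve(
    ka: float, duplex_total: float, dimer_ratios
) -> list[SpeciationState]:
    """Speciation at fixed duplex for a grid of dimer:duplex molar ratios."""
    ratios = np.asarray(dimer_ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("dimer ratios must be >= 0")
    return [
        solve_trimolecular_equilibrium(ka, r * duplex_total, duplex_total)
        for r in ratios
    ]


def sequential_two_site_speciation(
    k1: float, k2: float, dimer_total: float, duplex_total: float
) -> dict[str, float]:
    """Stepwise contrast model  A + D <=> AD (K1),  AD + A <=> A2D (K2).

    Solves the coupled mass balances for free dimer a and free duplex d:

        d (1 + K1 a + K1 K2 a^2) = D_t
        a + (K1 a + 2 K1 K2 a^2) d = A_t

    by bracketing on a (the left side of the second equation is strictly
    increasing in a once d is eliminated).  K1*K2 equals the macroscopic
    M^-2 constant of the tri-molecular model.

    Returns
    -------
    dict
        Duplex-species fractions ``free_duplex``, ``intermediate`` (AD)
        and ``saturated`` (A2D), plus free dimer concentration ``free_dimer``.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("K1 and K2 must be >= 0")
    if dimer_total < 0 or duplex_total < 0:
        raise ValueError("totals must be >= 0")
    if duplex_total == 0.0:
        return {
            "free_duplex": 0.0,
            "intermediate": 0.0,
            "saturated": 0.0,
            "free_dimer": dimer_total,
        }

    def free_duplex(a: float) -> float:
        return duplex_total / (1.0 + k1 * a + k1 * k2 * a * a)

    def g(a: float) -> float:
        d = free_duplex(a)
        return a + (k1 * a + 2.0 * k1 * k2 * a * a) * d - dimer_total

    if dimer_total == 0.0:
        a = 0.0
    else:
        a = optimize.brentq(
            g, 0.0, dimer_total, xtol=1e-30, rtol=4 * np.finfo(float).eps
        )
    d = free_duplex(a)
    ad = k1 * a * d
    aad = k1 * k2 * a * a * d
    return {
        "free_duplex": d / duplex_total,
        "intermediate": ad / duplex_total,
        "saturated": aad / duplex_total,
        "free_dimer": a,
    }


def max_intermediate_fraction(
    k1: float,
    k2: float,
    duplex_total: float,
    dimer_ratios=None,
) -> float:
    """Maximum AD (singly-bound duplex) fraction across a titration grid."""
    if dimer_ratios is None:
        dimer_ratios = np.linspace(0.0, 4.0, 81)
    best = 0.0
    for r in np.asarray(dimer_ratios, dtype=float):
        frac = sequential_two_site_speciation(
            k1, k2, r * duplex_total, duplex_total
        )["intermediate"]
        best = max(best, frac)
    return best


# ---------------------------------------------------------------------------
# Titration simulation
# ---------------------------------------------------------------------------

def _cell_totals(
    protocol: TitrationProtocol, dilution: str = "displacement"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection total dimer and duplex concentrations in the cell.

    ``displacement`` applies the standard perfusion model: each injected
    volume dv displaces cell content, scaling existing totals by
    (1 - dv/V0) while adding dv*syringe_conc/V0 of injectant.
    ``none`` disables displacement (totals simply accumulate).
    """
    if dilution not in ("displacement", "none"):
        raise ValueError(f"unknown dilution model {dilution!r}")
    v0 = protocol.cell_volume_ul
    a = protocol.cell_conc
    d = 0.0
    a_tot, d_tot = [], []
    for dv in protocol.injection_volumes_ul:
        if dilution == "displacement":
            fd = 1.0 - dv / v0
            a *= fd
            d = d * fd + dv * protocol.syringe_conc / v0
        else:
            d = d + dv * protocol.syringe_conc / v0
        a_tot.append(a)
        d_tot.append(d)
    return np.asarray(a_tot), np.asarray(d_tot)


def model_ndh(
    params: BindingParameters,
    protocol: TitrationProtocol,
    dilution: str = "displacement",
) -> np.ndarray:
    """Noise-free normalized heats (kcal per mol injectant) per injection.

    Heat of injection i is V0*dH*(C_i - C_{i-1}*(1 - dv_i/V0)): the enthalpy
    of newly formed complex, corrected for complex displaced out of the cell
    by the injection itself.
    """
    v0_l = protocol.cell_volume_ul * 1e-6
    a_tot, d_tot = _cell_totals(protocol, dilution)
    ndh = np.empty(protocol.n_injections)
    c_prev = 0.0
    for i, dv in enumerate(protocol.injection_volumes_ul):
        c_i = solve_trimolecular_equilibrium(params.ka, a_tot[i], d_tot[i]).complex
        carry = 1.0 - dv / protocol.cell_volume_ul if dilution == "displacement" else 1.0
        heat_kcal = v0_l * params.dh * (c_i - c_prev * carry)
        moles_injected = dv * 1e-6 * protocol.syringe_conc
        ndh[i] = heat_kcal / moles_injected + params.offset
        c_prev = c_i
    return ndh


def simulate_isotherm(
    params: BindingParameters,
    protocol: TitrationProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilution: str = "displacement",
) -> TitrationExperiment:
    """Simulate a titration with additive Gaussian noise on the heats.

    Deterministic given ``seed``; the seed is recorded on the experiment.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ndh = model_ndh(params, protocol, dilution)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ndh = ndh + rng.normal(0.0, noise_sd, size=ndh.size)
    sigma = None
    if noise_sd > 0:
        sigma = tuple([noise_sd] * ndh.size)
    return TitrationExperiment(
        protocol=protocol, ndh=tuple(ndh), sigma=sigma, seed=seed
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsothermFit:
    """Result of a least-squares isotherm fit."""

    params: BindingParameters
    log10_ka: float
    se_log10_ka: float
    se_dh: float
    se_offset: float
    dg: float
    se_dg: float
    converged: bool
    ka_lower_bound: bool
    residuals: tuple[float, ...]
    residual_rms: float
    n_injections: int
    cost: float

    def to_dict(self) -> dict:
        return {
            "K_A": self.params.ka,
            "log10_K_A": self.log10_ka,
            "dG_kcal_mol": self.dg,
            "dH_kcal_mol": self.params.dh,
            "offset_kcal_mol": self.params.offset,
            "se_log10_K_A": self.se_log10_ka,
            "se_dG_kcal_mol": self.se_dg,
            "se_dH_kcal_mol": self.se_dh,
            "se_offset_kcal_mol": self.se_offset,
            "converged": self.converged,
            "ka_lower_bound": self.ka_lower_bound,
            "n_injections": self.n_injections,
            "residual_rms": self.residual_rms,
        }


def delta_g_from_ka(ka: float, temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """dG = -RT ln K_A in kcal/mol (reported at 25 C by default)."""
    if ka < 0:
        raise ValueError("ka must be >= 0")
    if ka == 0:
        return float("inf")  # no binding
    return -GAS_CONSTANT_KCAL * temperature_k * math.log(ka)


def _auto_init(
    exp: TitrationExperiment, dilution: str
) -> BindingParameters:
    ndh = np.asarray(exp.ndh)
    n = ndh.size
    tail = ndh[max(n - 3, n // 2):]
    offset0 = float(np.mean(tail))
    head = ndh[: max(2, n // 5)]
    dh0 = float(np.mean(head) - offset0)
    if dh0 == 0.0:
        dh0 = -1.0
    # Steepness guess: dimensionless K_A * A^2 of order 100.
    a0 = exp.protocol.cell_conc
    ka0 = 100.0 / (a0 * a0)
    return BindingParameters(ka=ka0, dh=dh0, offset=offset0)


def fit_isotherm(
    exp: TitrationExperiment,
    init: BindingParameters | None = None,
    dilution: str = "displacement",
    discard_first: bool = False,
    multistart_decades: float = 2.0,
) -> IsothermFit:
    """Least-squares fit of (log10 K_A, dH, offset) to an isotherm.

    Optimizes log10(K_A) rather than K_A for conditioning and uses three
    starts spanning +-``multistart_decades`` in log10 K_A to avoid local
    minima on steep isotherms.  Standard errors come from the Jacobian at
    the optimum; the error on dG is ln(10)*RT*se(log10 K_A).

    A fit whose isotherm carries no curvature information flags
    ``ka_lower_bound`` (K_A only bounded from below) instead of failing.
    """
    if exp.protocol.n_injections < 5:
        raise ValueError("need at least 5 injections to fit")
    p0 = init if init is not None else _auto_init(exp, dilution)
    if p0.ka <= 0:
        raise ValueError("initial ka must be > 0 for fitting")

    obs = np.asarray(exp.ndh)
    weights = (
        1.0 / np.asarray(exp.sigma) if exp.sigma is not None else np.ones(obs.size)
    )
    keep = slice(1, None) if discard_first else slice(None)

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        log10_ka, dh, offset = theta
        params = BindingParameters(ka=10.0 ** log10_ka, dh=dh, offset=offset)
        model = model_ndh(params, exp.protocol, dilution)
        return ((model - obs) * weights)[keep]

    starts = [
        math.log10(p0.ka) + shift
        for shift in (0.0, -multistart_decades, +multistart_decades)
    ]
    best = None
    for log_ka_start in starts:
        theta0 = np.array([log_ka_start, p0.dh, p0.offset])
        try:
            sol = optimize.least_squares(
                residual_vec,
                theta0,
                bounds=([-5.0, -1e4, -1e4], [30.0, 1e4, 1e4]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    log10_ka, dh, offset = best.x
    params = BindingParameters(ka=10.0 ** log10_ka, dh=dh, offset=offset)
    res = residual_vec(best.x)
    m, p = res.size, 3
    dof = max(m - p, 1)
    s2 = float(res @ res) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        singular = False
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)
        singular = True

    converged = bool(best.success) and not singular
    lower_bound = bool(
        singular or se[0] > 1.0 or log10_ka >= 30.0 - 1e-6
    )
    rt = GAS_CONSTANT_KCAL * STANDARD_TEMPERATURE_K
    return IsothermFit(
        params=params,
        log10_ka=float(log10_ka),
        se_log10_ka=float(se[0]),
        se_dh=float(se[1]),
        se_offset=float(se[2]),
        dg=delta_g_from_ka(params.ka),
        se_dg=float(math.log(10.0) * rt * se[0]),
        converged=converged,
        ka_lower_bound=lower_bound,
        residuals=tuple(res),
        residual_rms=float(np.sqrt(np.mean(res**2))),
        n_injections=exp.protocol.n_injections,
        cost=float(best.cost),
    )
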