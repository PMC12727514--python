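"""Open-system carbonate speciation, calcite saturation, and rate inversion.

The experimental fluids are dilute NaCl/NaHCO3(/CaCl2) solutions in
contact with a fixed-pCO2 atmosphere, so the carbonate system is treated
as open: dissolved CO2 is pinned by Henry's law, and pH (or charge
balance) fixes the rest of the speciation. The calcite saturation index

    Ω = a(Ca²⁺) · a(CO3²⁻) / Ksp

uses Davies activity coefficients, valid for the experiment's ionic
strength of ~0.1 molal. Three inversions around Ω drive the interfacial
chemistry analysis:

* ``outlet_ca_ppm`` — steady-state outlet [Ca] of a flow-through cell
  from the dissolution flux ([Ca] = r·M_Ca·SA / (10⁻⁶·ν));
* ``solve_ph_for_omega`` — the local pH at which a solution of known Ca
  and pCO2 reaches a target Ω (closed form in {H⁺});
* ``omega_from_rate_reduction`` — the Ω implied by an observed
  fractional drop of the dissolution rate, given a rate law R(Ω).

Equilibrium constants default to the Plummer & Busenberg (1982)
temperature expressions; they are injectable so alternative constant
sets (e.g. a full geochemical code's) can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

M_CA_G_MOL = 40.0
DAVIES_I_LIMIT = 0.5


@dataclass
class ThermoConstants:
    """Equilibrium constants for the CO2–water–calcite system.

    kh: Henry's constant for CO2 (mol·kg⁻¹·atm⁻¹); k1, k2: carbonic acid
    dissociation; ksp: calcite solubility product; kw: water; davies_a:
    Debye–Hückel A parameter used in the Davies equation.
    """

    kh: float
    k1: float
    k2: float
    ksp: float
    kw: float
    davies_a: float
    temperature_c: float
    provenance: str = "user"

    @classmethod
    def at_temperature(cls, temperature_c: float = 20.0) -> "ThermoConstants":
        """Plummer & Busenberg (1982) expressions, T in 0–40 °C."""
        t_k = temperature_c + 273.15
        log10 = np.log10

        def pb(a, b, c, d, e=0.0):
            return a + b * t_k + c / t_k + d * log10(t_k) + e / t_k**2

        log_kh = pb(108.3865, 0.01985076, -6919.53, -40.45154, 669365.0)
        log_k1 = pb(-356.3094, -0.06091964, 21834.37, 126.8339, -1684915.0)
        log_k2 = pb(-107.8871, -0.03252849, 5151.79, 38.92561, -563713.9)
        log_ksp = pb(-171.9065, -0.077993, 2839.319, 71.595)
        # Harned & Owen fit for the water ion product
        log_kw = -4470.99 / t_k + 6.0875 - 0.01706 * t_k
        # quadratic through A = 0.4918 (0 °C), 0.5085 (25 °C), 0.5425 (60 °C)
        a_dh = 0.4918 + 5.42e-4 * temperature_c + 5.05e-6 * temperature_c**2
        return cls(
            kh=10**log_kh,
            k1=10**log_k1,
            k2=10**log_k2,
            ksp=10**log_ksp,
            kw=10**log_kw,
            davies_a=a_dh,
            temperature_c=temperature_c,
            provenance="Plummer & Busenberg (1982); Harned & Owen Kw",
        )


@dataclass
class SolutionState:
    """Aqueous composition (molal) under a fixed-pCO2 atmosphere."""

    nacl_m: float = 0.09925
    nahco3_m: float = 0.00102
    cacl2_m: float = 0.0
    extra_ca_m: float = 0.0  # dissolution-derived Ca
    pco2_atm: float = 550e-6
    temperature_c: float = 20.0
    ph: float | None = None
    omega: float | None = None
    ionic_strength_m: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        for name in ("nacl_m", "nahco3_m", "cacl2_m", "extra_ca_m", "pco2_atm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.ionic_strength_m = self.background_ionic_strength()

    @property
    def ca_total_m(self) -> float:
        return self.cacl2_m + self.extra_ca_m

    def background_ionic_strength(self) -> float:
        """I from the fully dissociated salts (carbonate re-speciation adds little)."""
        na = self.nacl_m + self.nahco3_m
        cl = self.nacl_m + 2 * self.cacl2_m
        hco3 = self.nahco3_m
        ca = self.ca_total_m
        return 0.5 * (na + cl + hco3 + 4 * ca)


def davies_log_gamma(charge: int, ionic_strength_m: float, davies_a: float) -> float:
    """Davies equation, log10 of the single-ion activity coefficient."""
    if ionic_strength_m > DAVIES_I_LIMIT:
        warnings.warn(
            f"ionic strength {ionic_strength_m:.3f} m exceeds the Davies "
            f"validity range (~{DAVIES_I_LIMIT} m)",
            stacklevel=2,
        )
    if ionic_strength_m == 0:
        return 0.0
    sqrt_i = np.sqrt(ionic_strength_m)
    return -davies_a * charge**2 * (sqrt_i / (1 + sqrt_i) - 0.3 * ionic_strength_m)


def gamma(charge: int, ionic_strength_m: float, constants: ThermoConstants) -> float:
    return 10 ** davies_log_gamma(charge, ionic_strength_m, constants.davies_a)


def carbonate_activities(
    ph: float, pco2_atm: float, constants: ThermoConstants
) -> dict[str, float]:
    """Activities of the open-system carbonate species at given pH."""
    h = 10.0**-ph
    a_co2 = constants.kh * pco2_atm
    a_hco3 = constants.k1 * a_co2 / h
    a_co3 = constants.k2 * a_hco3 / h
    return {"H+": h, "CO2(aq)": a_co2, "HCO3-": a_hco3, "CO3--": a_co3,
            "OH-": constants.kw / h}


def ionic_strength_at(
    state: SolutionState, ph: float, constants: ThermoConstants
) -> float:
    """Self-consistent ionic strength at a given pH under fixed pCO2.

    I = ½ Σ m·z² over Na⁺, Cl⁻, Ca²⁺ and the pH-dependent carbonate
    species (open system: DIC follows pCO2 and pH, so the speciated
    HCO3⁻/CO3²⁻ replace the nominal added bicarbonate). Two fixed-point
    refinements of the activity coefficients are ample at I ≲ 0.1 m.
    """
    na = state.nacl_m + state.nahco3_m
    cl = state.nacl_m + 2 * state.cacl2_m
    fixed = 0.5 * (na + cl + 4 * state.ca_total_m)
    i = state.background_ionic_strength()
    acts = carbonate_activities(ph, state.pco2_atm, constants)
    for _ in range(2):
        g1 = gamma(1, i, constants)
        g2 = gamma(2, i, constants)
        i = fixed + 0.5 * (
            acts["H+"] / g1
            + acts["OH-"] / g1
            + acts["HCO3-"] / g1
            + 4 * acts["CO3--"] / g2
        )
    return i


def saturation_index(
    state: SolutionState,
    constants: ThermoConstants | None = None,
    ph: float | None = None,
    activity_scale: bool = True,
) -> float:
    """Calcite saturation index Ω at the state's (or a given) pH.

    Ω = a(Ca²⁺)·a(CO3²⁻)/Ksp with a(CO3²⁻) = K1·K2·KH·pCO2/{H⁺}² and
    Davies activity coefficients at the self-consistent ionic strength;
    ``activity_scale=False`` forms the ion product from concentrations
    instead (γ = 1).
    """
    constants = _check_constants(state, constants)
    ph = state.ph if ph is None else ph
    if ph is None:
        raise ValueError("pH must be set on the state or passed explicitly")
    acts = carbonate_activities(ph, state.pco2_atm, constants)
    i = ionic_strength_at(state, ph, constants)
    g2 = gamma(2, i, constants) if activity_scale else 1.0
    co3 = acts["CO3--"] if activity_scale else acts["CO3--"] / gamma(2, i, constants)
    return g2 * state.ca_total_m * co3 / constants.ksp


def equilibrium_ph(
    state: SolutionState, constants: ThermoConstants | None = None
) -> float:
    """Charge-balance pH of the solution under its fixed pCO2.

    Solves Na⁺ + 2Ca²⁺ + H⁺ = Cl⁻ + HCO3⁻ + 2CO3²⁻ + OH⁻ (molal) with the
    carbonate side pinned by pCO2, by bracketed root finding on pH 2–13.
    """
    constants = _check_constants(state, constants)
    na = state.nacl_m + state.nahco3_m
    cl = state.nacl_m + 2 * state.cacl2_m
    ca = state.ca_total_m
    i = state.ionic_strength_m
    g1 = gamma(1, i, constants)
    g2 = gamma(2, i, constants)

    def balance(ph: float) -> float:
        acts = carbonate_activities(ph, state.pco2_atm, constants)
        m_h = acts["H+"] / g1
        m_oh = acts["OH-"] / g1
        m_hco3 = acts["HCO3-"] / g1
        m_co3 = acts["CO3--"] / g2
        return (na + 2 * ca + m_h) - (cl + m_hco3 + 2 * m_co3 + m_oh)

    return float(optimize.brentq(balance, 2.0, 13.0, xtol=1e-10))


def solve_ph_for_omega(
    state: SolutionState,
    omega_target: float,
    constants: ThermoConstants | None = None,
) -> float:
    """pH at which the solution reaches a target calcite saturation Ω.

    Closed form: {H⁺} = sqrt(a(Ca)·K1·K2·KH·pCO2 / (Ω·Ksp)), fixed-point
    iterated with the self-consistent ionic strength at the provisional
    pH, so that :func:`saturation_index` at the returned pH reproduces
    the target Ω to well below 10⁻⁶.
    """
    if omega_target <= 0:
        raise ValueError("no finite pH gives Ω = 0; omega_target must be > 0")
    if state.ca_total_m <= 0:
        raise ValueError("total Ca must be > 0")
    constants = _check_constants(state, constants)

    def ph_at(i: float) -> float:
        g2 = gamma(2, i, constants)
        a_ca = g2 * state.ca_total_m
        h2 = (
            a_ca
            * constants.k1
            * constants.k2
            * constants.kh
            * state.pco2_atm
            / (omega_target * constants.ksp)
        )
        return float(-0.5 * np.log10(h2))

    ph = ph_at(state.ionic_strength_m)
    for _ in range(20):
        ph_new = ph_at(ionic_strength_at(state, ph, constants))
        if abs(ph_new - ph) < 1e-12:
            ph = ph_new
            break
        ph = ph_new
    return ph


def outlet_ca_ppm(
    rate_mol_m2_s: float,
    surface_area_m2: float = 1e-4,
    flow_ml_s: float = 0.004,
    molar_mass_g_mol: float = M_CA_G_MOL,
) -> float:
    """Steady-state outlet [Ca] (ppm) of a flow-through dissolution cell.

    [Ca] = r · M_Ca · SA / (10⁻⁶ · ν) with r in mol·m⁻²·s⁻¹, SA in m²
    and ν in mL/s; exact arithmetic, no rounding.
    """
    if flow_ml_s <= 0:
        raise ValueError("flow rate must be > 0")
    if surface_area_m2 <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("surface area and molar mass must be > 0")
    if rate_mol_m2_s < 0:
        raise ValueError("dissolution rate must be >= 0")
    return rate_mol_m2_s * molar_mass_g_mol * surface_area_m2 / (1e-6 * flow_ml_s)


def ppb_to_molal(ca_ppb: float, molar_mass_g_mol: float = M_CA_G_MOL) -> float:
    """ppb (µg/kg) to molality for a dilute solution."""
    return ca_ppb * 1e-6 / molar_mass_g_mol


@dataclass
class RateLaw:
    """Calcite dissolution rate as a function of saturation, R = k·(1−Ω)ⁿ.

    The exponent defaults to n = log(0.8)/log(0.9) ≈ 2.115, the value
    calibrated so that a 20% rate reduction maps to Ω = 0.1 — a
    documented stand-in for empirical rate–Ω relationships whose exact
    form varies between studies. k is the far-from-equilibrium rate
    (mol·m⁻²·s⁻¹); its value cancels in rate-ratio inversions.
    """

    k: float = 9e-7
    n: float = float(np.log(0.8) / np.log(0.9))

    def __call__(self, omega: float) -> float:
        if not 0 <= omega <= 1:
            raise ValueError("rate law defined on Ω in [0, 1]")
        return self.k * (1.0 - omega) ** self.n


def omega_from_rate_reduction(fraction: float, rate_law=None, tol: float = 1e-6) -> float:
    """Invert R(Ω) = (1−fraction)·R(0): the Ω implied by a rate drop.

    ``fraction`` is the observed fractional reduction of the dissolution
    rate under attached cells (0.2 for a 20% drop). Bisection on [0, 1];
    the rate law must be non-increasing there.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if rate_law is None:
        rate_law = RateLaw()
    r0 = rate_law(0.0)
    probe = [rate_law(x) for x in np.linspace(0, 1, 21)]
    if any(b > a + 1e-15 * abs(r0) for a, b in zip(probe, probe[1:])):
        raise ValueError("rate law is not non-increasing on [0, 1]")
    if fraction == 0:
        return 0.0
    target = (1.0 - fraction) * r0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rate_law(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _check_constants(
    state: SolutionState, constants: ThermoConstants | None
) -> ThermoConstants:
    if constants is None:
        constants = ThermoConstants.at_temperature(state.temperature_c)
    elif abs(constants.temperature_c - state.temperature_c) > 5.0:
        warnings.warn(
            f"constant set at {constants.temperature_c} °C used for a "
            f"{state.temperature_c} °C solution",
            stacklevel=3,
        )
    return constants
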