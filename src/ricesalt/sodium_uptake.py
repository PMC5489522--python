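"""Daily shoot Na+ uptake through the apoplastic (bypass-flow) pathway.

Sodium enters the rice shoot mainly with the transpiration stream that
short-circuits the root membranes through the apoplast.  The genotype
limits this route by depositing suberin in the root exo- and endodermis:
suberin content grows with plant age and with salinity exposure, and the
relative bypass flow declines from 1 (no suberin beyond the baseline) to
``rrbf_min``/100 at maximum suberin content.  The chain of functions below
turns one day of transpiration, air humidity and external Na+ molarity
into the total mass of Na+ (mg ha-1) entering the shoot.

Unit conventions: water fluxes in mm d-1 over one hectare (1 mm ha-1 =
10^4 L), Na+ molarity in mM, Na+ masses in mg ha-1 (molar mass of Na =
22.99 mg mmol-1).
"""

from __future__ import annotations

from .parameters import TraitParameters, AuxiliaryConstants, ConfigurationError

LITRES_PER_MM_HA = 1.0e4
NA_MOLAR_MASS = 22.99  # mg mmol-1


def relative_bypass_water(rh: float) -> float:
    """Percentage of water uptake taking the apoplastic path, from RH (%).

    Empirical linear decline with air relative humidity (higher RH, lower
    transpiration pull through the apoplast): ``-0.0275 * rh + 3.92``,
    floored at 0.
    """
    if not (0.0 <= rh <= 100.0):
        raise ValueError("rh must be in [0, 100]")
    return max(-0.0275 * rh + 3.92, 0.0)


def bypass_water_flux(tr_act: float, rjv_b: float) -> float:
    """Water flux through the apoplastic pathway (mm d-1).

    ``tr_act`` is actual transpiration (mm d-1); ``rjv_b`` the apoplastic
    percentage of water uptake.
    """
    if tr_act < 0.0:
        raise ValueError("tr_act must be non-negative")
    return tr_act * rjv_b / 100.0


def suberin_deposition_response(na_ext: float, max_na_ext: float, sub_dep_eff: float) -> float:
    """Salinity-induced suberin deposition signal F_sc, clamped to [0, 1].

    Scales with the ratio of external Na+ to the saturating concentration,
    amplified by the genotype's deposition efficiency ``sub_dep_eff``
    (efficiency 1 would be a singular, instantaneous response).
    """
    if not (0.0 <= sub_dep_eff <= 1.0):
        raise ValueError("sub_dep_eff must be in [0, 1]")
    if sub_dep_eff >= 1.0:
        raise ZeroDivisionError("sub_dep_eff = 1 makes the deposition response singular")
    if max_na_ext <= 0.0:
        raise ConfigurationError("max_na_ext must be positive")
    if na_ext < 0.0:
        raise ValueError("na_ext must be non-negative")
    f = (na_ext / max_na_ext) / (1.0 - sub_dep_eff)
    return min(max(f, 0.0), 1.0)


def suberin_content(dvs: float, f_sc: float, sc_max: float) -> float:
    """Root suberin content (mg g-1) as a function of age and salinity signal.

    Saturating in the development stage ``dvs`` (0 emergence, 1 anthesis,
    2 maturity); the salinity signal ``f_sc`` accelerates deposition.
    Bounded by ``sc_max``; 0 at emergence.
    """
    if not (0.0 <= dvs <= 2.0):
        raise ValueError("dvs must be in [0, 2]")
    denom = (1.0 - f_sc) + dvs
    if denom == 0.0:
        return 0.0  # dvs=0 with f_sc=1: emergence limit
    sc = sc_max * dvs * (0.5 * (1.0 - f_sc) + 1.0) / denom
    return min(max(sc, 0.0), sc_max)


def relative_bypass_flow(
    sc: float,
    params: TraitParameters,
    aux: AuxiliaryConstants,
    literal_mode: bool = False,
) -> float:
    """Relative bypass flow RRBF (0-1) as a function of suberin content.

    Canonical form (default): ``(rrbf_min/100) ** frac`` with
    ``frac = (sc - sc_min)/(sc_max - sc_min)`` — equal to 1 with no suberin
    beyond the baseline and to ``rrbf_min/100`` at maximum suberin content,
    strictly decreasing in between.  ``literal_mode`` evaluates the
    alternative placement ``(1/100) * rrbf_min ** frac`` instead, retained
    for auditability.
    """
    if params.sc_max <= aux.sc_min:
        raise ConfigurationError("sc_max must exceed sc_min")
    sc = min(max(sc, aux.sc_min), params.sc_max)
    frac = (sc - aux.sc_min) / (params.sc_max - aux.sc_min)
    if literal_mode:
        return 0.01 * params.rrbf_min ** frac
    return (params.rrbf_min / 100.0) ** frac


def apoplastic_na_uptake(jv_b: float, rrbf: float, na_ext: float) -> float:
    """Na+ delivered to the shoot via bypass flow (mg ha-1 d-1).

    ``jv_b`` (mm d-1) of water over one hectare is ``jv_b * 1e4`` litres;
    each litre at ``na_ext`` mM carries ``na_ext * 22.99`` mg of Na+; the
    relative bypass flow ``rrbf`` discounts for suberisation.
    """
    if jv_b < 0.0 or rrbf < 0.0 or na_ext < 0.0:
        raise ValueError("jv_b, rrbf and na_ext must be non-negative")
    return jv_b * LITRES_PER_MM_HA * rrbf * na_ext * NA_MOLAR_MASS


def total_na_uptake(uptake_ap: float, rh: float, aux: AuxiliaryConstants) -> float:
    """Total daily shoot Na+ uptake (mg ha-1) from the apoplastic share.

    The bypass route carries only part of the uptake; its percentage share
    is an RH-dependent linear function (defaults map the 58-92 % RH band
    onto a 35-22 % bypass share).  Total uptake = apoplastic / share.
    """
    if uptake_ap < 0.0:
        raise ValueError("uptake_ap must be non-negative")
    share = aux.bypass_share(rh)
    if share <= 0.0:
        raise ConfigurationError("bypass share must be positive")
    return uptake_ap * 100.0 / share


def daily_shoot_uptake(
    tr_act: float,
    rh: float,
    na_ext: float,
    dvs: float,
    params: TraitParameters,
    aux: AuxiliaryConstants,
    literal_mode: bool = False,
) -> float:
    """One day's total shoot Na+ uptake (mg ha-1), chaining the full pathway."""
    if na_ext <= 0.0 or tr_act <= 0.0:
        return 0.0
    rjv_b = relative_bypass_water(rh)
    jv_b = bypass_water_flux(tr_act, rjv_b)
    f_sc = suberin_deposition_response(na_ext, aux.max_na_ext, params.sub_dep_eff)
    sc = suberin_content(dvs, f_sc, params.sc_max)
    rrbf = relative_bypass_flow(sc, params, aux, literal_mode=literal_mode)
    up_ap = apoplastic_na_uptake(jv_b, rrbf, na_ext)
    return total_na_uptake(up_ap, rh, aux)
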