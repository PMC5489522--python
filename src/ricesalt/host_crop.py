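"""Minimal multilayer daily crop engine hosting the salt-stress module.

The host is a deliberately small SUCROS/WOFOST-style simulator: RUE-based
growth from intercepted radiation, thermal-time phenology (DVS 0-2),
DVS-tabulated photosynthate partitioning, and an age-ordered canopy kept
as N equal-biomass quantile layers (layer 0 = bottom = oldest tissue).
It exposes exactly the coupling surface the salinity module needs —
actual transpiration, DVS, panicle partitioning share, per-layer leaf
biomass — and consumes the five stress multipliers:

* per-layer photosynthesis factor weights gross growth by each layer's
  share of intercepted light, and accelerates senescence of stressed
  layers;
* the respiration factor scales leaf and culm maintenance respiration by
  ``1 + mresp_f``;
* the sterility factor reduces the photosynthate flux to panicles;
* the osmotic factors modify specific leaf area and culm growth.

New leaf biomass enters the canopy at the top with zero Na+; senesced
biomass leaves from the bottom carrying its Na+ into a dead-tissue
ledger.  Both moves re-bin the Na+ profile along the cumulative-biomass
coordinate so the layers remain equal-biomass quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import TraitParameters, AuxiliaryConstants, HostParameters
from .scenarios import DailyEnvironment, make_weather, with_salinity
from .sodium_allocation import SodiumPools, allocate_day, tissue_concentration
from .stress_response import StressFactors, compute_stress


@dataclass
class CropState:
    """Live host state; the coupling surface seen by the salinity module."""

    dvs: float
    leaf_biomass: float          # kg ha-1, total living leaves
    culm_biomass: float          # kg ha-1
    panicle_biomass: float       # kg ha-1
    lai: float                   # m2 m-2
    dead_leaf_biomass: float
    tr_act: float                # mm d-1, last computed actual transpiration
    par_p: float                 # current photosynthate share to panicles
    plant_density: float         # plants ha-1
    n_layers: int

    @property
    def leaf_biomass_by_layer(self) -> tuple[float, ...]:
        """Equal-biomass quantile layers, bottom (oldest) first."""
        return (self.leaf_biomass / self.n_layers,) * self.n_layers

    @property
    def aboveground_biomass(self) -> float:
        return self.leaf_biomass + self.culm_biomass + self.panicle_biomass + self.dead_leaf_biomass


@dataclass
class SimulationResult:
    """Season outcome: final summaries plus (optionally) the daily table."""

    final_yield: float            # kg ha-1, panicle biomass at season end
    final_agb: float              # kg ha-1, aboveground incl. dead leaves
    cumulative_fertility: float   # product of (1 - sterility_f) over the season
    cumulative_uptake: float      # mg ha-1 of shoot Na+ taken up over the season
    final_pools: SodiumPools
    final_state: CropState
    days_run: int
    daily: pd.DataFrame | None = None


def _interp(x: float, xs: Sequence[float], ys: Sequence[float]) -> float:
    """Piecewise-linear table lookup with edge clamping."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for j in range(1, len(xs)):
        if x <= xs[j]:
            w = (x - xs[j - 1]) / (xs[j] - xs[j - 1])
            return ys[j - 1] + w * (ys[j] - ys[j - 1])
    return ys[-1]


def partitioning(dvs: float, host: HostParameters) -> tuple[float, float, float]:
    """Photosynthate fractions (leaf, culm, panicle) at ``dvs``, renormalised."""
    fl = _interp(dvs, host.part_dvs, host.part_leaf)
    fc = _interp(dvs, host.part_dvs, host.part_culm)
    fp = _interp(dvs, host.part_dvs, host.part_panicle)
    s = fl + fc + fp
    return fl / s, fc / s, fp / s


def advance_phenology(dvs: float, tmean: float, host: HostParameters) -> float:
    """Advance DVS by one day of thermal time; capped at 2 (maturity)."""
    dd = max(tmean - host.t_base, 0.0)
    if dvs < 1.0:
        dvs = dvs + dd / host.tt_emergence_anthesis
        # thermal time spilling past anthesis is carried into the next phase
        if dvs > 1.0:
            spill = (dvs - 1.0) * host.tt_emergence_anthesis
            dvs = 1.0 + spill / host.tt_anthesis_maturity
    else:
        dvs = dvs + dd / host.tt_anthesis_maturity
    return min(dvs, 2.0)


def _layer_light_weights(lai: float, n: int, k_ext: float) -> list[float]:
    """Share of intercepted light per layer (bottom-first), Beer's law.

    LAI is spread evenly over the equal-biomass layers; light enters at the
    top (layer n-1).  Weights sum to 1 (uniform if LAI is ~0).
    """
    if lai <= 1e-12:
        return [1.0 / n] * n
    dl = lai / n
    shares = []
    for j in range(n):  # j=0 bottom; LAI above bottom layer j is (n-1-j)*dl
        above = (n - 1 - j) * dl
        shares.append(math.exp(-k_ext * above) - math.exp(-k_ext * (above + dl)))
    tot = sum(shares)
    return [s / tot for s in shares]


def _rebin_canopy(
    na_by_layer: Sequence[float], w_old: float, dead: float, added: float, n: int
) -> tuple[list[float], float]:
    """Re-bin the leaf Na+ profile after bottom senescence and top growth.

    The canopy is a cumulative-biomass axis [0, w_old] with piecewise-
    constant Na+ density per equal bin.  Remove the slice [0, dead]
    (oldest tissue; its Na+ is returned as retired), append ``added``
    biomass with zero Na+ at the top, and re-bin into ``n`` equal bins.
    """
    if w_old <= 0.0:
        return [0.0] * n, 0.0
    dead = min(max(dead, 0.0), w_old)
    h_old = w_old / n
    # Na removed with the dead slice
    removed = 0.0
    for i in range(n):
        lo, hi = i * h_old, (i + 1) * h_old
        overlap = max(0.0, min(hi, dead) - lo)
        if overlap > 0.0:
            removed += na_by_layer[i] * overlap / h_old
    w_new = w_old - dead + added
    if w_new <= 0.0:
        return [0.0] * n, removed
    h_new = w_new / n
    out = [0.0] * n
    for j in range(n):
        lo_n, hi_n = dead + j * h_new, dead + (j + 1) * h_new
        for i in range(n):
            lo_o, hi_o = i * h_old, (i + 1) * h_old
            overlap = max(0.0, min(hi_n, hi_o) - max(lo_n, max(lo_o, dead)))
            if overlap > 0.0:
                out[j] += na_by_layer[i] * overlap / h_old
    return out, removed


def initial_state(host: HostParameters) -> CropState:
    return CropState(
        dvs=0.0,
        leaf_biomass=host.init_leaf_biomass,
        culm_biomass=host.init_culm_biomass,
        panicle_biomass=0.0,
        lai=host.init_lai,
        dead_leaf_biomass=0.0,
        tr_act=0.0,
        par_p=0.0,
        plant_density=host.plant_density,
        n_layers=host.n_layers,
    )


def run_season(
    weather: Sequence[DailyEnvironment],
    params: TraitParameters | None = None,
    aux: AuxiliaryConstants | None = None,
    host: HostParameters | None = None,
    *,
    salinity: Sequence[float] | None = None,
    disable_salt: bool = False,
    literal_rrbf: bool = False,
    literal_rpn: bool = False,
    record: bool = True,
    stop_at_maturity: bool = True,
) -> SimulationResult:
    """Run one season of the coupled host + salt model.

    ``weather`` carries the daily forcing; if ``salinity`` (mM, same
    length) is given it overrides each day's ``na_ext``.  With
    ``disable_salt`` the salinity module is bypassed entirely (host-only
    run).  Deterministic given inputs.
    """
    params = params or TraitParameters()
    aux = aux or AuxiliaryConstants()
    host = host or HostParameters()
    if salinity is not None:
        if len(salinity) != len(weather):
            raise ValueError("weather and salinity series must have equal length")
        weather = with_salinity(weather, salinity)

    n = host.n_layers
    state = initial_state(host)
    pools = SodiumPools.zeros(n)
    fertility = 1.0
    uptake_total = 0.0
    from .sodium_uptake import daily_shoot_uptake

    rows: list[dict] = [] if record else None
    days_run = 0
    for day, env in enumerate(weather):
        # --- host supply side: interception and transpiration
        fint = 1.0 - math.exp(-host.k_ext * state.lai)
        state.tr_act = host.trans_coeff * env.et0 * fint
        fl, fc, fp = partitioning(state.dvs, host)
        state.par_p = fp

        # --- salt module: stress from current tissue state, then uptake
        layer_bm = state.leaf_biomass / n
        if disable_salt:
            stress = StressFactors.neutral(n)
            uptake = 0.0
        else:
            conc_layers = [tissue_concentration(p, layer_bm) for p in pools.leaf_na_by_layer]
            conc_mean = tissue_concentration(pools.leaf_na, state.leaf_biomass)
            pan_conc = tissue_concentration(pools.panicle_na, state.panicle_biomass)
            stress = compute_stress(
                conc_layers, conc_mean, pan_conc, env.na_ext, state.dvs,
                params, aux, literal_rpn=literal_rpn,
            )
            uptake = daily_shoot_uptake(
                state.tr_act, env.rh, env.na_ext, state.dvs, params, aux,
                literal_mode=literal_rrbf,
            )
            pools = allocate_day(uptake, pools, state, params)
            uptake_total += uptake

        # --- growth
        weights = _layer_light_weights(state.lai, n, host.k_ext)
        rpn_eff = sum(w * r for w, r in zip(weights, stress.rpn_by_layer))
        par = host.par_fraction * env.radiation
        gross = host.rue * par * fint * rpn_eff * 10.0  # g m-2 -> kg ha-1
        maint = (
            (host.mresp_leaf * state.leaf_biomass + host.mresp_culm * state.culm_biomass)
            * (1.0 + stress.mresp_f)
            + host.mresp_panicle * state.panicle_biomass
        )
        resp_applied = min(maint, gross)
        net = gross - resp_applied
        d_leaf = net * fl
        d_culm = net * fc * stress.cvs_stress
        d_pan = net * fp * (1.0 - stress.sterility_f)
        stress_loss = net * fc * (1.0 - stress.cvs_stress) + net * fp * stress.sterility_f
        fertility *= 1.0 - stress.sterility_f

        # --- senescence: oldest tissue first, boosted by stressed layers
        d_base = 0.002 + host.death_rate_maturity * max(state.dvs - 1.0, 0.0)
        death_frac = 0.0
        for w_layer, rpn_i in zip([1.0 / n] * n, stress.rpn_by_layer):
            rate = min(d_base * (1.0 + aux.k_senescence * (1.0 - rpn_i)), 0.5)
            death_frac += w_layer * rate
        dead = state.leaf_biomass * death_frac

        # --- canopy bookkeeping: re-bin Na along the biomass axis
        new_na, retired = _rebin_canopy(pools.leaf_na_by_layer, state.leaf_biomass, dead, d_leaf, n)
        pools = pools.replace(leaf_na_by_layer=tuple(new_na), dead_na=pools.dead_na + retired)

        sla = _interp(state.dvs, host.sla_dvs, host.sla_values)
        lai_gain = d_leaf * sla * stress.sla_stress / 1.0e4  # kg ha-1 * m2 kg-1 -> m2 m-2
        lai_loss = state.lai * (dead / state.leaf_biomass) if state.leaf_biomass > 0 else 0.0

        state.leaf_biomass = max(state.leaf_biomass - dead + d_leaf, 0.0)
        state.dead_leaf_biomass += dead
        state.culm_biomass += d_culm
        state.panicle_biomass += d_pan
        state.lai = max(state.lai - lai_loss + lai_gain, 0.0)

        # --- post-anthesis stem-reserve remobilisation culm -> panicle;
        # Na+ moves with the biomass so the culm concentration is unchanged
        remob = 0.0
        if state.dvs >= 1.0 and state.culm_biomass > 0.0:
            remob = host.remobilisation_rate * state.culm_biomass
            na_moved = pools.culm_na * remob / state.culm_biomass
            state.culm_biomass -= remob
            state.panicle_biomass += remob
            pools = pools.replace(
                culm_na=pools.culm_na - na_moved,
                panicle_na=pools.panicle_na + na_moved,
            )

        if record:
            rows.append(
                {
                    "day": day + 1, "dvs": state.dvs, "tmean": env.tmean,
                    "na_ext": env.na_ext, "tr_act": state.tr_act, "lai": state.lai,
                    "leaf_biomass": state.leaf_biomass, "culm_biomass": state.culm_biomass,
                    "panicle_biomass": state.panicle_biomass,
                    "dead_leaf_biomass": state.dead_leaf_biomass,
                    "agb": state.aboveground_biomass,
                    "na_uptake": uptake, "culm_na": pools.culm_na,
                    "panicle_na": pools.panicle_na, "leaf_na": pools.leaf_na,
                    "dead_na": pools.dead_na, "plant_na": pools.total,
                    "rpn_canopy": rpn_eff, "mresp_f": stress.mresp_f,
                    "sterility_f": stress.sterility_f, "sla_stress": stress.sla_stress,
                    "cvs_stress": stress.cvs_stress,
                    "gross": gross, "resp": resp_applied, "stress_loss": stress_loss,
                    "d_leaf": d_leaf, "d_culm": d_culm, "d_pan": d_pan, "dead": dead,
                    "remob": remob,
                }
            )

        # --- phenology advances at end of day
        state.dvs = advance_phenology(state.dvs, env.tmean, host)
        days_run = day + 1
        if stop_at_maturity and state.dvs >= 2.0:
            break

    return SimulationResult(
        final_yield=state.panicle_biomass,
        final_agb=state.aboveground_biomass,
        cumulative_fertility=fertility,
        cumulative_uptake=uptake_total,
        final_pools=pools,
        final_state=state,
        days_run=days_run,
        daily=pd.DataFrame(rows) if record else None,
    )


# ------------------------------------------------------------- hydroponics

#: day/night (14 h / 10 h) temperatures of the growth-chamber protocol
HYDROPONIC_T_DAY = 26.0
HYDROPONIC_T_NIGHT = 18.0
HYDROPONIC_TREATMENTS_MM = (0.0, 10.0, 25.0, 35.0, 50.0)


def hydroponic_weather(season_length: int = 140) -> list[DailyEnvironment]:
    """Deterministic growth-chamber forcing: constant NaCl added separately.

    Daily mean temperature is the photoperiod-weighted 26/18 deg C cycle;
    RH cycles deterministically within the experimental 58-92 % band;
    radiation and ET0 are constant lamp-driven values.
    """
    tmean = (14.0 * HYDROPONIC_T_DAY + 10.0 * HYDROPONIC_T_NIGHT) / 24.0
    out = []
    for d in range(season_length):
        rh = 75.0 + 17.0 * math.sin(2.0 * math.pi * d / 7.0)
        out.append(DailyEnvironment(rh=rh, na_ext=0.0, tmean=tmean, radiation=12.0, et0=4.0))
    return out


def hydroponic_season(
    treatment_mm: float,
    params: TraitParameters | None = None,
    aux: AuxiliaryConstants | None = None,
    host: HostParameters | None = None,
    season_length: int = 140,
    onset_day: int = 21,
    **kw,
) -> SimulationResult:
    """Run one constant-NaCl growth-chamber treatment to maturity.

    Following the growth-chamber protocol, NaCl is applied from
    ``onset_day`` (default three weeks after sowing) until the end of the
    season, at a constant concentration ``treatment_mm``.
    """
    weather = hydroponic_weather(season_length)
    salinity = [0.0] * onset_day + [treatment_mm] * (season_length - onset_day)
    return run_season(weather, params, aux, host, salinity=salinity, **kw)


def field_season(
    params: TraitParameters | None = None,
    aux: AuxiliaryConstants | None = None,
    host: HostParameters | None = None,
    *,
    scenario=None,
    season_length: int = 150,
    seed: int = 0,
    **kw,
) -> SimulationResult:
    """Convenience field run: synthetic weather + a salinity scenario."""
    from .scenarios import make_salinity_series

    weather = make_weather(season_length, seed)
    salinity = (
        make_salinity_series(scenario, season_length)
        if scenario is not None
        else [0.0] * season_length
    )
    return run_season(weather, params, aux, host, salinity=salinity, **kw)
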