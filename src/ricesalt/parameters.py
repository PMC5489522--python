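"""Parameter containers for the salt-stress model and its host crop engine.

``TraitParameters`` holds the ten genotype parameters that map one-to-one
onto the five tolerance traits rice breeders select for; its defaults are
the distribution means used throughout the ideotyping workflow.
``AuxiliaryConstants`` collects the fixed physiological constants of the
stress equations.  ``HostParameters`` configures the minimal daily crop
engine that hosts the salinity module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its structural invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class TraitParameters:
    """Genotype trait parameters (defaults are the reference distribution means).

    Trait groups:

    * T1 — reduction of shoot Na+ uptake: ``rrbf_min`` (%), relative bypass
      flow remaining when root suberin content is maximal; ``sub_dep_eff``
      (0-1), suberin deposition efficiency; ``sc_max`` (mg g-1), maximum
      root suberin content.
    * T2 — sequestration into structural tissue: ``pot_c_seq``
      (mg plant-1 d-1), potential culm sequestration rate; ``na_culm_max``
      (mg g-1), ceiling culm Na+ concentration.
    * T3 — tolerance to salt-induced sterility: ``susc_st`` (unitless)
      susceptibility; ``na_to_pan`` (0-1), Na+ translocation factor to the
      panicle.
    * T4 — compartmentation into senescent leaves: ``part_cap`` (0-1),
      partitioning capability toward the oldest canopy layers.
    * T5 — leaf tissue tolerance: ``thresh_l`` (mg g-1), leaf Na+
      concentration where photosynthesis stress starts; ``crit_l``
      (mg g-1), concentration where photosynthesis becomes null.
    """

    rrbf_min: float = 5.0
    sub_dep_eff: float = 0.62
    sc_max: float = 30.0
    pot_c_seq: float = 0.029
    na_culm_max: float = 26.0
    susc_st: float = 0.00135
    na_to_pan: float = 0.2
    part_cap: float = 0.7
    thresh_l: float = 1.5
    crit_l: float = 35.0

    def __post_init__(self) -> None:
        _require(0.0 < self.rrbf_min <= 100.0, "rrbf_min must be in (0, 100]")
        _require(0.0 <= self.sub_dep_eff <= 1.0, "sub_dep_eff must be in [0, 1]")
        for name in ("sc_max", "pot_c_seq", "na_culm_max", "susc_st", "thresh_l", "crit_l"):
            _require(getattr(self, name) >= 0.0, f"{name} must be non-negative")
        _require(0.0 <= self.na_to_pan <= 1.0, "na_to_pan must be in [0, 1]")
        _require(0.0 <= self.part_cap <= 1.0, "part_cap must be in [0, 1]")
        _require(self.crit_l > self.thresh_l, "crit_l must exceed thresh_l")

    # order used by the sensitivity workflow and by vector round-trips
    FIELD_ORDER = (
        "rrbf_min", "sub_dep_eff", "sc_max", "pot_c_seq", "na_culm_max",
        "susc_st", "na_to_pan", "part_cap", "thresh_l", "crit_l",
    )

    def to_vector(self) -> list[float]:
        return [getattr(self, f) for f in self.FIELD_ORDER]

    @classmethod
    def from_vector(cls, values: Sequence[float]) -> "TraitParameters":
        if len(values) != len(cls.FIELD_ORDER):
            raise ConfigurationError(
                f"expected {len(cls.FIELD_ORDER)} values, got {len(values)}"
            )
        return cls(**dict(zip(cls.FIELD_ORDER, values)))

    def replace(self, **kw) -> "TraitParameters":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AuxiliaryConstants:
    """Fixed constants of the stress equations, configurable but not traits.

    ``sc_min`` (mg g-1): suberin content below which bypass flow is not yet
    reduced.  ``max_na_ext`` (mM): external Na+ concentration at which
    suberin deposition saturates.  ``na_leaf_min`` (mg g-1): leaf Na+
    concentration of unstressed tissue.  ``shape_c``: shape coefficient of
    the photosynthesis response.  ``na_resp_thresh``/``na_resp_crit``
    (mg g-1): leaf Na+ concentrations where maintenance respiration starts
    to rise and where it doubles.  ``bypass_share_*``: linear map from air
    relative humidity to the percentage of total Na+ uptake entering
    through the apoplastic path (the bypass share), anchored to the 22-35 %
    range reported for rice over the experimental RH band 58-92 %.
    """

    sc_min: float = 9.0
    max_na_ext: float = 400.0
    na_leaf_min: float = 0.0
    shape_c: float = 1.0
    na_resp_thresh: float = 0.5
    na_resp_crit: float = 3.0
    bypass_share_rh_lo: float = 58.0
    bypass_share_rh_hi: float = 92.0
    bypass_share_at_lo: float = 35.0
    bypass_share_at_hi: float = 22.0
    bell_centers: tuple[float, float] = (0.8, 1.0)
    bell_sigma: float = 0.05
    k_senescence: float = 1.0
    clamp_sla_stress: bool = True

    def __post_init__(self) -> None:
        _require(self.max_na_ext > 0.0, "max_na_ext must be positive")
        _require(self.na_resp_crit > self.na_resp_thresh,
                 "na_resp_crit must exceed na_resp_thresh")
        _require(self.bypass_share_rh_hi > self.bypass_share_rh_lo,
                 "bypass-share RH band must be increasing")
        _require(self.bypass_share_at_lo > 0.0 and self.bypass_share_at_hi > 0.0,
                 "bypass shares must be positive percentages")
        _require(self.bell_sigma > 0.0, "bell_sigma must be positive")

    def bypass_share(self, rh: float) -> float:
        """Percentage of total Na+ uptake taken through the bypass path at ``rh``.

        Linear in RH between the two anchor points, clamped to the anchor
        values outside the band.
        """
        lo, hi = self.bypass_share_rh_lo, self.bypass_share_rh_hi
        slope = (self.bypass_share_at_hi - self.bypass_share_at_lo) / (hi - lo)
        rh_c = min(max(rh, lo), hi)
        return self.bypass_share_at_lo + slope * (rh_c - lo)

    def replace(self, **kw) -> "AuxiliaryConstants":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HostParameters:
    """Configuration of the minimal multilayer daily crop engine.

    The engine is a deliberately small RUE-based, thermal-time simulator:
    it exists to provide the coupling surface the salinity module needs
    (actual transpiration, development stage, organ biomasses split over an
    age-ordered multilayer canopy, photosynthate partitioning), not to
    reproduce any full crop model.  Default magnitudes are generic for a
    temperate japonica rice stand.
    """

    # phenology (thermal time, degree-days above base)
    t_base: float = 8.0                  # deg C
    tt_emergence_anthesis: float = 1200.0  # deg C d to DVS 1
    tt_anthesis_maturity: float = 500.0    # deg C d from DVS 1 to 2

    # growth
    rue: float = 2.2                     # g DM per MJ intercepted PAR
    k_ext: float = 0.5                   # canopy extinction coefficient
    par_fraction: float = 0.5            # PAR : global radiation

    # potential specific leaf area (m2 kg-1) interpolated on DVS nodes
    sla_dvs: tuple[float, ...] = (0.0, 1.0, 2.0)
    sla_values: tuple[float, ...] = (24.0, 16.0, 14.0)

    # photosynthate partitioning (fractions to leaf/culm/panicle per DVS node)
    part_dvs: tuple[float, ...] = (0.0, 0.5, 0.75, 1.0, 1.2, 2.0)
    part_leaf: tuple[float, ...] = (0.55, 0.50, 0.30, 0.00, 0.00, 0.00)
    part_culm: tuple[float, ...] = (0.45, 0.50, 0.50, 0.20, 0.00, 0.00)
    part_panicle: tuple[float, ...] = (0.00, 0.00, 0.20, 0.80, 1.00, 1.00)

    # maintenance respiration coefficients (g g-1 d-1)
    mresp_leaf: float = 0.016
    mresp_culm: float = 0.004
    mresp_panicle: float = 0.003

    # transpiration: tr_act = trans_coeff * et0 * light interception
    trans_coeff: float = 1.1

    # background relative leaf death rate at maturity (d-1), ramps in after
    # anthesis; amplified per layer by salt stress
    death_rate_maturity: float = 0.03

    # post-anthesis stem-reserve remobilisation to the panicle (d-1 of
    # current culm biomass); Na+ moves with the biomass, conserving
    # tissue concentration
    remobilisation_rate: float = 0.02

    # canopy / stand structure
    n_layers: int = 5
    plant_density: float = 2.0e6         # plants ha-1

    # initial seedling state (kg ha-1 / m2 m-2)
    init_leaf_biomass: float = 200.0
    init_culm_biomass: float = 100.0
    init_lai: float = 0.5

    def __post_init__(self) -> None:
        _require(self.n_layers >= 1, "n_layers must be >= 1")
        _require(self.plant_density >= 0.0, "plant_density must be non-negative")
        _require(self.tt_emergence_anthesis > 0.0 and self.tt_anthesis_maturity > 0.0,
                 "thermal-time requirements must be positive")
        nodes = len(self.part_dvs)
        _require(len(self.part_leaf) == len(self.part_culm) == len(self.part_panicle) == nodes,
                 "partitioning tables must share the DVS nodes")
        for i in range(nodes):
            s = self.part_leaf[i] + self.part_culm[i] + self.part_panicle[i]
            _require(abs(s - 1.0) < 1e-9,
                     f"partitioning fractions must sum to 1 at DVS {self.part_dvs[i]}")
        for name in ("rue", "k_ext", "mresp_leaf", "mresp_culm", "mresp_panicle",
                     "trans_coeff", "death_rate_maturity", "remobilisation_rate"):
            _require(getattr(self, name) >= 0.0, f"{name} must be non-negative")

    def replace(self, **kw) -> "HostParameters":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return asdict(self)
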