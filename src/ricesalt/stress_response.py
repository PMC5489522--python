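"""Stress feedbacks: tissue Na+ and external salinity to host multipliers.

Five factors are returned to the host crop engine each day: a per-layer
photosynthesis reduction (also used to accelerate senescence), a
maintenance-respiration increase, a daily spikelet-sterility factor, and
two osmotic multipliers acting on specific leaf area and culm growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import AuxiliaryConstants, ConfigurationError


@dataclass(frozen=True)
class StressFactors:
    """Daily stress multipliers passed to the host engine.

    ``rpn_by_layer``: photosynthesis factor per canopy layer (1 = no
    stress, 0 = photosynthesis null); ``mresp_f``: fractional increase of
    maintenance respiration (host applies 1 + mresp_f to leaves and
    culms); ``sterility_f``: daily reduction of photosynthate flux to
    panicles; ``sla_stress`` and ``cvs_stress``: osmotic modifiers of SLA
    and culm growth.
    """

    rpn_by_layer: tuple[float, ...]
    mresp_f: float = 0.0
    sterility_f: float = 0.0
    sla_stress: float = 1.0
    cvs_stress: float = 1.0

    @classmethod
    def neutral(cls, n_layers: int) -> "StressFactors":
        return cls(rpn_by_layer=(1.0,) * n_layers)


def photosynthesis_stress(
    na_leaf: float,
    thresh_l: float,
    crit_l: float,
    na_leaf_min: float = 0.0,
    shape_c: float = 1.0,
    literal_mode: bool = False,
) -> float:
    """Photosynthesis stress factor RPn (0-1) from leaf Na+ concentration.

    Canonical mode (default) is a beta-type response: 1 up to the
    threshold concentration ``thresh_l``, 0 at and beyond the critical
    concentration ``crit_l``, and strictly decreasing in between as

        RPn = (a ** (1/k) * b) ** shape_c,
        a = (na - na_min)/(thresh - na_min),
        b = (crit - na)/(crit - thresh),
        k = (crit - thresh)/(thresh - na_min),

    i.e. the steep exponent is applied in reciprocal form to the
    sub-threshold factor ``a`` only, so the decline is anchored by the
    ``b`` term and photosynthesis reaches zero exactly at the critical
    concentration; the inner product is strictly below 1 on the open
    interval for any parameter ordering, so any ``shape_c`` > 0
    preserves the boundary semantics and strict monotonicity.  ``literal_mode`` instead raises the product
    ``a*b`` to the exponent ``k**shape_c``, without clamping, for
    auditing the alternative formula placement.
    """
    if not (na_leaf_min < thresh_l < crit_l):
        raise ConfigurationError("require na_leaf_min < thresh_l < crit_l")
    a = (na_leaf - na_leaf_min) / (thresh_l - na_leaf_min)
    b = (crit_l - na_leaf) / (crit_l - thresh_l)
    k = (crit_l - thresh_l) / (thresh_l - na_leaf_min)
    if literal_mode:
        return (a * b) ** (k ** shape_c)
    if na_leaf <= thresh_l:
        return 1.0
    if na_leaf >= crit_l:
        return 0.0
    return min(max((a ** (1.0 / k) * b) ** shape_c, 0.0), 1.0)


def respiration_factor(na_leaves_mean: float, aux: AuxiliaryConstants) -> float:
    """Fractional maintenance-respiration increase from mean leaf Na+.

    Linear ramp from 0 at ``na_resp_thresh`` (default 0.5 mg g-1) to 1 at
    ``na_resp_crit`` (default 3 mg g-1, where respiration doubles),
    clamped to [0, 1].
    """
    f = (na_leaves_mean - aux.na_resp_thresh) / (aux.na_resp_crit - aux.na_resp_thresh)
    return min(max(f, 0.0), 1.0)


def phenology_bell(dvs: float, aux: AuxiliaryConstants) -> float:
    """Susceptibility bell for sterility: peaks at booting and flowering.

    Maximum of Gaussian bells centred on the two most sensitive stages
    (DVS 0.8, booting/microsporogenesis; DVS 1.0, flowering), zero outside
    the window [0.6, 1.1].
    """
    if not (0.6 <= dvs <= 1.1):
        return 0.0
    return max(
        math.exp(-0.5 * ((dvs - c) / aux.bell_sigma) ** 2) for c in aux.bell_centers
    )


def sterility_factor(
    na_panicle_conc: float,
    susc_st: float,
    dvs: float,
    aux: AuxiliaryConstants,
) -> float:
    """Daily spikelet-fertility reduction (0-1) from panicle Na+.

    Proportional to panicle Na+ concentration and genotype susceptibility,
    modulated by the phenological bell; zero outside DVS [0.6, 1.1].
    """
    if na_panicle_conc < 0.0:
        raise ValueError("na_panicle_conc must be non-negative")
    if not (0.6 <= dvs <= 1.1):
        return 0.0
    f = susc_st * na_panicle_conc * phenology_bell(dvs, aux)
    return min(max(f, 0.0), 1.0)


def osmotic_sla_factor(na_ext: float, clamp_at_one: bool = False) -> float:
    """Osmotic modifier of specific leaf area from external Na+ (mM).

    Quadratic ``-0.0002*x**2 + 0.008*x + 1`` floored at 0; mildly above 1
    for low salinity unless ``clamp_at_one``.
    """
    if na_ext < 0.0:
        raise ValueError("na_ext must be non-negative")
    f = max(-0.0002 * na_ext**2 + 0.008 * na_ext + 1.0, 0.0)
    return min(f, 1.0) if clamp_at_one else f


def osmotic_culm_factor(na_ext: float) -> float:
    """Osmotic reduction of culm growth from external Na+ (mM), in [0, 1]."""
    if na_ext < 0.0:
        raise ValueError("na_ext must be non-negative")
    return min(max(0.0002 * na_ext**2 - 0.024 * na_ext + 1.0, 0.0), 1.0)


def compute_stress(
    leaf_conc_by_layer,
    leaf_conc_mean: float,
    panicle_conc: float,
    na_ext: float,
    dvs: float,
    params,
    aux: AuxiliaryConstants,
    literal_rpn: bool = False,
) -> StressFactors:
    """Assemble all five factors from the day's concentrations and salinity."""
    rpn = tuple(
        photosynthesis_stress(
            c, params.thresh_l, params.crit_l, aux.na_leaf_min, aux.shape_c,
            literal_mode=literal_rpn,
        )
        for c in leaf_conc_by_layer
    )
    return StressFactors(
        rpn_by_layer=rpn,
        mresp_f=respiration_factor(leaf_conc_mean, aux),
        sterility_f=sterility_factor(panicle_conc, params.susc_st, dvs, aux),
        sla_stress=osmotic_sla_factor(na_ext, aux.clamp_sla_stress),
        cvs_stress=osmotic_culm_factor(na_ext),
    )
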