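"""Allocation of daily shoot Na+ among culm, panicle and leaf layers.

The culm base acts as a feedback-limited storage sink that intercepts Na+
before it reaches photosynthetic tissue; from the surplus, a fraction
travels to the panicle with the photosynthate stream during the
reproductive phase; the residual reaches the leaves, where it is
preferentially deposited into the oldest (bottom) canopy layers.  All
pools are cumulative masses in mg ha-1; tissue concentrations (mg g-1)
are derived by dividing by the organ dry biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import TraitParameters, ConfigurationError

KG_TO_G = 1000.0


def tissue_concentration(pool_mg_ha: float, biomass_kg_ha: float) -> float:
    """Na+ concentration (mg g-1) of a pool over an organ biomass; 0 if no biomass."""
    if biomass_kg_ha <= 0.0:
        return 0.0
    return pool_mg_ha / (biomass_kg_ha * KG_TO_G)


@dataclass(frozen=True)
class SodiumPools:
    """Cumulative Na+ mass pools (mg ha-1); layer index 0 = bottom/oldest."""

    culm_na: float = 0.0
    panicle_na: float = 0.0
    leaf_na_by_layer: tuple[float, ...] = ()
    dead_na: float = 0.0  # Na+ retired with senesced leaf tissue

    def __post_init__(self) -> None:
        if self.culm_na < 0 or self.panicle_na < 0 or self.dead_na < 0:
            raise ValueError("pools must be non-negative")
        if any(x < -1e-9 for x in self.leaf_na_by_layer):
            raise ValueError("leaf layer pools must be non-negative")

    @property
    def leaf_na(self) -> float:
        return sum(self.leaf_na_by_layer)

    @property
    def total(self) -> float:
        """Total Na+ in the living plant plus retired tissue (mg ha-1)."""
        return self.culm_na + self.panicle_na + self.leaf_na + self.dead_na

    @classmethod
    def zeros(cls, n_layers: int) -> "SodiumPools":
        return cls(leaf_na_by_layer=(0.0,) * n_layers)

    def replace(self, **kw) -> "SodiumPools":
        return replace(self, **kw)


def relative_sink_size(culm_na_conc: float, na_culm_max: float) -> float:
    """Remaining relative culm sink capacity (0 full sink empty... 1 empty).

    ``1 - conc/max`` clamped to [0, 1]: 1 for an empty sink, 0 once the
    culm Na+ concentration has reached its genotype ceiling.
    """
    if na_culm_max <= 0.0:
        raise ConfigurationError("na_culm_max must be positive")
    if culm_na_conc < 0.0:
        raise ValueError("culm_na_conc must be non-negative")
    return min(max(1.0 - culm_na_conc / na_culm_max, 0.0), 1.0)


def culm_sequestration_rate(rel_sink: float, pot_c_seq: float, density: float) -> float:
    """Actual culm sequestration rate (mg ha-1 d-1) with sink feedback.

    The genotype's potential per-plant rate, scaled by stand density and a
    hyperbolic feedback in the remaining sink size; the feedback term goes
    negative as the sink fills and is floored at 0 (a saturated sink
    sequesters nothing).
    """
    if not (0.0 <= rel_sink <= 1.0):
        raise ValueError("rel_sink must be in [0, 1]")
    feedback = 1.0 - 0.08 * ((rel_sink + 0.1) ** -1.13 - 0.08)
    return max(pot_c_seq * density * feedback, 0.0)


def panicle_na_delivery(
    na_uptake: float,
    culm_seq: float,
    par_p: float,
    na_to_pan: float,
    dvs: float,
) -> float:
    """Na+ reaching the panicle (mg ha-1 d-1) during the reproductive window.

    A fraction of the culm-sequestration surplus, proportional to the
    photosynthate share currently routed to panicles (``par_p``) and the
    genotype translocation factor; zero outside DVS [0.6, 2].
    """
    if not (0.6 <= dvs <= 2.0):
        return 0.0
    return par_p * na_to_pan * max(na_uptake - culm_seq, 0.0)


def leaf_layer_partition(na_leaves: float, part_cap: float, n_layers: int) -> list[float]:
    """Split leaf-bound Na+ over canopy layers, oldest (bottom, index 0) first.

    Layer i (1-based from the bottom) receives weight
    ``(1 - part_cap) ** ((i-1)/(N-1))``, normalised over layers: geometric
    decline toward the youngest leaves, equal split at ``part_cap`` = 0,
    everything to the bottom layer in the ``part_cap`` -> 1 limit.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if not (0.0 <= part_cap <= 1.0):
        raise ValueError("part_cap must be in [0, 1]")
    if na_leaves < 0.0:
        raise ValueError("na_leaves must be non-negative")
    if n_layers == 1:
        return [na_leaves]
    if part_cap >= 1.0:  # degenerate limit: all to the oldest layer
        return [na_leaves] + [0.0] * (n_layers - 1)
    weights = [(1.0 - part_cap) ** ((i - 1) / (n_layers - 1)) for i in range(1, n_layers + 1)]
    s = sum(weights)
    return [na_leaves * w / s for w in weights]


def allocate_day(uptake: float, pools: SodiumPools, state, params: TraitParameters) -> SodiumPools:
    """Distribute one day's shoot Na+ uptake over the pools; mass-conserving.

    ``state`` provides the host coupling surface: ``dvs``, ``par_p``,
    ``plant_density``, ``culm_biomass`` (kg ha-1) and ``n_layers``.  The
    culm intake is capped both by the feedback-limited sequestration rate
    and by the hard concentration ceiling ``na_culm_max``; the panicle
    takes its share of the surplus during the reproductive window; the
    residual goes to the leaf layers.  The deltas sum exactly to
    ``uptake``.
    """
    if uptake < 0.0:
        raise ValueError("uptake must be non-negative")
    n_layers = state.n_layers
    if len(pools.leaf_na_by_layer) != n_layers:
        raise ValueError("pools layer count does not match state.n_layers")
    if uptake == 0.0:
        return pools

    culm_conc = tissue_concentration(pools.culm_na, state.culm_biomass)
    rel_sink = relative_sink_size(culm_conc, params.na_culm_max)
    seq_rate = culm_sequestration_rate(rel_sink, params.pot_c_seq, state.plant_density)
    capacity = max(params.na_culm_max * state.culm_biomass * KG_TO_G - pools.culm_na, 0.0)
    culm_seq = min(seq_rate, uptake, capacity)

    panicle = panicle_na_delivery(uptake, culm_seq, state.par_p, params.na_to_pan, state.dvs)
    panicle = min(panicle, uptake - culm_seq)

    na_leaves = uptake - culm_seq - panicle
    layer_add = leaf_layer_partition(na_leaves, params.part_cap, n_layers)

    return pools.replace(
        culm_na=pools.culm_na + culm_seq,
        panicle_na=pools.panicle_na + panicle,
        leaf_na_by_layer=tuple(a + b for a, b in zip(pools.leaf_na_by_layer, layer_add)),
    )
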