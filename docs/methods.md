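# Methods

`ricesalt` simulates the toxic and osmotic effects of field-water salinity
on a rice crop, with the genotype described by ten parameters that map
one-to-one onto five tolerance traits under active selection in rice
breeding:

* **T1 — reduction of shoot Na⁺ uptake** (`rrbf_min`, `sub_dep_eff`,
  `sc_max`): the apoplastic "bypass flow" that short-circuits the root
  membranes is progressively blocked by suberin deposited in the root
  exo-/endodermis.
* **T2 — sequestration into structural tissue** (`pot_c_seq`,
  `na_culm_max`): the culm base stores Na⁺ before it reaches the leaves,
  with a feedback that shuts the sink as it fills.
* **T3 — tolerance to salt-induced sterility** (`susc_st`, `na_to_pan`):
  panicle Na⁺ around booting and flowering reduces spikelet fertility.
* **T4 — compartmentation into senescent leaves** (`part_cap`): Na⁺
  reaching the canopy is preferentially deposited in the oldest layers,
  protecting young photosynthetic tissue; senescence then retires the
  loaded tissue.
* **T5 — leaf tissue tolerance** (`thresh_l`, `crit_l`): the leaf Na⁺
  concentration at which photosynthesis stress starts, and the one at
  which photosynthesis is null.

## Sodium uptake

Daily shoot uptake follows the transpiration stream. The percentage of
water taking the apoplastic path is an empirical linear function of air
relative humidity, `RJv_B = −0.0275·RH + 3.92` (%), so the bypass water
flux is `Jv_B = Tr_act · RJv_B/100` (mm d⁻¹). Root suberin content `SC`
(mg g⁻¹) is an instantaneous function of plant age (DVS, the 0–2
development-stage clock) and of a salinity-deposition signal
`F_sc = ([Na⁺]_ext / Max[Na⁺]_ext) / (1 − SubDepEff)`, clamped to [0, 1]:

    SC = SCmax · DVS · (0.5·(1 − F_sc) + 1) / ((1 − F_sc) + DVS)

The relative bypass flow declines geometrically with suberin beyond a
threshold content `SC_min`:

    RRBF = (RRBF_min/100) ** ((SC − SC_min)/(SCmax − SC_min)),

equal to 1 for `SC ≤ SC_min` and to `RRBF_min/100` at maximum suberin.
An alternative placement of the 1/100 factor, `0.01 · RRBF_min**frac`,
is preserved behind `literal_rrbf` for auditing; it is not used by
default because it would make bypass flow *increase* with suberin.

Mass delivery makes the unit constants explicit: 1 mm of water over one
hectare is 10⁴ L, and 1 mM Na⁺ is 22.99 mg L⁻¹, so apoplastic delivery
is `Jv_B · 10⁴ · RRBF · [Na⁺]_ext · 22.99` (mg ha⁻¹ d⁻¹). The bypass
route carries only part of total uptake; its share is modelled as linear
in RH, anchored so the experimental humidity band 58–92 % maps onto the
35–22 % bypass share reported for rice (both anchors configurable).
Total uptake = apoplastic / share.

### Constants chosen here

Three constants of this chain have no published value and are set by the
package (all configurable):

* `Max[Na⁺]_ext = 400 mM` — the deposition signal saturates only near
  sea-water molarity. Much smaller values make `F_sc` saturate within
  the agronomic range, which (a) collapses the suberin curve to `SCmax`
  at any age and (b) can make shoot uptake *decrease* as external
  salinity rises, an over-compensation that breaks the monotone
  dose-response observed across constant-salinity treatments.
* `SC_min = 9 mg g⁻¹` — the unstressed early-tillering suberin content
  (30 % of the mean `SCmax`). Young roots therefore pass bypass flow
  unimpeded, which is the stated mechanism by which an early salinity
  peak bypasses the T1 defence; with `SC_min = 0` even seedling roots
  are partially sealed.
* bypass-share anchors 35 % at RH 58 and 22 % at RH 92, clamped outside
  the band.

## Internal allocation

The culm intercepts Na⁺ first, at rate
`PotCSeq · D · {1 − 0.08·((RelSinkSize + 0.1)^−1.13 − 0.08)}` (mg ha⁻¹,
`D` = plant density), floored at zero (the brace goes negative for a
nearly full sink) and additionally capped so culm concentration never
exceeds `na_culm_max`. During the reproductive window (DVS 0.6–2) a
fraction `ParP · Na⁺ToPan` of the surplus moves to the panicle with the
photosynthate stream. The residual reaches the leaves and is split over
the `N` canopy layers with weights `(1 − PartCap)^((i−1)/(N−1))`
(layer 1 = bottom/oldest), normalised to conserve mass exactly. Na⁺ in
tissue that senesces is retired to a dead-tissue ledger and excluded
from the active-leaf concentrations, consistent with the protective
purpose of trait T4.

## Stress feedbacks

* **Photosynthesis** (also accelerating senescence): per-layer factor
  `RPn = (a^(1/k) · b)^C` on `ThreshL < [Na⁺] < CritL`, with
  `a = [Na⁺]/ThreshL`, `b = (CritL − [Na⁺])/(CritL − ThreshL)`,
  `k = (CritL − ThreshL)/ThreshL` (general form uses `[Na⁺]_leafmin` as
  origin; default 0, shape `C` default 1). The inner product is strictly
  below 1 on the open interval, so the factor is 1 up to the threshold,
  0 at the critical concentration, and strictly decreasing in between
  for any `C > 0`. The verbatim alternative `(a·b)^(k^C)` — which
  exceeds 1 over most of the interval and behaves like a step near
  `CritL` — is available via `literal_rpn`.
* **Maintenance respiration**: linear ramp from 0 at 0.5 mg g⁻¹ to 1 at
  3 mg g⁻¹ mean leaf Na⁺; the host multiplies leaf and culm maintenance
  by `1 + MRespF`, so respiration doubles at 3 mg g⁻¹.
* **Spikelet sterility**: `SuscSt · [Na⁺]_panicle · bellF` inside DVS
  0.6–1.1, clamped to [0, 1]. `bellF` is the maximum of two Gaussian
  bells centred on booting (DVS 0.8) and flowering (DVS 1.0) with
  σ = 0.05 DVS units — the published form of this phenological window is
  not available, so it is parameterised and configurable.
* **Osmotic effects** of external salinity: SLA multiplier
  `−0.0002x² + 0.008x + 1` and culm-growth multiplier
  `0.0002x² − 0.024x + 1` (x in mM), both clamped to [0, 1]. The SLA
  quadratic literally exceeds 1 for 0 < x < 40 mM; it is declared a 0–1
  reduction factor, and leaving it unclamped makes mild salinity
  *increase* yield through extra leaf area, so the default clamps at 1
  (`clamp_sla_stress=False` restores the literal value).

## Host crop engine

The host is a deliberately minimal daily engine providing exactly the
coupling surface the salt module needs; it is not a reimplementation of
any full crop model. Phenology is thermal time (base 8 °C; 1200 °C·d to
anthesis, 500 °C·d to maturity). Growth is radiation-use efficiency
(2.2 g MJ⁻¹ intercepted PAR) on Beer-law interception (k = 0.5), with
the per-layer photosynthesis factors weighted by each layer's share of
intercepted light. Assimilate is partitioned to leaf/culm/panicle by a
DVS-indexed table; new leaf area uses a DVS-declining potential SLA
(24→16→14 m² kg⁻¹) times the osmotic SLA factor. Maintenance
respiration coefficients are 0.016 (leaf), 0.004 (culm) and 0.003
(panicle) g g⁻¹ d⁻¹ — the culm value reflects mostly structural,
low-respiring tissue; with a higher value the engine develops a perverse
economy in which salt-suppressed culm growth *raises* yield via saved
respiration. After anthesis, 2 % d⁻¹ of culm biomass is remobilised to
the panicle (stem reserves), carrying its Na⁺ at unchanged
concentration; this is what couples culm growth positively to yield, as
in real rice where stem reserves contribute a substantial share of grain
filling. Actual transpiration is `1.1 · ET0 · interception`.

The canopy is an age-ordered column of `N = 5` equal-biomass quantile
layers. New leaf biomass enters at the top with zero Na⁺; senesced
biomass (background turnover 0.002 d⁻¹, ramping to +0.03 d⁻¹ at
maturity, amplified per layer by `1 + k_sen·(1 − RPn_i)`, `k_sen` = 1)
leaves from the bottom carrying its Na⁺ into the dead-tissue ledger.
Both moves re-bin the Na⁺ profile along the cumulative-biomass
coordinate, so the layers remain equal-biomass quantiles and "oldest"
tissue always sits at the bottom. The initial state is an established
(transplanted) stand: 200 kg ha⁻¹ leaves, LAI 0.5, 2·10⁶ plants ha⁻¹.

Daily carbon accounting closes exactly: gross assimilation minus
respiration equals the organ increments plus the carbon withheld by the
sterility and culm-osmotic factors (tracked as an explicit stress loss).
Tillering, individual leaf size, soil water/salt balance and nitrogen
are not simulated.

## Forcing

Two idealised field salinity archetypes are built in, parameterised in
EC (dS m⁻¹) and converted at 10 mM per dS m⁻¹ (dilute-NaCl
approximation, configurable): an *early peak* (linear rise to the peak
at 15 % of the season, hold, sharp exponential decay after fresh-water
inflow at 33 %) and a *gradual ramp* (linear rise to a plateau at
mid-season). Reference peak values are 3.5 and 2.5 dS m⁻¹. The shapes
are idealised piecewise curves, not digitised from any figure.

The weather generator produces seeded half-sine seasonal curves for
temperature and radiation with bounded noise, RH uniform in a
configurable band (default 58–92 %), and a Hargreaves-flavoured ET0. A
*hydroponic* mode reproduces the growth-chamber design used for model
evaluation: photoperiod-weighted 26/18 °C days, RH cycling inside
58–92 %, constant lamp radiation, and constant NaCl treatments (0, 10,
25, 35, 50 mM) applied from day 21, as in the protocol where treatments
start three weeks after sowing.

What the generators do *not* emulate: real weather autocorrelation and
extremes, soil evapo-concentration dynamics behind the salinity curves,
and cultivar-specific host parameterisations. Passing tests therefore
demonstrate internal consistency and qualitative behaviour, not
predictive skill on real fields.

## Sensitivity analysis and ideotyping

Trait parameters get independent normal marginals with sd = 5 % of the
mean, truncated at ±4 sd and at physical bounds (almost never active at
this sd). The sample size is the smallest `M = 2^(q+3)·(2n+2)` strictly
exceeding `γ·n` (γ = 500 runs per parameter); for n = 10 this gives
M = 5632, i.e. a base block of 256. The Saltelli design (A, B, ABᵢ, BAᵢ
blocks from a scrambled Sobol' sequence in 2n dimensions) feeds Jansen's
estimators for first- and total-order indices; using both cross blocks,
each index is the average of two half-sample estimates. Confidence
bounds come from bootstrap resampling of base rows. Estimator accuracy
is verified against closed-form indices of an additive linear model and
the Ishigami function (error < 0.01 at a base block of 1024). The
ideotype is the sampled parameter vector with the highest yield, ties
broken by the lowest row index.

The packaged trait-ranking property runs the full pipeline at a reduced
base block of 64 (1408 model runs per scenario per seed) over five
seeds — problem sizes chosen to keep the complete check within a few
minutes on one core while leaving the qualitative contrast stable:
tissue-tolerance parameters lead the total-order ranking under the
early-peak scenario, and uptake-reduction (suberin) parameters under
the gradual ramp.

## Evaluation metrics

For observed/simulated pairs: RRMSE (% of the observed mean),
Nash–Sutcliffe modelling efficiency, coefficient of residual mass
(CRM = (Σobs − Σsim)/Σobs, negative = overestimation; sign conventions
differ across the literature and this one is fixed so overestimation is
negative), and squared Pearson correlation. All are undefined (raise)
on degenerate series; the CLI reports such metrics as null.

## Known limitations

* K⁺ dynamics and the Na⁺:K⁺ ratio are not represented; toxicity is a
  function of Na⁺ concentration alone.
* Osmotic adjustment and stomatal responses are implicit in the two
  fixed quadratic factors.
* Transmembrane (HKT-mediated) uptake is not modelled separately;
  genotypic differences act through the bypass pathway only.
* The host engine is intentionally coarse: no tillering, no soil water
  or salt balance, no nitrogen; absolute yields are indicative only.
* Suberin content is an instantaneous function of age and salinity;
  real deposition has a time lag.
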