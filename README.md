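# ricesalt

Trait-based simulation of salt stress in rice (*Oryza sativa*), built for
ideotype design: every genotype parameter of the salt module corresponds
directly to a tolerance trait that rice breeders select for, so
variance-based sensitivity analysis of simulated yield ranks *breedable
traits*, not abstract model constants.

The package couples a sodium module — apoplastic (bypass-flow) Na⁺
uptake limited by root suberin deposition, culm sequestration with sink
feedback, preferential compartmentation into old leaves, and stress
feedbacks on photosynthesis, respiration, senescence, spikelet fertility
and osmotically limited expansion — to a minimal multilayer daily crop
engine (thermal-time phenology, radiation-use-efficiency growth,
Beer-law interception, DVS-tabulated partitioning). On top sit a Sobol'
sensitivity/ideotyping workflow and the model-evaluation statistics
customary in crop modelling (RRMSE, EF, CRM, R²).

## The model in brief

Daily shoot Na⁺ uptake follows the transpiration stream:

    Jv_B = Tr_act · RJv_B/100,      RJv_B = −0.0275·RH + 3.92   (% of water)
    RRBF = (RRBF_min/100)^((SC − SC_min)/(SC_max − SC_min))
    uptake_AP = Jv_B · 10⁴ · RRBF · [Na⁺]_ext · 22.99           (mg ha⁻¹)

with suberin content SC growing with plant age (DVS) and salinity
exposure, and the total uptake scaled from the bypass share (22–35 %
over the experimental humidity range). Uptaken Na⁺ is allocated to culm
storage (feedback-limited), panicle, and leaf layers by age; tissue
concentrations drive five stress multipliers returned to the host crop
engine. Ten parameters represent the five tolerance traits (T1 uptake
reduction, T2 culm sequestration, T3 sterility tolerance, T4
compartmentation into senescent leaves, T5 leaf tissue tolerance). See
`docs/methods.md` for the full equations, constants and design choices.

## Worked example

Simulate a season under the early-salinity-peak scenario (salinity rises
to 3.5 dS m⁻¹ ≈ 35 mM in the first third of the season, then collapses
when fresh water returns):

```yaml
# example.yaml
mode: field
seed: 42
season_length: 150
scenario:
  pattern: early_peak
  peak_ec: 3.5
```

```bash
ricesalt simulate example.yaml -o demo_out
```

prints

```json
{
  "final_yield_kg_ha": 5144.372938086394,
  "final_agb_kg_ha": 9063.289329003655,
  "cumulative_fertility": 0.9930170007634916,
  "plant_na_mg_ha": 45722555.43809946,
  "days_run": 95
}
```

The crop reaches maturity after 95 days of thermal time, yields
5144 kg ha⁻¹ of panicle biomass (an unstressed run with the same weather
yields ≈ 8.1 t ha⁻¹, so the early peak costs roughly a third of the
yield), loses under 1 % of spikelet fertility (the salinity peak has
passed before the sensitive booting/flowering window), and accumulates
≈ 46 kg ha⁻¹ of Na⁺ in plant tissue. `demo_out/daily.tsv` holds the
day-by-day state (biomass per organ, LAI, Na⁺ pools, all five stress
factors), and `demo_out/provenance.yaml` the fully resolved
configuration plus its hash, from which the run can be reproduced
exactly.

The same library calls are available in Python:

```python
import ricesalt as rs

control = rs.hydroponic_season(0.0)    # growth-chamber mode, 0 mM NaCl
salted  = rs.hydroponic_season(50.0)   # 50 mM from day 21
print(control.final_yield, salted.final_yield)   # 4327.7  690.0
```

Other subcommands: `ricesalt sensitivity` (Sobol' indices + ideotype for
a configured scenario), `ricesalt make-scenario` (write the weather and
salinity series as TSV), `ricesalt evaluate` (RRMSE/EF/CRM/R² for an
observed-vs-simulated table).

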