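# minnow

Desk-scale bioenergetic simulation of a spatially explicit, size-structured
fish community, built to study how the **realised** thermal performance curve
(TPC) of net energy diverges from the **fundamental** one, and to decompose
that divergence into food-limitation and oxygen-limitation shares across life
stages and trophic levels.

## The scientific problem

The aerobic-scope view of fish energetics predicts a dome-shaped response of
net energy to temperature: mobilised energy (≈ maximum metabolic rate) rises
with temperature more slowly than maintenance (≈ resting metabolic rate), so
the net energy rate

```
E_P(T) = E_M(T) − E_m(T)
```

is positive only between two temperatures `T_min < T_max` and peaks at
`T_opt`. Measured under maximum ingestion and full oxygen saturation, this is
the *fundamental* TPC — intrinsic physiology only. In the sea, however, food
and dissolved oxygen covary with temperature in space and season, so the
performance a fish actually realises traces a different, lower curve. `minnow`
quantifies the gap as the mean relative deviation over all occupied
(cell × time-step) samples `j` of a species and life stage,

```
D_total = (1/n) Σ_j (E_fund(T_j) − E_real,j) / E_fund(T_j)
```

and splits it exactly — the energy fluxes are additive — into an oxygen share
`D_oxygen` (recompute each sample at maximum ingestion but the cell's actual
oxygen) and a food share `D_food = D_total − D_oxygen`.

The community model is individual-based: super-individual *schools* carry
(age, somatic mass `w`, gonadic mass, abundance, location). Ingestion follows
a Holling type-1 response with a satiety plateau `η · I_max · w^β`; a fixed
fraction is assimilated; mobilisation is limited by a Hill oxygen
dose–response and an Arrhenius temperature response with a supra-peak
decline; maintenance is Arrhenius in temperature and allometric in mass.
Positive net energy grows soma (immature fish) or is split soma/gonads
(mature fish, biphasic growth); maturation follows an age–length reaction
norm; predation is opportunistic and size-based among co-occurring schools
and low-trophic-level (plankton/benthos) pools supplied by a synthetic
seasonal climatology. Each species' temperature responses are calibrated so
its fundamental TPC hits prescribed `(T_min, T_opt, T_max)` exactly.

## Worked example

The packaged demo community has three species with contrasting thermal
preferences and trophic ecology — a cool-water planktivore ("sprat"), a
mid-trophic demersal ("whiting") and a warm-preferring piscivore ("saithe") —
on a 10 × 10 grid of 30 km cells, forced by a seasonal climatology in which
plankton covaries with the temperature anomaly and a hypoxic patch develops
over the southern rows in late summer. Twenty simulated years, the last ten
analysed:

```
minnow run-all --seed 1 --out demo_out
minnow tpc --seed 1 --out demo_out
```

prints the per-species × stage deviation table (fractions, not percent):

```
species    stage  d_total  d_oxygen  d_food     n  excluded_n  realised_topt  fundamental_topt
  sprat    early    0.251     0.006   0.244  2637           0          10.75              11.0
  sprat juvenile    0.044     0.016   0.028  3527           0          11.25              11.0
  sprat    adult    0.016     0.016  -0.000  5772           4          10.75              11.0
whiting    early    0.321     0.032   0.289  2701           0          11.75              13.0
whiting juvenile    0.253     0.091   0.162  5981           0          13.25              13.0
whiting    adult    0.178     0.118   0.060  9288          92          12.75              13.0
 saithe    early    0.187     0.047   0.140  2662           0          12.25              14.5
 saithe juvenile    0.161     0.103   0.057  8078           0          14.25              14.5
 saithe    adult    0.120     0.120   0.000 11510           1          14.75              14.5
```

Read it per species, down the stages: the total deviation `d_total` shrinks
from early life to adults, its food share `d_food` collapses with age (early
stages depend on volatile plankton and need denser prey to satiate; adults
eat stable benthos and fish), while the oxygen share `d_oxygen` *grows* with
age — older stages have lower mass-specific ingestion, so the same relative
cut in mobilised energy bites a larger fraction of their net energy. The
realised optimum temperature differs from the fundamental one by up to
~1 °C in either direction. `minnow analyse` then estimates flow-weighted
trophic levels from the simulated diets (spanning ≈ 2.4 for sprat larvae to
≈ 3.5 for adult saithe) and fits the ANCOVA of the food share on trophic
level × stage; all three stage slopes are negative (food limitation fades
towards the top of the web):

```
   stage  intercept_pct  slope_pct_per_tl  slope_se
   early           44.0              -7.3      11.4
juvenile          130.0             -36.3      38.4
   adult          132.2             -38.0      79.0
```

The same pipeline is available as a library:

```python
from minnow import load_config, demo_config_path, run_all
run_all(load_config(demo_config_path()), "demo_out")
```

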