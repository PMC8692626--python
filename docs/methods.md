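# Methods

## Model

The assessment is a carbon budget for a diapausing copepod. Measured per
individual are prosome length *L* (mm), lipid sac area *A* (mm²) and total
body carbon *M* (μg C, elemental analysis). Derived quantities:

* wax esters: WE = 0.167·*A*^1.42 (μg) — an empirical area→mass allometry
  for the *Calanus* lipid sac;
* lipid carbon: *w* = 0.79·WE (μg C) — the carbon fraction of wax esters;
* structural carbon: *m* = *M* − *w*. Only *m* is metabolically active
  during diapause.

Respiration of a diapausing individual is

    r = b · m^(3/4) · exp[E (T − T₀)/(k T T₀)] · 86 400   (μg C day⁻¹)

a 3/4-power mass allometry with Boltzmann–Arrhenius temperature dependence.
Diapause duration is the time to respire the reserve down to a retained
fraction ρ kept for the spring moult and reproduction,

    D = (w − ρ·w)/r ,

and an individual is classified overwinter-capable when D ≥ 150 days
(closed boundary). The closed-form inversion w_req = D_thr·r/(1 − ρ) gives
the reserve needed for exactly the threshold duration; the fullness index
w/w_max, with w_max = c·L^e an allometric ceiling, expresses how close an
individual is to the best reserve its body size permits.

### Parameters (units, default, rationale)

| parameter | default | notes |
|---|---|---|
| b, μg C^(1/4) s⁻¹ | 2.5×10⁻⁷ | universal metabolic scaling constant of the respiration model |
| E, eV | 0.65 | standard metabolic-theory activation energy; configurable because published applications differ |
| k, eV K⁻¹ | 8.617333×10⁻⁵ | Boltzmann constant |
| T₀, K | 273.15 | Arrhenius reference; the factor is exactly 1 at 0 °C. Interpreting T₀ as absolute zero would make the exponent singular, so the deviation-from-reference form is used; T₀ is configurable |
| ρ (retained fraction) | 0.2 | 20% of the pre-diapause reserve remains at emergence |
| D threshold, days | 150 | conservative successful-overwinter duration |
| deep cutoff, m | 250 | boundary of the candidate overwintering stock |
| w_max allometry (c, e) | none | must be supplied; published coefficients vary by population, so no uncited default is baked in. The synthetic allometry c = 20 μg C mm⁻³, e = 3 is used in examples/tests and is labelled as such |

Per-individual temperature is, by default, the station CTD temperature at
the capture-stratum midpoint ("stratum_midpoint" mode); "deep_mean" (mean
temperature of the layer below the cutoff) and "fixed" (a configured
overwintering temperature) modes are selectable, since field applications
are ambiguous about which temperature enters the respiration model.

## Numerical and design choices

* **Units are fixed at the boundary** (mm, mm², μg C, °C, m); no unit
  inference anywhere.
* **Infeasible records** (estimated *w* ≥ measured *M*) are excluded and
  counted, never clamped: clamping would fabricate m ≈ 0 and explode
  respiration-based durations.
* **Fullness > 1** is retained with a flag rather than truncated, so
  averages of fullness are computed on untruncated values.
* **CTD profiles** are piecewise linear; layer means are exact trapezoidal
  integrals divided by layer thickness; outside the sampled range the
  profile extends as a constant (with a warning). Duplicate depths are
  averaged at ingestion.
* **Depth integration** assumes uniform concentration within a stratum;
  strata straddling an integration bound contribute pro-rata thickness.
  Integration starts at the shallowest sampled depth — never extrapolated
  to 0 m. Reported abundances are rounded half-up to integer ind m⁻² and
  durations to integer days (the convention of field tables); underlying
  CSVs keep full precision.
* **Capability boundary** D == threshold classifies as capable.
* **Capable fraction** is pooled across all deep strata of a station; an
  individual counts as deep when its capture-stratum midpoint lies below
  the cutoff. (The stratified alternative — weighting per-stratum fractions
  by per-stratum abundance — is deliberately not asserted as "the" method;
  field descriptions are ambiguous here.)
* **Species length classes** for discriminating *C. finmarchicus* /
  *glacialis* / *hyperboreus* are configuration (closed lower bounds); no
  hard-coded defaults.

## Synthetic campaign

The generator emulates a late-summer, three-station ice-edge transect:

* **CTD**: a warm surface mixed layer (0–30 m) over a linear thermocline to
  200 m and constant cold deep water, with the surface temperature solved so
  the exact 0–125 m mean equals the station archetype (2.36/3.64/4.32 °C
  west→east; deep water −0.7/−0.5/−0.3 °C), plus N(0, 0.02 °C) sensor noise
  on a 5 m grid to 1000 m.
* **Individuals**: stage from a mix (70% CV); prosome length stage-specific
  normal (CV: 2.0 ± 0.15 mm, chosen jointly with the synthetic allometry so
  a full CV carries w_max ≈ 160 μg C); lipid fullness Beta(2.7, 3.3) — the
  minimal bounded family on [0, 1], tuned so roughly a tenth of the deep
  stock is capable; structural carbon 12·L^2.9 μg C with lognormal noise
  (σ = 0.08); capture depth from a station-specific mixture of depth bands
  (the easternmost station holds a second deep abundance peak). Total
  carbon is constructed as M = m + w, so no generated record violates the
  partition. Lipid sac area is back-computed from w, so the biometric chain
  inverts the generator exactly.
* **Catch**: per-stratum counts Poisson (optionally negative-binomial) with
  expectation = true concentration × filtered volume; volume = 1 m² net
  mouth × stratum thickness; 8 equal strata over 5–1000 m; station totals
  per stage follow the archetypes (e.g. ≈15 700 CV ind m⁻² at the
  easternmost station).
* **Seeding**: one integer seed; each artifact and station draws from its
  own child stream (`default_rng([seed, stream, station_index])`) so
  profiles, populations and catches regenerate independently.

Ground truth for the capable fraction is a dense Monte-Carlo integral
(2×10⁵ draws, dedicated stream) of the deterministic capability indicator
over the generating distributions at the generated temperatures; its Monte-
Carlo standard error (≈7×10⁻⁴) is negligible against the sampling error of
an n = 500 subsample. Because capability is deterministic given the latent
variables, a generated subsample's capable count is exactly Binomial(n, p),
which is what the central-95%-interval recovery test exploits (200 seeds of
n = 500 individuals; 200 Poisson replicates for abundance unbiasedness —
sizes chosen to make the Monte-Carlo tolerances sharp while the whole suite
stays fast on a single CPU).

### What the generator does not emulate

Advective supply and seasonal succession; measurement error in lipid-sac
segmentation or elemental analysis (generated areas invert the conversion
exactly); inter-individual correlation between fullness and depth (deep
individuals are not lipid-enriched by construction); multi-species mixtures.
Passing recovery tests therefore demonstrates the pipeline's internal
consistency and statistical calibration under the stated conditions, not
the field accuracy of the underlying empirical conversions.

## Known limitations

* The activation energy and reference temperature are assumptions of this
  implementation (prominently echoed in every run log); reported durations
  scale with exp-type sensitivity to both.
* The maximum-lipid allometry must come from the user; fullness values and
  the required-fullness statistic are only as good as those coefficients.
* Capable fractions from ~10-individual-per-stratum subsamples carry large
  binomial error; the station summaries report n_assessed so users can
  judge this.
* Durations assume constant temperature over the whole diapause and no
  active-metabolism costs at entry/exit.
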