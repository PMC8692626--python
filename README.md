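# calanus-diapause

Bioenergetic assessment of overwintering (diapause) capability in *Calanus*
copepods, scaled from individual body condition to depth-stratified
population abundances.

## The scientific problem

Late developmental stages of *Calanus finmarchicus* (principally copepodite
stage CV) survive the polar winter in diapause at depth, fuelled entirely by
a wax-ester lipid sac. Whether an individual can overwinter — and hence
whether a population at an ice-edge location can complete its life-cycle
locally rather than depend on advection — comes down to a carbon budget:
does the lipid reserve cover a winter's worth of suppressed metabolism with
enough left over to moult and reproduce in spring?

This package implements that assessment as a tested, reusable pipeline for
anyone working with multinet (MOCNESS-style) catches, CTD profiles and
individual biometrics:

1. **Biometry** — lipid sac area *A* (mm², from lateral images) is converted
   to wax-ester mass, WE = 0.167·*A*^1.42 (μg), then to lipid carbon
   *w* = 0.79·WE (μg C). Structural carbon is the remainder of measured
   total body carbon, *m* = *M* − *w*.
2. **Metabolism** — diapause respiration follows a 3/4-power allometry of
   structural mass with Boltzmann–Arrhenius temperature scaling,

       r = b · m^(3/4) · exp[E (T − T₀) / (k T T₀)] · 86 400   (μg C day⁻¹)

   with *b* = 2.5×10⁻⁷ μg C^(1/4) s⁻¹, *E* = 0.65 eV (configurable),
   *k* the Boltzmann constant and T₀ = 273.15 K. Diapause duration is the
   time to respire the reserve down to a retained fraction (default 20%):

       D = (w − 0.2 w) / r   (days)

   An individual is overwinter-capable when D ≥ 150 days.
3. **Hydrography** — per-individual temperatures come from station CTD
   profiles (piecewise-linear interpolation at the capture-stratum midpoint
   by default; fixed or deep-layer-mean temperature selectable).
4. **Population** — stratified net counts with filtered volumes become
   depth-integrated abundances (ind m⁻²); the capable fraction of assessed
   deep individuals (below 250 m by default) scales the deep stock to a
   capable abundance.
5. **Synthetic data** — a seeded generator emulates a full campaign
   (two-water-mass CTD profiles, stage-structured vertical distributions,
   Beta-distributed lipid fullness, Poisson net counts) with known ground
   truth, so every stage of the pipeline is testable without field data.

The maximum-lipid allometry (w_max = c·L^e, used for the fullness index
w/w_max) is deliberately *not* defaulted from literature: it must be
supplied explicitly. A clearly-labelled synthetic allometry
(c = 20 μg C mm⁻³, e = 3) is used throughout the examples and tests.

## Worked example

Generate a synthetic three-station campaign and assess it in one step:

```sh
calanus-diapause assess --synthetic --seed 7 --out-dir run
```

which prints (abridged):

```text
station  total_abundance_m2  deep_abundance_m2  capable_fraction  capable_abundance_m2  diapause_max_days  diapause_mean_days  n_assessed
     S1                2561                492          0.363636                   179                171                 122          11
     S2               11945               3103          0.000000                     0                142                  85          20
     S3               15614              12118          0.074627                   904                186                  89          67
```

Reading the S3 row: the station holds ≈15 600 CV ind m⁻² of which
≈12 100 ind m⁻² sit below 250 m; 5 of the 67 assessed deep individuals
(7.5%) carry enough lipid carbon to respire for ≥150 days at their in-situ
temperature, scaling to ≈900 ind m⁻² of overwinter-capable deep stock; the
best-provisioned individual could last 186 days. Per-individual energetics,
rejection diagnostics and a parameter-echo log are written to `run/`.

The same analysis is available as library calls:

```python
from calanus_diapause import ModelParams, respiration_rate, diapause_duration

r = respiration_rate(100.0, 0.0)        # 0.683 ug C/day at 0 degC, m = 100 ug C
d = diapause_duration(150.0, r)         # 175.7 days from w = 150 ug C
```

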