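# phenodecomp

Space-for-time decomposition of phenology–temperature relationships, with a
phylogenetic meta-analysis of the resulting species-level estimates.

## The problem

Butterfly flight dates advance in warm years (phenotypic plasticity), and
they also vary across a species' range with the local climate.  If the
spatial phenology–temperature slope matches the temporal one, geographic
variation can be explained by plasticity alone; if populations are locally
adapted to their climate, the two slopes diverge.  This package implements
the statistical machinery to separate the two from transect-count
monitoring data — or from synthetic data with known truth:

1. **Phenology** — the flight period at one site in one year is summarised
   by the count-weighted mean day of adult counts (day 1 = 1 April).
2. **Climate windows** — for each species, twelve candidate three-month
   temperature windows (centre months January–December) are regressed
   against the national annual mean flight date; the window with the
   largest |t| is the species' temperature cue.
3. **Slope decomposition** — sites are aggregated into populations on a
   50-km grid and the pair (window temperature, mean flight date) per
   site-year is modelled as a bivariate Gaussian mixed model with
   population, year and residual covariance components, fitted by a Gibbs
   sampler with inverse-Wishart priors (V = I, ν = 0.002), 13 000
   iterations, 3 000 burn-in, thinning 10.  For a fitted 2×2 component Σ,

       slope = Σ[temp, phen] / Σ[temp, temp]

   so the **year** component gives the within-population slope *b*<sub>time</sub>
   (plasticity), the **population** component gives the among-population
   slope *b*<sub>space</sub> (plasticity + local adaptation), and
   Δ*b* = *b*<sub>space</sub> − *b*<sub>time</sub> measures local adaptation.  The null
   Δ*b* = 0 is rejected when the 95% highest-posterior-density interval of
   Δ*b* excludes zero; with negative slopes, Δ*b* > 0 (shallower spatial
   slope) is the countergradient pattern, Δ*b* < 0 co-gradient.
4. **Phylogenetic meta-analysis** — species estimates *y*ᵢ (of
   *b*<sub>time</sub> or Δ*b*) are modelled as
   *y*ᵢ = μ + β*x*ᵢ + *a*ᵢ + *e*ᵢ + *m*ᵢ with phylogenetic effects
   *a* ~ N(0, σ²ₐA) on the Brownian correlation matrix A of a tree,
   residuals *e* ~ N(0, σ²ₑI), and measurement error *m* ~ N(0, diag(m²ᵢ))
   held fixed at the per-species posterior variances.  Phylogenetic
   heritability is H² = σ²ₐ / (σ²ₐ + σ²ₑ); posteriors can be pooled over a
   sample of trees to fold in phylogeny uncertainty.

Because the monitoring and gridded-climate data behind published analyses
of this kind are not redistributable, the package ships a first-class
synthetic-data module (`phenodecomp.simulate`) that emulates their
structure with known ground truth, and every stage is validated by
parameter recovery against it.

## Worked example

The numbered drivers under `analysis/` run the full chain on a simulated
60-site, 20-year, 5-species landscape:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_flight_phenology.py
python analysis/03_select_windows.py
python analysis/04_decompose_slopes.py
python analysis/05_phylo_meta.py
python analysis/06_space_time_figure.py
```

Step 04 prints the slope table (truth columns from the generator):

```
species_id  b_time_mode  b_time_true  b_space_mode  b_space_true  delta_b_mode  delta_b_true  reject_equal_slopes       direction
    sp_cog        -6.58         -7.0         -8.74          -9.0         -2.16          -2.0                 True     co-gradient
    sp_ct2        -5.11         -5.0         -1.13          -1.0          3.94           4.0                 True countergradient
    sp_ct3        -7.80         -8.0         -4.81          -5.0          2.99           3.0                 True countergradient
    sp_ctg        -6.87         -6.4         -4.22          -4.0          2.62           2.4                 True countergradient
    sp_nul        -5.96         -6.0         -5.85          -6.0          0.12           0.0                False

true delta_b inside its 95% HPD for 5/5 species
```

Reading it: `sp_ctg` advances 6.9 days per °C of interannual warming but
only 4.2 days per °C across the spatial gradient, so its populations are
more synchronised across the range than plasticity alone predicts —
countergradient local adaptation (Δ*b* ≈ +2.6, HPD excluding zero).  The
null species `sp_nul` shows matching slopes and the test correctly fails
to reject.  Step 03 recovers the generating cue window for 5/5 species,
and step 05 recovers H² = 0.75 on the 31-tip study tree.

The same pipeline is scriptable from a YAML config via the `phenodecomp`
CLI (`simulate`, `phenology`, `select-window`, `decompose`, `meta`, `run`,
`plot` subcommands).

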