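# traitenv

Trait–environment–performance analysis for nested on-farm crop trials.

`traitenv` asks how the *slope* of a trait's effect on plant performance
changes along an environmental gradient, and whether that change differs
between crop genotypes. It was built around participatory trials of
Nantes-type carrot varieties on organic farms — performance measured as
light-saturated photosynthesis (A_sat) and instantaneous water-use
efficiency (WUE = A_sat / transpiration), traits as leaf area (LA), leaf
mass per area (LMA), petiole diameter (PD) and taproot tissue density
(TTD), and the environment as soil N, C and Bray-1 P — but every stage is
generic over the trait, environment and genotype lists.

## The model

For standardized trait *T* and environment *E*, performance *Y* is modeled
by the quadratic interaction surface

    Y = β₀ + β₁T + β₂T² + β₃E + β₄E² + β₅TE + ε

so that the environment-dependent mean slope of the trait–performance
relationship is the line

    φ(E) = β₁ + β₅E.

β₂ and β₄ capture curvature ('n'- vs 'u'-shaped relationships), and β₅ is
the trait–environment interaction: the strength and direction of
environment-dependent selection on the trait. With several traits, several
soil variables, and a genotype factor (variety), the full fixed-effect
design contains all trait and soil linear and quadratic terms, all
trait × soil products, variety and its two-way interactions with every
linear term, all trait × soil × variety three-way interactions, and
farm-level climate covariates — 83 columns for 4 traits, 2 soils,
5 varieties and 2 covariates under treatment coding. The random part is
three nested intercepts (farm ⊃ plot ⊃ subplot), estimated by REML.

Inference uses type-II ANOVA respecting the principle of marginality with
Kenward–Roger (or Satterthwaite) denominator degrees of freedom; model
simplification is marginality-respecting backward elimination of fixed
effects at α = 0.05; correlated soil predictors (|r| > 0.6, canonically
soil N vs C) spawn alternative models compared by AIC; variance explained
is decomposed into marginal and conditional R². The REML engine,
Kenward–Roger adjustment and type-II machinery are implemented in this
package and cross-checked in the test suite against closed-form balanced
cases, brute-force likelihood grids, and the lme4/lmerTest/pbkrtest stack
through R.

## Worked example

```python
from traitenv import GeneratorConfig, RunConfig, generate, run_pipeline

table, truth = generate(GeneratorConfig(seed=5))   # 405-plant synthetic trial
manifest, results = run_pipeline(table, RunConfig(), outdir="out")
for resp, r in results["responses"].items():
    print(resp, r["chosen"], round(r["aic"], 1),
          round(r["r2_marginal"], 3), round(r["r2_conditional"], 3))
    print("  final terms:", [t.label for t in r["design"].graph.terms])
```

prints (seed 5):

```
Asat SC+SP 768.4 0.05 0.68
  final terms: ['(Intercept)', 'variety', 'PD', 'TTD', 'SP', 'SP x TTD', 'PD x variety']
WUE SN+SP 311.7 0.147 0.899
  final terms: ['(Intercept)', 'variety', 'LA', 'PD', 'SN', 'SP', 'LA x SP',
                'PD x SN', 'LA x variety', 'PD x variety', 'SN x variety',
                'SP x variety', 'LA x SP x variety', 'PD x SN x variety']
```

Reading this: for each response the pipeline fit one full model per
alternative soil set (soil N vs soil C, branched automatically by the
collinearity screen), simplified both by backward elimination, and kept the
lower-AIC branch: for A_sat the soil-C branch (AIC 768.4 vs 770.6 — its
selection path shed one more spurious term, and no soil-N/C term survives
in it anyway), for WUE the soil-N branch (AIC 311.7). The A_sat
model retained the TTD × soil-P interaction the data were generated with —
a negative β₅, i.e. dense taproots pay off at low P and hurt at high P —
and the WUE model retained the PD × soil-N × variety three-way, meaning the
petiole-diameter–WUE slope along soil N differs between varieties. The R²
pairs (0.05/0.68 and 0.147/0.899) say fixed effects explain a small share
of variance while farm/plot/subplot effects dominate, as expected in
multi-farm trials. `out/` contains the ANOVA tables, φ-slope tables,
selection traces, surface grids (TSV) and a machine-readable
`results.json` + `manifest.json`.

The same pipeline is scriptable from the shell:

```
traitenv simulate --out obs.tsv --seed 5
traitenv all --input obs.tsv --outdir out
```

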