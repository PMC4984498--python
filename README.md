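# sdmevol

Macro-evolutionary analysis of sex-determining mechanisms (SDM) on
phylogenies.  Reptile sex is determined either genotypically (GSD) or by
incubation temperature (TSD), and the two mechanisms are distributed very
unevenly across clades — most turtles have TSD, most lizards have GSD.
`sdmevol` implements the comparative machinery needed to dissect that
pattern on a dated phylogeny with binary tip states:

* **Trait-dependent diversification tests** — MacroCAIC-style
  species-richness contrasts with minimal-clade-size (MNS) filtering, and
  BiSSE (binary-state speciation–extinction) model comparisons — each
  calibrated with a **parametric bootstrap**: neutral characters are
  re-simulated on the fixed tree under fitted Markov rates and the observed
  statistic is ranked against its simulated null.
* **Transition-rate asymmetry tests** — the two-state Markov (Mk2) model by
  maximum likelihood (free vs equal rates, LRT), by slice-sampling MCMC with
  exponential priors (posterior probability that q_TG > q_GT), and by a
  BiSSE fit with shared speciation/extinction rates and a skeletal-tree
  sampling fraction.
* **Marginal ancestral-state reconstruction** under both Mk2 and BiSSE.
* **Regime-dependent lifespan evolution** — BM1/BM2/OU1/OUM Gaussian models
  on log lifespan over a GSD/TSD regime painting derived from the
  reconstruction, compared by LRT and AIC.
* A **synthetic-data module** that generates birth–death trees, exact
  two-state character histories, and regime-dependent lifespans, including
  "turtle-like" and "lizard-like" dataset profiles used throughout the
  tests.

The discrete character follows a continuous-time Markov chain with rates
q_GT (GSD→TSD) and q_TG; BiSSE adds state-dependent speciation λ_i and
extinction μ_i through the standard extinction/data ODE system integrated
along every branch.  The OU lifespan models share α and σ² across regimes
and let each SDM state track its own optimum θ.  See `docs/methods.md` for
the full model descriptions, defaults, and numerical choices.

## Worked example

Generate a turtle-like dataset (87 tips, TSD-majority, near-equal
transition rates, TSD lineages evolving toward longer lifespans) and run
the core analyses:

```python
import numpy as np
from sdmevol import synthetic_data as syn, mk2, trait_models as tm

fx = syn.make_fixture("turtle-like", 87, seed=7)
print("TSD share:", round(float(np.mean(fx.states.state == 1)), 3))

m_free, ll_free = mk2.fit_mk2(fx.tree, fx.states)
m_eq, ll_eq = mk2.fit_mk2(fx.tree, fx.states, constrain_equal=True)
comp = mk2.lrt(ll_eq, max(ll_free, ll_eq), df=1)
print(f"q_GT={m_free.q01:.4f} q_TG={m_free.q10:.4f} LRT p={comp.p_value:.3f}")

rec = mk2.marginal_asr_mk2(fx.tree, fx.states, m_free)
print("root p(TSD) =", round(float(rec.root_probs[1]), 3))

painting = tm.paint_regimes(rec, fx.states, fx.tree)
fits = {m: tm.fit_trait_model(fx.tree, fx.lifespans, painting, m)
        for m in tm.MODELS}
row = tm.compare_trait_models(fits).to_row()
print(f"best model: {row['best_AIC']}  OU p={row['OU_p_value']:.4f}")
print(f"optimum_GSD={row['optimum_GSD_years']:.1f} yr  "
      f"optimum_TSD={row['optimum_TSD_years']:.1f} yr")
```

Output:

```
TSD share: 0.77
q_GT=0.0000 q_TG=0.0069 LRT p=0.290
root p(TSD) = 1.0
best model: OUM  OU p=0.0029
optimum_GSD=22.1 yr  optimum_TSD=31.3 yr
```

Read: 77% of tips are TSD; the rate asymmetry is not significant on a tree
this small (the turtle situation — TSD prevails by retention of the
ancestral state, reconstructed as TSD with probability 1.0); and lifespan
fits best under the two-optimum OU model, with TSD lineages pulled toward
a substantially higher optimum (31 vs 22 years; the generating optima were
35.9 and 22.6).

The same analyses are scriptable from the shell:

```bash
sdmevol simulate-fixture --profile lizard-like --n-tips 300 --seed 1 --outdir data/
sdmevol fit-mk2 --tree data/tree.nwk --states data/states.tsv
sdmevol bootstrap --tree data/tree.nwk --states data/states.tsv \
    --statistic macrocaic-F --richness data/richness.tsv --reps 1000 --seed 7
sdmevol run-all --config config.yaml   # full pipeline, TSV + JSON report bundle
```

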