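# treelfa

Bayesian inference of multimorbidity patterns — *disease topics* — from
binary diagnosis matrices, for epidemiologists and statistical
geneticists working with biobank-style data. This package implements
treeLFA (latent factor allocation with a tree-structured prior): a
topic model for individuals × disease-codes 0/1 matrices in which
topics are sparsified by a spike-and-slab prior whose binary activity
indicators follow a Markov process on the disease-code hierarchy
(e.g. ICD-10 chapters), so related codes tend to be active in the same
topic.

## Model

Per individual *d* with topic weights θ_d ~ Dirichlet(α), each code *s*
gets a topic z_{ds} ~ Cat(θ_d) and a diagnosis
x_{ds} ~ Bernoulli(Φ[z_{ds}, s]). Each topic–code probability has a
spike-and-slab prior selected by an indicator I[k, s]:

    Φ[k,s] ~ Beta(a₁, b₁) if I[k,s] = 1 (active), Beta(a₀, b₀) otherwise

with the indicators generated root-to-leaf on the code hierarchy:
P(child active | parent inactive) = ρ01 ~ Beta(3, 20),
P(child active | parent active) = ρ11 ~ Beta(3, 3).

Inference is by collapsed Gibbs sampling (θ integrated out) with α
optimized by two-stage Gibbs-EM (digamma fixed point, entries floored
at 0.01). Because topic order is not identifiable across posterior
samples, post-processing pools all sampled topic vectors, clusters them
(Louvain on a shared-nearest-neighbor graph, then hierarchical merging
under cosine distance) and routes topic weights, α and ESS diagnostics
through the clusters. Topic quality is scored by NPMI coherence and
topic diversity. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from treelfa import (SimConfig, simulate_example, gibbs_em_train,
                     gibbs_train, match_topics)

# 5,000 individuals x 15 codes from 4 topics (active prob 0.3, alpha 0.1)
data, tree, topics_true, alpha_true = simulate_example(SimConfig(seed=20))

em = gibbs_em_train(data, tree, K=4, alpha0=np.full(4, 0.1),
                    cycle_1=200, cycle_2=50, burn_in=19,
                    opt_N_1=1, opt_N_2=10, seed=21)
print(np.round(em.alpha, 4))
# [0.095  0.0943 0.0963 0.0937]        <- generating value: 0.1

g = gibbs_train(data, tree, em.state, em.alpha,
                burn_in=2500, cycle=5000, interval=50, seed=22)
phi = np.mean(g.Phi_samples, axis=0)   # posterior-mean topics, 50 samples
cols, sims = match_topics(topics_true, phi)
print(np.round(sims, 3))
# [0.998 1.    0.999 0.999]            <- cosine match to generating topics
print(round(phi[cols][topics_true > 0].mean(), 3))
# 0.296                                <- generating active probability: 0.3
```

The optimized α returns the generating Dirichlet concentration, the
four inferred topics match the generating topics almost exactly, and
the posterior-mean probability of the truly active codes lands on the
simulated 0.3.

The scripts in `examples/` walk through each capability — simulation,
input validation, training/sampling, label-switching resolution via
clustering, and topic metrics — each printing a few annotated numbers.
A thin CLI mirrors the same steps
(`treelfa simulate|validate|train-em|sample|postprocess|metrics|run`);
`treelfa run --config cfg.yaml --out dir` drives the whole pipeline
from one YAML file.

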