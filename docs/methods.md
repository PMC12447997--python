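# Methods

## The model

treeLFA ("latent factor allocation with a tree-structured prior")
factorizes a binary diagnosis matrix — D individuals by S disease
codes, 1 marking a diagnosis — into K *disease topics*. It is a topic
model in the LDA family, with individuals playing the role of documents
and disease codes the role of words, but with a Bernoulli rather than a
multinomial emission: a topic is a vector Φ_k ∈ (0,1)^S of per-code
occurrence probabilities, not a distribution over codes.

The generative process, per individual d:

1. θ_d ~ Dirichlet(α) — the individual's topic weights;
2. for each code s: z_{ds} ~ Categorical(θ_d), then
   x_{ds} ~ Bernoulli(Φ[z_{ds}, s]).

Topics are sparsified by a spike-and-slab prior. A binary indicator
I[k, v] per topic k and tree node v selects the Beta prior for the
code's probability: the *spike* (inactive, e.g. Beta(0.1, 500), mean
≈ 0.0002) or the *slab* (active, e.g. Beta(2, 4), mean 1/3). The
indicators follow a Markov process on the disease-code hierarchy,
running from the root down: P(child active | parent inactive) = ρ01,
P(child active | parent active) = ρ11, with priors ρ01 ~ Beta(3, 20)
and ρ11 ~ Beta(3, 3). Small ρ01 makes topics sparse; larger ρ11 makes
activity heritable along the tree, encoding the assumption that codes
near each other in the hierarchy tend to be active in the same topic.
Internal nodes carry indicators but no Φ entries — only terminal codes
emit data. When no hierarchy is available, a flat tree (every code a
child of the root) removes the similarity structure while keeping the
sparsity mechanism ("flatLFA").

The root indicator is fixed at 0 and never resampled. This keeps the
Markov process strictly top-down, matches the all-zero initialization,
and keeps the "empty topic" (no active codes) representable; empty
topics arise routinely when K is set above the true number of patterns,
and an individual's weight on the empty topic tracks overall disease
burden.

## Inference

### Collapsed Gibbs sampling

θ is integrated out analytically (Dirichlet-multinomial conjugacy), so
one systematic sweep updates, in order:

* **Z** — for each (d, s):
  P(z = k | rest) ∝ (n_{dk}^{-(d,s)} + α_k) · Φ[k,s]^x (1−Φ[k,s])^{1−x},
  where n_{dk} counts the individual's other codes assigned to k. The
  scan is sequential over codes but vectorized across individuals
  (rows are conditionally independent given Φ), which is what makes
  5,000-individual sweeps take ~10 ms.
* **Φ** — conjugate: Φ[k,s] ~ Beta(a_I + n₁, b_I + n₀) with n₁/n₀ the
  counts of 1/0 observations currently assigned to topic k at code s,
  and (a_I, b_I) the spike or slab shapes chosen by I.
* **I** — single-site Gibbs per (topic, non-root node), combining the
  parent transition, the children's transitions, and for terminal codes
  the Beta density of the current Φ under slab vs spike (computed in
  log space: the spike density underflows linear arithmetic).
* **ρ** — conjugate Beta updates from the 2×2 table of parent→child
  indicator transitions pooled over all topics and edges.

Every sweep records `L_all`, the log10 joint density
P(X|Z,Φ)·P(Z|α)·P(Φ|I)·P(I|ρ)·P(ρ), with P(Z|α) the collapsed
Dirichlet-multinomial. A healthy trace rises sharply, then fluctuates
with no trend. After `burn_in` sweeps, one posterior sample of
(Φ, I, ρ, Z_sum) is kept every `interval` sweeps; Z itself is not
retained — the count matrix Z_sum (rows sum to S) is what downstream
steps need.

Sampled probabilities are clamped to [1e-12, 1−1e-12] before Bernoulli
likelihood evaluation. All sampling is single-threaded and
deterministic given the seed.

### Spike/slab prior selection

The Beta prior pair is selected once from the minimal code prevalence
in the data: [0.01, 1) → Beta(0.1, 500)/Beta(2, 4); [0.005, 0.01) →
Beta(0.1, 1000)/Beta(1.5, 3); (0, 0.005) → Beta(0.1, 4000)/Beta(1.2, 3).
Rarer diseases need a tighter spike so that inactive-code probabilities
stay well below the smallest real signal. Prevalences outside (0, 1)
(all-zero or all-one columns) are clamped inward; all-zero columns are
legal but warned about, since the prior then dominates.

### Gibbs-EM

α is optimized rather than sampled. Each EM cycle runs an E-step of
`burn_in` (default 19) warm-started sweeps followed by `opt_N`
consecutive sweeps whose Z_sum samples are kept, then an M-step: the
standard digamma fixed point for the Dirichlet-multinomial MLE,

    α_k ← α_k · E[Σ_d ψ(n_dk + α_k) − D ψ(α_k)] / (D (ψ(S + A) − ψ(A))),

the expectation averaged over the collected samples, iterated to
relative change < 1e-8 (cap 10,000 iterations — slowly-converging cases
with large α need several thousand), each entry floored at 0.01 to
avoid degeneration. A topic receiving no counts converges to exactly
the floor. Training has two stages: stage 1 with opt_N_1 = 1 (cheap,
many cycles), stage 2 with opt_N_2 = 10 (more samples per M-step for a
more stable α). The 19-sweep burn-in precedes only the first collected
sample of an E-step; the remaining opt_N − 1 samples are consecutive
sweeps — the cheapest reading consistent with a per-E-step burn-in, and
the one implemented here.

Checkpoints (every 50 cycles in stage 1, every 5 in stage 2) hold the
state arrays as `.npy` files plus a JSON manifest with α, the cycle
index, the RNG state and a config digest, so an interrupted run resumes
bit-exactly. The digest covers the data, tree, K, α₀, burn-in, opt_N
values and seed — but not the cycle counts, so a finished run can be
extended, mirroring multi-phase training on large data.

## Post-processing

Topic order is not identifiable across posterior samples (label
switching), so the N_ps × K pooled topic vectors are clustered rather
than averaged positionally:

1. **Louvain on an SNN graph.** Each pooled vector's neighborhood is
   its k nearest vectors under cosine distance (self included); points
   appearing in each other's neighborhoods are joined with Jaccard
   overlap of the neighbor sets as edge weight, and Louvain community
   detection (resolution 1, seeded) yields clusters whose means are
   `topics_ave`. k in (N_ps/2, N_ps) works well; smaller k fragments,
   larger k over-merges. The Jaccard weighting is the simplest standard
   SNN scheme; nothing downstream is sensitive to this choice on
   well-separated topics.
2. **Hierarchical merge.** Louvain typically leaves near-duplicate
   clusters (the model was given too many topics). The closest pair of
   cluster means under cosine distance — insensitive to small
   elementwise differences and to scale — is merged repeatedly
   (member-weighted centroids, lowest-index tie-break) until the
   requested count remains, giving `topics_ave_h`. The target count is
   chosen by inspecting `topics_ave`; for the worked example 5 is right
   (4 disease topics + 1 empty topic).
3. **Routing everything else.** Within each posterior sample, α entries
   and estimated topic-weight columns have one-to-one correspondence
   with topics, so they are routed to the topics' final clusters.
   Duplicated topics within one sample have their α entries and weight
   columns *summed* (a merged topic's usage accumulates) and their Φ
   vectors averaged; across samples everything is averaged, giving
   `alpha_ave` and `tw_ave`. A cluster absent from a sample receives no
   contribution from it. Topic weights are recovered from the counts as
   the collapsed posterior mean θ̂[d,k] = (Z_sum[d,k] + α_k)/(S + Σα).
4. **ESS.** Mixing is summarized by the effective sample size of every
   per-cluster Φ entry and θ̂ entry across samples, using the
   autocovariance estimator with Geyer's initial-monotone positive-pair
   truncation. Constant chains report ESS = chain length with a
   warning; clusters present in fewer than 4 samples report NaN.

## Topic-quality metrics

**Topic coherence** averages the normalized pointwise mutual
information f(ci, cj) = log(P_ij/(P_i P_j)) / (−log P_ij) over ordered
top-code pairs within each topic, with empirical frequencies from the
training data and normalization 1/(S′(S′−1)) over the Σ_{i<j} sum —
kept verbatim from the defining equation even though it halves the
plain pair average. Never-co-occurring pairs score −1; pairs involving
a zero-prevalence code are undefined and skipped with a warning.
**Topic diversity** is U/(N·K): the fraction of unique codes among all
topics' top-N lists. Ranking ties break by code order, so both metrics
are deterministic.

## The simulator

`simulate_example` reproduces the worked example's design: D = 5,000
individuals, S = 15 codes under 5 internal nodes of 3 children each,
K = 4 topics with disjoint active sets at probability p_active = 0.3,
symmetric Dirichlet α = 0.1. The default active sets are the blocks
D1–D4 / D5–D8 / D9–D12 / D13–D15 (the last coinciding with one tree
branch) — this package's own choice of sets with the canonical shape
(disjoint, 3–4 codes per topic). With these settings each
code's expected prevalence is 0.25 · 0.3 = 0.075, which lands in the
[0.01, 1) prior range.

What the simulator does *not* emulate: real diagnosis data has
prevalences spanning orders of magnitude, overlapping topics, age/sex
structure, and coding noise. Passing recovery tests on this generator
demonstrates the correctness of the inference machinery under the
model's own assumptions, not robustness to their violation.

## Numerical and design notes

* Topic indices are 0-based internally, 1-based only in printed output.
* `estimate_memory_kb` implements the storage formula
  M = 8·D·K·N_ps + 8·D·S·2 verbatim, keeping its conventional kilobyte
  label even though the quantity it counts is 8-byte entries.
* Degenerate inputs: K = 1 makes the Z update a no-op; ρ at an exact
  boundary (0 or 1) is handled in log space (0 · log 0 ≡ 0); empty
  sample sets and malformed files raise typed errors with the offending
  row/column or rule named.
* Problem sizes in the test suite: the end-to-end recovery tests run
  the full example design (5,000 × 15) with Gibbs-EM 200+50 cycles and
  2,500+2,500 Gibbs sweeps — enough for the L_all trace to stabilize
  and for α and Φ recovery, chosen as the package's standard small-data
  schedule; unit tests use a 600 × 6 two-topic dataset.

## Known limitations

* Single-threaded: biobank-scale data (10⁵–10⁶ individuals, hundreds
  of codes) is out of desk reach; the sweep cost is linear in D·S·K.
* One global spike/slab prior pair for all codes, selected from the
  minimal prevalence; per-code priors are not supported.
* The hierarchical-merge target count is user-chosen, not automated.
* Multi-chain diagnostics beyond ESS and the L_all trace (e.g. R-hat)
  are not provided; on multimodal posteriors different chains can land
  in different local optima, and comparing repeated runs remains the
  practical safeguard.
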