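# Methods

## Model

The interaction model is a two-tower neural factorization with a logistic
link. A compound tower maps a fingerprint `x_c ∈ R^{d_c}` through
`d_c → 128 → 64` (ReLU hidden layer, linear output, biases everywhere) and
a kinase tower maps a sequence descriptor `x_p ∈ R^{d_p}` through
`d_p → 128 → 64`; the active probability of a pair is
`σ(⟨e_c, e_p⟩)` on the embeddings' inner product. Training minimizes the
mean binary cross-entropy over observed active/inactive pairs plus
`λ · (sum of squared tower weights)`; biases are not penalized. The default
`λ = 1e-4` is deliberately light — the towers are small and the data
binary — and is configurable everywhere it appears.

Inductivity is structural: nothing in the model indexes compounds or
kinases; any entity with features can be scored, including entities absent
from training.

Numerical conventions: probabilities reported to callers are clipped to
`[1e-12, 1 − 1e-12]` (the forward pass itself is the stable two-branch
sigmoid/softplus and produces no NaN for |logit| up to ~1e3); the
classification threshold is 0.5 with score ≥ threshold counted positive;
ranking ties break lexicographically by kinase id.

## Meta-learning

Head kinases are tasks. Each outer iteration draws one fresh episode per
head task from its training pool — 5 active + 5 inactive support pairs,
10 + 10 query pairs, disjoint by construction — runs `inner_steps = 4`
full-batch gradient steps of the support loss at rate `α = 0.01`, and
takes one outer gradient step (rate `β = 0.01`, plain SGD by default, Adam
optional) on the sum of query losses at the adapted parameters.

The second-order meta-gradient backpropagates through the inner
trajectory: each inner step `θ_{t+1} = θ_t − α ∇L_S(θ_t)` contributes a
factor `(I − α H_S(θ_t))`, applied to the query gradient from the last
iterate backwards. The Hessian-vector products are computed by
complex-step differentiation of the analytic gradient
(`Hv = Im ∇L(θ + ih v)/h`, `h = 1e-100`): the perturbation lives entirely
in the imaginary part, so there is no subtractive cancellation and the
product is exact to machine precision. All kernels are complex-safe;
branch decisions (ReLU masks, sigmoid/softplus branches) use real parts
only, so the piecewise-linear activations differentiate correctly away
from their kinks. First-order mode (gradient stopped at the adapted
parameters) is available and coincides with second order when
`inner_steps = 0`. Identity laws hold exactly: `α = 0` or
`inner_steps = 0` make adaptation the identity; `β = 0` returns the
initialization bit-for-bit.

Tail kinases never enter meta-training. `few_shot_adapt` runs the same
inner loop from the meta-trained initialization on the tail kinase's
5+5 support set only; its test pairs are untouched by construction.

## Data protocol

Activity records (pKi/pKd/pIC50, −log10 molar) are binarized at 6.0
(boundary inclusive, i.e. ≤ 1 µM is active). Replicate records of the same
(compound, kinase) pair — including across measure types — are averaged
before thresholding; this is a package decision where mixed-source corpora
leave the merge rule open. Kinases lacking either class after binarization
are dropped and reported. Mutant kinases are handled as an id-level
exclusion list supplied by the caller, not by sequence analysis.

The long-tail split takes the `head_count` most populous kinases with
≥ 500 pairs of each class (descending total, lexicographic tie-break —
a deterministic rule standing in for "sufficient samples") and samples
exactly 500 + 500 training pairs from each; every other kinase with
≥ 5 + 5 pairs and at least one spare becomes a tail task with a 5 + 5
support set and all remaining pairs as test. Per-kinase draws use
independent named substreams of the global seed, so the split is invariant
to iteration order and reproducible component-wise.

## Synthetic benchmark generator

The generator emulates the long-tailed regime without real data. Compound
"fingerprints" are i.i.d. Bernoulli(0.3) bit vectors (`d_c = 64`); kinase
"descriptors" are non-negative rows normalized to sum one (`d_p = 32`),
mimicking a conjoint-triad distribution. Ground truth for kinase `k` is
the bilinear map `x_c^T A0 (B0 + τ E_k)^T x_p + b_k` with shared factor
maps `A0, B0` (rank 8), i.i.d. standard-normal perturbations `E_k`, and
heterogeneity scale `τ` (default 0.3): at `τ = 0` every kinase shares one
map; large `τ` destroys cross-task structure and with it anything worth
transferring.

Raw bilinear scores are standardized to zero mean and unit variance over
all sampled pairs and multiplied by `logit_scale` (default 8). The scale
matters: with unit-variance logits, labels drawn from `Bernoulli(σ(z))`
carry so much link noise that even the Bayes-optimal scorer tops out near
AUC 0.74, and no training procedure could demonstrate structure recovery.
At scale 8 the link is steep (Bayes AUC ≈ 0.985) and label stochasticity
is governed explicitly by the flip rate `ε` (default 0.05) rather than
implicitly by link softness. Intercepts `b_k` are solved per kinase by
bisection so the expected positive rate equals the target prevalence
(default 0.5) over that kinase's sampled compounds.

Head kinases label a pool of 1300 compounds and tail kinases 160, drawn
without replacement; pools are sized so the 500+500 / 5+5 split draws
succeed with overwhelming probability while per-kinase prevalence remains
binomial around the target. Tail test sets are then trimmed to exactly
50 + 50 per class. The `heterogeneity_probe` diagnostic evaluates every
kinase's map over the full compound panel at a fixed reference descriptor
(the mean kinase descriptor), so it isolates map heterogeneity from
descriptor diversity: it is exactly 1.0 at `τ = 0` and decays to 0 as
`τ` grows.

What the generator does **not** emulate: real chemistry (bits are
exchangeable, with none of the correlation structure of substructure
keys), sequence-driven kinase similarity (descriptors are unstructured
noise), assay heterogeneity beyond symmetric label flips, and
compound-series redundancy. Passing benchmarks here demonstrate that the
optimization and transfer machinery works when cross-task structure
exists; they say nothing about how much such structure real kinome panels
contain.

## Evaluation

`roc_auc` is the Mann–Whitney statistic (ties 1/2); `pr_auc` is the
step-wise precision–recall area (precision held constant over each recall
increment, no linear interpolation — for a constant scorer it equals the
positive prevalence); both are backed by scikit-learn and verified in the
test suite against brute-force pair counting and an exhaustive threshold
sweep. Balanced accuracy is the mean of sensitivity and specificity;
precision is defined as 0 (and flagged) when nothing is predicted
positive. Global evaluation is pair-level k-fold cross-validation
(unstratified by default, matching a plain random division; stratified
optional). Local evaluation computes metrics per tail task on that task's
own test pairs and averages them unweighted; degenerate single-class test
sets are skipped and reported rather than failing a batch run.

## Reference experiments and problem sizes

The standard benchmark world uses 2000 compounds, 16 head and 20 tail
kinases, `τ = 0.3`, `ε = 0.05`, 200 outer iterations — sizes chosen so the
full suite and the acceptance script each run in minutes on one CPU while
leaving the transfer effect far larger than seed noise. The transfer
experiment compares meta-training + adaptation against training the same
architecture from scratch on each tail support set (Adam, 100 epochs);
the head-count trend re-runs meta-training on nested subsets {2, 8, 16}
of the same world's head tasks, paired within seeds.

The learnability experiment sets `ε = 0, τ = 0` and asks whether plain
supervised training recovers the planted structure. It uses linear towers
(`hidden=()`): the inner product of two affine maps spans exactly the
planted bilinear-plus-intercept family, so held-out (pair-level, 10%)
performance measures structure recovery. The ReLU default reaches ~0.94
here — a capacity/regularization effect of fitting a bilinear truth with
an over-parameterized network, not an implementation defect — while the
matched family reaches ~0.96–0.98 in seconds. Held-out is read at the pair
level; generalizing to entirely unseen kinase descriptors from only 16
training kinases is statistically capped near 0.87 regardless of training
and is a different (harder) question than structure recovery.

## Limitations

Second-order meta-training is O(inner_steps) Hessian-vector products per
task per iteration; fine at these scales, but first-order mode is the
pragmatic choice for much larger towers. The ECFP implementation uses
binary bits (not counts). ProtVec-style pre-trained sequence embeddings
are deliberately out of scope — the kinase tower accepts any fixed-length
descriptor, so they remain a plug-in point. No calibration
post-processing is applied to predicted probabilities.
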