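# metakinase

Few-shot kinase–inhibitor activity prediction with meta-learned inductive
logistic matrix completion.

## The problem

Kinase bioactivity panels are extremely long-tailed: a handful of
well-studied kinases have thousands of labelled compounds, while most of
the kinome has only a few. Models trained on the pooled data look good on
pooled metrics but fail exactly where predictions are most needed — the
data-poor "tail" kinases. This package is for cheminformaticians and
method developers who want a tested, reproducible implementation of the
two ideas that address this:

1. **Inductive logistic matrix completion (ILMC).** The partially observed
   binary interaction matrix `T ∈ {1, 0, ∅}^{n×m}` (active = pKi/pKd/pIC50
   ≥ 6, i.e. ≤ 1 µM) is modelled through two MLP towers over side
   information — a compound fingerprint `x_c` (MACCS, 167 bits, or ECFP,
   radius 2 / 256 bits) and a kinase conjoint-triad descriptor `x_p`
   (7³ = 343 dims):

   ```
   P(T_ij = 1) = σ( ⟨ NN(x_c,i | U), NN(x_p,j | V) ⟩ )
   ```

   trained by minimizing the mean binary cross-entropy over observed pairs
   plus `λ(‖U‖²_F + ‖V‖²_F)`. Because both towers consume features, the
   model scores compounds and kinases never seen in training.

2. **MAML-style meta-training.** Data-rich head kinases are treated as
   tasks. The inner loop adapts the towers to a task's 5+5 support set by
   a few gradient steps (`θ″ = θ − α∇L_S(θ)`, repeated); the outer loop
   updates the initialization through the adapted parameters
   (`θ ← θ − β ∇θ Σ_k L_{Q_k}(θ″_k)`), differentiating through the inner
   steps (second order; Hessian-vector products are computed exactly by
   complex-step differentiation of the analytic gradient). The result is
   an initialization from which any tail kinase gets a useful model after
   four gradient steps on ten labelled compounds.

A fully seeded synthetic kinome generator plants a shared-plus-perturbed
bilinear structure with calibrated class prevalence and long-tailed task
sizes, so every stage — featurization, splitting, episodic meta-training,
adaptation, evaluation — runs end-to-end with no downloads.

## Worked example

```python
from metakinase import run_transfer_benchmark

res = run_transfer_benchmark(seed=0)   # 16 head / 20 tail kinases, 200 outer iterations
print(f"meta tail AUC    {res['meta_mean'].auc:.3f}")
print(f"scratch tail AUC {res['scratch_mean'].auc:.3f}")
print(f"gap              {res['auc_gap']:.3f}")
```

prints

```
meta tail AUC    0.728
scratch tail AUC 0.577
gap              0.151
```

Each tail kinase here has only a 5+5 support set. Training the same
architecture from scratch on those ten pairs barely beats chance (0.577);
adapting the meta-learned initialization with the identical four gradient
steps reaches 0.728 mean AUC on held-out test pairs — the transfer signal
that motivates meta-learning on the long tail.

The same pipeline is scriptable from the shell:

```bash
metakinase simulate --out world/
metakinase meta-train --split world/split.json \
    --compound-feats world/compounds.feat.npz \
    --kinase-feats world/kinases.feat.npz --out model/
metakinase evaluate --mode local --split world/split.json --meta model/ \
    --compound-feats world/compounds.feat.npz \
    --kinase-feats world/kinases.feat.npz --out eval/
```

Real data enters through the same formats: a compound CSV
(`compound_id,smiles`), a kinase FASTA, and an activity CSV
(`compound_id,kinase_id,measure,value` with measures pKi/pKd/pIC50 on the
−log10 molar scale) via `metakinase featurize-compounds`,
`featurize-kinases`, `build-dataset` and `split-longtail`.

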