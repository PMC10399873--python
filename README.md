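# cnvprior

Gene prioritization from case/control copy-number-variant (CNV) cohorts.

Rare CNV burden studies compare how often deletions and duplications of
each gene occur in affected individuals versus controls. `cnvprior` turns
such a cohort into a per-sample feature matrix (overlap length of each
gene × dosage feature, in kb), trains a semi-supervised variational
autoencoder on it, and scores every feature by the product of the learned
weight matrices — a signed, first-order attribution of the case logit to
each gene.  Alongside the model it provides the classical statistics the
field expects: Fisher's exact burden test, a label-permutation null,
male/female segregation analysis, gene-set fold enrichment and
phenotype-term ratios.  A built-in simulator generates cohorts with
planted risk genes so the whole pipeline is testable without any external
data source.

## Model

For sample *i* with CNV set *C_i*, the feature for gene *g* and dosage
*d* ∈ {del, dup} is

    X[i, (g,d)] = Σ_{c ∈ C_i, dosage(c)=d} |c ∩ g| / 1000   (kb),

scaled per column to [0, 1]; the label is y = 1 for cases, 0 for
controls.  A VAE with encoder Q(z|x), diagonal-Gaussian latent z and
mirrored decoder P(x|z) is trained by Adam on the negative evidence lower
bound

    L = E_q[ ‖x − x̂‖² ] + KL( Q(z|x) ‖ N(0, I) ),

with hidden widths following the square-root rule (each layer is
⌈√(previous width)⌉, at most three layers, latent ⌈√(last hidden)⌉).
Training is two-phase: unsupervised pretraining on the pooled CNVs of all
available disorders, then supervised fine-tuning on the target cohort —
the decoder is set aside and a sigmoid head on the latent mean is trained
with binary cross-entropy (jointly with the encoder by default, or with
the encoder frozen).  The final per-feature score is the weight-matrix
product

    w_final = W¹ · W² · ⋯ · W_mu · w_head    (I × 1),

biases and activations omitted.  Positive entries mark case-associated
features; results are ranked by score with control-dominated and
never-overlapped features excluded, next to each feature's Fisher p,
optional permutation p and Benjamini–Hochberg q-value.

## Worked example

Simulate the reference benchmark (300 cases + 300 controls, 500 genes on
a 50 Mb chromosome, 10 planted deletion features carried by 30 % of cases
vs 5 % of controls) and run the full flow:

```python
from cnvprior.benchmark import run_benchmark
from cnvprior.prioritize import results_to_frame

r = run_benchmark(seed=1)
print(results_to_frame(r.results_vae).head(7).to_string(index=False))
print("recall@20:", r.recall_vae_at_20,
      "held-out accuracy:", round(r.heldout_accuracy, 3))
```

```
 rank  gene status score  caseOV  controlOV fisher_p ...
  1.0 G0400    del 2.621      96         14 1.79e-19
  2.0 G0050    del 2.055      89         12 1.48e-18
  3.0 G0100    del 1.763      98         15  1.8e-19
  4.0 G0450    del 1.748      77         15 3.83e-13
  5.0 G0300    del 1.470      91         22 1.43e-13
  6.0 G0200    del 1.467      92         19 2.49e-15
  7.0 G0150    del 1.451      93         19 1.27e-15
recall@20: 1.0 held-out accuracy: 0.867
```

All ten planted features (gene ids G0000, G0050, …, G0450, deletions)
rank in the top 20 of 527 testable features; `caseOV`/`controlOV` are the
distinct overlapped individuals per arm and `fisher_p` the one-sided
burden p-value.

The same pipeline runs from the shell on the documented TSV/BED formats:

```sh
cnvprior simulate --seed 11 --out-dir sim
cnvprior run --config config.yaml --seed 1
cnvprior stats sim/cnvs.tsv sim/genes.bed --out stats.tsv
cnvprior sexbias sim/cnvs.tsv sim/genes.bed --gene G0050:del --out sex.tsv
```

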