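# decoyfeat

Autoencoder-based featurization of protein tertiary-structure decoy
ensembles, with supervised decoy selection on the learned features.

## The problem

Template-free protein structure prediction generates tens of thousands of
candidate structures ("decoys") per target protein. Two questions follow:
how to summarize such an ensemble with a handful of informative coordinates,
and how to pick out the decoys closest to the (withheld) native structure —
the *decoy selection* problem. `decoyfeat` casts both as representation
learning on CA traces: each structure is reduced to its alpha-carbon
coordinates, rigidly superposed onto a reference, and turned into a
deviation vector dS ∈ ℝ³ⁿ; a family of dense autoencoders (and PCA/Isomap
baselines) compresses these deviations into a low-dimensional code y, and
simple regressors predict each decoy's lRMSD from the native structure out
of y.

The package is aimed at structural-bioinformatics practitioners who want a
self-contained, dependency-light pipeline: every stage works end-to-end on
synthetic decoy ensembles with planted ground truth, so the whole method is
testable without access to large decoy sets.

## The model

An autoencoder maps the input x (a 3n-dimensional deviation vector) to a
code y = f_θ(x) = σ(Wx + b) and back to a reconstruction z = g_θ′(y), with
θ = {W, b}, θ′ = {W′, b′}. Architectures covered:

- **vanilla (vAE)**: x → y → z, no hidden layers;
- **deep (dAE)**: x = L0 → L1 → L2 → y → L2 → L1 → z, with |L1| = 250 for
  |x| < 250 (else |x| + 30) and |L2| = 125;
- activations per side: identity, sigmoid, leaky ReLU (α = 0.3), and
  parametric leaky ReLU (one learnable α per layer);
- **weight tying**: W_dec = W_encᵀ as a structural constraint;
- **orthogonality (oAE)**: a soft penalty β·Σ‖W_enc·W_dec − I‖²_F over
  mirrored layer pairs.

Training is mini-batch Adam (learning rate 0.008, batch 256, 100 epochs) on
the summed-squared reconstruction error ‖dS − dŜ‖², implemented directly in
NumPy with analytic gradients. The model search crosses {2, 5, 10, 20} code
dimensions × 16 activation pairs × {vanilla, deep} = 128 architectures per
regularization branch, trains each 3 times from different seeds, and ranks
by mean test MSE against a PCA baseline fit on the same training split.

Decoy selection scales lRMSD labels into [0, 1] by the training-set maximum
and fits (a) closed-form linear regression and (b) a sigmoid single-layer
perceptron on the learned features, reporting MSE and explained variance on
held-out targets.

## Worked example

```python
import numpy as np
import decoyfeat as df

# a synthetic 60-residue target with 2000 decoys and 2 planted modes
spec = df.SyntheticSpec(n_residues=60, n_decoys=2000, n_modes=2,
                        noise_sigma=0.3, seed=0)
ensemble, gt = df.sample_ensemble(spec)

dataset = df.split_dataset(df.centralize(ensemble), seed=0)

pca = df.pca_fit(dataset.rows("train"), 2)
print(df.pca_mse(pca, dataset.rows("test")))          # 15.66 (A^2)

arch = df.AEArchitectureSpec(family="vanilla", code_dim=2,
                             encoder_activation="identity",
                             decoder_activation="identity")
model = df.build_model(arch, dataset.input_dim, seed=1)
df.train(model, dataset, df.TrainConfig(seed=1))
print(df.reconstruction_mse(model, dataset.rows("test"))[0])   # 16.08
```

The run prints:

```
ensemble: 2000 decoys, 60 residues (input dim 180)
lRMSD to native: min 0.48 A, median 5.02 A, max 13.75 A
split: 1000/200/800 train/validation/test
PCA test MSE (k=2):        15.66 A^2
linear vAE test MSE (|y|=2): 16.08 A^2
axis-1 walk decoys: [946, 972, 1132, 1601, 1494, 1490]
their planted mode-1 amplitudes: [ 97.4  72.2  42.8  11.6 -18.5 -31. ]
```

The linear vanilla AE lands within a few percent of PCA at the same code
dimension — the expected equivalence of linear autoencoders and principal
components — and a walk along the first latent axis visits decoys whose
planted mode-1 amplitudes decrease monotonically, showing that the latent
axis encodes the planted collective motion.

The same pipeline is scriptable from the shell:

```bash
decoyfeat simulate --n-residues 60 --n-decoys 2000 --difficulty medium \
    --seed 0 --out ens.txt
decoyfeat embed  --ensemble ens.txt --method pca --dim 2 --seed 0 --out emb.tsv
decoyfeat search --ensemble ens.txt --grid small --seed 0 --out report.csv
```

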