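# zbind

Z-scale QSAR modelling of peptide–MHC binding affinity: amino-acid
principal-component descriptors, per-allele PLS regression with Variable
Importance in Projection (VIP), perceptron-ensemble regression with two
cross-validation schemes, strong/weak-binder evaluation and VIP heat-map
visualization.

## Who this is for

Immunoinformaticians and cheminformaticians who want local, inspectable
models of MHC-I/MHC-II binding — per-allele regressions of ln(ic50) on
peptide physicochemistry that run on a laptop, expose every fitted quantity
and visualize which binding-groove positions drive affinity — rather than
black-box web servers.

## The model

Each amino acid is encoded by its scores on the first three principal
components of a panel of physicochemical property scales (the "z-scales":
z1 polarity/hydrophobicity, z2 size, z3 electronic character).  A 9-mer
(MHC-I) becomes a 27-vector and a 15-mer (MHC-II) a 45-vector:
{z1(aa1), z2(aa1), z3(aa1), …, z3(aaL)}.

**PLS.**  ln(ic50) is regressed on the descriptors by single-response
NIPALS partial least squares (columns centered, not scaled).  With SSY_a
the residual response SS after a latent dimensions and w_ak the PLS
weights, the importance of descriptor k is

    VIP_k = sqrt( K · Σ_a w_ak² (SSY_{a−1} − SSY_a) / (SSY_0 − SSY_A) )

normalized so Σ VIP² = K (average VIP = 1); descriptors with VIP > 1 are
the ones that matter.  Arranged as a groove-position × PC grid per allele,
the VIP matrix is a statistical picture of the binding pocket.

**Neural nets.**  A three-layer perceptron with logistic hidden units —
as many as binding-domain residues (9 for class I, 15 for class II) — and
a linear ln(ic50) output, trained with an L2 overfitting penalty tuned to a
training r² of 0.9.  Method 1 keeps the best of several random-holdback
tours; Method 2 averages an ensemble of nine networks trained on random
2/3 subsets, reporting per-peptide mean, SEM and CV%.

**Evaluation.**  r² between predicted and observed ln(ic50), plus AROC
after the conventional dichotomies: strong binders (ic50 ≤ 50 nM) and
binders (≤ 500 nM) vs non-binders.

A synthetic-data module generates binding datasets with the pathologies of
the public compilations (overlapping measurement subsets with different
mean affinities, censoring spikes at assay limits, planted ground truth),
so the whole pipeline is testable without external downloads.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from zbind import (SyntheticConfig, canonical_zscales, compute_vip,
                   encode_dataset, evaluate, fit_pls, generate_dataset,
                   select_factors)

cfg = SyntheticConfig(seed=42)            # 232+167+49 peptides, censor spikes
ds = generate_dataset(cfg)
X, y = encode_dataset(ds.records, canonical_zscales())
a = select_factors(X, y, max_factors=6, seed=0)
m = fit_pls(X, y, n_factors=a)
vip = compute_vip(m, allele="DRB1*0101")

print("n =", len(ds), "factors =", a)
print("sum VIP^2 / K =", round(float((vip.vip_flat**2).sum()) / 45, 6))
k = int(np.argmax(vip.vip_flat))
print(f"top VIP: {vip.position_labels[k // 3]} PC{k % 3 + 1} = {vip.vip_flat[k]:.2f}")
res = evaluate(m.predict(X), [r.ic50_nM for r in ds.records], allele="DRB1*0101")
print(f"r2={res.r2:.3f} aroc_sb={res.aroc_sb:.3f} aroc_wb={res.aroc_wb:.3f}")
```

prints

```
n = 448 factors = 2
sum VIP^2 / K = 1.0
top VIP: P4 PC1 = 3.61
r2=0.202 aroc_sb=0.763 aroc_wb=0.729
```

Cross-validation detects two latent factors (the generator's overlapping
subsets create exactly the latent structure seen in real compilations);
the VIP normalization holds by construction; the top cell says the
polarity (PC1) of pocket P4 drives this synthetic allele; and the linear
model ranks binders well above random (AROC ≈ 0.76) even though heavy
censoring caps the attainable r².

The same flow is available from the shell:

```sh
zbind simulate --out data.tsv --seed 42
zbind train --model pls --allele 'DRB1*0101' --in data.tsv --out model.json --seed 0
zbind predict --model model.json --in data.tsv --out pred.tsv
zbind evaluate --pred pred.tsv --truth data.tsv
zbind heatmap --vip vip.tsv --scaling column_relative --out vip.png
```

plus `zbind zscales derive|show`, `zbind sample-kmers` (random proteome
k-mer test sets) and `--model nn1|nn2` for the perceptron schemes.

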