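# lipidlink

Integration of paired lipidomics and bulk-transcriptomics profiles from
multi-group dietary studies of metabolic disease — the kind of design where a
standard-diet control (SD) is compared against high-fat-diet prediabetes
(HFD) and HFD + streptozotocin type-2-diabetes (HFD-STZ) models, with
dietary-reversal (DR) arms that return diseased animals to the control diet.
The package answers three questions about such data:

1. **Which lipids and genes change with disease and change back with
   reversal?** Per-lipid Student's *t*-tests and a lightweight
   negative-binomial Wald test for genes, both with Benjamini–Hochberg FDR
   control, followed by disease ∩ reversal overlap analysis.
2. **What do the two omics layers share?** A from-scratch two-way orthogonal
   partial least squares (O2PLS) decomposition that splits each matrix into
   joint covariation, matrix-specific systematic variation, and noise, and
   ranks integration candidates by joint-loading magnitude.
3. **Which lipid–gene relationships survive biological filtering?** A
   Pearson correlation network (|r| > 0.6) over lipids and
   annotation-restricted genes, with modularity-based subnetwork detection
   and reversal-status labelling.

A fully seeded synthetic-study generator emulates the whole design —
log-normal lipid intensities over 17 lipid classes with missing values, ion
modes and internal standards; negative-binomial gene counts; a planted
disease effect on TG/DG species and lipid-metabolism genes that is absent in
the DR groups; and a planted latent factor loading jointly on TG lipids and
a designated gene set — so every stage is testable end to end, with ground
truth, without any external download.

## The model at the core

Given column-centred, unit-variance matrices **X** (n samples × p lipids)
and **Y** (n × q genes), O2PLS estimates

```
X = T Wᵀ + T_Yo P_Yoᵀ + E
Y = U Cᵀ + U_Xo P_Xoᵀ + F
```

where **W**, **C** are the K leading left/right singular vectors of **XᵀY**
(the joint loadings), **T = XW**, **U = YC** the joint scores, and the
orthogonal blocks (nx and ny components) capture structured variation unique
to each matrix, estimated from the residual covariance **EᵀT** (resp.
**FᵀU**) and removed by deflation before the final scores. Inner regressions
**B_T**, **B_U** link the score sets; squared Frobenius norms give the
joint / orthogonal / noise variance partition. Features are ranked by the
Euclidean norm of their rows of **W** (or **C**).

## Worked example

```python
import numpy as np
import lipidlink as ll
from lipidlink.o2pls import fit_o2pls, scale_transform, top_loadings
from lipidlink.pipeline import RunConfig, preprocess_lipids

study = ll.simulate_study(ll.StudyDesign(), ll.SimulationConfig(n_genes=2000, seed=1))
merged, funnel = preprocess_lipids(study.lipids, RunConfig())
model = fit_o2pls(scale_transform(merged), scale_transform(study.genes),
                  K=2, nx=2, ny=2)
r2 = model.r2["Y"]
print(f"genes: joint {r2['joint']:.1%}, orthogonal {r2['orthogonal']:.1%}, "
      f"noise {r2['noise']:.1%}")
s = np.array([study.truth["joint"]["latent_score"][i] for i in merged.sample_ids])
print(f"|corr(T1, planted latent score)| = {abs(np.corrcoef(model.T[:,0], s)[0,1]):.3f}")
```

prints (seed 1):

```
genes: joint 29.2%, orthogonal 5.0%, noise 65.8%
|corr(T1, planted latent score)| = 0.960
```

i.e. about a quarter of the gene-matrix variance is shared with the lipid
matrix, and the leading joint score essentially recovers the planted
disease-linked latent factor. The `examples/` directory has one short
narrative script per capability (simulation, preprocessing, differential
overlaps, O2PLS, network); each prints its numbers with a line on what they
mean. A thin CLI mirrors the stages:

```bash
lipidlink simulate --seed 1 --outdir sim/
lipidlink run-all --config run.yaml --seed 1
```

`run-all` executes preprocess → differential → O2PLS → network from one YAML
config and writes a `report.json`/`report.txt` whose counts (lipids
identified, DALs/DEGs per contrast, overlap direction splits, variance
partition, network sizes) are byte-reproducible from the echoed config and
seed.

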