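# kgddi — drug–drug interaction prediction from knowledge graphs and fingerprints

Predicting drug–drug interactions (DDIs) — one drug altering another's
pharmacological effect — from heterogeneous pharmacological data is a core
screening problem in drug development: unlabeled drug pairs vastly outnumber
experimentally verified interactions, and an unlabeled pair may well be an
undiscovered interaction rather than a true negative. `kgddi` implements a
complete pipeline for this setting, aimed at cheminformatics researchers who
have (or can synthesize) a typed knowledge graph and per-drug structures:

1. **Knowledge-graph convolutional (KGCN) embeddings.** Entities (drugs,
   proteins, genes, diseases) and relation types get trainable vectors. A
   drug's representation aggregates its H-hop sampled neighborhood with
   attention weights softmax(⟨e_query, r⟩) over the edge relations r, then
   combines self and neighborhood with a *concat* aggregator
   σ(W[e ‖ e_S(v)] + b). Training scores a candidate pair (a, b) as
   σ(⟨rep(a|query=b), rep(b|query=a)⟩) under binary cross-entropy.
2. **Neural factorization machine (NFM) pair scoring.** Each pair becomes a
   2(B+d)-dimensional vector [fp(a) ‖ fp(b) ‖ emb(a) ‖ emb(b)] (2176 at the
   default B = 1024 Morgan bits and d = 64). The NFM scores

   ŷ(x) = w₀ + Σᵢ wᵢxᵢ + pᵀ σ_L(W_L … σ₁(W₁ f_Bi(V_x) + b₁) … + b_L),

   where f_Bi(V_x) = Σ_{i<j} (xᵢvᵢ) ⊙ (xⱼvⱼ) is bi-interaction pooling,
   computed in linear time via ½[(Σu)² − Σu²]. A sigmoid head yields the
   interaction probability; a separate 512/256/128/64 feedforward softmax
   classifier types interactions as *increase* vs *decrease*.
3. **Reliable negatives from unlabeled pairs (PU learning).** The mean of
   positive pair fingerprints (2B = 2048 dims) forms a cluster center; an
   unlabeled pair is accepted as a reliable negative when its Euclidean
   distance to the center strictly exceeds D = n × AED (default n = 1.2),
   AED being the average such distance over all unlabeled pairs.
4. **Evaluation harness.** Acc/Sen/Spe/Pre/F1/MCC/AUROC/AUPR with mean ±
   RSD(%) over repeated stratified 10-fold CV, plus cold-start
   *pairwise-disjoint* CV (drug-level folds: no test drug ever appears in a
   training pair), with embeddings re-learned inside every fold so nothing
   fit on test pairs leaks into training.
5. **Synthetic worlds.** A deterministic generator plants interaction signal
   in latent drug clusters and emits the KG, fingerprints, and labeled pairs
   in the exact file dialects the pipeline reads — every stage is testable
   offline, with hidden ground truth written to a separate oracle file.

All training runs on a small NumPy reverse-mode autodiff core shipped with
the package (`kgddi._autograd`), gradient-checked against finite differences.

## Worked example

Generate a synthetic world, run the full pipeline (reliable negatives →
per-fold KGCN → NFM → 10-fold CV), and print the metric report:

```python
from kgddi import pipeline

cfg = pipeline.default_config()
cfg["synth"]["n_drugs"] = 60       # desk-scale demo; default world has 300
cfg["synth"]["n_proteins"] = 30
cfg["synth"]["n_genes"] = 20
cfg["synth"]["n_diseases"] = 15
cfg["synth"]["n_pairs"] = 400
cfg["synth"]["seed"] = 1
cfg["kgcn"].update({"dim": 16, "epochs": 3, "neighbor_size": 4})
cfg["nfm"].update({"latent_dim": 16, "epochs": 5})
cfg["cv"]["k"] = 3
manifest = pipeline.run_all(cfg, out_dir="runs/demo")
print({k: round(v, 3) for k, v in manifest.report.mean.items()})
```

This prints (deterministic for the fixed master seed):

```
{'acc': 0.934, 'sen': 0.883, 'spe': 0.989, 'pre': 0.989, 'f1': 0.932,
 'mcc': 0.875, 'auroc': 0.959, 'aupr': 0.975}
```

i.e. on the demo world the pipeline recovers the planted pair-interaction
signal almost perfectly: ~93% of held-out pairs classified correctly at the
0.5 threshold, AUROC ≈ 0.96 (ranking quality), MCC ≈ 0.88 (balanced
agreement). `runs/demo/` holds the generated data, a `report.tsv` with
per-fold metrics and RSD(%), and a `manifest.json` snapshot sufficient to
replay the run bit-for-bit (`pipeline.replay`).

The same pipeline is scriptable from the shell:

```bash
kgddi synth --n-drugs 300 --seed 0 --out data/
kgddi featurize --smiles drugs.tsv --width 1024 --radius 2 --out fp.tsv
kgddi negatives --pairs data/pairs.tsv --fingerprints data/fingerprints.tsv \
    --n 1.2 --seed 7 --out neg.tsv
kgddi run --seed 0 --out runs/full
```

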