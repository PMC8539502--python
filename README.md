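# dgin — composite graph neural networks for lipophilicity and solubility

`dgin` is a library + CLI for predicting physicochemical properties of small
molecules — the distribution coefficient at pH 7.4 (logD), aqueous solubility
(logS) and the octanol–water partition coefficient (logP) — directly from
SMILES with a **directed-edge graph isomorphism network (D-GIN)** and its two
sub-architectures, D-MPNN and GIN. It is aimed at cheminformatics
practitioners who want a small, dependency-light, fully inspectable
implementation of directed-edge message passing with GIN-style node updates,
together with the complete evaluation protocol around it: featurization
strategies, multi-task training, combined-RMSE model selection, classical-ML
baselines, consensus averaging, bootstrap confidence intervals and feature
ablation.

## The model

A molecule is a directed graph: every bond u–v contributes two directed edges
`e_uv ≠ e_vu`, nodes carry atom features `x_v ∈ R^d`, directed edges carry
bond features `x_e_uv ∈ R^b`. The D-GIN runs two propagation phases:

**Phase 1 — directed-edge message passing** (hidden states on edges, width c):

    h⁰_uw = τ(W_init · cat(x_u, x_e_uw))
    m_uw^(t+1) = Σ_{k ∈ N(u)\w} h_ku^(t)          (no immediate backtracking)
    h_uw^(t+1) = τ(h⁰_uw + W_m · m_uw^(t+1))       (skip to the initial state)

repeated T times, then aggregated per node over incoming edges,
`m_u = Σ h_·u^(T)`, and joined with the raw atom features,
`h_u = cat(m_u, x_u)`.

**Phase 2 — GIN updates** (hidden states on nodes, T2 layers):

    h_u^(l+1) = MLP_l((1 + ε_l) · h_u^(l) + Σ_{w ∈ N(u)} h_w^(l))

with one learnable scalar ε per layer — the update form whose discriminative
power matches the 1-WL graph-isomorphism test. Sum pooling
`h_G = Σ_u h_u` and a feed-forward readout `ŷ = f(h_G)` produce one value per
trained property. D-MPNN is phase 1 alone (with a learned linear node
aggregation `h_u = W_agg·cat(m_u, x_u)`); GIN is phase 2 alone, started from
raw atom features. Everything — forward pass, reverse-mode gradients, Adam —
is implemented on NumPy (`dgin.nn`), so a run is bit-reproducible from its
seed on a single thread.

Six featurization strategies (ids 3–8) assemble node/edge vectors from
declarative feature blocks: element, formal charge, aromaticity,
hybridization, degree, H-count, ring membership and ring size (as 1/size or a
ten-instance one-hot); edges carry bond order, conjugation and ring flags.
Strategy 5 is deliberately minimal (element + charge / bond order), 3 and 4
are maximal and differ only in the ring-size encoding, 8 is the reduced set
kept after feature ablation.

The training protocol mirrors a multi-task study design: seven training
strategies (logD/P/S, logD/P, logD/S, logS/P, logD, logS, logP), an 81:9:10
random split shared across models, per-property offsets to non-negative
targets, a masked multi-task MSE, per-epoch checkpointing on the *combined*
(summed) evaluation RMSE, best-of-two-runs selection, and 100-replicate
bootstrap 95% CIs that leave out 10% of the test set per replicate. RF / SVM
/ KNN baselines (scikit-learn defaults) run on ECFP-1024/1536/2048 (radius 4)
or MACCS keys, with or without the standardized RDKit descriptor block — 8
settings; a consensus model averages the predictions of two models.

## Worked example

The synthetic generator samples valid heavy-atom molecules and labels them
with a known additive ground truth (per-element + per-bond contributions +
ring bonus, Gaussian noise σ = 0.1), so a full train/evaluate cycle runs in
about a minute with no external data:

```python
from dgin import (GNNConfig, GNNModel, OffsetTransform, PropertyRecord,
                  TrainConfig, build_dataset, evaluate, bootstrap_ci,
                  get_training_strategy, split, train)
from dgin.synthetic import generate_dataset

df = generate_dataset(500, seed=1)                   # smiles, logd, logs, logp
records = [PropertyRecord(r.smiles, logd=r.logd, logs=r.logs, logp=r.logp)
           for r in df.itertuples()]
strategy = get_training_strategy("logP")
recs = strategy.effective_records(records)
offset = OffsetTransform.fit(recs, strategy.properties)
sp = split(len(recs), seed=1)                        # 405 / 45 / 50
ds = build_dataset(recs, strategy, strategy_id=3, offset=offset)

model = GNNModel(GNNConfig(architecture="d-gin", strategy_id=3, c=128,
                           T=2, T2=1, readout_hidden=(128,), n_props=1, seed=1))
result = train(model, ds.subset(sp.train), ds.subset(sp.eval),
               TrainConfig(epochs=200, lr=1e-2, batch_size=64, seed=1))
test = ds.subset(sp.test)
print("test RMSE:", evaluate(model, test))
pred = model.predict(test.graphs)[:, 0]
print("95% CI:", bootstrap_ci(pred, test.y[:, 0], seed=1))
```

Output:

```
test RMSE: {'logp': 0.168...}
95% CI: (0.153..., 0.177...)
```

A test RMSE of ≈ 0.17 against a noise floor of σ = 0.1 means the network has
recovered most of the additive structure from 405 training molecules; the CI
is the spread of RMSE over 100 bootstrap replicates each scoring a random 90%
of the 50 test molecules.

The same pipeline is scriptable from the shell:

```bash
dgin synth data.csv --n 500 --seed 1
dgin train config.yaml runs/exp1        # config: data, architecture, epochs...
dgin grid  config.yaml runs/grid        # featurization x strategy grid + summary
dgin ablate runs/exp1/ckpt data.csv impacts.json
```

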