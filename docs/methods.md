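# Methods

## Model family

Three regressors over directed molecular graphs share one code path
(`dgin.gnn`). A molecule parsed from SMILES (RDKit perception, implicit
hydrogens, heavy-atom graph) becomes `G = (V, E)` where each bond contributes
the two directed edges `e_uv` and `e_vu` with identical feature vectors; the
binary adjacency is therefore symmetric, and an n-atom molecule with m bonds
has exactly 2m directed edges.

**Directed-edge phase (D-MPNN, and phase 1 of D-GIN).** Hidden states of
width `c` live on directed edges and are initialized from the *source* node's
features concatenated with the bond features,
`h⁰_uw = τ(W_init cat(x_u, x_e_uw))`. The message into `u→w` sums the hidden
states of edges arriving at `u` *excluding the reverse edge* `w→u`, so
information never immediately backtracks; each update keeps a skip connection
to `h⁰` (not to the previous iterate): `h^(t+1) = τ(h⁰ + W_m m^(t+1))`. After
T rounds the per-node message `m_u` sums the final states of *incoming*
edges. The printed form of the node aggregation in the source material
indexes outgoing edges; we aggregate incoming edges, matching the
directed-edge architecture this design descends from, and expose
`incoming_aggregation` as a flag. The t = 0 branch of the message definition
is identical to the general branch and is implemented as one rule.

**GIN phase (GIN, and phase 2 of D-GIN).** Node states update as
`h^(l+1) = MLP_l((1+ε_l) h^(l) + Σ_{w∈N(u)} h_w^(l))` with a per-layer
learnable scalar ε initialized to 0 and a per-layer one-hidden-layer MLP
(width c, activation τ, linear output). This is the standard
sum-aggregation update whose discriminative power matches 1-WL color
refinement; the printed equation's parenthesization is ambiguous and
references the initial state, but only this reading supports the claimed
1-WL expressiveness, so it is the one implemented. D-GIN feeds phase 2 from
`cat(m_u, x_u)` (so its first GIN layer maps c+d → c); plain GIN starts from
raw node features (d → c). The self-node enters only through the (1+ε) term.

**Readout.** Sum pooling `h_G = Σ_u h_u` followed by a feed-forward network
(default two hidden layers of width c, activation τ, linear output), one
output per trained property. The two aggregation weight matrices (the
D-MPNN node aggregation and the GIN MLPs) are independent parameter sets:
their input dimensions differ, so a single shared matrix is not
well-defined. Edge hidden width equals c (the notation table of the source
assigns edge states dimension d, which collides with the node feature
dimension; c is the only shape consistent with the update equations).

Defaults: τ = ReLU (sigmoid available), T = 3, T2 = 2, c = 128, readout
(128, 128). These are config keys; the desk-scale runs below state their own
values. Bond-free molecules (one heavy atom) flow through with empty sums.

## Numerical core

No deep-learning framework is used. `dgin.nn` is a ~300-line reverse-mode
autodiff on float64 NumPy arrays (matmul, broadcast add/mul, ReLU/sigmoid,
concat, row gather, segment sum) with Glorot-uniform initialization and Adam
(β = 0.9/0.999, ε = 1e-8). Graphs are batched as one disjoint union; segment
sums route edge→node and node→graph aggregations. Gradients are verified
against central finite differences in the test suite, and the full forward
passes of all three architectures against a naive per-edge/per-node loop
reference (agreement ≤ 1e-6 on random graphs). Single-threaded runs are
bit-reproducible from their seeds. Weight checkpoints round-trip exactly
(npz + JSON metadata).

## Featurization strategies

Node/edge schemas are declarative block lists (`dgin.molgraph.STRATEGIES`),
so a schema change never touches graph construction. Blocks: element one-hot
over (H, C, N, O, S, F, Cl, Br, I, P) plus an "other" slot (unknown elements
raise by default; a permissive flag maps them to "other" with a logged
warning); formal charge one-hot over −2…+2 (clamped); aromatic flag;
hybridization (sp/sp2/sp3/other); heavy degree one-hot 0–5; total H count
one-hot 0–4; ring flag; ring size either as 1/size (0 for acyclic atoms) or
as a one-hot over the ten instances (0,3,4,…,11) with larger rings clamped
to the last instance. An atom in several rings reports its smallest ring.
Bond order is a categorical one-hot (single/double/triple/aromatic — aromatic
is its own category, not 1.5); edges optionally carry conjugation and ring
flags. Strategy 3 = all node blocks with the float ring size + all edge
blocks; 4 = the same with the one-hot ring size; 5 = element+charge /
bond order; 6 = node of 5 with edge of 3; 7 = node of 3 with edge of 5;
8 = five node blocks (element, charge, aromatic, H count, ring size) with
the three edge blocks.

## Training protocol

Seven strategies combine the three properties (logD/P/S, logD/P, logD/S,
logS/P, logD, logS, logP). Two-property strategies involving logP train only
on records carrying *both* properties, to keep evaluation data comparable.
Preprocessing: solubility sets are reduced to the largest fragment,
neutralized (RDKit standardization; applied transformations are logged) and
filtered to logS ∈ [−10, 0] with boundaries retained (the removal rule is
strict inequality); lipophilicity sets are neutralized only; unparsable
records are dropped and counted. The 81:9:10 split is a seeded two-stage
draw — hold out the test tenth, then a tenth of the remainder for evaluation
— *rounding* at each stage, which keeps every partition within one record of
its exact quota and yields exactly (81, 9, 10) at n = 100. Per-property
offsets (subtract the dataset minimum, fitted before splitting) make targets
non-negative; RMSE is shift-invariant, so all reported metrics are identical
on raw and offset scales. The loss is the per-property mean squared error
over records where that property is present, summed over the strategy's
properties (missing entries contribute nothing). Training (Adam, default
lr 1e-3, batch 64, 1600 epochs at study scale) evaluates the combined
(summed) per-property evaluation RMSE after every epoch and checkpoints
strictly improving models; each setting is run twice and the run with the
better test combined RMSE is kept. The 95% CI of a test RMSE is the
2.5–97.5 percentile range over 100 bootstrap replicates, each scoring a
seeded random 90% subset drawn without replacement ("leaving out 10%"); a
classical resample-with-replacement variant is available behind a flag.

## Baselines, consensus, grid, ablation

RF, SVM and KNN (scikit-learn, default hyperparameters, single task per
property) run on 8 settings: ECFP with 1024/1536/2048 bits at radius 4
(radius, not diameter — flagged in code) or MACCS keys (167 bits), with or
without the full standardized RDKit descriptor block (the descriptor count is
recorded from the toolkit at run time rather than hard-coded; constant
descriptors keep unit scale, so standardization never divides by zero).
Consensus predictions are the element-wise mean of two models; by L2
convexity the consensus RMSE never exceeds the mean of the component RMSEs.
The experiment grid crosses the six featurizations with the training
strategies whose evaluation covers a property — four each for logD and logS,
two for logP (the three-property multi-task and the single-task logP run) —
giving 24/24/12 settings, doubled with repeats. Summaries report mean, min,
max and the SEM (sample standard deviation / √n). Feature ablation
zero-masks one feature *block* at a time at inference on a trained model (no
retraining; a retrain mode exists behind a flag) and ranks blocks by the
RMSE increase, selecting the top five node and top three edge blocks.

**Known limitation of zero-mask ablation:** it measures what the trained
model *relies on*, not ground-truth relevance. Blocks that are constant over
a dataset (e.g. formal charge on an all-neutral library) act as learned
biases, and blocks correlated with an informative one (degree relates to
element via valence) share credit, so they can outrank the causally relevant
block. On a fixture whose labels depend on element composition alone, the
element block carries large positive impact and is always selected, but is
not guaranteed the top rank.

## Synthetic data

`dgin.synthetic` samples random heavy-atom trees over C/N/O/S (≤ 12 atoms,
carbon-rich element draw, single bonds, optional single ring closure;
draws whose small heteroatom rings re-perceive as aromatic are rejected so
the library stays saturated). Labels are additive with known ground truth:
logP = Σ element contributions (C 0.5, N −0.7, O −0.9, S 0.2) + 0.1 per bond
+ 0.4 ring bonus + N(0, σ); logD = logP − 0.3 per nitrogen (an ionization
proxy); logS = −logP − 2 + independent N(0, σ). Defaults σ = 0.1 and these
magnitudes put logP roughly in −2…7 and logS roughly in −9…0, so the
preprocessing filters are exercised, and the anticorrelated coupling gives
multi-task learning genuine shared signal. What the generator does *not*
emulate: realistic medicinal-chemistry scaffolds and functional groups,
charged species, stereochemistry, tautomers, heavy-tailed property
distributions, and assay noise structure — so passing recovery tests shows
the architecture and protocol are implemented correctly, not that benchmark
accuracy on real data is reproduced.

Because the labels are additive and sum pooling matches that structure, a
noise-free library is an exact oracle: least squares on composition counts
recovers every contribution to machine precision, and a trained D-GIN should
approach the noise floor. The desk-scale recovery run uses 500 molecules
(405/45/50 split), strategy 3, c = 128, T = 2, T2 = 1, readout (128,),
lr 1e-2, batch 64, 200 epochs — sizes chosen so the run finishes in about
half a minute per repeat on one CPU; two repeats with the better test RMSE
kept, per the protocol above. Typical best test RMSE is 0.13–0.19 against
the σ = 0.1 floor.

## The 1-WL motivating pair

`wl_pair()` returns the naphthalene skeleton (two fused 6-cycles) and the
1,1-bi(cyclopentane) skeleton (two 5-cycles joined by a bond): 10 nodes, 11
bonds, identical degree multisets, non-isomorphic, with uniform node/edge
features so topology is the only signal. These graphs are a sharper test
than usually appreciated: they are equivalent under 1-WL color refinement
*and* under non-backtracking directed-edge color refinement at every depth
(verified exactly in this codebase). Since message-passing networks compute
refinement-bounded functions, GIN, D-MPNN and D-GIN all provably assign the
pair identical embeddings under uniform features — the unit tests assert
this equality, and the acceptance script reports the measured distances
(~1e-14, pure float noise). What separates the actual molecules in practice
is chemistry, not topology: with strategy-3 features (ring size 1/5 vs 1/6,
aromaticity) the embeddings differ by orders of magnitude, which is also
asserted. The claim that GIN-style updates distinguish this particular pair
is therefore incorrect as a statement about uniform-feature topology, and
this package documents the boundary honestly rather than asserting it.

## Degenerate inputs and numerical choices

Empty SMILES and parse failures raise typed errors naming the input;
molecules with no bonds propagate zero messages; strategies with fewer
blocks than an ablation requests select all available with a warning; ties
in best-of-runs and ranking go to the earliest entry; non-finite training
loss aborts with a diagnostic; bootstrap requires ≥ 10 pairs; splits
require every partition non-empty. All tolerances asserted in tests are
stated there: 1e-6 absolute for oracle agreement, 1e-5 relative for
permutation invariance, exact zero for the backtracking exclusion, machine
precision (1e-12) for the offset round-trip.
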