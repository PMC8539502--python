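"""Dataset handling, multi-task training and evaluation protocol.

Covers the full experimental protocol around the networks: record
preprocessing (neutralization, salt stripping, solubility range filter), the
81:9:10 split, target offsetting to non-negative values, the seven single- and
multi-task training strategies, the masked multi-task loss, combined-RMSE
checkpoint selection over epochs, best-of-two-runs selection, and bootstrap
confidence intervals on test RMSE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .gnn import GNNModel, GraphBatch
from .molgraph import MolecularGraph, build_graph, parse_molecule

logger = logging.getLogger(__name__)

PROPERTIES = ("logd", "logs", "logp")


@dataclass
class PropertyRecord:
    """A molecule with any subset of logD / logS / logP labels."""

    smiles: str
    logd: float | None = None
    logs: float | None = None
    logp: float | None = None

    def value(self, prop: str) -> float | None:
        return getattr(self, prop)

    @property
    def mask(self) -> dict[str, bool]:
        return {p: getattr(self, p) is not None for p in PROPERTIES}

    def has(self, *props: str) -> bool:
        return all(getattr(self, p) is not None for p in props)


# ---------------------------------------------------------------------------
# Training strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingStrategy:
    """One of the seven single-/multi-task property combinations."""

    name: str
    properties: tuple[str, ...]

    @property
    def pairs_logp(self) -> bool:
        """Two-property strategies involving logP train only on records
        carrying both properties."""
        return len(self.properties) == 2 and "logp" in self.properties

    def effective_records(self, records: list[PropertyRecord]) -> list[PropertyRecord]:
        if self.pairs_logp:
            return [r for r in records if r.has(*self.properties)]
        return [r for r in records if any(r.has(p) for p in self.properties)]


TRAINING_STRATEGIES: dict[str, TrainingStrategy] = {
    "logD/P/S": TrainingStrategy("logD/P/S", ("logd", "logs", "logp")),
    "logD/P": TrainingStrategy("logD/P", ("logd", "logp")),
    "logD/S": TrainingStrategy("logD/S", ("logd", "logs")),
    "logS/P": TrainingStrategy("logS/P", ("logs", "logp")),
    "logD": TrainingStrategy("logD", ("logd",)),
    "logS": TrainingStrategy("logS", ("logs",)),
    "logP": TrainingStrategy("logP", ("logp",)),
}


def get_training_strategy(name: str) -> TrainingStrategy:
    try:
        return TRAINING_STRATEGIES[name]
    except KeyError:
        raise ValueError(
            f"unknown training strategy {name!r}; valid: {sorted(TRAINING_STRATEGIES)}"
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _standardize_smiles(smiles: str, strip_salts: bool) -> tuple[str, list[str]]:
    """Neutralize (and optionally keep only the largest fragment) via RDKit.

    Returns the standardized SMILES and the list of applied transformations.
    """
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    applied = []
    if strip_salts and len(Chem.GetMolFrags(mol)) > 1:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
        applied.append("largest_fragment")
    charged = any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())
    if charged:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        if all(a.GetFormalCharge() == 0 for a in mol.GetAtoms()):
            applied.append("neutralized")
    return Chem.MolToSmiles(mol), applied


def preprocess(
    records: list[PropertyRecord],
    dataset_kind: str,
    logs_range: tuple[float, float] = (-10.0, 0.0),
) -> tuple[list[PropertyRecord], dict[str, int]]:
    """Clean a dataset, returning kept records and a per-filter count report.

    Solubility sets are reduced to their largest fragment, neutralized and
    filtered to logS within the closed range [-10, 0] (boundaries retained);
    lipophilicity sets are neutralized only.  Unparsable records are dropped
    with a logged warning.
    """
    if dataset_kind not in ("lipophilicity", "solubility"):
        raise ValueError(f"unknown dataset kind {dataset_kind!r}")
    strip = dataset_kind == "solubility"
    lo, hi = logs_range
    report = {
        "input": len(records),
        "unparsable": 0,
        "logs_out_of_range": 0,
        "neutralized": 0,
        "salt_stripped": 0,
        "kept": 0,
    }
    kept: list[PropertyRecord] = []
    for rec in records:
        try:
            smi, applied = _standardize_smiles(rec.smiles, strip_salts=strip)
        except ValueError:
            logger.warning("dropping unparsable record %r", rec.smiles)
            report["unparsable"] += 1
            continue
        if "neutralized" in applied:
            report["neutralized"] += 1
        if "largest_fragment" in applied:
            report["salt_stripped"] += 1
        if applied:
            logger.info("standardized %r -> %r (%s)", rec.smiles, smi,
                        ",".join(applied))
        if strip and rec.logs is not None and not (lo <= rec.logs <= hi):
            report["logs_out_of_range"] += 1
            continue
        kept.append(replace(rec, smiles=smi))
    report["kept"] = len(kept)
    return kept, report


def load_dataset_csv(path) -> tuple[list[PropertyRecord], dict[str, int]]:
    """Read the standard dataset CSV (smiles, logd, logs, logp; empty cell =
    missing) and report per-column presence counts."""
    import pandas as pd

    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise ValueError(f"dataset {path} lacks a 'smiles' column")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for p in PROPERTIES:
            v = row.get(p)
            kwargs[p] = float(v) if v is not None and np.isfinite(v) else None
        records.append(PropertyRecord(smiles=str(row["smiles"]), **kwargs))
    counts = {p: int(sum(r.value(p) is not None for r in records))
              for p in PROPERTIES}
    counts["n"] = len(records)
    return records, counts


# ---------------------------------------------------------------------------
# Splitting and offsetting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/eval/test index partitions of 0..n-1."""

    train: np.ndarray
    eval: np.ndarray
    test: np.ndarray
    seed: int
    ratios: tuple[int, int, int] = (81, 9, 10)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.eval) + len(self.test)


def split(n: int, ratios: tuple[int, int, int] = (81, 9, 10),
          seed: int = 0) -> SplitSpec:
    """Seeded two-stage random split: hold out the test fraction first, then
    carve the evaluation fraction from the remainder (rounded at each stage,
    which keeps every partition within one record of its exact quota).

    For n = 100 and ratios 81:9:10 the partition sizes are exactly (81, 9, 10).
    """
    if n < 3:
        raise ValueError(f"cannot split {n} records into three partitions")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * ratios[2] / total))
    remainder = n - n_test
    n_eval = int(round(remainder * ratios[1] / (ratios[0] + ratios[1])))
    n_train = remainder - n_eval
    if min(n_train, n_eval, n_test) < 1:
        raise ValueError(
            f"n={n} too small to populate all partitions with ratios {ratios}"
        )
    test = np.sort(perm[:n_test])
    eval_ = np.sort(perm[n_test:n_test + n_eval])
    train = np.sort(perm[n_test + n_eval:])
    return SplitSpec(train=train, eval=eval_, test=test, seed=seed,
                     ratios=tuple(ratios))


@dataclass(frozen=True)
class OffsetTransform:
    """Per-property shift by the dataset minimum so targets are >= 0.

    RMSE is shift-invariant, so metrics agree on raw and offset scales.
    """

    offsets: dict

    @classmethod
    def fit(cls, records: list[PropertyRecord],
            properties: tuple[str, ...] = PROPERTIES) -> "OffsetTransform":
        offsets = {}
        for p in properties:
            vals = [r.value(p) for r in records if r.value(p) is not None]
            if not vals:
                raise ValueError(f"no values present for property {p!r}")
            offsets[p] = float(min(vals))
        return cls(offsets=offsets)

    def apply(self, prop: str, values):
        return np.asarray(values, dtype=float) - self.offsets[prop]

    def invert(self, prop: str, values):
        return np.asarray(values, dtype=float) + self.offsets[prop]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def combined_rmse(per_property_rmse: dict) -> float:
    """Model-selection metric: the sum of per-property RMSEs."""
    if not per_property_rmse:
        raise ValueError("need at least one property RMSE")
    return float(sum(per_property_rmse.values()))


def multitask_loss(preds: dict, records: list[PropertyRecord],
                   strategy: TrainingStrategy) -> float:
    """Masked multi-task training loss: per-property MSE over the records
    where that property is present, summed across the strategy's properties.
    """
    total = 0.0
    for p in strategy.properties:
        if p not in preds:
            raise ValueError(f"predictions missing property {p!r}")
        pred = np.asarray(preds[p], dtype=float)
        if len(pred) != len(records):
            raise ValueError("prediction / record length mismatch")
        mask = np.array([r.value(p) is not None for r in records])
        if not mask.any():
            warnings.warn(f"no records carry property {p!r}; term is 0")
            continue
        obs = np.array([r.value(p) for r, m in zip(records, mask) if m])
        total += float(np.mean((pred[mask] - obs) ** 2))
    return total


def bootstrap_ci(preds, obs, reps: int = 100, leave_out: float = 0.10,
                 seed: int = 0, method: str = "subsample") -> tuple[float, float]:
    """95% CI of the test RMSE via bootstrapping.

    The default replicate evaluates RMSE on a random 90% subset drawn without
    replacement ("leaving out 10%"); ``method='resample'`` uses a classical
    bootstrap resample with replacement instead.  Returns the 2.5th and
    97.5th percentiles of the replicate RMSEs.
    """
    preds = np.asarray(preds, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(preds) != len(obs):
        raise ValueError("length mismatch")
    if len(preds) < 10:
        raise ValueError("need at least 10 pairs for bootstrapping")
    rng = np.random.default_rng(seed)
    n = len(preds)
    keep = max(1, int(round(n * (1.0 - leave_out))))
    stats = np.empty(reps)
    for i in range(reps):
        if method == "subsample":
            idx = rng.choice(n, size=keep, replace=False)
        elif method == "resample":
            idx = rng.choice(n, size=n, replace=True)
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
        stats[i] = rmse(preds[idx], obs[idx])
    lower, upper = np.percentile(stats, [2.5, 97.5])
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class GraphDataset:
    """Featurized graphs with offset-scale targets for one strategy."""

    graphs: list[MolecularGraph]
    y: np.ndarray       # (n, k) offset-scale targets, NaN where missing
    mask: np.ndarray    # (n, k) presence flags
    properties: tuple[str, ...]

    def __len__(self):
        return len(self.graphs)

    def subset(self, idx) -> "GraphDataset":
        idx = np.asarray(idx)
        return GraphDataset(
            graphs=[self.graphs[i] for i in idx],
            y=self.y[idx], mask=self.mask[idx], properties=self.properties,
        )


def build_dataset(records: list[PropertyRecord], strategy: TrainingStrategy,
                  strategy_id: int, offset: OffsetTransform | None = None,
                  permissive: bool = True) -> GraphDataset:
    """Featurize records under one schema and stack their strategy targets."""
    graphs, rows, masks = [], [], []
    for rec in records:
        graphs.append(build_graph(parse_molecule(rec.smiles), strategy_id,
                                  permissive=permissive))
        row, m = [], []
        for p in strategy.properties:
            v = rec.value(p)
            if v is not None and offset is not None:
                v = float(offset.apply(p, v))
            row.append(np.nan if v is None else v)
            m.append(v is not None)
        rows.append(row)
        masks.append(m)
    return GraphDataset(
        graphs=graphs,
        y=np.asarray(rows, dtype=float),
        mask=np.asarray(masks, dtype=bool),
        properties=strategy.properties,
    )


@dataclass
class TrainConfig:
    epochs: int = 1600
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0


@dataclass
class TrainResult:
    """Selected weights plus the full per-epoch metric history."""

    best_weights: list
    history: list
    best_epoch: int
    best_eval_combined: float
    eval_rmse: dict = field(default_factory=dict)
    test_rmse: dict = field(default_factory=dict)
    test_combined: float = float("nan")


def _masked_rmse(pred: np.ndarray, ds: GraphDataset) -> dict:
    out = {}
    for j, p in enumerate(ds.properties):
        m = ds.mask[:, j]
        if m.any():
            out[p] = rmse(pred[m, j], ds.y[m, j])
    return out


def evaluate(model: GNNModel, ds: GraphDataset) -> dict:
    """Per-property RMSE of a model on a dataset (offset scale)."""
    pred = model.predict(ds.graphs)
    return _masked_rmse(pred, ds)


def train(model: GNNModel, train_set: GraphDataset, eval_set: GraphDataset,
          config: TrainConfig) -> TrainResult:
    """Train with Adam on the masked multi-task MSE; after every epoch the
    combined evaluation RMSE is computed and strictly-improving models are
    checkpointed.  Fully seeded and deterministic in single-threaded runs.
    """
    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    history: list[dict] = []
    best = TrainResult(best_weights=model.get_weights(), history=history,
                       best_epoch=-1, best_eval_combined=np.inf)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = train_set.subset(idx)
            batch = GraphBatch.from_graphs(sub.graphs)
            preds = model.forward(batch)
            # per-property mean over present entries, summed across properties
            weight = np.zeros_like(sub.y)
            for j in range(sub.y.shape[1]):
                cnt = sub.mask[:, j].sum()
                if cnt:
                    weight[sub.mask[:, j], j] = 1.0 / cnt
            target = np.where(sub.mask, sub.y, 0.0)
            resid = nn.mul(nn.sub(preds, nn.Tensor(target)),
                           nn.Tensor(sub.mask.astype(float)))
            loss = nn.tsum(nn.mul(nn.mul(resid, resid), nn.Tensor(weight)))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        eval_rmse = evaluate(model, eval_set)
        combined = combined_rmse(eval_rmse)
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "eval_rmse": eval_rmse, "eval_combined": combined})
        if combined < best.best_eval_combined:
            best.best_eval_combined = combined
            best.best_epoch = epoch
            best.best_weights = model.get_weights()
            best.eval_rmse = eval_rmse
    model.set_weights(best.best_weights)
    return best


def best_of_runs(results: list[TrainResult]) -> TrainResult:
    """Pick the run with the lowest test combined RMSE (earliest run wins
    ties)."""
    if not results:
        raise ValueError("need at least one run")
    keys = [r.test_combined for r in results]
    return results[int(np.argmin(keys))]
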