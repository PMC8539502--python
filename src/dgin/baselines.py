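"""Classical-ML baselines on fingerprints (+/- descriptors) and consensus.

Eight featurization settings (four fingerprints x with/without standardized
RDKit descriptors) feed single-task random-forest, support-vector and
k-nearest-neighbor regressors at their library defaults.  Consensus models
average the predictions of two models element-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

FINGERPRINTS = ("ECFP-1024", "ECFP-1536", "ECFP-2048", "MACCS")
BASELINE_KINDS = ("RF", "SVM", "KNN")
ECFP_RADIUS = 4  # circular-fingerprint radius parameter (diameter 8)


@dataclass(frozen=True)
class BaselineSetting:
    fingerprint: str
    with_descriptors: bool

    @property
    def name(self) -> str:
        suffix = "+desc" if self.with_descriptors else ""
        return f"{self.fingerprint}{suffix}"


def enumerate_settings() -> list[BaselineSetting]:
    """All 8 settings: 4 fingerprints x 2 descriptor options."""
    return [BaselineSetting(fp, d) for fp in FINGERPRINTS for d in (False, True)]


class DescriptorStandardizer:
    """Z-scores the full RDKit descriptor block, fitted on training data.

    Constant descriptors keep deviation 1 so standardization never divides by
    zero (scikit-learn's StandardScaler already guarantees this).
    """

    def __init__(self):
        from sklearn.preprocessing import StandardScaler

        self.scaler = StandardScaler()
        self.names: list[str] | None = None

    def _raw(self, rdmol) -> np.ndarray:
        from rdkit.Chem import Descriptors

        values = Descriptors.CalcMolDescriptors(rdmol)
        if self.names is None:
            self.names = sorted(values)
        vec = np.array([values[k] for k in self.names], dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ValueError("descriptor computation produced non-finite values")
        return vec

    def fit(self, rdmols) -> "DescriptorStandardizer":
        X = np.stack([self._raw(m) for m in rdmols])
        self.scaler.fit(X)
        logger.info("fitted descriptor standardizer on %d descriptors", X.shape[1])
        return self

    @property
    def n_descriptors(self) -> int:
        return len(self.names) if self.names else 0

    def transform(self, rdmol) -> np.ndarray:
        return self.scaler.transform(self._raw(rdmol)[None, :])[0]


def _fingerprint(rdmol, fingerprint: str) -> np.ndarray:
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    if fingerprint == "MACCS":
        return np.array(MACCSkeys.GenMACCSKeys(rdmol), dtype=float)
    if fingerprint.startswith("ECFP-"):
        n_bits = int(fingerprint.split("-")[1])
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=ECFP_RADIUS, fpSize=n_bits
        )
        return np.array(gen.GetFingerprint(rdmol), dtype=float)
    raise ValueError(f"unknown fingerprint {fingerprint!r}")


def featurize_baseline(
    smiles: str,
    setting: BaselineSetting,
    standardizer: DescriptorStandardizer | None = None,
) -> np.ndarray:
    """Fingerprint of the configured type, optionally concatenated with the
    standardized descriptor block."""
    from rdkit import Chem

    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = _fingerprint(rdmol, setting.fingerprint)
    if not setting.with_descriptors:
        return fp
    if standardizer is None:
        raise ValueError("descriptor setting requires a fitted standardizer")
    return np.concatenate([fp, standardizer.transform(rdmol)])


def featurize_many(
    smiles_list, setting: BaselineSetting,
    standardizer: DescriptorStandardizer | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Featurize a list; molecules whose descriptors fail are dropped with a
    warning.  Returns the matrix and the kept indices."""
    rows, kept = [], []
    for i, smi in enumerate(smiles_list):
        try:
            rows.append(featurize_baseline(smi, setting, standardizer))
            kept.append(i)
        except ValueError as exc:
            logger.warning("dropping record %d (%s): %s", i, smi, exc)
    return np.stack(rows), kept


def fit_baseline(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0,
                 **kwargs):
    """Fit a single-task RF / SVM / KNN regressor at default hyperparameters."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to fit a regressor")
    if kind == "RF":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(random_state=seed, **kwargs)
    elif kind == "SVM":
        from sklearn.svm import SVR

        model = SVR(**kwargs)
    elif kind == "KNN":
        from sklearn.neighbors import KNeighborsRegressor

        model = KNeighborsRegressor(**kwargs)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; valid: {BASELINE_KINDS}")
    model.fit(X, y)
    return model


def consensus(pred_a, pred_b) -> np.ndarray:
    """Element-wise mean of two prediction vectors."""
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if pred_a.shape != pred_b.shape:
        raise ValueError(f"length mismatch: {pred_a.shape} vs {pred_b.shape}")
    return (pred_a + pred_b) / 2.0
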