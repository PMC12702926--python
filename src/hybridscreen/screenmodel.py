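"""ECFP4 featurization, the MLP bioactivity classifier, and evaluation metrics.

The classifier is a small feed-forward network — 2048-bit Morgan fingerprint
input, two ReLU hidden layers of 512 and 128 units with a 20% dropout layer
between them, and a single sigmoid output — trained with Adam (lr 1e-3) on
binary cross-entropy for 20 epochs at batch size 32.  It is implemented
directly on NumPy so that the exact architecture (including dropout) is
expressed, training is bit-reproducible from a single seed, and weights
persist as a portable ``.npz`` + JSON spec with no pickled code.

The training fingerprint matrix is retained with the model: downstream triage
uses it as the reference set for the Tanimoto applicability domain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .chemio import InputError, MoleculeRecord


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan/ECFP parameterization; defaults give standard 2048-bit ECFP4."""

    radius: int = 2
    n_bits: int = 2048
    counts: bool = False
    use_chirality: bool = False

    def __post_init__(self):
        n = self.n_bits
        if n < 256 or (n & (n - 1)) != 0:
            raise ValueError("n_bits must be a power of two >= 256")

    def generator(self):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius,
            fpSize=self.n_bits,
            includeChirality=self.use_chirality,
        )


def featurize(
    records: Sequence[MoleculeRecord] | Sequence[Chem.Mol],
    spec: FingerprintSpec = FingerprintSpec(),
) -> tuple[np.ndarray, list[int]]:
    """Fingerprint a list of records (or raw mols) into a (n, n_bits) uint8 matrix.

    Row order matches input order with unfingerprintable entries removed; the
    second return value lists the skipped input indices.
    """
    gen = spec.generator()
    rows, skipped = [], []
    for i, rec in enumerate(records):
        mol = rec.mol if isinstance(rec, MoleculeRecord) else rec
        if mol is None:
            skipped.append(i)
            continue
        if spec.counts:
            fp = gen.GetCountFingerprintAsNumPy(mol)
        else:
            fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=np.uint8))
    if not rows:
        raise InputError("no molecule could be fingerprinted")
    return np.vstack(rows), skipped


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_stratified(
    records: Sequence[MoleculeRecord], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Stratified, seeded train/test split preserving class balance within 1."""
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise InputError("all records need labels for a stratified split")
    if len(set(labels)) < 2:
        raise InputError("stratified split needs both classes present")
    train, test = train_test_split(
        list(records),
        test_size=test_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return list(train), list(test)


# ---------------------------------------------------------------------------
# the MLP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    hidden: tuple[int, int] = (512, 128)
    activation: str = "relu"
    dropout: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.learning_rate, self.epochs, self.batch_size, *self.hidden) <= 0:
            raise ValueError("all hyperparameters must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class TrainedClassifier:
    """A trained MLP plus the fingerprint context it was trained in.

    Holds the weight matrices, the per-epoch loss trace, and the training
    fingerprints (kept for the applicability-domain filter downstream).
    """

    def __init__(
        self,
        spec: ModelSpec,
        fp_spec: FingerprintSpec,
        weights: dict[str, np.ndarray],
        training_fps: np.ndarray,
        loss_trace: Optional[list[float]] = None,
    ):
        self.spec = spec
        self.fp_spec = fp_spec
        self.weights = weights
        self.training_fps = training_fps
        self.loss_trace = loss_trace or []

    # -- inference ----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> np.ndarray:
        w = self.weights
        h1 = np.maximum(X @ w["W1"] + w["b1"], 0.0)
        # dropout is train-time only; at inference the layer is identity
        h2 = np.maximum(h1 @ w["W2"] + w["b2"], 0.0)
        return _sigmoid(h2 @ w["W3"] + w["b3"]).ravel()

    def predict_proba(
        self, records: Sequence[MoleculeRecord] | np.ndarray
    ) -> np.ndarray:
        """Probability of the active class, one value in [0,1] per input."""
        if isinstance(records, np.ndarray):
            X = records.astype(np.float64)
        else:
            X, skipped = featurize(records, self.fp_spec)
            if skipped:
                raise InputError(f"unfingerprintable records at indices {skipped}")
            X = X.astype(np.float64)
        return self._forward(X)

    def predict(self, records, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(records) >= threshold).astype(int)

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        """Model directory = spec.json + weights.npz + training_fps.npz."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "model_spec": {**asdict(self.spec), "hidden": list(self.spec.hidden)},
            "fingerprint_spec": asdict(self.fp_spec),
            "loss_trace": self.loss_trace,
        }
        (d / "spec.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        np.savez_compressed(d / "weights.npz", **self.weights)
        np.savez_compressed(
            d / "training_fps.npz", fps=np.packbits(self.training_fps, axis=1),
            n_bits=np.array([self.training_fps.shape[1]]),
        )

    @classmethod
    def load(cls, directory) -> "TrainedClassifier":
        d = Path(directory)
        meta = json.loads((d / "spec.json").read_text())
        ms = meta["model_spec"]
        ms["hidden"] = tuple(ms["hidden"])
        with np.load(d / "weights.npz") as z:
            weights = {k: z[k] for k in z.files}
        with np.load(d / "training_fps.npz") as z:
            n_bits = int(z["n_bits"][0])
            fps = np.unpackbits(z["fps"], axis=1)[:, :n_bits]
        return cls(
            spec=ModelSpec(**ms),
            fp_spec=FingerprintSpec(**meta["fingerprint_spec"]),
            weights=weights,
            training_fps=fps.astype(np.uint8),
            loss_trace=meta.get("loss_trace", []),
        )


def train(
    train_records: Sequence[MoleculeRecord],
    model_spec: ModelSpec = ModelSpec(),
    fp_spec: FingerprintSpec = FingerprintSpec(),
) -> TrainedClassifier:
    """Train the MLP on fingerprinted records; fully reproducible per seed.

    One seed drives weight initialization, per-epoch shuffling, and the
    dropout masks.  Returns the classifier with its per-epoch mean BCE loss
    trace attached.
    """
    labels = np.array([r.label for r in train_records], dtype=float)
    if np.any(np.isnan(labels)) or len(np.unique(labels)) < 2:
        raise InputError("training needs records of both classes with 0/1 labels")
    X_u8, skipped = featurize(train_records, fp_spec)
    if skipped:
        labels = np.delete(labels, skipped)
    X = X_u8.astype(np.float64)
    return _fit(X, labels, model_spec, fp_spec, training_fps=X_u8)


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    fp_spec: FingerprintSpec,
    training_fps: np.ndarray,
) -> TrainedClassifier:
    rng = np.random.default_rng(spec.seed)
    n, d = X.shape
    h1, h2 = spec.hidden
    # He initialization for the ReLU layers
    w = {
        "W1": rng.normal(0, np.sqrt(2.0 / d), (d, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0, np.sqrt(2.0 / h1), (h1, h2)),
        "b2": np.zeros(h2),
        "W3": rng.normal(0, np.sqrt(2.0 / h2), (h2, 1)),
        "b3": np.zeros(1),
    }
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(val) for k, val in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    keep = 1.0 - spec.dropout
    t = 0
    loss_trace: list[float] = []

    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = X[idx], y[idx]
            b = len(idx)

            z1 = xb @ w["W1"] + w["b1"]
            a1 = np.maximum(z1, 0.0)
            if spec.dropout > 0:
                mask = (rng.random(a1.shape) < keep) / keep  # inverted dropout
                a1d = a1 * mask
            else:
                mask = None
                a1d = a1
            z2 = a1d @ w["W2"] + w["b2"]
            a2 = np.maximum(z2, 0.0)
            z3 = (a2 @ w["W3"] + w["b3"]).ravel()
            p = _sigmoid(z3)

            p_c = np.clip(p, 1e-12, 1 - 1e-12)
            epoch_losses.append(
                float(-np.mean(yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c)))
            )

            # backprop: d(BCE)/dz3 = p - y
            dz3 = ((p - yb) / b)[:, None]
            gW3 = a2.T @ dz3
            gb3 = dz3.sum(0)
            da2 = dz3 @ w["W3"].T
            dz2 = da2 * (z2 > 0)
            gW2 = a1d.T @ dz2
            gb2 = dz2.sum(0)
            da1 = dz2 @ w["W2"].T
            if mask is not None:
                da1 = da1 * mask
            dz1 = da1 * (z1 > 0)
            gW1 = xb.T @ dz1
            gb1 = dz1.sum(0)

            grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
            t += 1
            for k in w:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                w[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        loss_trace.append(float(np.mean(epoch_losses)))

    return TrainedClassifier(spec, fp_spec, w, training_fps, loss_trace)


def predict_proba(classifier: TrainedClassifier, records) -> np.ndarray:
    """Module-level convenience wrapper around ``classifier.predict_proba``."""
    return classifier.predict_proba(records)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricPanel:
    """Confusion counts and the derived classification-report panel.

    Undefined ratios (zero denominators) are reported as None; ``roc_auc`` is
    None when it was not computable (hard labels only, or a single class).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: dict  # class -> value
    recall: dict
    f1: dict
    support: dict
    macro_avg: dict  # {"precision": .., "recall": .., "f1": ..}
    weighted_avg: dict
    roc_auc: Optional[float] = None
    auc_error: Optional[str] = None

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)

    def rounded(self, ndigits: int = 3) -> dict:
        """Classification-report style dict rounded for display."""
        rnd = lambda x: None if x is None else round(x, ndigits)
        return {
            "accuracy": rnd(self.accuracy),
            "precision": {k: rnd(v) for k, v in self.precision.items()},
            "recall": {k: rnd(v) for k, v in self.recall.items()},
            "f1": {k: rnd(v) for k, v in self.f1.items()},
            "macro_avg": {k: rnd(v) for k, v in self.macro_avg.items()},
            "weighted_avg": {k: rnd(v) for k, v in self.weighted_avg.items()},
            "support": self.support,
            "roc_auc": rnd(self.roc_auc),
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> MetricPanel:
    """Full metric panel from confusion counts, in exact rational arithmetic."""
    if min(tp, fp, tn, fn) < 0:
        raise InputError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise InputError("empty confusion matrix")

    def ratio(num: int, den: int) -> Optional[float]:
        return float(Fraction(num, den)) if den > 0 else None

    prec = {1: ratio(tp, tp + fp), 0: ratio(tn, tn + fn)}
    rec = {1: ratio(tp, tp + fn), 0: ratio(tn, tn + fp)}

    def f1_of(p, r):
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    f1 = {c: f1_of(prec[c], rec[c]) for c in (0, 1)}
    support = {1: tp + fn, 0: tn + fp}

    def avg(d, weights=None):
        vals = {c: d[c] for c in (0, 1)}
        if any(v is None for v in vals.values()):
            present = {c: v for c, v in vals.items() if v is not None}
            if not present:
                return None
            vals = present
        if weights is None:
            return float(np.mean(list(vals.values())))
        wsum = sum(weights[c] for c in vals)
        return sum(vals[c] * weights[c] for c in vals) / wsum if wsum else None

    macro = {"precision": avg(prec), "recall": avg(rec), "f1": avg(f1)}
    weighted = {
        "precision": avg(prec, support),
        "recall": avg(rec, support),
        "f1": avg(f1, support),
    }
    return MetricPanel(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=float(Fraction(tp + tn, n)),
        precision=prec, recall=rec, f1=f1, support=support,
        macro_avg=macro, weighted_avg=weighted,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic ROC-AUC with midrank tie handling (Mann–Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("ROC-AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricPanel:
    """Threshold probabilities at 0.5 (active iff p >= threshold) and report
    the confusion matrix, derived metrics, and rank-based ROC-AUC."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) != len(y):
        raise InputError("probabilities and labels differ in length")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    panel = metrics_from_confusion(tp, fp, tn, fn)
    try:
        panel.roc_auc = roc_auc(p, y)
    except InputError as exc:
        panel.auc_error = str(exc)
    return panel


def probability_histogram(
    probabilities: np.ndarray, bin_edges: Optional[np.ndarray] = None
) -> dict:
    """Histogram of prediction probabilities plus the confidence fractions
    used to characterize a screen: p > 0.9 (high confidence) and
    p in [0.4, 0.6] (ambiguous)."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise InputError("probabilities must lie in [0, 1]")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    counts, edges = np.histogram(p, bins=bin_edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "n": int(p.size),
        "fraction_above_0.9": float(np.mean(p > 0.9)) if p.size else 0.0,
        "fraction_mid_0.4_0.6": float(np.mean((p >= 0.4) & (p <= 0.6))) if p.size else 0.0,
    }
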