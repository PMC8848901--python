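"""On-target scoring: a logistic position-weight model and a linear SVR.

Two scorers share one feature encoding.  The 30-base scoring context is
expanded into a first-order one-hot matrix (position x base, L x 4) and a
second-order one-hot matrix over adjacent dinucleotides ((L-1) x 16); the
two are flattened row-major into a single vector of length 4L + 16(L-1)
(584 for the default 30-mer).

The logistic scorer computes

    f(s) = 1 / (1 + exp(-(intercept + k + sum(W1*X1) + sum(W2*X2))))

where k is a GC-content offset over the 20-base guide portion
(k = -0.2026259 below 50% GC, -0.1665878 at or above 50%) and the
intercept defaults to 0.59763615.  The weight matrices are supplied by
the user via a parameter file (the published matrices are not bundled);
with zero weights the scorer reduces to its closed-form branch values.

The SVR scorer is a linear epsilon-insensitive regressor trained to
predict the per-gene percentile rank of measured guide efficacy — a
continuous score rather than a pass/fail class, so lower-scoring guides
remain accessible to the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import r2_score
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.svm import LinearSVR

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCS = [a + b for a in BASES for b in BASES]
DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}

DEFAULT_INTERCEPT = 0.59763615
DEFAULT_K_LOW = -0.2026259
DEFAULT_K_HIGH = -0.1665878


class EncodingError(ValueError):
    pass


class ScorerConfigError(ValueError):
    pass


class TrainingError(ValueError):
    pass


@dataclass
class OneHotFeatures:
    first_order: np.ndarray   # L x 4
    second_order: np.ndarray  # (L-1) x 16

    @property
    def flat_vector(self) -> np.ndarray:
        return np.concatenate([self.first_order.ravel(), self.second_order.ravel()])


def flat_length(context_length: int) -> int:
    return 4 * context_length + 16 * (context_length - 1)


def encode(context_seq: str) -> OneHotFeatures:
    """One-hot encode a context sequence (A,C,G,T only)."""
    L = len(context_seq)
    bad = set(context_seq) - set(BASES)
    if bad:
        raise EncodingError(f"cannot encode characters {sorted(bad)}")
    first = np.zeros((L, 4))
    second = np.zeros((L - 1, 16))
    for i, b in enumerate(context_seq):
        first[i, BASE_INDEX[b]] = 1.0
    for i in range(L - 1):
        second[i, DINUC_INDEX[context_seq[i : i + 2]]] = 1.0
    return OneHotFeatures(first, second)


def decode(features: OneHotFeatures) -> str:
    """Inverse of encode (test helper: encode must be a bijection)."""
    idx = features.first_order.argmax(axis=1)
    return "".join(BASES[i] for i in idx)


def encode_matrix(contexts: list[str]) -> np.ndarray:
    """Stack flat feature vectors for a batch of equal-length contexts."""
    return np.vstack([encode(c).flat_vector for c in contexts])


def feature_rowspace(context_length: int = 30, n_probe: int = 3000, seed: int = 123) -> np.ndarray:
    """Orthonormal basis of the identifiable weight subspace.

    The flat one-hot encoding is redundant: every block of indicator columns
    sums to one, and each first-order column is a marginal sum of sixteen
    second-order columns, so distinct weight vectors can induce identical
    scores.  Weight comparisons (e.g. parameter-recovery checks) are only
    meaningful after projecting onto the row space of the centered design,
    estimated here from a seeded probe sample of random contexts.
    Returns a (rank, n_features) matrix with orthonormal rows.
    """
    rng = np.random.default_rng(seed)
    contexts = [
        "".join(np.array(list(BASES))[rng.integers(0, 4, size=context_length)]) for _ in range(n_probe)
    ]
    X = encode_matrix(contexts)
    Xc = X - X.mean(axis=0)
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-8 * s[0]).sum())
    return vt[:rank]


def identifiable_cosine(w_a: np.ndarray, w_b: np.ndarray, basis: np.ndarray | None = None) -> float:
    """Cosine similarity of two weight vectors inside the identifiable subspace."""
    if basis is None:
        basis = feature_rowspace()
    pa, pb = basis @ w_a, basis @ w_b
    return float(pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb)))


@dataclass
class ScoringConstants:
    """Parameters of the logistic scorer."""

    context_length: int = 30
    guide_length: int = 20
    context_flank: int = 5
    intercept: float = DEFAULT_INTERCEPT
    k_low: float = DEFAULT_K_LOW
    k_high: float = DEFAULT_K_HIGH
    gc_threshold: float = 0.5
    w1: np.ndarray = field(default=None)  # type: ignore[assignment]
    w2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.w1 is None:
            self.w1 = np.zeros((self.context_length, 4))
        if self.w2 is None:
            self.w2 = np.zeros((self.context_length - 1, 16))
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.shape != (self.context_length, 4):
            raise ScorerConfigError(f"w1 shape {self.w1.shape} != {(self.context_length, 4)}")
        if self.w2.shape != (self.context_length - 1, 16):
            raise ScorerConfigError(f"w2 shape {self.w2.shape} != {(self.context_length - 1, 16)}")

    @classmethod
    def from_file(cls, path: str) -> "ScoringConstants":
        """Load constants from a JSON parameter file.

        Keys: intercept, k_low, k_high, gc_threshold (scalars, optional) and
        w1 / w2 as dense nested lists, or sparse lists of [row, col, weight].
        """
        with open(path) as fh:
            raw = json.load(fh)
        L = int(raw.get("context_length", 30))
        kwargs = dict(
            context_length=L,
            intercept=float(raw.get("intercept", DEFAULT_INTERCEPT)),
            k_low=float(raw.get("k_low", DEFAULT_K_LOW)),
            k_high=float(raw.get("k_high", DEFAULT_K_HIGH)),
            gc_threshold=float(raw.get("gc_threshold", 0.5)),
        )
        for key, shape in (("w1", (L, 4)), ("w2", (L - 1, 16))):
            if key not in raw:
                continue
            val = raw[key]
            if val and isinstance(val[0], list) and len(val[0]) == 3 and shape[1] != 3:
                mat = np.zeros(shape)
                for r, c, w in val:
                    mat[int(r), int(c)] = float(w)
                kwargs[key] = mat
            else:
                kwargs[key] = np.asarray(val, dtype=float)
        return cls(**kwargs)


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def score_logistic(context_seq: str, constants: ScoringConstants | None = None) -> float:
    """Logistic on-target score of one scoring context, in (0, 1).

    The GC offset k is chosen from the GC fraction of the 20-base guide
    portion of the context (not the full 30-mer); the 50% boundary takes
    the high branch.
    """
    if constants is None:
        constants = ScoringConstants()
    if len(context_seq) != constants.context_length:
        raise ScorerConfigError(
            f"context length {len(context_seq)} != expected {constants.context_length}"
        )
    feats = encode(context_seq)
    guide = context_seq[constants.context_flank : constants.context_flank + constants.guide_length]
    k = constants.k_low if gc_fraction(guide) < constants.gc_threshold else constants.k_high
    total = (
        constants.intercept
        + k
        + float((constants.w1 * feats.first_order).sum())
        + float((constants.w2 * feats.second_order).sum())
    )
    return float(1.0 / (1.0 + np.exp(-total)))


@dataclass
class TrainingSet:
    """Rows of (30-mer context, gene group label, rank in [0,1])."""

    contexts: list[str]
    gene_ids: list[str]
    ranks: np.ndarray

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=float)
        n = len(self.contexts)
        if not (len(self.gene_ids) == n == len(self.ranks)):
            raise TrainingError("contexts, gene_ids and ranks must be the same length")
        if n and (self.ranks.min() < 0 or self.ranks.max() > 1):
            raise TrainingError("ranks must lie in [0, 1]")
        lengths = {len(c) for c in self.contexts}
        if len(lengths) > 1:
            raise TrainingError(f"mixed context lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.contexts)

    @classmethod
    def from_tsv(cls, path: str) -> "TrainingSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["context_seq"].tolist(), df["gene_id"].astype(str).tolist(), df["rank"].to_numpy())

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {"context_seq": self.contexts, "gene_id": self.gene_ids, "rank": self.ranks}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SvrModel:
    weights: np.ndarray
    bias: float
    C: float = 1.0
    epsilon: float = 0.1
    trained_on: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X @ self.weights + self.bias, 0.0, 1.0)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "C": self.C,
                    "epsilon": self.epsilon,
                    "trained_on": self.trained_on,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str) -> "SvrModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            weights=np.asarray(raw["weights"], dtype=float),
            bias=float(raw["bias"]),
            C=float(raw.get("C", 1.0)),
            epsilon=float(raw.get("epsilon", 0.1)),
            trained_on=raw.get("trained_on", ""),
        )


def train_svr(data: TrainingSet, C: float = 1.0, epsilon: float = 0.1, seed: int = 0) -> SvrModel:
    """Fit the linear epsilon-insensitive rank regressor.

    Deterministic given the data and seed.  Requires at least two distinct
    gene groups so leave-one-group-out evaluation remains possible.
    """
    if len(data) < 2:
        raise TrainingError("need at least two training rows")
    if len(set(data.gene_ids)) < 2:
        raise TrainingError("need at least two distinct gene groups")
    X = encode_matrix(data.contexts)
    reg = LinearSVR(C=C, epsilon=epsilon, random_state=seed, max_iter=20000, tol=1e-5)
    reg.fit(X, data.ranks)
    import hashlib

    fingerprint = hashlib.sha1(
        ("|".join(data.contexts) + "|" + ",".join(f"{r:.6f}" for r in data.ranks)).encode()
    ).hexdigest()[:12]
    return SvrModel(
        weights=np.asarray(reg.coef_, dtype=float).ravel(),
        bias=float(np.atleast_1d(reg.intercept_)[0]),
        C=C,
        epsilon=epsilon,
        trained_on=fingerprint,
    )


def score_svr(context_seq: str, model: SvrModel) -> float:
    """Clipped linear prediction in [0, 1] for one context."""
    x = encode(context_seq).flat_vector
    if x.shape[0] != model.weights.shape[0]:
        raise ScorerConfigError(
            f"feature length {x.shape[0]} != model weight length {model.weights.shape[0]}"
        )
    return float(model.predict(x[None, :])[0])


def evaluate_logo(data: TrainingSet, C: float = 1.0, epsilon: float = 0.1, seed: int = 0) -> dict:
    """Leave-one-group-out cross-validation of the SVR scorer.

    Each gene group is held out in turn; the model is refit on the rest and
    predicts the held-out guides.  Returns per-group and pooled r² and
    Pearson r over all held-out predictions.
    """
    groups = np.asarray(data.gene_ids)
    if len(set(data.gene_ids)) < 3:
        raise TrainingError("leave-one-group-out needs at least three groups")
    X = encode_matrix(data.contexts)
    y = data.ranks
    logo = LeaveOneGroupOut()
    pooled_pred = np.empty_like(y)
    per_group: dict[str, dict[str, float]] = {}
    for train_idx, test_idx in logo.split(X, y, groups):
        reg = LinearSVR(C=C, epsilon=epsilon, random_state=seed, max_iter=20000, tol=1e-5)
        reg.fit(X[train_idx], y[train_idx])
        pred = np.clip(X[test_idx] @ reg.coef_.ravel() + float(np.atleast_1d(reg.intercept_)[0]), 0, 1)
        pooled_pred[test_idx] = pred
        gname = str(groups[test_idx][0])
        metrics = {"r2": float(r2_score(y[test_idx], pred)) if len(test_idx) > 1 else float("nan")}
        if len(test_idx) > 1 and np.std(pred) > 0 and np.std(y[test_idx]) > 0:
            metrics["pearson_r"] = float(pearsonr(y[test_idx], pred)[0])
        else:
            metrics["pearson_r"] = float("nan")
        per_group[gname] = metrics
    pooled = {
        "r2": float(r2_score(y, pooled_pred)),
        "pearson_r": float(pearsonr(y, pooled_pred)[0]) if np.std(pooled_pred) > 0 else float("nan"),
    }
    return {"per_group": per_group, "pooled": pooled}
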