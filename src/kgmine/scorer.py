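"""Neural edge scoring: an 11-feature feed-forward regressor.

A knowledge graph mined from heterogeneous supplementary tables carries
edges whose statistics mean different things (different tests, corrections,
cohort sizes, mapping databases). A small feed-forward network regresses a
single strictly positive score per edge from 11 mixed-type features,
serving as a centralized semantic unifier so that edges become comparable
and usable as weights in centrality analyses.

The 11 features: p_value, adjusted_p, sample_size, effect_size (numeric);
fdr_corrected, statistical_test, nlp_type, subject_map_db, object_map_db
(categorical); notes, caption (free text). Numeric features are z-scored
(nulls imputed at the training mean, i.e. encode to 0), categoricals are
label-encoded with index 0 reserved for unknown, and free text goes through
a pluggable embedder — the default is deterministic feature hashing of word
unigrams into 64 dimensions, so nothing needs a download and every encoding
is reproducible bit-for-bit.

Architecture: three linear layers (in -> 256 -> 64 -> 1) delimited by
LeakyReLU (slope 0.01), dropout 0.2 between the two largest layers
(training only), and a Softplus on the output so scores are strictly
positive. Training minimizes Huber / SmoothL1 loss (transition 1) with a
hand-rolled Adam optimizer, full batch, under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
from scipy.special import expit

from .graph import Edge, KnowledgeGraph

NUMERIC_FEATURES = ("p_value", "adjusted_p", "sample_size", "effect_size")
CATEGORICAL_FEATURES = (
    "fdr_corrected", "statistical_test", "nlp_type",
    "subject_map_db", "object_map_db",
)
TEXT_FEATURES = ("notes", "caption")

FDR_CORRECTING_METHODS = {"benjamini_hochberg", "bonferroni"}

DEFAULT_EMBED_DIM = 64
DEFAULT_HIDDEN = (256, 64)
LEAKY_SLOPE = 0.01
DROPOUT_RATE = 0.2


class TrainingError(RuntimeError):
    pass


@dataclass
class EdgeFeatureRecord:
    """The fixed-order 11-feature view of one edge."""

    p_value: Optional[float] = None
    adjusted_p: Optional[float] = None
    sample_size: Optional[int] = None
    fdr_corrected: str = "unknown"
    effect_size: Optional[float] = None
    statistical_test: str = ""
    nlp_type: str = ""
    subject_map_db: str = ""
    object_map_db: str = ""
    notes: str = ""
    caption: str = ""

    def __post_init__(self) -> None:
        assert len(dc_fields(self)) == 11


def assemble_features(edge: Edge) -> EdgeFeatureRecord:
    """Project an edge's attribute map onto the 11-feature record.

    ``fdr_corrected`` is true iff the correction method is a multiple-testing
    correction (Benjamini–Hochberg or Bonferroni), false when the method is
    explicitly ``none``, and unknown otherwise.
    """
    a = edge.attributes
    method = a.get("correction_method")
    if method in FDR_CORRECTING_METHODS:
        fdr = "true"
    elif method == "none":
        fdr = "false"
    else:
        fdr = "unknown"
    return EdgeFeatureRecord(
        p_value=a.get("p_value"),
        adjusted_p=a.get("adjusted_p"),
        sample_size=a.get("sample_size"),
        fdr_corrected=fdr,
        effect_size=a.get("effect_size"),
        statistical_test=str(a.get("statistical_test") or ""),
        nlp_type=str(a.get("nlp_type") or ""),
        subject_map_db=str(a.get("subject_map_db") or ""),
        object_map_db=str(a.get("object_map_db") or ""),
        notes=str(a.get("notes") or ""),
        caption=str(a.get("caption") or ""),
    )


# ---------------------------------------------------------------------------
# Text embedding


class HashingEmbedder:
    """Deterministic word-unigram feature hashing with l2 normalization.

    Each token is hashed (md5, so stable across processes and platforms) to
    a coordinate and a sign; the token-count vector is then l2-normalized.
    Empty text embeds to the zero vector. A transformer pooler output can be
    dropped in behind the same two-method contract (``dim``, ``embed``).
    """

    embedder_id = "hashing-unigram-v1"

    def __init__(self, dim: int = DEFAULT_EMBED_DIM) -> None:
        self.dim = int(dim)

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        tokens = text.lower().split()
        if not tokens:
            return vec
        for tok in tokens:
            digest = hashlib.md5(tok.encode("utf-8")).digest()
            idx = int.from_bytes(digest[:4], "little") % self.dim
            sign = 1.0 if digest[4] % 2 == 0 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def embed_text(text: str, embedder: HashingEmbedder | None = None) -> np.ndarray:
    embedder = embedder or HashingEmbedder()
    return embedder.embed(text)


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessorState:
    """Frozen training-set statistics used to encode records.

    Numeric features carry their training mean/sd (zero-variance features
    get sd 1 so encodings stay finite); categoricals carry a frozen
    vocabulary with index 0 reserved for values unseen at fit time.
    """

    numeric_mean: dict[str, float]
    numeric_sd: dict[str, float]
    vocab: dict[str, dict[str, int]]
    embedder_id: str = HashingEmbedder.embedder_id
    embed_dim: int = DEFAULT_EMBED_DIM

    @property
    def input_dim(self) -> int:
        return (
            len(NUMERIC_FEATURES)
            + len(CATEGORICAL_FEATURES)
            + len(TEXT_FEATURES) * self.embed_dim
        )


def fit_preprocessor(
    records: Sequence[EdgeFeatureRecord],
    embedder: HashingEmbedder | None = None,
) -> PreprocessorState:
    if len(records) < 2:
        raise ValueError("need at least 2 records to fit the preprocessor")
    embedder = embedder or HashingEmbedder()
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for feat in NUMERIC_FEATURES:
        vals = [getattr(r, feat) for r in records if getattr(r, feat) is not None]
        if vals:
            m = float(np.mean(vals))
            s = float(np.std(vals))
        else:
            m, s = 0.0, 1.0
        mean[feat] = m
        sd[feat] = s if s > 0 else 1.0
    vocab: dict[str, dict[str, int]] = {}
    for feat in CATEGORICAL_FEATURES:
        levels = sorted({str(getattr(r, feat)) for r in records})
        vocab[feat] = {lvl: i + 1 for i, lvl in enumerate(levels)}  # 0 = unknown
    return PreprocessorState(
        numeric_mean=mean,
        numeric_sd=sd,
        vocab=vocab,
        embedder_id=embedder.embedder_id,
        embed_dim=embedder.dim,
    )


def encode(
    record: EdgeFeatureRecord,
    state: PreprocessorState,
    embedder: HashingEmbedder | None = None,
) -> np.ndarray:
    """Encode one record to a vector of length ``state.input_dim``."""
    embedder = embedder or HashingEmbedder(state.embed_dim)
    if embedder.dim != state.embed_dim:
        raise ValueError(
            f"embedder dim {embedder.dim} != preprocessor dim {state.embed_dim}"
        )
    parts = []
    for feat in NUMERIC_FEATURES:
        v = getattr(record, feat)
        if v is None:
            parts.append(0.0)  # mean imputation == z-score 0
        else:
            parts.append((float(v) - state.numeric_mean[feat]) / state.numeric_sd[feat])
    for feat in CATEGORICAL_FEATURES:
        parts.append(float(state.vocab[feat].get(str(getattr(record, feat)), 0)))
    head = np.asarray(parts, dtype=np.float64)
    texts = [embedder.embed(getattr(record, feat)) for feat in TEXT_FEATURES]
    return np.concatenate([head] + texts)


def encode_batch(
    records: Sequence[EdgeFeatureRecord],
    state: PreprocessorState,
    embedder: HashingEmbedder | None = None,
) -> np.ndarray:
    return np.stack([encode(r, state, embedder) for r in records])


# ---------------------------------------------------------------------------
# Model


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def _leaky_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, LEAKY_SLOPE)


@dataclass
class ScorerModel:
    """Weights of the three-layer scoring network plus training metadata."""

    weights: list[np.ndarray]  # W1 (D,H1), W2 (H1,H2), W3 (H2,1)
    biases: list[np.ndarray]
    hyper: dict[str, Any] = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference pass (dropout disabled); output > 0."""
        h1 = _leaky(X @ self.weights[0] + self.biases[0])
        h2 = _leaky(h1 @ self.weights[1] + self.biases[1])
        z3 = h2 @ self.weights[2] + self.biases[2]
        return _softplus(z3).ravel()

    def checksum(self) -> str:
        h = hashlib.sha256()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path, state: PreprocessorState) -> None:
        """Self-describing JSON checkpoint: weights + preprocessor + seed."""
        payload = {
            "hyper": self.hyper,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "preprocessor": {
                "numeric_mean": state.numeric_mean,
                "numeric_sd": state.numeric_sd,
                "vocab": state.vocab,
                "embedder_id": state.embedder_id,
                "embed_dim": state.embed_dim,
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> tuple["ScorerModel", PreprocessorState]:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(
            weights=[np.asarray(w, dtype=np.float64) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in payload["biases"]],
            hyper=payload["hyper"],
        )
        p = payload["preprocessor"]
        state = PreprocessorState(
            numeric_mean=p["numeric_mean"],
            numeric_sd=p["numeric_sd"],
            vocab={k: dict(v) for k, v in p["vocab"].items()},
            embedder_id=p["embedder_id"],
            embed_dim=int(p["embed_dim"]),
        )
        return model, state


def _huber(r: np.ndarray) -> np.ndarray:
    a = np.abs(r)
    return np.where(a < 1.0, 0.5 * r * r, a - 0.5)


def _huber_grad(r: np.ndarray) -> np.ndarray:
    return np.clip(r, -1.0, 1.0)


def _init_params(
    dims: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_scorer(
    records: Sequence[EdgeFeatureRecord],
    labels: Sequence[float],
    hyper: dict[str, Any] | None = None,
    state: PreprocessorState | None = None,
    embedder: HashingEmbedder | None = None,
) -> tuple[ScorerModel, PreprocessorState, dict[str, float]]:
    """Fit the scoring network; returns (model, preprocessor, loss history).

    Full-batch Adam under a fixed seed: two runs with identical inputs give
    bit-identical weights on one platform. Labels are unconstrained
    nonnegative reals (the manual scoring scale need not be [0, 1]).
    """
    hyper = {"lr": 1e-3, "epochs": 200, "seed": 42, **(hyper or {})}
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    if len(records) < 10:
        raise ValueError("need at least 10 training records")
    y = np.asarray(labels, dtype=np.float64)
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite and >= 0")

    embedder = embedder or HashingEmbedder()
    if state is None:
        state = fit_preprocessor(records, embedder)
    X = encode_batch(records, state, embedder)
    n = X.shape[0]

    rng = np.random.default_rng(hyper["seed"])
    dims = [X.shape[1], *DEFAULT_HIDDEN, 1]
    W, B = _init_params(dims, rng)

    # Adam state
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mB = [np.zeros_like(b) for b in B]
    vB = [np.zeros_like(b) for b in B]
    lr, beta1, beta2, eps = hyper["lr"], 0.9, 0.999, 1e-8

    initial_loss = final_loss = None
    for epoch in range(1, int(hyper["epochs"]) + 1):
        z1 = X @ W[0] + B[0]
        h1 = _leaky(z1)
        mask = (rng.random(h1.shape) >= DROPOUT_RATE) / (1.0 - DROPOUT_RATE)
        h1d = h1 * mask
        z2 = h1d @ W[1] + B[1]
        h2 = _leaky(z2)
        z3 = h2 @ W[2] + B[2]
        pred = _softplus(z3).ravel()

        r = pred - y
        loss = float(np.mean(_huber(r)))
        if not math.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        if initial_loss is None:
            initial_loss = loss
        final_loss = loss

        dpred = _huber_grad(r) / n
        dz3 = (dpred * expit(z3.ravel()))[:, None]  # softplus' = sigmoid
        gW3 = h2.T @ dz3
        gB3 = dz3.sum(axis=0)
        dh2 = dz3 @ W[2].T
        dz2 = dh2 * _leaky_grad(z2)
        gW2 = h1d.T @ dz2
        gB2 = dz2.sum(axis=0)
        dh1 = (dz2 @ W[1].T) * mask
        dz1 = dh1 * _leaky_grad(z1)
        gW1 = X.T @ dz1
        gB1 = dz1.sum(axis=0)

        for i, (gw, gb) in enumerate([(gW1, gB1), (gW2, gB2), (gW3, gB3)]):
            mW[i] = beta1 * mW[i] + (1 - beta1) * gw
            vW[i] = beta2 * vW[i] + (1 - beta2) * gw * gw
            mB[i] = beta1 * mB[i] + (1 - beta1) * gb
            vB[i] = beta2 * vB[i] + (1 - beta2) * gb * gb
            mw_hat = mW[i] / (1 - beta1 ** epoch)
            vw_hat = vW[i] / (1 - beta2 ** epoch)
            mb_hat = mB[i] / (1 - beta1 ** epoch)
            vb_hat = vB[i] / (1 - beta2 ** epoch)
            W[i] -= lr * mw_hat / (np.sqrt(vw_hat) + eps)
            B[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)

    model = ScorerModel(weights=W, biases=B, hyper=dict(hyper))
    return model, state, {"initial_loss": initial_loss, "final_loss": final_loss}


# ---------------------------------------------------------------------------
# Applying the scorer


def score_edges(
    graph: KnowledgeGraph,
    model: ScorerModel,
    state: PreprocessorState,
    embedder: HashingEmbedder | None = None,
) -> KnowledgeGraph:
    """Set every edge's ``score`` attribute; the graph is otherwise unchanged."""
    if model.input_dim != state.input_dim:
        raise ValueError(
            f"model input dim {model.input_dim} != preprocessor layout "
            f"{state.input_dim}"
        )
    if graph.edges:
        X = encode_batch(
            [assemble_features(e) for e in graph.edges], state, embedder
        )
        scores = model.forward(X)
        for e, s in zip(graph.edges, scores):
            e.attributes["score"] = float(s)
    return graph


def score_distribution_summary(
    graph: KnowledgeGraph, bin_width: float = 5.0
) -> dict[str, Any]:
    """Summary statistics of the edge-score distribution.

    ``mode_count`` counts nonzero histogram bins that are >= both neighbors
    (a coarse multimodality indicator); ``mean_by_significance`` groups by
    the Boolean significance attribute (None = unknown).
    """
    scores = []
    for e in graph.edges:
        if e.score is None:
            raise ValueError(f"unscored edge: {e.subject} -> {e.object}")
        scores.append(e.score)
    arr = np.asarray(scores, dtype=np.float64)
    lo = math.floor(arr.min() / bin_width) * bin_width
    hi = math.ceil(arr.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    padded = np.concatenate([[0], counts, [0]])
    modes = sum(
        1
        for i in range(1, len(padded) - 1)
        if padded[i] > 0 and padded[i] >= padded[i - 1] and padded[i] >= padded[i + 1]
    )
    by_class: dict[Any, list[float]] = {}
    for e in graph.edges:
        by_class.setdefault(e.attributes.get("significant"), []).append(e.score)
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "histogram": {"bin_edges": edges.tolist(), "counts": counts.tolist()},
        "mode_count": modes,
        "mean_by_significance": {
            k: float(np.mean(v)) for k, v in by_class.items()
        },
    }
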