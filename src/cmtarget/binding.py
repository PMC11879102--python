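"""Compound-protein binding prediction from SMILES and amino-acid strings.

The classifier reads each pair as two character strings — the compound's
SMILES line notation and the protein's amino-acid sequence — and outputs the
probability that the compound binds the protein.  Each branch is featurized
by character n-gram counts (substructure tokens for SMILES, short sequence
words for proteins); the concatenated features feed a multilayer perceptron
trained with binary cross-entropy.  Pairs whose score clears a threshold
(default 0.90) are called binding targets; a multi-component preparation's
binding-target set is the union over its components.

Training data lists positives only in most interaction databases, so
negatives are sampled uniformly from unobserved compound-protein pairs at
1:1 with positives (seeded) when the caller does not supply them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

PAD, UNK = 0, 1

#: character vocabulary covering organic-subset SMILES plus common ions
SMILES_CHARS = list("#%()+-./0123456789=@[]\\BCFHIKLNOPSZacegilnoprstu")
SMILES_INDEX = {c: i + 2 for i, c in enumerate(SMILES_CHARS)}

AA_CHARS = list("ACDEFGHIKLMNPQRSTVWY") + ["X"]
AA_INDEX = {c: i + 2 for i, c in enumerate(AA_CHARS)}

DEFAULT_BINDING_THRESHOLD = 0.90
DEFAULT_MAX_SMILES_LEN = 100
DEFAULT_MAX_PROTEIN_LEN = 1000


@dataclass
class BindingPair:
    compound_id: str
    smiles: str
    protein_id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("empty SMILES")
        if not self.sequence:
            raise ValueError("empty protein sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class BindingScore:
    compound_id: str
    protein_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class TrainConfig:
    """Optimizer and encoding settings for the binding classifier.

    The historical full-scale configuration is learning_rate 0.0008, batch
    size 256 and 100 epochs; the default epoch count here is reduced for
    desk-scale datasets.
    """

    learning_rate: float = 0.0008
    batch_size: int = 256
    epochs: int = 30
    max_smiles_len: int = DEFAULT_MAX_SMILES_LEN
    max_protein_len: int = DEFAULT_MAX_PROTEIN_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs",
                     "max_smiles_len", "max_protein_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _tokenize(text: str, index: dict[str, int], max_len: int, kind: str) -> list[int]:
    tokens = []
    unknown = 0
    for ch in text[:max_len]:
        idx = index.get(ch, UNK)
        if idx == UNK:
            unknown += 1
        tokens.append(idx)
    if unknown:
        logger.warning("%d character(s) outside the %s vocabulary", unknown, kind)
    tokens.extend([PAD] * (max_len - len(tokens)))
    return tokens


def tokenize_smiles(smiles: str, max_len: int = DEFAULT_MAX_SMILES_LEN) -> list[int]:
    """Character-level SMILES indices, right-padded/truncated to ``max_len``."""
    if not smiles:
        raise ValueError("empty SMILES")
    return _tokenize("".join(smiles.split()), SMILES_INDEX, max_len, "SMILES")


def tokenize_protein(sequence: str, max_len: int = DEFAULT_MAX_PROTEIN_LEN) -> list[int]:
    """Amino-acid indices (input uppercased), right-padded/truncated."""
    if not sequence:
        raise ValueError("empty protein sequence")
    return _tokenize("".join(sequence.split()).upper(), AA_INDEX, max_len, "protein")


_SMILES_REVERSE = {v: k for k, v in SMILES_INDEX.items()}
_AA_REVERSE = {v: k for k, v in AA_INDEX.items()}


def detokenize_smiles(tokens: Sequence[int]) -> str:
    """Inverse of tokenize_smiles on the unpadded prefix (in-vocabulary)."""
    return "".join(_SMILES_REVERSE.get(t, "?") for t in tokens if t != PAD)


def detokenize_protein(tokens: Sequence[int]) -> str:
    return "".join(_AA_REVERSE.get(t, "?") for t in tokens if t != PAD)


def _truncated(pair: BindingPair, config: TrainConfig) -> tuple[str, str]:
    """Apply vocabulary normalization and length truncation to a pair."""
    s = detokenize_smiles(tokenize_smiles(pair.smiles, config.max_smiles_len))
    p = detokenize_protein(tokenize_protein(pair.sequence, config.max_protein_len))
    return s, p


@dataclass
class BindingModel:
    """Trained classifier with its featurizers and provenance."""

    smiles_vectorizer: CountVectorizer
    protein_vectorizer: CountVectorizer
    classifier: MLPClassifier
    config: TrainConfig
    loss_curve: list[float] = field(default_factory=list)
    auroc: float = float("nan")
    aupr: float = float("nan")

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "BindingModel":
        model = joblib.load(path)
        if not isinstance(model, BindingModel):
            raise ValueError("not a binding model file")
        return model


def _features(
    model_or_vecs: tuple[CountVectorizer, CountVectorizer],
    pairs: Sequence[BindingPair],
    config: TrainConfig,
) -> sparse.csr_matrix:
    sv, pv = model_or_vecs
    texts = [_truncated(p, config) for p in pairs]
    xs = sv.transform([t[0] for t in texts])
    xp = pv.transform([t[1] for t in texts])
    return sparse.hstack([xs, xp], format="csr")


def split_pairs(
    pairs: Sequence[BindingPair], seed: int, fractions=(0.8, 0.1, 0.1)
) -> tuple[list[BindingPair], list[BindingPair], list[BindingPair]]:
    """Seeded train/validation/test split by pair."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = int(round(fractions[0] * len(pairs)))
    n_val = int(round(fractions[1] * len(pairs)))
    idx = [order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]]
    return tuple([pairs[i] for i in part] for part in idx)  # type: ignore[return-value]


def sample_negatives(
    positives: Sequence[BindingPair], seed: int, ratio: float = 1.0
) -> list[BindingPair]:
    """Uniformly sampled unobserved compound-protein pairs labelled 0."""
    rng = np.random.default_rng(seed)
    compounds = sorted({(p.compound_id, p.smiles) for p in positives})
    proteins = sorted({(p.protein_id, p.sequence) for p in positives})
    observed = {(p.compound_id, p.protein_id) for p in positives}
    n_needed = int(round(ratio * len(positives)))
    negatives: list[BindingPair] = []
    attempts = 0
    while len(negatives) < n_needed and attempts < 100 * n_needed:
        c = compounds[rng.integers(len(compounds))]
        pr = proteins[rng.integers(len(proteins))]
        attempts += 1
        if (c[0], pr[0]) in observed:
            continue
        observed.add((c[0], pr[0]))
        negatives.append(BindingPair(c[0], c[1], pr[0], pr[1], label=0))
    if len(negatives) < n_needed:
        logger.warning(
            "could only sample %d/%d negatives", len(negatives), n_needed
        )
    return negatives


def train(
    pairs: Sequence[BindingPair], config: TrainConfig | None = None
) -> BindingModel:
    """Fit the binding classifier on labelled pairs.

    Holds out 10% validation + 10% test (seeded, by pair); reports the
    per-epoch training loss and the held-out-test AUROC/AUPR on the model.
    Raises on single-class input.
    """
    config = config or TrainConfig()
    labelled = [p for p in pairs if p.label is not None]
    if len(labelled) < 2:
        raise ValueError("need at least 2 labelled pairs")
    labels = {p.label for p in labelled}
    if labels != {0, 1}:
        raise ValueError("degenerate labels: both classes required")
    train_set, _val, test_set = split_pairs(labelled, config.seed)
    if len({p.label for p in train_set}) < 2:
        raise ValueError("degenerate labels in the training split")
    texts = [_truncated(p, config) for p in train_set]
    sv = CountVectorizer(analyzer="char", ngram_range=(2, 3), min_df=1)
    pv = CountVectorizer(analyzer="char", ngram_range=(2, 3), min_df=1)
    xs = sv.fit_transform([t[0] for t in texts])
    xp = pv.fit_transform([t[1] for t in texts])
    X = sparse.hstack([xs, xp], format="csr")
    y = np.array([p.label for p in train_set])
    clf = MLPClassifier(
        hidden_layer_sizes=(128, 64),
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(train_set)),
        max_iter=config.epochs,
        random_state=config.seed,
        solver="adam",
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # stopping at the configured epoch count is intentional
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    model = BindingModel(
        smiles_vectorizer=sv,
        protein_vectorizer=pv,
        classifier=clf,
        config=config,
        loss_curve=list(clf.loss_curve_),
    )
    if test_set and len({p.label for p in test_set}) == 2:
        scores = [s.score for s in predict(model, test_set)]
        y_test = [p.label for p in test_set]
        model.auroc = float(roc_auc_score(y_test, scores))
        model.aupr = float(average_precision_score(y_test, scores))
        logger.info("held-out AUROC %.3f, AUPR %.3f", model.auroc, model.aupr)
    return model


def predict(model: BindingModel, pairs: Sequence[BindingPair]) -> list[BindingScore]:
    """Binding probability in [0, 1] for each pair; deterministic per model."""
    if not isinstance(model, BindingModel) or model.classifier is None:
        raise ValueError("tokenizer mismatch: model is missing its featurizers")
    X = _features(
        (model.smiles_vectorizer, model.protein_vectorizer), pairs, model.config
    )
    probs = model.classifier.predict_proba(X)[:, 1]
    probs = np.clip(probs, 0.0, 1.0)
    return [
        BindingScore(p.compound_id, p.protein_id, float(s))
        for p, s in zip(pairs, probs)
    ]


def call_binding_targets(
    scores: Sequence[BindingScore], threshold: float = DEFAULT_BINDING_THRESHOLD
) -> set[tuple[str, str]]:
    """Pairs whose score meets the threshold (inclusive)."""
    return {(s.compound_id, s.protein_id) for s in scores if s.score >= threshold}
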