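"""Receipt-vs-non-receipt sentence classification.

A sentence that mentions a drug may state that the poster actually received it
("I started ipilimumab in March 2014") or not (questions, options discussed
with the oncologist, other people's treatment, negated statements). Three
classic text classifiers over TF-IDF unigram features are compared — linear
SVM, multinomial naive Bayes, and KNN (K=5) — and the best by precision +
recall is carried forward.

TF-IDF dialect: lowercased unigrams, smoothed inverse document frequency
idf(t) = ln((1+N)/(1+df(t))) + 1, rows L2-normalized, vocabulary fitted on the
training fold only (scikit-learn's ``TfidfVectorizer`` defaults, with a token
pattern that keeps single-character tokens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

__all__ = [
    "MODEL_ORDER",
    "RECEIPT",
    "NON_RECEIPT",
    "ClassifierMetrics",
    "build_vectorizer",
    "featurize",
    "balance_classes",
    "train",
    "evaluate",
    "select_model",
    "compare_models",
]

RECEIPT = "receipt"
NON_RECEIPT = "non_receipt"

#: Fixed candidate order; also the tie-break order for model selection.
MODEL_ORDER = ("svm_linear", "naive_bayes", "knn")

#: Downsample the majority class when its share exceeds this bound.
BALANCE_BOUND = 0.60

KNN_NEIGHBORS = 5


@dataclass(frozen=True)
class ClassifierMetrics:
    """Precision/recall of one model, treating "receipt" as the positive class.

    An undefined ratio (zero denominator) is reported as None, never as 0.
    """

    model_name: str
    precision: float | None
    recall: float | None

    def score(self) -> float:
        return (self.precision or 0.0) + (self.recall or 0.0)


def build_vectorizer() -> TfidfVectorizer:
    return TfidfVectorizer(lowercase=True, token_pattern=r"(?u)\b\w+\b")


def featurize(corpus: list[str]):
    """Fit TF-IDF on ``corpus`` and return (matrix, fitted vectorizer)."""
    if not corpus:
        raise ValueError("cannot featurize an empty corpus")
    vec = build_vectorizer()
    return vec.fit_transform(corpus), vec


def _make_estimator(model_name: str, seed: int):
    if model_name == "svm_linear":
        return LinearSVC(random_state=seed)
    if model_name == "naive_bayes":
        return MultinomialNB()
    if model_name == "knn":
        return KNeighborsClassifier(n_neighbors=KNN_NEIGHBORS)
    raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_ORDER}")


def balance_classes(labeled: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample the majority class when the split is worse than 60/40."""
    counts = labeled["label"].value_counts()
    if len(counts) < 2 or counts.iloc[0] / counts.sum() <= BALANCE_BOUND:
        return labeled
    majority = counts.index[0]
    # target the bound exactly: majority <= BALANCE_BOUND/(1-BALANCE_BOUND) * minority
    cap = int(counts.iloc[1] * BALANCE_BOUND / (1 - BALANCE_BOUND))
    rng = np.random.default_rng(seed)
    maj_rows = labeled.index[labeled["label"] == majority].to_numpy()
    keep = rng.choice(maj_rows, size=cap, replace=False)
    kept = labeled.loc[sorted(set(keep) | set(labeled.index[labeled["label"] != majority]))]
    return kept.reset_index(drop=True)


def train(labeled: pd.DataFrame, model_name: str, seed: int = 0) -> Pipeline:
    """Fit one candidate on labeled sentences (columns ``text``, ``label``)."""
    classes = set(labeled["label"])
    if len(classes) < 2:
        raise ValueError(
            f"training requires both classes; got only {sorted(classes)}"
        )
    model = Pipeline(
        [("tfidf", build_vectorizer()), ("clf", _make_estimator(model_name, seed))]
    )
    model.fit(labeled["text"], labeled["label"])
    return model


def evaluate(truth, predicted) -> ClassifierMetrics:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN) on the receipt class."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(predicted)}")
    tp = sum(t == RECEIPT and p == RECEIPT for t, p in zip(truth, predicted))
    fp = sum(t != RECEIPT and p == RECEIPT for t, p in zip(truth, predicted))
    fn = sum(t == RECEIPT and p != RECEIPT for t, p in zip(truth, predicted))
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return ClassifierMetrics("", precision, recall)


def select_model(metrics: list[ClassifierMetrics]) -> str:
    """Best model by precision + recall; ties broken by precision, then by the
    fixed candidate order."""
    if not metrics:
        raise ValueError("no candidate metrics to select from")

    def rank(m: ClassifierMetrics):
        order = MODEL_ORDER.index(m.model_name) if m.model_name in MODEL_ORDER else 99
        return (-m.score(), -(m.precision or 0.0), order)

    return min(metrics, key=rank).model_name


def compare_models(
    labeled: pd.DataFrame,
    seed: int = 0,
    test_size: float = 0.2,
    models: tuple[str, ...] = MODEL_ORDER,
) -> tuple[dict[str, ClassifierMetrics], str]:
    """Stratified train/test comparison of the candidate models.

    Balancing is applied to the training fold only; metrics are measured on
    the untouched held-out fold. Returns (metrics by model, selected model).
    """
    train_df, test_df = train_test_split(
        labeled,
        test_size=test_size,
        random_state=seed,
        stratify=labeled["label"],
    )
    train_df = balance_classes(train_df.reset_index(drop=True), seed=seed)
    results: dict[str, ClassifierMetrics] = {}
    for name in models:
        fitted = train(train_df, name, seed=seed)
        predicted = fitted.predict(test_df["text"])
        scores = evaluate(test_df["label"], predicted)
        results[name] = ClassifierMetrics(name, scores.precision, scores.recall)
    best = select_model(list(results.values()))
    return results, best
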