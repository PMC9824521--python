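"""Likert-to-class mapping and the imbalance-aware bagged forest ensemble.

Twice-daily questionnaire answers on a 1-5 Likert scale are collapsed to
three ordinal stress classes {bad, neutral, good}.  The morning question
asks whether the resident felt physically refreshed (high answer = good);
the night question asks whether physical stress was felt (high answer =
bad), so the two default mappings have opposite polarity.

Because "bad" days are rare but clinically the most important to catch,
training composes three imbalance counter-measures:

1. SMOTE oversampling to fixed per-class targets (bad 100, neutral 100,
   good 200; k_neighbors 3, random_state 0);
2. random undersampling *with replacement* down to a balanced count (the
   post-SMOTE minority size), re-seeded per ensemble member with seeds
   1..10;
3. bagging: ten random forests, one per undersample, combined by per-row
   majority vote.  Ties resolve by the fixed priority bad > neutral > good,
   i.e. toward the class whose miss is costliest.

Missing feature values are imputed with per-feature training medians fitted
inside each training set, never from held-out rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError
from .resampling import random_undersample, smote_oversample

#: Class order doubles as the vote tie-break priority (earlier wins).
CLASSES = ("bad", "neutral", "good")

#: Integer codes used when configuring per-class resampling targets.
CLASS_CODES = {"bad": 1, "neutral": 2, "good": 3}

#: Default 5-point Likert -> 3-class maps per question polarity.
DEFAULT_LIKERT_MAPPING = {
    "MQ": {1: "bad", 2: "bad", 3: "neutral", 4: "good", 5: "good"},
    "NQ": {1: "good", 2: "good", 3: "neutral", 4: "bad", 5: "bad"},
}


@dataclass(frozen=True)
class ResamplingConfig:
    """Parameters of the SMOTE + undersample + bagging pipeline."""

    smote_targets: dict = field(
        default_factory=lambda: {"bad": 100, "neutral": 100, "good": 200}
    )
    smote_k_neighbors: int = 3
    smote_random_state: int = 0
    under_replacement: bool = True
    under_seeds: tuple = tuple(range(1, 11))

    @property
    def n_bags(self) -> int:
        return len(self.under_seeds)


@dataclass
class EnsembleModel:
    """Seed-indexed forest members plus the voting rule and imputation."""

    members: list  # list of (seed, fitted RandomForestClassifier)
    feature_names: list
    medians: np.ndarray
    config: ResamplingConfig
    base_seed: int = 0

    def manifest(self) -> dict:
        rf = self.members[0][1]
        return {
            "n_members": len(self.members),
            "under_seeds": [s for s, _ in self.members],
            "feature_names": list(self.feature_names),
            "classes": list(CLASSES),
            "smote_targets": dict(self.config.smote_targets),
            "smote_k_neighbors": self.config.smote_k_neighbors,
            "smote_random_state": self.config.smote_random_state,
            "under_replacement": self.config.under_replacement,
            "rf_params": rf.get_params(),
        }


def map_likert(answer: int, question: str, mapping=None) -> str:
    """Map one 1-5 Likert answer to a stress class."""
    mapping = DEFAULT_LIKERT_MAPPING if mapping is None else mapping
    if question not in mapping:
        raise ValidationError(f"unknown question {question!r}")
    answer = int(answer)
    if answer not in mapping[question]:
        raise ValidationError(f"Likert answer must be 1..5, got {answer}")
    return mapping[question][answer]


def map_likert_series(answers: pd.Series, questions: pd.Series, mapping=None) -> pd.Series:
    """Vectorised :func:`map_likert` over aligned answer/question series."""
    return pd.Series(
        [map_likert(a, q, mapping) for a, q in zip(answers, questions)],
        index=answers.index,
        name="label",
    )


def _prepare(features, labels):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels differ in length")
    return X, y, names


def _impute_fit(X: np.ndarray) -> np.ndarray:
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(X, axis=0)
    # A feature missing everywhere in the fold imputes to 0.
    return np.where(np.isnan(medians), 0.0, medians)


def _impute_apply(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan = np.isnan(out)
    if nan.any():
        out[nan] = np.broadcast_to(medians, out.shape)[nan]
    return out


def fit_ensemble(features, labels, config: ResamplingConfig | None = None, base_seed: int = 0) -> EnsembleModel:
    """Fit the SMOTE + undersample + bagged-forest ensemble.

    Every source of randomness is pinned: SMOTE uses its configured random
    state, each member its own undersample seed, and each forest a
    random_state derived from (base_seed, member seed); two fits on the same
    inputs are therefore identical.
    """
    config = config or ResamplingConfig()
    X, y, names = _prepare(features, labels)
    present = np.unique(y)
    if present.size < 2:
        raise ValidationError("training data contain a single class")
    medians = _impute_fit(X)
    Xi = _impute_apply(X, medians)
    targets = {c: config.smote_targets[c] for c in config.smote_targets if c in present}
    Xs, ys = smote_oversample(
        Xi, y, targets, k_neighbors=config.smote_k_neighbors,
        random_state=config.smote_random_state,
    )
    members = []
    for seed in config.under_seeds:
        Xu, yu = random_undersample(Xs, ys, seed=seed, replacement=config.under_replacement)
        rf = RandomForestClassifier(random_state=base_seed + seed)
        rf.fit(Xu, yu)
        members.append((seed, rf))
    return EnsembleModel(members=members, feature_names=names, medians=medians,
                         config=config, base_seed=base_seed)


def member_votes(model: EnsembleModel, features) -> np.ndarray:
    """Per-member predictions: array of shape (n_members, n_rows)."""
    X = _check_features(model, features)
    Xi = _impute_apply(X, model.medians)
    return np.stack([rf.predict(Xi) for _, rf in model.members])


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Plurality over members; ties break by CLASSES priority order."""
    n_rows = votes.shape[1]
    out = np.empty(n_rows, dtype=object)
    for j in range(n_rows):
        col = votes[:, j]
        best, best_count = None, -1
        for cls in CLASSES:  # priority order: first class wins ties
            count = int(np.sum(col == cls))
            if count > best_count:
                best, best_count = cls, count
        out[j] = best
    return out


def predict(model: EnsembleModel, features) -> np.ndarray:
    """Majority-vote prediction of the ensemble."""
    return majority_vote(member_votes(model, features))


def _check_features(model: EnsembleModel, features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in features.columns]
        extra = [n for n in features.columns if n not in model.feature_names]
        if missing or extra:
            raise ValidationError(
                f"feature mismatch: missing {missing}, unexpected {extra}"
            )
        return features[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValidationError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    return X


SCHEMES = (
    "not_manipulated",
    "oversampler",
    "undersampler",
    "under_bagging",
    "over_under_bagging",
)


def fit_scheme(features, labels, scheme: str, config: ResamplingConfig | None = None,
               base_seed: int = 0) -> EnsembleModel:
    """Fit one of the five data-processing schemes.

    ``not_manipulated`` is a single plain forest; ``oversampler`` adds SMOTE
    only; ``undersampler`` a single balanced undersample; ``under_bagging``
    ten undersampled members without SMOTE; ``over_under_bagging`` the full
    pipeline of :func:`fit_ensemble`.  All return an :class:`EnsembleModel`
    (single-member models are one-member ensembles), so prediction is
    uniform.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    config = config or ResamplingConfig()
    if scheme == "over_under_bagging":
        return fit_ensemble(features, labels, config, base_seed)
    X, y, names = _prepare(features, labels)
    if np.unique(y).size < 2:
        raise ValidationError("training data contain a single class")
    medians = _impute_fit(X)
    Xi = _impute_apply(X, medians)
    present = np.unique(y)
    members = []
    if scheme == "not_manipulated":
        rf = RandomForestClassifier(random_state=base_seed)
        rf.fit(Xi, y)
        members.append((0, rf))
    elif scheme == "oversampler":
        targets = {c: config.smote_targets[c] for c in config.smote_targets if c in present}
        Xs, ys = smote_oversample(Xi, y, targets, config.smote_k_neighbors,
                                  config.smote_random_state)
        rf = RandomForestClassifier(random_state=base_seed)
        rf.fit(Xs, ys)
        members.append((0, rf))
    elif scheme == "undersampler":
        seed = config.under_seeds[0]
        Xu, yu = random_undersample(Xi, y, seed=seed, replacement=config.under_replacement)
        rf = RandomForestClassifier(random_state=base_seed + seed)
        rf.fit(Xu, yu)
        members.append((seed, rf))
    else:  # under_bagging
        for seed in config.under_seeds:
            Xu, yu = random_undersample(Xi, y, seed=seed, replacement=config.under_replacement)
            rf = RandomForestClassifier(random_state=base_seed + seed)
            rf.fit(Xu, yu)
            members.append((seed, rf))
    return EnsembleModel(members=members, feature_names=names, medians=medians,
                         config=config, base_seed=base_seed)
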