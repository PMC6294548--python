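"""UP/DOWN brain-state decoding from band-power features.

Stratified 10-fold cross-validated linear maximum-margin classification
(C = 1), a permutation null built by re-running the identical pipeline on
shuffled labels, recursive feature elimination, and cross-subject modal
feature-rank aggregation.

Features are z-scored inside each training fold only, so no information
leaks from held-out trials into the standardisation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bands import BAND_NAMES
from .eeg import RATIO_NAME, SCALED_PREFIX

#: fixed, ordered hotspot feature dictionary: 8 x 1/f-scaled band powers
#: plus the (unscaled) low-gamma : high-alpha ratio.
HOTSPOT_FEATURES: tuple[str, ...] = tuple(
    SCALED_PREFIX + b for b in BAND_NAMES) + (RATIO_NAME,)


def feature_columns(electrodes: tuple[str, ...] = ("hotspot",)) -> list[str]:
    cols: list[str] = []
    for el in electrodes:
        suffix = "" if el == "hotspot" else f"_{el}"
        cols += [c + suffix for c in HOTSPOT_FEATURES]
    return cols


def build_feature_matrix(features: pd.DataFrame,
                         electrodes: tuple[str, ...] = ("hotspot",)
                         ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, names) from a tidy feature table with a 'condition' column;
    labels are 1 for UP and 0 for DOWN."""
    cols = feature_columns(electrodes)
    X = features.loc[:, cols].to_numpy(dtype=float)
    y = (features["condition"] == "UP").to_numpy(dtype=int)
    return X, y, cols


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    folds: int = 10
    C: float = 1.0

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.fold_accuracies) * 100.0)


@dataclass
class NullDistribution:
    null_accuracies_pct: np.ndarray
    true_accuracy_pct: float

    @property
    def p(self) -> float:
        """Rank-based p of the true accuracy against the null."""
        n = len(self.null_accuracies_pct)
        return float((1 + np.sum(self.null_accuracies_pct >= self.true_accuracy_pct))
                     / (n + 1))


@dataclass
class FeatureRanking:
    order: list[int]            # feature indices, best first
    names: list[str] = field(default_factory=list)


def _svm_pipeline(C: float = 1.0, standardize: bool = True):
    svc = SVC(kernel="linear", C=C)
    return make_pipeline(StandardScaler(), svc) if standardize else svc


def crossval_classify(X: np.ndarray, y: np.ndarray, folds: int = 10,
                      seed: int = 0, C: float = 1.0,
                      standardize: bool = True) -> CVResult:
    """Stratified k-fold CV accuracy of the linear SVM (C = 1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = cross_val_score(_svm_pipeline(C, standardize), X, y, cv=cv,
                           scoring="accuracy")
    return CVResult(fold_accuracies=accs, folds=folds, C=C)


def permutation_null(X: np.ndarray, y: np.ndarray, n_perm: int = 100,
                     seed: int = 0, folds: int = 10, C: float = 1.0
                     ) -> NullDistribution:
    """Label-permutation null: the identical CV pipeline on shuffled labels."""
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    true = crossval_classify(X, y, folds=folds, seed=seed, C=C).mean_accuracy_pct
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null[i] = crossval_classify(X, y_perm, folds=folds, seed=seed,
                                    C=C).mean_accuracy_pct
    return NullDistribution(null_accuracies_pct=null, true_accuracy_pct=true)


def rfe_rank(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
             C: float = 1.0) -> FeatureRanking:
    """Recursive feature elimination, one feature per step: refit, drop the
    feature with the smallest absolute margin weight; reversed elimination
    order is the ranking (ties resolved by column order)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two features to rank")
    Xz = StandardScaler().fit_transform(X)
    Xz = np.nan_to_num(Xz)  # constant features z-score to 0 -> eliminated first
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=1, step=1)
    rfe.fit(Xz, y)
    order = list(np.argsort(rfe.ranking_, kind="stable"))
    return FeatureRanking(order=[int(i) for i in order],
                          names=[names[i] for i in order] if names else [])


def aggregate_rankings(rankings: list[list[int]], n_features: int | None = None
                       ) -> tuple[list[int], float]:
    """Cross-subject modal ranking.

    For each rank position (best first) the modal not-yet-chosen feature is
    selected, ties broken by overall mean rank.  Returns (modal order,
    stability), where stability is the mean fraction of subjects agreeing
    with the modal choice at each position; values near 1/n_features mean
    no stable mode exists.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two subjects")
    R = np.asarray(rankings)  # subjects x positions, entries are feature ids
    n_sub, n_pos = R.shape
    n_features = n_features or n_pos
    mean_rank = np.full(n_features, np.inf)
    for f in range(n_features):
        pos = [np.nonzero(row == f)[0][0] for row in R if f in row]
        if pos:
            mean_rank[f] = float(np.mean(pos))
    chosen: list[int] = []
    agreement = []
    for pos in range(n_pos):
        counts = np.zeros(n_features)
        for row in R:
            if row[pos] not in chosen:
                counts[row[pos]] += 1
        if counts.max() == 0:  # all subjects' picks already used
            rest = [f for f in np.argsort(mean_rank, kind="stable")
                    if f not in chosen]
            chosen.append(int(rest[0]))
            agreement.append(0.0)
            continue
        best = counts.max()
        cands = np.nonzero(counts == best)[0]
        pick = cands[np.argmin(mean_rank[cands])]
        chosen.append(int(pick))
        agreement.append(best / n_sub)
    return chosen, float(np.mean(agreement))
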