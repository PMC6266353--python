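"""Template-dictionary letter classification for the P300 speller.

For every channel a dictionary of feature templates is built from the
averaged target (P300-bearing) row and column segments of the training
trials — two templates per trial, thirty from a 15-trial training split.
A spelled letter is then identified per channel by a k-nearest-neighbor
rule: among the six candidate row features (and, independently, the six
candidate column features), the class whose summed Euclidean distance to
its k nearest dictionary templates is smallest wins.  The MP1 variant
ranks classes by the matching-pursuit residual norm against a dictionary
of signal templates instead of a feature distance.  A linear-margin SVM
on the z-scored signal serves as the non-waveform control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features import (
    FeatureConfig,
    Method,
    MPDictionary,
    build_mp1_dictionary,
    build_mp2_dictionary,
    extract_feature,
    mp1_score,
)
from .preprocess import Segment, ensemble_average
from .synth import COL_IDS, ROW_IDS, SPELLER_LAYOUT, StimulusSchedule, letter_position, matrix_letter

logger = logging.getLogger(__name__)


@dataclass
class SpellerMatrix:
    """6x6 character grid addressed by (row_id 1-6, col_id 7-12)."""

    cells: tuple[str, ...] = SPELLER_LAYOUT

    def __post_init__(self) -> None:
        if len(self.cells) != 36 or len(set(self.cells)) != 36:
            raise ValueError("speller matrix needs 36 unique characters")

    def letter(self, row_id: int, col_id: int) -> str:
        if row_id not in ROW_IDS or col_id not in COL_IDS:
            raise ValueError(f"ids out of range: row {row_id}, col {col_id}")
        return self.cells[(row_id - 1) * 6 + (col_id - 7)]


def identify_letter(row_id: int, col_id: int, matrix: SpellerMatrix | None = None) -> str:
    """Return the matrix character selected by a (row, column) pair."""
    matrix = matrix or SpellerMatrix()
    return matrix.letter(row_id, col_id)


@dataclass
class TemplateDictionary:
    """Per-channel pool of feature templates plus the neighbor count k.

    For MP1 the templates are unit-norm *signal* atoms held in
    ``mp_dictionary``; for every other method they are feature vectors.
    """

    method: Method
    channel: str
    templates: np.ndarray | None = None     #: (n_templates, L) feature vectors
    mp_dictionary: MPDictionary | None = None
    k: int = 3

    def __post_init__(self) -> None:
        if self.method is Method.MP1:
            if self.mp_dictionary is None:
                raise ValueError("MP1 dictionary requires signal atoms")
        else:
            if self.templates is None or len(self.templates) == 0:
                raise ValueError("template dictionary is empty")
            self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
            if self.k > len(self.templates):
                raise ValueError("k cannot exceed the template pool size")

    @property
    def size(self) -> int:
        if self.method is Method.MP1:
            return self.mp_dictionary.size
        return len(self.templates)


def build_template_dictionary(
    segments: list[Segment],
    schedule: StimulusSchedule,
    train_trials: list[int],
    method: Method | str,
    channel: int,
    channel_name: str = "",
    k: int = 3,
    cfg: FeatureConfig | None = None,
    n_sequences: int | None = None,
) -> TemplateDictionary:
    """Build the per-channel template dictionary from training trials.

    For each training trial the averaged segments of the target row and
    target column — the two classes known to carry the P300 — are
    extracted and featurized, yielding two templates per trial (30 from 15
    trials, 70 from 35).
    """
    method = Method(method)
    cfg = cfg or FeatureConfig()
    signals = []
    for t in train_trials:
        target = schedule.trials[t].target
        if not target:
            raise ValueError(f"trial {t} lacks target metadata")
        row_id, col_id = letter_position(target)
        trial_segments = [s for s in segments if s.trial_index == t]
        for sid in (row_id, col_id):
            avg = ensemble_average(trial_segments, sid, n_sequences)
            signals.append(avg.data[channel])
    if method is Method.MP1:
        return TemplateDictionary(
            method=method,
            channel=channel_name,
            mp_dictionary=build_mp1_dictionary(signals),
            k=k,
        )
    mp2_dict = build_mp2_dictionary(signals[0].size) if method is Method.MP2 else None
    features = [extract_feature(s, method, cfg, mp2_dict=mp2_dict) for s in signals]
    return TemplateDictionary(
        method=method, channel=channel_name, templates=np.vstack(features), k=k
    )


@dataclass(frozen=True)
class Prediction:
    row: int
    col: int
    letter: str
    channel: str = ""

    def __post_init__(self) -> None:
        if self.row not in ROW_IDS or self.col not in COL_IDS:
            raise ValueError("prediction ids out of range")


def knn_select(
    features: dict[int, np.ndarray],
    dictionary: TemplateDictionary,
    k: int | None = None,
) -> int:
    """Select the class whose feature is nearest its k dictionary neighbors.

    For each candidate class ``u`` the Euclidean distances from its
    feature to every template are sorted and the k smallest are summed;
    the class with the minimal sum wins.  Ties go to the lowest class id
    (logged).
    """
    if not features:
        raise ValueError("no candidate class features")
    k = k or dictionary.k
    if dictionary.templates is None:
        raise ValueError("knn_select needs feature templates (not an MP1 dictionary)")
    k = min(k, len(dictionary.templates))
    best_u, best_score = None, np.inf
    for u in sorted(features):
        dists = np.linalg.norm(dictionary.templates - features[u][None, :], axis=1)
        score = float(np.sort(dists)[:k].sum())
        if score == best_score:
            logger.info("knn tie between classes %d and %d; keeping %d", best_u, u, best_u)
        if score < best_score:
            best_u, best_score = u, score
    return best_u


def mp1_select(
    signals: dict[int, np.ndarray],
    dictionary: TemplateDictionary | MPDictionary,
    m_atoms: int = 5,
) -> int:
    """Select the class whose averaged segment leaves the smallest MP residual.

    Candidate segments are unit-normalized before scoring so the ranking
    reflects waveform mismatch rather than signal energy: the residual of
    a raw segment scales with its norm, and candidate classes differ in
    energy simply because the ERP adds power to the target one.  With
    unit-norm candidates (matching the unit-norm atoms) the score is the
    relative residual, a pure shape measure.
    """
    if not signals:
        raise ValueError("no candidate class signals")
    mp_dict = dictionary.mp_dictionary if isinstance(dictionary, TemplateDictionary) else dictionary
    best_u, best_eps = None, np.inf
    for u in sorted(signals):
        x = signals[u]
        norm = np.linalg.norm(x)
        if norm == 0:
            continue
        eps = mp1_score(x / norm, mp_dict, m_atoms=m_atoms)
        if eps < best_eps:
            best_u, best_eps = u, eps
    return best_u


def predict_letter(
    row_candidates: dict[int, np.ndarray],
    col_candidates: dict[int, np.ndarray],
    dictionary: TemplateDictionary,
    matrix: SpellerMatrix | None = None,
    m_atoms: int = 5,
) -> Prediction:
    """Identify the spelled letter on one channel from class candidates.

    ``row_candidates`` maps row ids 1-6 (and ``col_candidates`` column ids
    7-12) to the feature — or, for MP1, the averaged signal — of the
    corresponding averaged segment.
    """
    if dictionary.method is Method.MP1:
        row = mp1_select(row_candidates, dictionary, m_atoms)
        col = mp1_select(col_candidates, dictionary, m_atoms)
    else:
        row = knn_select(row_candidates, dictionary)
        col = knn_select(col_candidates, dictionary)
    return Prediction(
        row=row, col=col, letter=identify_letter(row, col, matrix), channel=dictionary.channel
    )


# --- linear-margin control --------------------------------------------------


def train_linear_margin(X: np.ndarray, y: np.ndarray) -> SVC:
    """Fit the linear maximum-margin control classifier (target vs non-target)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def svm_select(features: dict[int, np.ndarray], clf: SVC) -> int:
    """Select the class whose feature scores highest as 'target'."""
    if not features:
        raise ValueError("no candidate class features")
    classes = sorted(features)
    scores = clf.decision_function(np.vstack([features[u] for u in classes]))
    return classes[int(np.argmax(scores))]


def linear_margin_control(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Train the linear SVM control and return its binary test labels."""
    clf = train_linear_margin(X_train, y_train)
    return clf.predict(np.asarray(X_test, dtype=float))
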