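"""Pairwise category cross-decoding with exemplar-generalizing folds.

The defining feature of the analysis is *cross-decoding*: classifiers are
always tested on stimulus exemplars they never saw in training, so
above-chance accuracy cannot reflect memorized image-specific patterns.
Three fold schemes implement this:

``paired_exemplar``
    N folds; exemplar i of each category is held out together.  For the
    illusory-vs-matched comparison the pairing follows the yoke links, so
    an illusory face and its visually similar matched object always leave
    the training set together (no leakage through yoked similarity).
``exhaustive_exemplar``
    N^2 folds; every cross-category combination of one held-out exemplar
    per category.
``run_by_exemplar``
    N x n_runs folds; the held-out exemplar pair is tested only on the
    held-out run, training uses the remaining exemplars on the remaining
    runs (combined leave-one-run-out / leave-one-exemplar-out).

Classifiers: regularized LDA (MEG timecourses) and linear SVM (fMRI
betas); both are selectable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import (
    DecodingResult,
    SensorEpochs,
    StimulusSet,
    ValidationError,
)
from .synth import ROIBetas

DEFAULT_LDA_SHRINKAGE = 0.05


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def fit_predict_lda(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    shrinkage: float = DEFAULT_LDA_SHRINKAGE,
) -> np.ndarray:
    """Binary LDA with shrinkage toward a scaled identity, equal priors.

    The pooled within-class covariance S is regularized as
    (1 - shrinkage) * S + shrinkage * (trace(S)/p) * I.  With
    shrinkage = 1 the discriminant reduces exactly to a nearest-centroid
    classifier.  Ties (discriminant exactly 0) go to the
    lexicographically first class label.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if not (np.all(np.isfinite(train_X)) and np.all(np.isfinite(test_X))):
        raise ValidationError("X: non-finite features")
    classes = np.unique(train_y)
    if classes.size != 2:
        raise ValidationError(f"train_y: expected exactly 2 classes, got {classes.size}")
    if not 0 <= shrinkage <= 1:
        raise ValidationError("shrinkage: must be in [0, 1]")
    c0, c1 = sorted(classes.tolist())
    X0, X1 = train_X[train_y == c0], train_X[train_y == c1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    p = train_X.shape[1]
    n = len(X0) + len(X1)
    R0, R1 = X0 - mu0, X1 - mu1
    S = (R0.T @ R0 + R1.T @ R1) / max(n - 2, 1)
    scale = np.trace(S) / p
    if scale <= 0:
        scale = 1.0  # exactly zero within-class scatter: any scale gives nearest-centroid
    S_reg = (1.0 - shrinkage) * S + shrinkage * scale * np.eye(p)
    try:
        w = np.linalg.solve(S_reg, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            "covariance: singular pooled covariance; increase shrinkage"
        ) from err
    if not np.all(np.isfinite(w)):
        raise ValidationError(
            "covariance: ill-conditioned pooled covariance; increase shrinkage"
        )
    scores = test_X @ w - w @ (mu0 + mu1) / 2.0
    return np.where(scores > 0, c1, c0)


def fit_predict_svm(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    cost: float = 1.0,
) -> np.ndarray:
    """Linear soft-margin binary SVM (deterministic given the data)."""
    train_y = np.asarray(train_y)
    if np.unique(train_y).size != 2:
        raise ValidationError("train_y: expected exactly 2 classes")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(np.asarray(train_X, dtype=float), train_y)
    return clf.predict(np.asarray(test_X, dtype=float))


_CLASSIFIERS = {"lda": fit_predict_lda, "svm": fit_predict_svm}


def _classify(name: str, train_X, train_y, test_X, **kwargs) -> np.ndarray:
    try:
        fn = _CLASSIFIERS[name]
    except KeyError:
        raise ValidationError(f"classifier: unknown classifier {name!r}") from None
    return fn(train_X, train_y, test_X, **kwargs)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    """(stimulus_id, run) pairs for training and testing; run None = all runs."""

    train: tuple[tuple[str, int | None], ...]
    test: tuple[tuple[str, int | None], ...]


@dataclass
class FoldPlan:
    folds: list[Fold]
    scheme: str
    comparison: tuple[str, str]

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for k, fold in enumerate(self.folds):
            train_stims = {s for s, _ in fold.train}
            test_stims = {s for s, _ in fold.test}
            if train_stims & test_stims:
                raise ValidationError(
                    f"folds: fold {k} has stimuli in both train and test: "
                    f"{sorted(train_stims & test_stims)}"
                )
            covered |= test_stims
        self._covered = covered

    def __len__(self) -> int:
        return len(self.folds)


def _exemplar_pairing(stimuli: StimulusSet, pair: tuple[str, str]) -> list[tuple[str, str]]:
    """Pair up exemplars across the two categories for paired hold-out.

    Yoked comparisons (illusory vs matched) pair along the yoke links;
    other comparisons pair by sorted index.
    """
    cat_a, cat_b = pair
    ids_a, ids_b = stimuli.by_category(cat_a), stimuli.by_category(cat_b)
    if len(ids_a) != len(ids_b):
        raise ValidationError("pair: categories have unequal exemplar counts")
    if {cat_a, cat_b} == {"illusory_face", "matched_object"}:
        ill = ids_a if cat_a == "illusory_face" else ids_b
        pairs = [(i, stimuli.yoke_of(i)) for i in ill]
        return pairs if cat_a == "illusory_face" else [(m, i) for i, m in pairs]
    return list(zip(ids_a, ids_b))


def make_folds(
    stimuli: StimulusSet,
    pair: tuple[str, str],
    scheme: str = "paired_exemplar",
    runs: list[int] | None = None,
) -> FoldPlan:
    """Build a cross-validation plan for one category pair.

    With N exemplars per category: ``paired_exemplar`` yields N folds
    (train on 2(N-1) stimuli, test on the held-out pair),
    ``exhaustive_exemplar`` yields N^2 folds, and ``run_by_exemplar``
    yields N x n_runs folds (requires ``runs``).
    """
    cat_a, cat_b = pair
    ids_a, ids_b = stimuli.by_category(cat_a), stimuli.by_category(cat_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("pair: need >= 2 exemplars per category")
    folds: list[Fold] = []
    if scheme == "paired_exemplar":
        for ea, eb in _exemplar_pairing(stimuli, pair):
            train = tuple(
                (s, None) for s in ids_a + ids_b if s not in (ea, eb)
            )
            folds.append(Fold(train, ((ea, None), (eb, None))))
    elif scheme == "exhaustive_exemplar":
        for ea in ids_a:
            for eb in ids_b:
                train = tuple(
                    (s, None) for s in ids_a + ids_b if s not in (ea, eb)
                )
                folds.append(Fold(train, ((ea, None), (eb, None))))
    elif scheme == "run_by_exemplar":
        if runs is None:
            raise ValidationError(
                "runs: run_by_exemplar scheme requires the run index list"
            )
        for ea, eb in _exemplar_pairing(stimuli, pair):
            for r in runs:
                train = tuple(
                    (s, rr)
                    for s in ids_a + ids_b
                    if s not in (ea, eb)
                    for rr in runs
                    if rr != r
                )
                folds.append(Fold(train, ((ea, r), (eb, r))))
    else:
        raise ValidationError(f"scheme: unknown scheme {scheme!r}")
    return FoldPlan(folds, scheme, pair)


# ---------------------------------------------------------------------------
# MEG timecourse decoding
# ---------------------------------------------------------------------------

def _trial_masks(epochs: SensorEpochs, fold: Fold) -> tuple[np.ndarray, np.ndarray]:
    stim = epochs.trials["stimulus_id"].to_numpy()
    train_stims = {s for s, _ in fold.train}
    test_stims = {s for s, _ in fold.test}
    return np.isin(stim, list(train_stims)), np.isin(stim, list(test_stims))


def decode_timecourse(
    epochs_per_subject: list[SensorEpochs],
    stimuli: StimulusSet,
    pair: tuple[str, str],
    scheme: str = "exhaustive_exemplar",
    classifier: str = "lda",
    times_ms: np.ndarray | None = None,
    **clf_kwargs,
) -> DecodingResult:
    """Cross-decode a category pair at every timepoint for every subject.

    For each fold and timepoint the classifier trains on all trials of the
    training exemplars and predicts all trials of the held-out exemplars;
    accuracy is percent correct averaged over folds.  ``times_ms``
    restricts the grid (useful at desk scale).
    """
    plan = make_folds(stimuli, pair, scheme)
    first = epochs_per_subject[0]
    if times_ms is None:
        times_ms = first.times_ms.copy()
    times_ms = np.asarray(times_ms, dtype=float)
    t_idx = [first.time_index(t) for t in times_ms]
    acc = np.zeros((len(epochs_per_subject), len(times_ms)))
    for s, ep in enumerate(epochs_per_subject):
        cat = ep.trials["stimulus_id"].map(stimuli.category_of).to_numpy()
        masks = [_trial_masks(ep, fold) for fold in plan.folds]
        for ti, t in enumerate(t_idx):
            X = ep.data[:, :, t]
            correct = total = 0
            for train_m, test_m in masks:
                pred = _classify(
                    classifier, X[train_m], cat[train_m], X[test_m], **clf_kwargs
                )
                correct += int(np.sum(pred == cat[test_m]))
                total += int(test_m.sum())
            acc[s, ti] = 100.0 * correct / total
    return DecodingResult(
        comparison=pair,
        accuracy_percent=acc,
        axis_name="time_ms",
        axis_values=times_ms,
        n_folds=len(plan),
        scheme=scheme,
        subjects=[ep.subject or f"S{k:02d}" for k, ep in enumerate(epochs_per_subject)],
    )


# ---------------------------------------------------------------------------
# fMRI ROI decoding
# ---------------------------------------------------------------------------

def decode_roi(
    datasets: list[dict[str, ROIBetas]],
    stimuli: StimulusSet,
    pair: tuple[str, str],
    scheme: str = "run_by_exemplar",
    classifier: str = "svm",
    **clf_kwargs,
) -> DecodingResult:
    """Cross-decode a category pair from ROI beta patterns per subject.

    The default combined leave-one-run-out / leave-one-exemplar-out
    scheme trains on the remaining exemplars' betas from the remaining
    runs and tests the held-out exemplar pair on the held-out run.
    """
    rois = list(datasets[0].keys())
    n_runs = datasets[0][rois[0]].values.shape[1]
    runs = list(range(n_runs))
    plan = make_folds(stimuli, pair, scheme, runs=runs if scheme == "run_by_exemplar" else None)
    acc = np.zeros((len(datasets), len(rois)))
    for s, per_roi in enumerate(datasets):
        for r_i, roi in enumerate(rois):
            stack = per_roi[roi]
            pos = {sid: k for k, sid in enumerate(stack.stimulus_ids)}
            correct = total = 0
            for fold in plan.folds:
                train_X, train_y, test_X, test_y = [], [], [], []
                for sid, run in fold.train:
                    cat = stimuli.category_of(sid)
                    for rr in runs if run is None else [run]:
                        train_X.append(stack.values[pos[sid], rr])
                        train_y.append(cat)
                for sid, run in fold.test:
                    cat = stimuli.category_of(sid)
                    for rr in runs if run is None else [run]:
                        test_X.append(stack.values[pos[sid], rr])
                        test_y.append(cat)
                pred = _classify(
                    classifier, np.array(train_X), np.array(train_y),
                    np.array(test_X), **clf_kwargs,
                )
                correct += int(np.sum(pred == np.array(test_y)))
                total += len(test_y)
            acc[s, r_i] = 100.0 * correct / total
    return DecodingResult(
        comparison=pair,
        accuracy_percent=acc,
        axis_name="roi",
        axis_values=rois,
        n_folds=len(plan),
        scheme=scheme,
        subjects=[f"fmri-{k:02d}" for k in range(len(datasets))],
    )


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """Integer offsets with dx^2 + dy^2 + dz^2 <= radius^2 (123 at radius 3)."""
    if radius_voxels < 1:
        raise ValidationError("radius_voxels: must be >= 1")
    r = int(radius_voxels)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return grid[(grid**2).sum(axis=1) <= r * r]


def searchlight_decode(
    volume_betas: np.ndarray,
    mask: np.ndarray,
    stimuli: StimulusSet,
    pair: tuple[str, str],
    radius_voxels: int = 3,
    scheme: str = "paired_exemplar",
    classifier: str = "svm",
    stimulus_ids: list[str] | None = None,
    **clf_kwargs,
) -> np.ndarray:
    """Volumetric searchlight cross-decoding.

    ``volume_betas`` is stimuli x X x Y x Z (one run-averaged pattern per
    stimulus); for every in-mask center voxel the features are the voxels
    within the inclusive Euclidean ``radius_voxels``, intersected with
    the mask.  Returns a map of accuracy (%) with NaN outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask: empty mask")
    if volume_betas.ndim != 4 or volume_betas.shape[1:] != mask.shape:
        raise ValidationError("volume_betas: expected stimuli x X x Y x Z matching mask")
    ids = stimulus_ids or stimuli.ids
    if len(ids) != volume_betas.shape[0]:
        raise ValidationError("stimulus_ids: length mismatch with volume_betas")
    cats = np.array([stimuli.category_of(s) for s in ids])
    plan = make_folds(stimuli, pair, scheme)
    offsets = sphere_offsets(radius_voxels)
    shape = mask.shape
    out = np.full(shape, np.nan)
    relevant = np.isin(cats, list(pair))
    flat = volume_betas.reshape(volume_betas.shape[0], -1)
    for center in np.argwhere(mask):
        coords = center[None, :] + offsets
        ok = np.all((coords >= 0) & (coords < np.array(shape)[None, :]), axis=1)
        coords = coords[ok]
        coords = coords[mask[coords[:, 0], coords[:, 1], coords[:, 2]]]
        feat_idx = np.ravel_multi_index(coords.T, shape)
        X = flat[:, feat_idx]
        correct = total = 0
        for fold in plan.folds:
            tr = np.isin(ids, [s for s, _ in fold.train]) & relevant
            te = np.isin(ids, [s for s, _ in fold.test]) & relevant
            pred = _classify(classifier, X[tr], cats[tr], X[te], **clf_kwargs)
            correct += int(np.sum(pred == cats[te]))
            total += int(te.sum())
        out[tuple(center)] = 100.0 * correct / total
    return out
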