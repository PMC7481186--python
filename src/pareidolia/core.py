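"""Typed containers for the pareidolia analysis pipeline.

The experiment is built around a 96-image design: 32 photographs of
illusory faces in inanimate objects, 32 *yoked* matched objects (same
object kind, no illusory face), and 32 human faces.  Everything downstream
— trial-resolved MEG epochs, per-stimulus fMRI beta patterns,
representational dissimilarity matrices (RDMs), and decoding results — is
expressed through the containers in this module.  Containers validate
their invariants at construction and refuse missing values, so pipeline
stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical category labels, in the order used for 3x3 category matrices.
CATEGORIES = ("human_face", "illusory_face", "matched_object")

#: RDM metric tags whose entries are bounded in [0, 2].
CORRELATION_METRICS = frozenset({"one_minus_spearman", "one_minus_corr"})

CHANCE_PERCENT = 50.0


class ValidationError(ValueError):
    """Raised when a container invariant is violated; the message names the field."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: contains NaN or infinite values")


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusItem:
    """One image in the design.

    ``yoke_id`` links each illusory face to its matched object and vice
    versa; human faces are unyoked.  ``tilt_deg`` is the small in-plane
    rotation (+/-3 degrees) used for the orthogonal tilt-judgement task.
    """

    id: str
    category: str
    yoke_id: str | None = None
    filename: str | None = None
    tilt_deg: float = 3.0


@dataclass
class StimulusSet:
    """The full stimulus design with category bookkeeping and yoking.

    Invariants: unique ids, equal category counts, and a perfect yoke
    bijection between illusory faces and matched objects.
    """

    items: list[StimulusItem]

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        _require(len(ids) == len(set(ids)), "items: duplicate stimulus ids")
        for it in self.items:
            _require(
                it.category in CATEGORIES,
                f"items: unknown category {it.category!r} for {it.id!r}",
            )
        counts = {c: len(self.by_category(c)) for c in CATEGORIES}
        _require(
            len(set(counts.values())) == 1,
            f"items: unequal category counts {counts}",
        )
        self._check_yokes()
        self._index = {it.id: it for it in self.items}

    def _check_yokes(self) -> None:
        ill = {it.id: it.yoke_id for it in self.items if it.category == "illusory_face"}
        mat = {it.id: it.yoke_id for it in self.items if it.category == "matched_object"}
        orphans = [i for i, y in ill.items() if y not in mat]
        orphans += [m for m, y in mat.items() if y not in ill]
        _require(not orphans, f"items: broken yoke graph, orphans: {sorted(orphans)}")
        # bijection: yoke links must be mutual
        for i, y in ill.items():
            _require(
                mat[y] == i,
                f"items: yoke of {i!r} is {y!r} but {y!r} points back to {mat[y]!r}",
            )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __getitem__(self, stim_id: str) -> StimulusItem:
        return self._index[stim_id]

    def by_category(self, category: str) -> list[str]:
        return sorted(it.id for it in self.items if it.category == category)

    def category_of(self, stim_id: str) -> str:
        return self._index[stim_id].category

    def categories_for(self, ids: list[str]) -> list[str]:
        return [self.category_of(i) for i in ids]

    def yoke_of(self, stim_id: str) -> str | None:
        return self._index[stim_id].yoke_id

    def subset(self, exclude_categories: set[str]) -> "list[str]":
        """Ids outside ``exclude_categories``, in sorted order."""
        return sorted(
            it.id for it in self.items if it.category not in exclude_categories
        )


def make_stimulus_set(n_per_category: int = 32) -> StimulusSet:
    """Build the canonical design: yoked illusory/matched pairs plus human faces.

    Tilt alternates -3/+3 within each category so tilt is uninformative
    about category, mirroring the counterbalanced task design.
    """
    items: list[StimulusItem] = []
    for k in range(n_per_category):
        tilt = -3.0 if k % 2 == 0 else 3.0
        ii = f"illusory_{k:02d}"
        mi = f"matched_{k:02d}"
        items.append(StimulusItem(f"human_{k:02d}", "human_face", None,
                                  f"human_{k:02d}.png", tilt))
        items.append(StimulusItem(ii, "illusory_face", mi, f"{ii}.png", tilt))
        items.append(StimulusItem(mi, "matched_object", ii, f"{mi}.png", -tilt))
    return StimulusSet(items)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

REQUIRED_TRIAL_COLUMNS = ("stimulus_id", "run", "repeat")


@dataclass
class SensorEpochs:
    """Trial-resolved multichannel timeseries with trial metadata.

    ``data`` is trials x channels x timepoints in arbitrary units;
    ``times_ms`` is the per-sample latency relative to stimulus onset on a
    uniform grid with step 1000/sample_rate_hz.  ``trials`` carries one row
    per trial (stimulus_id, run, repeat, optionally category).
    ``feature_space`` is "sensors" for raw channels and "components" after
    PCA reduction.
    """

    data: np.ndarray
    times_ms: np.ndarray
    trials: pd.DataFrame
    sample_rate_hz: float
    feature_space: str = "sensors"
    subject: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        _require(self.data.ndim == 3, "data: expected trials x channels x timepoints")
        _check_finite(self.data, "data")
        _check_finite(self.times_ms, "times_ms")
        n_trials, _, n_times = self.data.shape
        _require(
            self.times_ms.shape == (n_times,),
            f"times_ms: length {self.times_ms.shape} does not match data "
            f"time axis {n_times}",
        )
        steps = np.diff(self.times_ms)
        _require(np.all(steps > 0), "times_ms: must be strictly increasing")
        expected = 1000.0 / self.sample_rate_hz
        if n_times > 1 and not np.allclose(steps, expected, atol=1e-6):
            raise ValidationError(
                f"times_ms: non-uniform step or step != 1000/sample_rate_hz "
                f"(expected {expected} ms)"
            )
        _require(
            len(self.trials) == n_trials,
            f"trials: table has {len(self.trials)} rows but data has "
            f"{n_trials} trials",
        )
        for col in REQUIRED_TRIAL_COLUMNS:
            _require(col in self.trials.columns, f"trials: missing column {col!r}")
        if self.trials[list(REQUIRED_TRIAL_COLUMNS)].isna().any().any():
            raise ValidationError("trials: missing values in required columns")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_index(self, time_ms: float) -> int:
        """Index of the grid timepoint nearest to ``time_ms``."""
        return int(np.argmin(np.abs(self.times_ms - time_ms)))

    def stimulus_ids(self) -> list[str]:
        return sorted(self.trials["stimulus_id"].unique())


# ---------------------------------------------------------------------------
# Pattern matrices
# ---------------------------------------------------------------------------

@dataclass
class PatternMatrix:
    """One feature vector per item (voxel betas or component patterns)."""

    values: np.ndarray
    item_labels: list[str]
    feature_space: str = "voxels"
    run: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _require(self.values.ndim == 2, "values: expected items x features")
        _check_finite(self.values, "values")
        _require(
            len(self.item_labels) == self.values.shape[0],
            f"item_labels: {len(self.item_labels)} labels for "
            f"{self.values.shape[0]} rows",
        )
        _require(
            len(set(self.item_labels)) == len(self.item_labels),
            "item_labels: duplicate labels",
        )

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """Square symmetric dissimilarity matrix over labeled items.

    For correlation-based metrics (1 - Spearman/Pearson) entries lie in
    [0, 2].  Symmetry is required within 1e-10 and the diagonal must be
    exactly zero (within the same tolerance); the stored matrix is
    symmetrized so equality checks are exact.
    """

    matrix: np.ndarray
    labels: list[str]
    metric: str = "custom"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        _require(
            self.matrix.ndim == 2 and self.matrix.shape == (n, n),
            "matrix: must be square",
        )
        _check_finite(self.matrix, "matrix")
        _require(len(self.labels) == n, f"labels: {len(self.labels)} labels for n={n}")
        _require(len(set(self.labels)) == n, "labels: duplicate labels")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        _require(asym <= 1e-10, f"matrix: asymmetric by {asym:.3g} (tolerance 1e-10)")
        _require(
            np.max(np.abs(np.diag(self.matrix))) <= 1e-10 if n else True,
            "matrix: nonzero diagonal",
        )
        if self.metric in CORRELATION_METRICS:
            lo, hi = self.matrix.min(), self.matrix.max()
            _require(
                -1e-10 <= lo and hi <= 2 + 1e-10,
                f"matrix: entries [{lo:.3g}, {hi:.3g}] outside [0, 2] for "
                f"metric {self.metric!r}",
            )
        self.matrix = (self.matrix + self.matrix.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """Strict lower triangle, row-major — the canonical RDM vectorization.

        All RDM-to-RDM statistics in the package consume this order, so two
        RDMs with identical label order are always compared cell-for-cell.
        """
        return self.matrix[np.tril_indices(self.n, k=-1)]

    def subset(self, labels: list[str]) -> "RDM":
        """RDM restricted to ``labels`` (in the given order)."""
        index = {lab: k for k, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        _require(not missing, f"labels: not present in RDM: {missing}")
        idx = np.array([index[lab] for lab in labels])
        return RDM(self.matrix[np.ix_(idx, idx)], list(labels), self.metric)


def mean_rdm(rdms: list[RDM]) -> RDM:
    """Arithmetic mean of RDMs sharing a label order (the group RDM)."""
    first = rdms[0]
    for r in rdms[1:]:
        _require(r.labels == first.labels, "labels: RDMs have mismatched labels")
    mat = np.mean([r.matrix for r in rdms], axis=0)
    return RDM(mat, list(first.labels), first.metric)


# ---------------------------------------------------------------------------
# Decoding results
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Percent-correct accuracies for one category comparison.

    ``accuracy_percent`` is subjects x axis (timepoints, ROIs, or voxels);
    ``axis_name``/``axis_values`` describe the second dimension.  Chance is
    50% for the binary comparisons used throughout.
    """

    comparison: tuple[str, str]
    accuracy_percent: np.ndarray
    axis_name: str
    axis_values: np.ndarray | list
    n_folds: int
    scheme: str
    chance_percent: float = CHANCE_PERCENT
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracy_percent = np.asarray(self.accuracy_percent, dtype=float)
        _check_finite(self.accuracy_percent, "accuracy_percent")
        _require(
            np.all((self.accuracy_percent >= 0) & (self.accuracy_percent <= 100)),
            "accuracy_percent: outside [0, 100]",
        )
        _require(self.n_folds > 0, "n_folds: must be positive")

    @property
    def group_mean(self) -> np.ndarray:
        return self.accuracy_percent.mean(axis=0)

    @property
    def group_sem(self) -> np.ndarray:
        n = self.accuracy_percent.shape[0]
        return self.accuracy_percent.std(axis=0, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (subject, axis value, accuracy)."""
        n_subj = self.accuracy_percent.shape[0]
        subjects = self.subjects or [f"S{k:02d}" for k in range(n_subj)]
        rows = []
        for s, subj in enumerate(subjects):
            for a, val in enumerate(np.atleast_1d(self.axis_values)):
                rows.append(
                    {
                        "subject": subj,
                        self.axis_name: val,
                        "accuracy_percent": self.accuracy_percent[s, a],
                        "comparison": f"{self.comparison[0]}_vs_{self.comparison[1]}",
                        "scheme": self.scheme,
                        "n_folds": self.n_folds,
                    }
                )
        return pd.DataFrame(rows)
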