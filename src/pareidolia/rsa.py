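"""Representational similarity analysis.

RDM construction (1 - Spearman between activation patterns), category
averaging, label-permutation contrasts, classical MDS, Kendall tau-a model
comparison with noise ceilings, and fMRI-MEG fusion.

Conventions
-----------
* RDM vectorization is the strict lower triangle in row-major order
  (:meth:`pareidolia.core.RDM.condensed`); every RDM-to-RDM statistic in
  this module consumes that vector, so label order is the only alignment
  that matters.
* The group RDM is the arithmetic mean of subject RDMs (no rank transform
  before averaging).
* Permutation p-values include the observed statistic in the null
  (+1/+1 convention), so p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import RDM, PatternMatrix, SensorEpochs, StimulusSet, ValidationError, mean_rdm
from .preprocess import stimulus_patterns


# ---------------------------------------------------------------------------
# RDM construction
# ---------------------------------------------------------------------------

def compute_rdm(patterns: PatternMatrix) -> RDM:
    """1 - Spearman rank correlation between every pair of feature vectors.

    Spearman is computed as Pearson on average ranks, which handles ties
    the conventional way.  A constant feature vector has undefined rank
    correlation and raises an error naming the item.
    """
    X = patterns.values
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("patterns: need >=2 items and >=2 features")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValidationError(
            f"patterns: constant feature vector for item(s) "
            f"{[patterns.item_labels[i] for i in bad]} (correlation undefined)"
        )
    ranks = sps.rankdata(X, axis=1)
    corr = np.corrcoef(ranks)
    mat = 1.0 - corr
    mat = np.clip((mat + mat.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(mat, 0.0)
    return RDM(mat, list(patterns.item_labels), metric="one_minus_spearman")


@dataclass
class RDMTimecourse:
    """Per-subject, per-timepoint RDM stacks on a shared label order."""

    values: np.ndarray  # subjects x timepoints x n x n
    labels: list[str]
    times_ms: np.ndarray
    metric: str = "one_minus_spearman"

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subject_rdm(self, subject: int, t_index: int) -> RDM:
        return RDM(self.values[subject, t_index], list(self.labels), self.metric)

    def group_rdm(self, t_index: int) -> RDM:
        """Mean of individual subjects' RDMs at one timepoint."""
        return RDM(self.values[:, t_index].mean(axis=0), list(self.labels), self.metric)

    def subset_items(self, labels: list[str]) -> "RDMTimecourse":
        index = {lab: k for k, lab in enumerate(self.labels)}
        idx = np.array([index[lab] for lab in labels])
        return RDMTimecourse(
            self.values[:, :, idx[:, None], idx[None, :]],
            list(labels),
            self.times_ms,
            self.metric,
        )


def rdm_timecourse(
    epochs_per_subject: list[SensorEpochs], times_ms: np.ndarray | None = None
) -> RDMTimecourse:
    """Stimulus RDMs at every timepoint for every subject.

    Patterns are trial averages per stimulus at each timepoint; the RDM is
    1 - Spearman between those patterns.  ``times_ms`` restricts the grid
    (default: all timepoints of the first subject).
    """
    first = epochs_per_subject[0]
    if times_ms is None:
        times_ms = first.times_ms.copy()
    times_ms = np.asarray(times_ms, dtype=float)
    labels = first.stimulus_ids()
    n = len(labels)
    out = np.empty((len(epochs_per_subject), len(times_ms), n, n))
    for s, ep in enumerate(epochs_per_subject):
        if ep.stimulus_ids() != labels:
            raise ValidationError("epochs: subjects have mismatched stimulus sets")
        for t, tm in enumerate(times_ms):
            pat = stimulus_patterns(ep, tm)
            out[s, t] = compute_rdm(pat).matrix
    return RDMTimecourse(out, labels, times_ms)


# ---------------------------------------------------------------------------
# Category-level statistics
# ---------------------------------------------------------------------------

@dataclass
class CategoryRDM:
    """Category-averaged dissimilarities (the 3x3 inset matrices).

    Unlike a stimulus RDM the diagonal is meaningful: it holds the mean
    *within*-category dissimilarity (self-pairs excluded).
    """

    matrix: np.ndarray
    labels: list[str]
    metric: str = "custom"

    def cell(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[ia, ib])


def category_average(rdm: RDM, categories: list[str]) -> CategoryRDM:
    """Average dissimilarity within/between categories (3x3 for the full design).

    ``categories`` gives the category of each RDM item, in label order.
    Within-category cells exclude the diagonal; a category needs at least
    two items for its within-category cell to be defined.
    """
    if len(categories) != rdm.n:
        raise ValidationError("categories: one label per RDM item required")
    cats = sorted(set(categories), key=lambda c: _category_rank(c))
    cat_arr = np.asarray(categories)
    n_c = len(cats)
    out = np.zeros((n_c, n_c))
    for a in range(n_c):
        ia = np.flatnonzero(cat_arr == cats[a])
        for b in range(a, n_c):
            ib = np.flatnonzero(cat_arr == cats[b])
            block = rdm.matrix[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    raise ValidationError(
                        f"categories: category {cats[a]!r} has <2 items; "
                        "within-category cell undefined"
                    )
                mask = ~np.eye(len(ia), dtype=bool)
                val = block[mask].mean()
            else:
                val = block.mean()
            out[a, b] = out[b, a] = val
    return CategoryRDM(out, cats, rdm.metric)


def _category_rank(cat: str) -> tuple:
    from .core import CATEGORIES

    return (CATEGORIES.index(cat), cat) if cat in CATEGORIES else (len(CATEGORIES), cat)


def category_contrast_perm(
    rdm: RDM,
    categories: list[str],
    contrast: tuple[tuple[str, str], tuple[str, str]],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test on a difference of category-average cells.

    ``contrast`` is ((a1, b1), (a2, b2)): the statistic is
    cell(a1, b1) - cell(a2, b2) of the category-averaged RDM.  The null
    permutes the item-to-category assignment (rows and columns jointly) of
    the full RDM.  Returns (observed difference, two-sided p) with the
    +1/+1 convention.
    """
    if n_perm < 1:
        raise ValidationError("n_perm: must be >= 1")
    rng = np.random.default_rng(seed)
    cat_arr = np.asarray(categories)

    (a1, b1), (a2, b2) = contrast

    def stat(assignment: np.ndarray) -> float:
        avg = category_average(rdm, list(assignment))
        return avg.cell(a1, b1) - avg.cell(a2, b2)

    observed = stat(cat_arr)
    exceed = 0
    for _ in range(n_perm):
        null = stat(rng.permutation(cat_arr))
        if abs(null) >= abs(observed) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def classical_mds(rdm: RDM, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical multidimensional scaling.

    Double-centers the squared dissimilarities, eigendecomposes, and
    returns coordinates from the top-k nonnegative eigenvalues together
    with all eigenvalues (descending).  Axis signs are fixed so the first
    nonzero loading of each axis is positive, making the embedding
    deterministic.  If fewer than ``k`` positive eigenvalues exist, fewer
    dimensions are returned with a warning.
    """
    D = rdm.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * max(evals.max(), 0.0))
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k_eff} dimensions",
            stacklevel=2,
        )
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for j in range(k_eff):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords, evals


# ---------------------------------------------------------------------------
# Kendall tau-a
# ---------------------------------------------------------------------------

def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Ties in either vector count as neither concordant nor discordant but
    stay in the denominator, which is what distinguishes tau-a from the
    tau-b most libraries implement.  Inputs are typically vectorized RDM
    lower triangles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x/y: equal-length 1-D vectors required")
    n = x.size
    if n < 2:
        raise ValidationError("x/y: need length >= 2")
    sx = np.sign(x[:, None] - x[None, :]).astype(np.int8)
    sy = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    # each unordered pair appears twice in the product matrix (diagonal is 0)
    num = int(np.sum(sx * sy, dtype=np.int64)) // 2
    return num / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Model comparison over time and the noise ceiling
# ---------------------------------------------------------------------------

@dataclass
class ModelCorrelation:
    """Per-subject tau-a between a model RDM and the neural RDM over time."""

    tau: np.ndarray  # subjects x timepoints
    times_ms: np.ndarray
    model_name: str = "model"

    @property
    def group_mean(self) -> np.ndarray:
        return self.tau.mean(axis=0)

    @property
    def group_sem(self) -> np.ndarray:
        n = self.tau.shape[0]
        return self.tau.std(axis=0, ddof=1) / np.sqrt(n)


def _aligned_condensed(rdm: RDM, labels: list[str]) -> np.ndarray:
    return rdm.subset(labels).condensed()


def model_correlation_timecourse(
    rdm_tc: RDMTimecourse,
    model_rdm: RDM,
    stimuli: StimulusSet | None = None,
    exclude_categories: set[str] = frozenset({"human_face"}),
    model_name: str = "model",
) -> ModelCorrelation:
    """Correlate a fixed model RDM with the time-varying neural RDM.

    Human faces are excluded by default: their strong neural response
    otherwise dominates and the question of interest is how an illusory
    face modulates the representation of an *object*.  tau-a is computed
    per subject and timepoint on the canonical lower-triangle vectors.
    """
    if stimuli is not None and exclude_categories:
        keep = stimuli.subset(set(exclude_categories))
        keep = [lab for lab in keep if lab in rdm_tc.labels]
    else:
        keep = list(rdm_tc.labels)
    missing = [lab for lab in keep if lab not in model_rdm.labels]
    if missing or len(keep) < 3:
        raise ValidationError(
            f"model_rdm: label mismatch after subsetting; missing {missing}"
        )
    sub_tc = rdm_tc.subset_items(keep)
    model_vec = _aligned_condensed(model_rdm, keep)
    S, T = sub_tc.values.shape[:2]
    tril = np.tril_indices(len(keep), k=-1)
    tau = np.empty((S, T))
    for s in range(S):
        for t in range(T):
            tau[s, t] = kendall_tau_a(sub_tc.values[s, t][tril], model_vec)
    return ModelCorrelation(tau, sub_tc.times_ms, model_name)


def noise_ceiling(subject_rdms: list[RDM]) -> tuple[float, float]:
    """Lower and upper bound on the attainable model correlation.

    upper: mean over subjects of tau-a(subject RDM, mean RDM of all
    subjects).  lower: the same with the subject's own RDM excluded from
    the mean.  Requires >= 2 subjects.
    """
    if len(subject_rdms) < 2:
        raise ValidationError("subject_rdms: need >= 2 subjects")
    labels = subject_rdms[0].labels
    vecs = np.array([_aligned_condensed(r, labels) for r in subject_rdms])
    total = vecs.sum(axis=0)
    n = len(subject_rdms)
    upper = np.mean([kendall_tau_a(v, total / n) for v in vecs])
    lower = np.mean(
        [kendall_tau_a(vecs[i], (total - vecs[i]) / (n - 1)) for i in range(n)]
    )
    return float(lower), float(upper)


def fusion_timecourse(
    fmri_rdms: dict[str, RDM],
    rdm_tc: RDMTimecourse,
    stimuli: StimulusSet,
    exclude_categories: set[str] = frozenset({"human_face"}),
) -> dict[str, ModelCorrelation]:
    """fMRI-MEG fusion: each ROI's group fMRI RDM against the MEG timecourse.

    The fMRI RDM is a group average (the two cohorts are different
    individuals), correlated with every MEG subject's RDM at every
    timepoint; inference is then across MEG subjects.  Human faces are
    removed so the matrices cover objects with and without an illusory
    face (64 x 64 at full scale).
    """
    return {
        roi: model_correlation_timecourse(
            rdm_tc, roi_rdm, stimuli, exclude_categories, model_name=roi
        )
        for roi, roi_rdm in fmri_rdms.items()
    }


__all__ = [
    "compute_rdm",
    "rdm_timecourse",
    "RDMTimecourse",
    "category_average",
    "CategoryRDM",
    "category_contrast_perm",
    "classical_mds",
    "kendall_tau_a",
    "model_correlation_timecourse",
    "ModelCorrelation",
    "noise_ceiling",
    "fusion_timecourse",
    "mean_rdm",
]
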