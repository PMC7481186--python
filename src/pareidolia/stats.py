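"""Group-level inference for timecourses and ROI summaries.

One-sample t-tests against chance, Benjamini-Hochberg / Bonferroni
multiple-comparison adjustment, 1-D threshold-free cluster enhancement
(TFCE), and family-wise sign-flip permutation inference over timecourses.

TFCE integrates supra-threshold cluster extent and height,
``TFCE(t) = sum_h extent(h, t)^E * h^H * dh``, removing the need for an
arbitrary cluster-forming threshold.  Defaults E = 0.5, H = 2, dh = 0.1
are the standard parameterization of the widely used implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

#: Cap on |t| in permutation maps; keeps the TFCE integral finite when a
#: timepoint has zero across-subject variance.
T_CAP = 100.0


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    ci_lower: float  # one-sided 95% CI lower bound (upper bound is +inf)


def ttest_vs_chance(
    values: np.ndarray, chance: float = 50.0, tail: str = "one"
) -> TTestResult:
    """One-sample t-test of per-subject values against chance.

    ``tail="one"`` tests the directional hypothesis mean > chance
    (decoding above chance); ``"two"`` is two-sided.  Cohen's d is
    mean/SD of the differences; the CI is the one-sided 95% lower bound
    on the mean, reported in the same units as ``values``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("values: need >= 2 subjects")
    diffs = values - chance
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValidationError("values: zero variance across subjects")
    n = diffs.size
    mean = diffs.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    if tail == "one":
        p = sps.t.sf(t, df)
    elif tail == "two":
        p = 2 * sps.t.sf(abs(t), df)
    else:
        raise ValidationError(f"tail: unknown tail {tail!r}")
    d = mean / sd
    ci_lower = chance + mean - sps.t.ppf(0.95, df) * se
    return TTestResult(float(t), df, float(p), float(d), float(ci_lower))


def ttest_paired(
    a: np.ndarray, b: np.ndarray, tail: str = "two", bonferroni_k: int = 1
) -> TTestResult:
    """Paired t-test (e.g. illusory vs yoked matched ratings) with optional
    Bonferroni correction of the p-value for k comparisons."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("a/b: shape mismatch")
    res = ttest_vs_chance(a - b, chance=0.0, tail=tail)
    p = min(1.0, res.p * max(bonferroni_k, 1))
    return TTestResult(res.t, res.df, p, res.cohen_d, res.ci_lower)


# ---------------------------------------------------------------------------
# Multiple-comparison adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(
    pvals: np.ndarray, method: str = "bh_fdr", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted p-values and rejection mask.

    ``bh_fdr`` is Benjamini-Hochberg step-up (with the usual monotonicity
    enforcement); ``bonferroni`` is min(1, k * p).  Output order matches
    input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValidationError("pvals: values outside [0, 1]")
    mapping = {"bh_fdr": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in mapping:
        raise ValidationError(f"method: unknown method {method!r}")
    reject, adjusted, _, _ = multipletests(pvals, alpha=alpha, method=mapping[method])
    return adjusted, reject


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_transform(
    stat_map: np.ndarray, e: float = 0.5, h: float = 2.0, dh: float = 0.1
) -> np.ndarray:
    """1-D TFCE over a time axis.

    Positive values are enhanced by summing extent^e * height^h * dh over
    height steps dh, 2dh, ... up to the map maximum; negative values are
    processed on the negated map and re-negated, so the transform is
    sign-symmetric.
    """
    if dh <= 0:
        raise ValidationError("dh: must be positive")
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.ndim != 1:
        raise ValidationError("stat_map: expected a 1-D (time) map")
    out = np.zeros_like(stat_map)
    for sign in (1.0, -1.0):
        m = sign * stat_map
        peak = m.max(initial=0.0)
        if peak <= 0:
            continue
        n_steps = int(np.floor(peak / dh + 1e-9))
        for k in range(1, n_steps + 1):
            height = k * dh
            supra = m >= height - 1e-12
            padded = np.diff(np.r_[0, supra.astype(np.int8), 0])
            starts = np.flatnonzero(padded == 1)
            ends = np.flatnonzero(padded == -1)
            for s, t in zip(starts, ends):
                out[s:t] += sign * (t - s) ** e * height**h * dh
    return out


# ---------------------------------------------------------------------------
# Sign-flip permutation inference with TFCE
# ---------------------------------------------------------------------------

@dataclass
class TFCEInference:
    z_map: np.ndarray
    significant: np.ndarray  # boolean mask over timepoints
    observed_tfce: np.ndarray
    threshold: float
    n_perm: int


def _t_maps(subject_maps: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps for many sign patterns at once.

    ``subject_maps`` is subjects x T, ``signs`` is patterns x subjects.
    Sum of squares is sign-invariant, so everything vectorizes.
    """
    n = subject_maps.shape[0]
    sums = signs @ subject_maps                      # patterns x T
    mean = sums / n
    ssq = np.sum(subject_maps**2, axis=0)            # T (flip-invariant)
    var = (ssq - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    t = mean / np.sqrt(var / n)
    # zero across-subject variance (e.g. every subject at ceiling) makes t
    # blow up; cap at a value far beyond anything attainable with real
    # variability so the TFCE height integral stays finite
    return np.clip(t, -T_CAP, T_CAP)


def tfce_signperm_inference(
    subject_maps: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tail: str = "one",
    seed: int | None = None,
    e: float = 0.5,
    h: float = 2.0,
    dh: float = 0.1,
) -> TFCEInference:
    """Family-wise corrected TFCE inference across a timecourse.

    ``subject_maps`` holds per-subject (statistic - null value) maps,
    subjects x timepoints.  The observed group t-map is TFCE-enhanced;
    the null distribution flips each subject's map sign at random (the
    statistic is assumed sign-symmetric under H0), and family-wise
    control comes from the max-TFCE distribution across time.  For
    n <= 12 subjects the 2^n sign patterns are enumerated exhaustively
    instead of sampled.  z values are normal quantiles of the max-null
    exceedance probability of each timepoint's TFCE score.
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    if subject_maps.ndim != 2 or subject_maps.shape[0] < 2:
        raise ValidationError("subject_maps: expected subjects x timepoints, >=2 subjects")
    if n_perm < 1:
        raise ValidationError("n_perm: must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution", stacklevel=2)
    n_subj, n_t = subject_maps.shape

    def enhance(tmap: np.ndarray) -> np.ndarray:
        scored = tfce_transform(tmap, e=e, h=h, dh=dh)
        return np.abs(scored) if tail == "two" else scored

    if tail not in ("one", "two"):
        raise ValidationError(f"tail: unknown tail {tail!r}")

    observed_t = _t_maps(subject_maps, np.ones((1, n_subj)))[0]
    observed = enhance(observed_t)

    if n_subj <= 12:
        patterns = np.array(
            [[1 if (i >> b) & 1 else -1 for b in range(n_subj)]
             for i in range(2**n_subj)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    tmaps = _t_maps(subject_maps, patterns)
    max_null = np.array([enhance(tm).max(initial=0.0) for tm in tmaps])
    n_eff = max_null.size
    threshold = float(np.quantile(max_null, 1 - alpha))
    significant = observed > threshold
    p_per_t = (1 + np.sum(max_null[None, :] >= observed[:, None], axis=1)) / (1 + n_eff)
    z_map = sps.norm.isf(np.clip(p_per_t, 1e-12, 1 - 1e-12))
    return TFCEInference(z_map, significant, observed, threshold, n_eff)


def significant_windows(
    mask: np.ndarray, times_ms: np.ndarray
) -> list[tuple[float, float]]:
    """(onset_ms, offset_ms) of each contiguous run of significant timepoints."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.diff(np.r_[0, mask.astype(np.int8), 0])
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(float(times_ms[s]), float(times_ms[t - 1])) for s, t in zip(starts, ends)]
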