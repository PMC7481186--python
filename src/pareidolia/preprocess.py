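"""Minimal MEG preprocessing: downsampling, PCA reduction, trial averaging.

The pipeline deliberately performs minimal preprocessing: epochs are
bin-mean downsampled (e.g. 1000 Hz -> 200 Hz, 5 ms resolution), channels
are reduced with PCA keeping the components explaining 99% of the
variance, and per-stimulus patterns are trial averages at a timepoint.
Decoding consumes raw single trials; RDMs consume the trial-averaged
stimulus patterns.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .core import PatternMatrix, SensorEpochs, ValidationError


def downsample(epochs: SensorEpochs, target_rate_hz: float) -> SensorEpochs:
    """Bin-mean downsampling to ``target_rate_hz``.

    Each output sample is the mean of its block of consecutive source
    samples (anti-aliasing by averaging, deterministic); output times are
    the bin centers.  The source rate must be an integer multiple of the
    target rate.  Trailing samples that do not fill a bin are dropped.
    """
    src = epochs.sample_rate_hz
    if target_rate_hz <= 0:
        raise ValidationError("target_rate_hz: must be positive")
    factor = src / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        divisors = [src / k for k in range(1, int(src) + 1) if (src / k).is_integer()]
        nearest = min(divisors, key=lambda r: abs(r - target_rate_hz))
        raise ValidationError(
            f"target_rate_hz: {target_rate_hz} does not divide source rate "
            f"{src}; nearest valid rate is {nearest}"
        )
    factor = int(round(factor))
    if factor == 1:
        return SensorEpochs(
            epochs.data.copy(), epochs.times_ms.copy(), epochs.trials.copy(),
            src, epochs.feature_space, epochs.subject,
        )
    n_out = epochs.n_times // factor
    if n_out < 1:
        raise ValidationError("target_rate_hz: epoch too short for this rate")
    trimmed = epochs.data[:, :, : n_out * factor]
    data = trimmed.reshape(epochs.n_trials, epochs.n_channels, n_out, factor).mean(axis=3)
    times = epochs.times_ms[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    return SensorEpochs(
        data, times, epochs.trials.copy(), target_rate_hz,
        epochs.feature_space, epochs.subject,
    )


def pca_reduce(epochs: SensorEpochs, var_retained: float = 0.99) -> SensorEpochs:
    """Reduce channels to principal components explaining ``var_retained``.

    The PCA is fitted once per subject on all trial-timepoints
    (observations = trials x timepoints, variables = channels), then the
    smallest k with cumulative explained variance >= ``var_retained`` is
    kept.  ``var_retained = 1.0`` keeps every component
    (min(channels, observations)), a lossless orthogonal rotation.  The
    fitted loadings are attached to the result as ``pca_components``.
    """
    if not 0 < var_retained <= 1:
        raise ValidationError("var_retained: must be in (0, 1]")
    if epochs.n_trials < 2:
        raise ValidationError("epochs: need >= 2 trials to fit PCA")
    n_tr, n_ch, n_t = epochs.data.shape
    # observations along rows: trial-timepoints
    X = np.transpose(epochs.data, (0, 2, 1)).reshape(n_tr * n_t, n_ch)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    if var_retained >= 1.0:
        k = min(n_ch, X.shape[0])
        k = min(k, scores.shape[1])
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, var_retained - 1e-12) + 1)
        k = min(k, scores.shape[1])
    reduced = scores[:, :k].reshape(n_tr, n_t, k).transpose(0, 2, 1)
    out = SensorEpochs(
        reduced, epochs.times_ms.copy(), epochs.trials.copy(),
        epochs.sample_rate_hz, "components", epochs.subject,
    )
    out.pca_components = pca.components_[:k]  # k x channels loadings
    out.pca_mean = pca.mean_
    out.explained_variance_ratio = pca.explained_variance_ratio_[:k]
    return out


def stimulus_patterns(epochs: SensorEpochs, time_ms: float) -> PatternMatrix:
    """One feature vector per stimulus: the trial average at a timepoint.

    ``time_ms`` is mapped to the nearest grid timepoint.  Stimulus order
    is sorted id order (the canonical RDM label order).
    """
    t = epochs.time_index(time_ms)
    ids = epochs.stimulus_ids()
    stim_col = epochs.trials["stimulus_id"].to_numpy()
    rows = np.empty((len(ids), epochs.n_channels))
    for k, sid in enumerate(ids):
        idx = np.flatnonzero(stim_col == sid)
        if idx.size == 0:
            raise ValidationError(f"trials: stimulus {sid!r} has zero trials")
        rows[k] = epochs.data[idx, :, t].mean(axis=0)
    return PatternMatrix(rows, ids, feature_space=epochs.feature_space)
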