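"""Synthetic data emulating the illusory-face experiment design.

The generator produces MEG-like epochs, fMRI-like ROI beta patterns,
behavioral face-ness ratings, and synthetic stimulus images for a
96-image (32 human faces / 32 illusory faces / 32 yoked matched objects)
design, so every downstream stage of the pipeline can be exercised and
calibrated without any downloads.

The representational content is controlled explicitly: a time-varying
3x3 category-distance matrix ``delta(t)`` (the *trajectory*) specifies
the geometry the MEG data should carry at each latency, and per-ROI
distance matrices specify what each simulated fMRI region carries.  At
each timepoint the three category centroids are embedded in a 2-D latent
space whose pairwise distances equal ``delta(t)`` (classical MDS); each
stimulus adds a fixed per-exemplar offset in an orthogonal latent
subspace, scaled by the within-category spread ``sigma_ex(t)``; sensors
see a subject-specific random linear mixture of the latent vector plus
i.i.d. Gaussian noise.

The default trajectory follows the empirical dynamics: signal onset
around 80 ms, all three category pairs separable by 130 ms, a first peak
near 160 ms at which illusory faces sit closer to human faces than the
matched objects do, and by 260 ms the illusory faces have collapsed back
onto the matched objects while the human-vs-object distinction peaks a
second time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    SensorEpochs,
    StimulusSet,
    ValidationError,
    make_stimulus_set,
)

_LATENT_CENTROID_DIM = 2  # smallest space embedding any 3x3 distance matrix


def _check_delta(delta: np.ndarray, where: str) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (3, 3):
        raise ValidationError(f"{where}: expected a 3x3 matrix, got {delta.shape}")
    for i in range(3):
        for j in range(3):
            if delta[i, j] < 0:
                raise ValidationError(
                    f"{where}: negative distance at cell ({i},{j})"
                )
            if abs(delta[i, j] - delta[j, i]) > 1e-12:
                raise ValidationError(
                    f"{where}: asymmetric at cell ({i},{j}) vs ({j},{i})"
                )
    if np.any(np.abs(np.diag(delta)) > 1e-12):
        k = int(np.argmax(np.abs(np.diag(delta))))
        raise ValidationError(f"{where}: nonzero diagonal at cell ({k},{k})")
    return delta


def _embed_centroids(delta: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """3 category centroids in 2-D with pairwise distances ``delta`` (Torgerson)."""
    n = 3
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta**2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    scale = max(evals.max(), 1.0)
    if evals.min() < -tol * scale:
        raise ValidationError(
            f"delta: not embeddable in Euclidean space "
            f"(negative eigenvalue {evals.min():.3g}); check the triangle inequality"
        )
    order = np.argsort(evals)[::-1][:_LATENT_CENTROID_DIM]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


@dataclass(frozen=True)
class Keyframe:
    time_ms: float
    delta: np.ndarray  # 3x3 category distances, CATEGORIES order
    sigma_ex: float    # within-category exemplar spread


@dataclass
class TrajectoryConfig:
    """Piecewise-linear category-geometry trajectory.

    ``delta(t)`` and ``sigma_ex(t)`` interpolate linearly between
    keyframes, are exactly zero before ``onset_ms``, ramp from zero at
    onset to the first keyframe, and hold the last keyframe's value
    afterwards.
    """

    keyframes: list[Keyframe]
    onset_ms: float = 80.0

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ValidationError("keyframes: at least one keyframe required")
        times = [kf.time_ms for kf in self.keyframes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("keyframes: times must be strictly increasing")
        if times[0] < self.onset_ms:
            raise ValidationError("keyframes: first keyframe precedes onset_ms")
        checked = []
        for kf in self.keyframes:
            delta = _check_delta(kf.delta, f"keyframe at {kf.time_ms} ms")
            if kf.sigma_ex < 0:
                raise ValidationError(
                    f"keyframe at {kf.time_ms} ms: negative sigma_ex"
                )
            checked.append(Keyframe(float(kf.time_ms), delta, float(kf.sigma_ex)))
            _embed_centroids(delta)  # reject unembeddable geometry at build time
        self.keyframes = checked
        # implicit zero keyframe at onset for the ramp-in
        self._times = np.array([self.onset_ms] + [kf.time_ms for kf in self.keyframes])
        self._deltas = np.concatenate(
            [np.zeros((1, 3, 3))] + [kf.delta[None] for kf in self.keyframes]
        )
        self._sigmas = np.array([0.0] + [kf.sigma_ex for kf in self.keyframes])
        if self.keyframes[0].time_ms == self.onset_ms:
            self._times = self._times[1:]
            self._deltas = self._deltas[1:]
            self._sigmas = self._sigmas[1:]

    def delta_at(self, t_ms: float | np.ndarray) -> np.ndarray:
        """Interpolated 3x3 distance matrix; shape (..., 3, 3)."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.empty(t.shape + (3, 3))
        for i in range(3):
            for j in range(3):
                out[..., i, j] = np.interp(t, self._times, self._deltas[:, i, j])
        out[t < self.onset_ms] = 0.0
        return out if np.ndim(t_ms) else out[0]

    def sigma_at(self, t_ms: float | np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.interp(t, self._times, self._sigmas)
        out[t < self.onset_ms] = 0.0
        return out if np.ndim(t_ms) else float(out[0])


def build_trajectory(
    keyframes: list[tuple[float, np.ndarray, float]], onset_ms: float = 80.0
) -> TrajectoryConfig:
    """Build a trajectory from (time_ms, delta, sigma_ex) tuples."""
    return TrajectoryConfig(
        [Keyframe(t, np.asarray(d, dtype=float), s) for t, d, s in keyframes],
        onset_ms=onset_ms,
    )


def _delta(d_hi: float, d_hm: float, d_im: float) -> np.ndarray:
    """3x3 distance matrix in (human, illusory, matched) order."""
    return np.array(
        [[0.0, d_hi, d_hm], [d_hi, 0.0, d_im], [d_hm, d_im, 0.0]]
    )


def default_trajectory() -> TrajectoryConfig:
    """The canonical dynamics with keyframes at 130, 160 and 260 ms.

    130 ms: all three pairs separable.  160 ms: first peak; illusory
    faces closer to human faces than matched objects are, and maximally
    separated from their matched objects.  260 ms: second human-vs-object
    peak while illusory faces have regrouped with the matched objects.
    A weak sustained tail decays through the rest of the epoch.
    """
    return build_trajectory(
        [
            (130.0, _delta(0.8, 1.0, 0.4), 0.30),
            (160.0, _delta(1.2, 1.8, 1.0), 0.40),
            (260.0, _delta(1.6, 1.8, 0.25), 0.40),
            (500.0, _delta(0.8, 0.9, 0.15), 0.30),
            (1000.0, _delta(0.3, 0.35, 0.05), 0.20),
        ],
        onset_ms=80.0,
    )


# ---------------------------------------------------------------------------
# MEG generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMEGConfig:
    """Design parameters of the simulated MEG experiment.

    Defaults mirror the empirical design: 22 subjects, 160 axial
    gradiometer channels, 96 stimuli (32 per category) presented 4 times
    per run over 6 runs (24 repeats, 2304 trials), epochs -100..1000 ms
    sampled at 1000 Hz.  ``signal_gain`` scales the injected geometry
    relative to unit-variance sensor noise; 0 yields pure-noise data for
    null calibration.
    """

    n_subjects: int = 22
    n_channels: int = 160
    n_exemplars_per_category: int = 32
    n_runs: int = 6
    repeats_per_run: int = 4
    sample_rate_hz: float = 1000.0
    epoch_ms: tuple[float, float] = (-100.0, 1000.0)
    sensor_noise_sd: float = 1.0
    signal_gain: float = 1.0
    exemplar_dim: int = 2
    yoke_offset_corr: float = 0.5
    evoked_gain: float = 10.0
    evoked_dim: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_subjects", "n_channels", "n_exemplars_per_category",
            "n_runs", "repeats_per_run",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name}: must be positive")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz: must be positive")
        t0, t1 = self.epoch_ms
        if not (t0 <= 0.0 <= t1):
            raise ValidationError("epoch_ms: window must contain stimulus onset (0)")
        if self.sensor_noise_sd < 0:
            raise ValidationError("sensor_noise_sd: must be >= 0")
        if not -1 <= self.yoke_offset_corr <= 1:
            raise ValidationError("yoke_offset_corr: must be in [-1, 1]")

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sample_rate_hz
        n = int(round((self.epoch_ms[1] - self.epoch_ms[0]) / step)) + 1
        return self.epoch_ms[0] + step * np.arange(n)

    @property
    def n_trials(self) -> int:
        return 3 * self.n_exemplars_per_category * self.n_runs * self.repeats_per_run


def _exemplar_offsets(
    stimuli: StimulusSet, dim: int, yoke_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Fixed latent identity offsets, one row per stimulus (stimuli.ids order).

    Yoked illusory/matched pairs get correlated offsets (shared visual
    structure of the same object kind); human faces are independent.
    """
    ids = stimuli.ids
    pos = {sid: k for k, sid in enumerate(ids)}
    offsets = np.zeros((len(ids), dim))
    done: set[str] = set()
    for sid in ids:
        if sid in done:
            continue
        item = stimuli[sid]
        if item.category == "human_face":
            offsets[pos[sid]] = rng.standard_normal(dim)
            done.add(sid)
        elif item.category == "illusory_face":
            a = rng.standard_normal(dim)
            b = yoke_corr * a + np.sqrt(1 - yoke_corr**2) * rng.standard_normal(dim)
            offsets[pos[sid]] = a
            offsets[pos[item.yoke_id]] = b
            done.update({sid, item.yoke_id})
    return offsets


def generate_meg_dataset(
    cfg: SyntheticMEGConfig, traj: TrajectoryConfig | None = None
) -> list[SensorEpochs]:
    """Simulate one epochs container per subject.

    Construction per the module contract: latent = [centroid of the
    stimulus category at t (2-D, distances = delta(t)); sigma_ex(t) x
    fixed exemplar offset]; sensors = subject mixing matrix @ latent x
    signal_gain + N(0, sensor_noise_sd).  Fully determined by
    ``cfg.seed``.
    """
    traj = traj or default_trajectory()
    stimuli = make_stimulus_set(cfg.n_exemplars_per_category)
    ids = stimuli.ids
    cat_idx = np.array([CATEGORIES.index(stimuli.category_of(s)) for s in ids])
    times = cfg.times_ms
    T = times.size
    # extra latent dimensions carry a stimulus-independent evoked response whose
    # direction drifts smoothly over time.  A shared evoked component makes
    # correlation-based dissimilarity increase monotonically with latent
    # distance (without it, 1-corr measures only the angle between centered
    # patterns and need not track the injected geometry), and spreading it over
    # several drifting directions keeps it visible to rank correlation after
    # PCA rotation, as the spatially extended evoked fields of real MEG are.
    latent_dim = _LATENT_CENTROID_DIM + cfg.exemplar_dim + cfg.evoked_dim

    ss = np.random.SeedSequence(cfg.seed)
    shared_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(cfg.n_subjects + 1)[1:]

    offsets = _exemplar_offsets(stimuli, cfg.exemplar_dim, cfg.yoke_offset_corr,
                                shared_rng)

    # latent trajectory: (T, n_stim, latent_dim)
    deltas = traj.delta_at(times)
    sigmas = traj.sigma_at(times)
    # evoked waveform: smooth random per-dimension time courses, unit-normalized
    # per timepoint, scaled by the signal envelope (zero before onset)
    env_max = sigmas.max(initial=0.0)
    envelope = sigmas / env_max if env_max > 0 else np.zeros_like(sigmas)
    if cfg.evoked_dim > 0:
        from scipy.ndimage import gaussian_filter1d

        g = gaussian_filter1d(
            shared_rng.standard_normal((T, cfg.evoked_dim)), sigma=2.0, axis=0
        )
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        g = g / np.maximum(norms, 1e-12)
        evoked = cfg.evoked_gain * envelope[:, None] * g
    else:
        evoked = np.zeros((T, 0))
    latent = np.zeros((T, len(ids), latent_dim))
    off_sl = slice(_LATENT_CENTROID_DIM, _LATENT_CENTROID_DIM + cfg.exemplar_dim)
    for t in range(T):
        centroids = _embed_centroids(deltas[t])
        latent[t, :, :_LATENT_CENTROID_DIM] = centroids[cat_idx]
        latent[t, :, off_sl] = sigmas[t] * offsets
        latent[t, :, _LATENT_CENTROID_DIM + cfg.exemplar_dim:] = evoked[t]

    datasets = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        mixing = rng.standard_normal((cfg.n_channels, latent_dim)) / np.sqrt(latent_dim)
        # (n_stim, channels, T)
        stim_signal = np.einsum("cd,tsd->sct", mixing, latent) * cfg.signal_gain

        stim_seq, runs, repeats = [], [], []
        for r in range(cfg.n_runs):
            block = np.repeat(np.arange(len(ids)), cfg.repeats_per_run)
            order = rng.permutation(block)
            seen: dict[int, int] = {}
            for stim in order:
                seen[stim] = seen.get(stim, 0) + 1
                stim_seq.append(stim)
                runs.append(r)
                repeats.append((r * cfg.repeats_per_run) + seen[stim] - 1)
        stim_seq = np.array(stim_seq)

        data = stim_signal[stim_seq]
        if cfg.sensor_noise_sd > 0:
            data = data + cfg.sensor_noise_sd * rng.standard_normal(data.shape)
        else:
            data = data.copy()
        trials = pd.DataFrame(
            {
                "stimulus_id": [ids[k] for k in stim_seq],
                "category": [CATEGORIES[cat_idx[k]] for k in stim_seq],
                "run": runs,
                "repeat": repeats,
            }
        )
        datasets.append(
            SensorEpochs(data, times, trials, cfg.sample_rate_hz,
                         "sensors", subject=f"meg-{s:02d}")
        )
    return datasets


# ---------------------------------------------------------------------------
# fMRI generator
# ---------------------------------------------------------------------------

@dataclass
class ROIProfile:
    """Representational profile of one simulated region of interest.

    ``delta`` fixes the category geometry the region carries (CATEGORIES
    order).  Face-selective profiles separate illusory faces from their
    matched objects (delta[1,2] > 0); object/scene profiles do not.
    """

    roi_name: str
    delta: np.ndarray
    exemplar_spread: float = 0.4
    voxel_range: tuple[int, int] = (100, 400)

    def __post_init__(self) -> None:
        self.delta = _check_delta(self.delta, f"ROI {self.roi_name!r} delta")
        if self.exemplar_spread < 0:
            raise ValidationError(f"ROI {self.roi_name!r}: negative exemplar_spread")
        lo, hi = self.voxel_range
        if lo < 1 or hi < lo:
            raise ValidationError(
                f"ROI {self.roi_name!r}: invalid voxel_range {self.voxel_range}"
            )


def default_roi_profiles() -> list[ROIProfile]:
    """Four ROI profiles with the empirically observed ordinal pattern.

    FFA and OFA separate illusory faces from matched objects (FFA most
    strongly); LO and PPA carry the face/object distinction but zero
    illusory/matched separation.  Voxel count ranges follow the reported
    per-ROI sizes.
    """
    return [
        ROIProfile("FFA", _delta(1.0, 1.4, 0.8), 0.4, (86, 577)),
        ROIProfile("OFA", _delta(1.0, 1.3, 0.75), 0.4, (101, 316)),
        ROIProfile("LO", _delta(1.2, 1.2, 0.0), 0.4, (70, 543)),
        ROIProfile("PPA", _delta(1.0, 1.0, 0.0), 0.4, (277, 712)),
    ]


@dataclass
class ROIBetas:
    """Per-ROI beta stack for one subject: stimuli x runs x voxels."""

    values: np.ndarray
    stimulus_ids: list[str]
    roi_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values: expected stimuli x runs x voxels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values: contains NaN or infinite values")
        if len(self.stimulus_ids) != self.values.shape[0]:
            raise ValidationError("stimulus_ids: length mismatch with values")

    def run_average(self) -> np.ndarray:
        return self.values.mean(axis=1)


def generate_fmri_dataset(
    n_subjects: int = 16,
    n_runs: int = 7,
    profiles: list[ROIProfile] | None = None,
    seed: int = 0,
    n_exemplars_per_category: int = 32,
    run_noise_sd: float = 3.0,
    signal_gain: float = 1.0,
    exemplar_dim: int = 2,
    yoke_offset_corr: float = 0.5,
    baseline: float = 2.0,
) -> tuple[list[dict[str, ROIBetas]], StimulusSet]:
    """Simulate per-subject, per-ROI beta stacks (stimuli x runs x voxels).

    Betas are an ROI-specific random projection of (category centroid per
    the ROI's delta + exemplar offset) plus independent run-level noise.
    Each stimulus appears once per run, as in the empirical seven-run
    event-related design.  Returns (datasets, stimulus set).
    """
    if n_runs < 2:
        raise ValidationError("n_runs: >=2 runs required for run-wise cross-validation")
    profiles = profiles if profiles is not None else default_roi_profiles()
    stimuli = make_stimulus_set(n_exemplars_per_category)
    ids = stimuli.ids
    cat_idx = np.array([CATEGORIES.index(stimuli.category_of(s)) for s in ids])
    # +1: shared baseline-response dimension.  The random voxel projection
    # spreads it over all voxels, which keeps rank-correlation dissimilarity
    # monotone in latent distance (cf. the evoked dimensions of the MEG
    # generator; no PCA is applied to betas, so one dimension suffices here).
    latent_dim = _LATENT_CENTROID_DIM + exemplar_dim + 1

    ss = np.random.SeedSequence(seed)
    shared_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(n_subjects + 1)[1:]

    offsets = _exemplar_offsets(stimuli, exemplar_dim, yoke_offset_corr, shared_rng)
    roi_latents = {}
    for prof in profiles:
        centroids = _embed_centroids(prof.delta)
        lat = np.zeros((len(ids), latent_dim))
        lat[:, :_LATENT_CENTROID_DIM] = centroids[cat_idx]
        lat[:, _LATENT_CENTROID_DIM:-1] = prof.exemplar_spread * offsets
        lat[:, -1] = baseline
        roi_latents[prof.roi_name] = lat

    datasets = []
    for s in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        per_roi = {}
        for prof in profiles:
            lo, hi = prof.voxel_range
            n_vox = int(rng.integers(lo, hi + 1))
            proj = rng.standard_normal((n_vox, latent_dim)) / np.sqrt(latent_dim)
            clean = signal_gain * (roi_latents[prof.roi_name] @ proj.T)  # stim x vox
            betas = np.repeat(clean[:, None, :], n_runs, axis=1)
            if run_noise_sd > 0:
                betas = betas + run_noise_sd * rng.standard_normal(betas.shape)
            per_roi[prof.roi_name] = ROIBetas(betas, list(ids), prof.roi_name)
        datasets.append(per_roi)
    return datasets, stimuli


# ---------------------------------------------------------------------------
# Behavioral ratings generator
# ---------------------------------------------------------------------------

@dataclass
class RatingConfig:
    """Face-ness rating simulation ("how easily can you see a face", 0-10).

    Category means/SDs default to the empirical values: human faces
    9.96/0.10, illusory faces 6.27/0.79, matched objects 0.70/0.36.
    The SDs describe spread of per-image means across items; raters add
    independent noise on top.
    """

    category_means: dict[str, float] = field(
        default_factory=lambda: {
            "human_face": 9.96, "illusory_face": 6.27, "matched_object": 0.70,
        }
    )
    category_sds: dict[str, float] = field(
        default_factory=lambda: {
            "human_face": 0.10, "illusory_face": 0.79, "matched_object": 0.36,
        }
    )
    n_raters: int = 20
    bounds: tuple[float, float] = (0.0, 10.0)
    rater_noise_sd: float = 0.25
    n_exemplars_per_category: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        for cat, m in self.category_means.items():
            if not lo <= m <= hi:
                raise ValidationError(f"category_means[{cat!r}]: {m} outside bounds")
        for cat, s in self.category_sds.items():
            if s < 0:
                raise ValidationError(f"category_sds[{cat!r}]: negative SD")
        if self.n_raters < 1:
            raise ValidationError("n_raters: must be positive")
        if self.rater_noise_sd < 0:
            raise ValidationError("rater_noise_sd: must be >= 0")


def generate_ratings(
    cfg: RatingConfig, stimuli: StimulusSet | None = None
) -> pd.DataFrame:
    """Simulate a rater x image ratings table.

    Per-image latent means are drawn around the category mean with the
    category SD; each rater adds independent Gaussian noise; ratings are
    clipped to the scale bounds.  Seeded and fully reproducible.
    """
    stimuli = stimuli or make_stimulus_set(cfg.n_exemplars_per_category)
    rng = np.random.default_rng(cfg.seed)
    ids = stimuli.ids
    lo, hi = cfg.bounds
    item_means = np.array(
        [
            cfg.category_means[stimuli.category_of(s)]
            + cfg.category_sds[stimuli.category_of(s)] * rng.standard_normal()
            for s in ids
        ]
    )
    ratings = item_means[None, :] + cfg.rater_noise_sd * rng.standard_normal(
        (cfg.n_raters, len(ids))
    )
    ratings = np.clip(ratings, lo, hi)
    return pd.DataFrame(
        ratings, index=[f"rater_{r:02d}" for r in range(cfg.n_raters)], columns=ids
    )


# ---------------------------------------------------------------------------
# Synthetic stimulus images
# ---------------------------------------------------------------------------

def generate_stimulus_images(
    stimuli: StimulusSet, size: int = 256, seed: int = 0
) -> dict[str, np.ndarray]:
    """Synthetic stand-in images for the (undistributed) photo set.

    These are procedurally drawn, not photographs: each yoked pair shares
    an object-like smooth texture; illusory-face images superimpose a
    face-like configuration (two eyes + mouth) on the object texture at
    moderate contrast; human-face images show a high-contrast face
    configuration on a clean background.  The construction preserves the
    property that matters for image-computable models — face-configural
    structure shared between human and illusory images but absent from
    matched objects — without claiming any visual resemblance to the
    original stimuli.  Returns id -> RGB float array in [0, 1].
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size

    def blob_texture(r: np.random.Generator) -> np.ndarray:
        tex = gaussian_filter(r.standard_normal((size, size)), sigma=size / 16)
        tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
        return 0.25 + 0.5 * tex

    def face_layout(img: np.ndarray, contrast: float, r: np.random.Generator) -> None:
        jit = lambda: 0.03 * r.standard_normal()
        for cx in (0.35 + jit(), 0.65 + jit()):
            cy = 0.38 + jit()
            rad = 0.05 + 0.01 * abs(r.standard_normal())
            mask = ((xx - cx) ** 2 + (yy - cy) ** 2) < rad**2
            img[mask] -= contrast
        # mouth: horizontal bar
        cy, cx, hw, hh = 0.68 + jit(), 0.5 + jit(), 0.16, 0.035
        mask = (np.abs(xx - cx) < hw) & (np.abs(yy - cy) < hh)
        img[mask] -= contrast
        # head outline: faint ring
        rr = np.sqrt((xx - 0.5) ** 2 + (yy - 0.52) ** 2)
        ring = np.abs(rr - 0.38) < 0.02
        img[ring] -= 0.5 * contrast

    images: dict[str, np.ndarray] = {}
    for item in stimuli.items:
        r = np.random.default_rng(rng.integers(2**31))
        if item.category == "human_face":
            img = 0.62 + 0.05 * gaussian_filter(
                r.standard_normal((size, size)), sigma=size / 8
            )
            face_layout(img, contrast=0.45, r=r)
        elif item.category == "illusory_face":
            pair_seed = int(
                np.frombuffer(item.yoke_id.encode() + bytes([seed % 256]), dtype=np.uint8).sum()
            )
            img = blob_texture(np.random.default_rng(pair_seed))
            face_layout(img, contrast=0.30, r=r)
        else:  # matched object: same texture family as its illusory partner
            pair_seed = int(
                np.frombuffer(item.id.encode() + bytes([seed % 256]), dtype=np.uint8).sum()
            )
            img = blob_texture(np.random.default_rng(pair_seed))
            img += 0.04 * gaussian_filter(r.standard_normal((size, size)), sigma=size / 12)
        img = np.clip(img, 0.0, 1.0)
        images[item.id] = np.stack([img, img * 0.95, img * 0.9], axis=-1)
    return images
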