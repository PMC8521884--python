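"""Synthetic cohort generator for the remote digital-phenotyping pipeline.

Emulates the study design the analysis assumes: a cohort of treatment
responders assessed weekly by smartphone (days 0, 7, 14, 21, 28) and in
clinic by MADRS (days 0, 14, 28).  A per-subject latent depression severity
on the MADRS scale declines linearly from a truncated-normal baseline
(mean 34.1, SD 4.9, bounds [25, 45]) to ``baseline x (1 - response_fraction)``
at week 4, and drives every digital marker through transparent linear link
functions (declining severity -> more facial expressivity, more speech, more
head movement).  Assessments go missing completely at random.

Two generation paths share the same latent model:

* :func:`simulate_marker_table` — the fast path, emitting the tidy 17-marker
  table directly from the latents; used for statistical calibration.
* :func:`simulate_cohort` + :meth:`CohortDataset.iter_records` — the rendered
  path, emitting per-response OpenFace-dialect frame tables (AU intensities,
  presence flags, head pose) and amplitude traces that the extraction stage
  consumes like real tracker output.

Same seed, bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stimuli as stim
from .catalog import MARKER_CATALOG, STIMULUS_CLASSES
from .facial import DEFAULT_EMOTION_MAP, EMOTION_ORDER

# ---------------------------------------------------------------------------
# constants of the generative model
# ---------------------------------------------------------------------------

#: OpenFace intensity/presence AU set emitted by the generator.
AU_IDS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

#: Presence flag = intensity strictly above this 0-5 threshold.
AU_ACTIVATION_THRESHOLD = 1.0

#: Fraction of frames inside emotion episodes at default settings.
ACTIVE_FRACTION = 0.6

#: Smartphone assessment days (weekly) and clinic MADRS days.
ASSESSMENT_DAYS = (0, 7, 14, 21, 28)
STUDY_LENGTH_DAYS = 28

#: Baseline MADRS distribution: truncated normal.
BASELINE_MEAN = 34.1
BASELINE_SD = 4.9
BASELINE_RANGE = (25.0, 45.0)

#: Reference severity at which the link-function intercepts are anchored.
REF_SEVERITY = 34.0

#: Severity -> latent link slopes (per MADRS point of improvement) and
#: anchor values at REF_SEVERITY.  These define the generator's default
#: treatment effect.
LINK_SLOPES = {
    "expressivity": 1.0 / 15.0,  # AU-intensity units per MADRS point
    "voice_fraction": 0.010,
    "movement_rate": 0.020,  # tracker units/frame
    "head_pose_rate": 0.0005,  # radians/frame
}
LINK_ANCHORS = {
    "expressivity": 1.0,
    "voice_fraction": 0.55,
    "movement_rate": 0.50,
    "head_pose_rate": 0.012,
}
LINK_BOUNDS = {
    "expressivity": (0.0, 5.0),
    "voice_fraction": (0.02, 0.98),
    "movement_rate": (0.0, np.inf),
    "head_pose_rate": (0.0, np.inf),
}

#: Per-assessment observation noise for the marker-level fast path.
DEFAULT_NOISE_SD = {
    "emotion_intensity": 0.05,
    "emotion_count": 0.03,
    "voice_percentage": 0.04,
    "head_movement": 0.06,
    "head_pose": 0.002,
}

#: Day-to-day wobble of the latent severity around its linear trajectory.
TRAJECTORY_JITTER_SD = 1.5

#: Nominal per-emotion share of episode time (6 emotions, uniform).
EPISODE_SHARE = ACTIVE_FRACTION / len(EMOTION_ORDER)

#: Emotion-episode mixing weights by stimulus valence class.
CLASS_EMOTION_WEIGHTS = {
    "positive": {"happiness": 0.45, "surprise": 0.20, "sadness": 0.08,
                 "fear": 0.08, "anger": 0.09, "disgust": 0.10},
    "negative": {"happiness": 0.06, "surprise": 0.10, "sadness": 0.26,
                 "fear": 0.20, "anger": 0.20, "disgust": 0.18},
    "neutral": {e: 1.0 / 6.0 for e in EMOTION_ORDER},
}

MADRS_VISIT_DAYS = {2: (0, 28), 3: (0, 14, 28)}


# ---------------------------------------------------------------------------
# configuration and latent state
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 18
    n_visits: int = 3
    assessments_per_week: int = 1
    fps: float = 30.0
    sample_rate: int = 8000
    response_duration_s: float = 10.0
    response_fraction: float = 0.45
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(LINK_SLOPES))
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    madrs_noise_sd: float = 2.0
    missing_rate: float = 0.15
    pool_size: int = 900
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for a reproducible cohort")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_visits < 2:
            raise ValueError("need at least 2 clinic visits")
        for name, p in [("response_fraction", self.response_fraction),
                        ("missing_rate", self.missing_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.response_duration_s <= 0:
            raise ValueError("response duration must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentState:
    """Latent drivers of one subject's assessment on one day."""

    subject_id: str
    study_day: int
    severity: float
    expressivity_level: float
    voice_fraction: float
    movement_rate: float
    head_pose_rate: float


def link(latent: str, severity, slopes: Mapping[str, float] | None = None) -> np.ndarray:
    """Linear severity -> latent map, clipped to the latent's valid range."""
    slopes = dict(LINK_SLOPES) | dict(slopes or {})
    lo, hi = LINK_BOUNDS[latent]
    val = LINK_ANCHORS[latent] + slopes[latent] * (REF_SEVERITY - np.asarray(severity, dtype=float))
    return np.clip(val, lo, hi)


def _madrs_days(n_visits: int) -> tuple[int, ...]:
    if n_visits in MADRS_VISIT_DAYS:
        return MADRS_VISIT_DAYS[n_visits]
    return tuple(int(round(d)) for d in np.linspace(0, STUDY_LENGTH_DAYS, n_visits))


# ---------------------------------------------------------------------------
# latent trajectories, MADRS, missingness
# ---------------------------------------------------------------------------

def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def simulate_latents(config: CohortConfig) -> pd.DataFrame:
    """Per subject x assessment-day latent states (before missingness).

    Severity declines linearly from the truncated-normal baseline to
    ``baseline x (1 - response_fraction)`` at day 28, with Gaussian day-to-day
    jitter (suppressed when ``madrs_noise_sd == 0`` so the deterministic limit
    is exact).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_subjects
    a, b = BASELINE_RANGE
    baselines = sps.truncnorm.rvs(
        (a - BASELINE_MEAN) / BASELINE_SD,
        (b - BASELINE_MEAN) / BASELINE_SD,
        loc=BASELINE_MEAN,
        scale=BASELINE_SD,
        size=n,
        random_state=rng,
    )
    jitter_sd = TRAJECTORY_JITTER_SD if config.madrs_noise_sd > 0 else 0.0
    rows = []
    for sid, base in zip(_subject_ids(n), baselines):
        for day in ASSESSMENT_DAYS:
            sev = base * (1.0 - config.response_fraction * day / STUDY_LENGTH_DAYS)
            sev = float(np.clip(sev + rng.normal(0.0, jitter_sd), 0.0, 60.0))
            rows.append(
                {
                    "subject_id": sid,
                    "study_day": day,
                    "baseline_madrs": float(base),
                    "severity": sev,
                    "expressivity_level": float(link("expressivity", sev, config.effect_sizes)),
                    "voice_fraction": float(link("voice_fraction", sev, config.effect_sizes)),
                    "movement_rate": float(link("movement_rate", sev, config.effect_sizes)),
                    "head_pose_rate": float(link("head_pose_rate", sev, config.effect_sizes)),
                }
            )
    return pd.DataFrame(rows)


def simulate_madrs(config: CohortConfig, latents: pd.DataFrame) -> pd.DataFrame:
    """Clinic MADRS table (subject x visit) from the latent trajectories.

    The day-0 observation is the latent baseline itself (the baseline rating
    anchors the trajectory); later visits add Gaussian rater noise.  Scores
    are rounded to integers and clipped to [0, 60], except in the
    ``madrs_noise_sd == 0`` deterministic limit where exact latent values are
    returned unrounded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    days = _madrs_days(config.n_visits)
    base = latents.drop_duplicates("subject_id").set_index("subject_id")["baseline_madrs"]
    rows = []
    for sid, b in base.items():
        for visit, day in enumerate(days):
            sev = b * (1.0 - config.response_fraction * day / STUDY_LENGTH_DAYS)
            if config.madrs_noise_sd > 0:
                noise = rng.normal(0.0, config.madrs_noise_sd) if day > 0 else 0.0
                val = float(np.clip(round(sev + noise), 0, 60))
            else:
                val = float(sev)
            rows.append(
                {"subject_id": sid, "visit": visit, "study_day": day, "madrs": val}
            )
    return pd.DataFrame(rows)


def simulate_missingness(config: CohortConfig) -> pd.DataFrame:
    """MCAR mask over subject x assessment day (True = assessment happened)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    rows = []
    for sid in _subject_ids(config.n_subjects):
        for day in ASSESSMENT_DAYS:
            rows.append(
                {
                    "subject_id": sid,
                    "study_day": day,
                    "present": bool(rng.random() >= config.missing_rate),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast path: tidy marker table straight from the latents
# ---------------------------------------------------------------------------

def simulate_marker_table(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy 17-marker table + MADRS table, generated at the marker level.

    Emotion intensities are each the per-emotion episode share of the latent
    expressivity level plus noise; overall expressivity is their sum (the same
    identity the extraction stage satisfies).  Emotion counts hover at the
    episode share independent of severity (null markers).  Voice percentage,
    head-movement and head-pose markers track their latents.
    """
    latents = simulate_latents(config)
    madrs = simulate_madrs(config, latents)
    mask = simulate_missingness(config)
    present = mask.set_index(["subject_id", "study_day"])["present"]
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    ns = config.noise_sd

    rows = []
    for rec in latents.itertuples(index=False):
        if not present.loc[(rec.subject_id, rec.study_day)]:
            continue
        for cls in STIMULUS_CLASSES:
            vals: dict[str, float] = {}
            total = 0.0
            for emo in EMOTION_ORDER:
                v = float(np.clip(
                    EPISODE_SHARE * rec.expressivity_level
                    + rng.normal(0.0, ns["emotion_intensity"]),
                    0.0, 5.0,
                ))
                vals[f"{emo}_intensity"] = v
                total += v
                vals[f"{emo}_count"] = float(np.clip(
                    EPISODE_SHARE + rng.normal(0.0, ns["emotion_count"]), 0.0, 1.0
                ))
            vals["overall_expressivity"] = total
            vals["voice_percentage"] = float(np.clip(
                rec.voice_fraction + rng.normal(0.0, ns["voice_percentage"]), 0.0, 1.0
            ))
            hm = max(rec.movement_rate + rng.normal(0.0, ns["head_movement"]), 0.0)
            vals["head_movement_mean"] = float(hm)
            vals["head_movement_std"] = float(
                max(0.42 * rec.movement_rate + rng.normal(0.0, ns["head_movement"] / 2), 0.0)
            )
            vals["head_pose_change_mean"] = float(
                max(rec.head_pose_rate + rng.normal(0.0, ns["head_pose"]), 0.0)
            )
            for marker in MARKER_CATALOG:
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "study_day": rec.study_day,
                        "stimulus_class": cls,
                        "marker": marker,
                        "value": vals[marker],
                    }
                )
    return pd.DataFrame(rows), madrs


# ---------------------------------------------------------------------------
# rendered path: AU frames, pose, audio
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeSeries:
    """Mono amplitude trace with its sample rate and ground-truth bursts."""

    samples: np.ndarray
    sample_rate: int
    bursts: list[tuple[float, float]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def make_episode_schedule(
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    active_fraction: float = ACTIVE_FRACTION,
    weights: Mapping[str, float] | None = None,
) -> list[tuple[int, int, str]]:
    """Random emotion-episode schedule: (start_frame, end_frame, emotion).

    Episode lengths ~ U(0.5, 1.5) s; gap lengths scaled so episodes cover
    ``active_fraction`` of the clip in expectation.
    """
    n_frames = int(round(duration_s * fps))
    if weights is None:
        weights = CLASS_EMOTION_WEIGHTS["neutral"]
    emotions = list(weights)
    probs = np.array([weights[e] for e in emotions], dtype=float)
    probs /= probs.sum()
    mean_ep = 1.0
    mean_gap = mean_ep * (1.0 - active_fraction) / active_fraction if active_fraction > 0 else np.inf
    schedule: list[tuple[int, int, str]] = []
    t = float(rng.uniform(0.0, 2.0 * mean_gap)) if np.isfinite(mean_gap) else duration_s
    while t < duration_s:
        ep_len = float(rng.uniform(0.5, 1.5))
        start = int(round(t * fps))
        end = min(int(round((t + ep_len) * fps)), n_frames)
        if end > start:
            emo = str(rng.choice(emotions, p=probs))
            schedule.append((start, end, emo))
        t += ep_len + float(rng.uniform(0.0, 2.0 * mean_gap))
    return schedule


def simulate_au_frames(
    expressivity_level: float,
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    episodes: Sequence[tuple[int, int, str]] | None = None,
    emotion_map: Mapping[str, frozenset[int]] = DEFAULT_EMOTION_MAP,
    class_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """OpenFace-dialect AU frame table for one stimulus response.

    During an episode of emotion *e*, the constituent AUs of *e* take
    intensities ~ ``expressivity_level`` (clipped to [0, 5]); outside
    episodes all AUs are zero.  Presence flags are 1 iff intensity exceeds
    :data:`AU_ACTIVATION_THRESHOLD`.  ``expressivity_level = 0`` yields an
    all-zero face.  The realized schedule is stored in ``df.attrs["episodes"]``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if expressivity_level < 0:
        raise ValueError("expressivity level cannot be negative")
    n = int(round(duration_s * fps))
    if episodes is None:
        episodes = make_episode_schedule(duration_s, fps, rng, weights=class_weights)
    intensity = {au: np.zeros(n) for au in AU_IDS}
    level = float(expressivity_level)
    for start, end, emo in episodes:
        if emo not in emotion_map:
            raise ValueError(f"unknown emotion '{emo}' in episode schedule")
        m = max(min(end, n) - start, 0)
        if m == 0 or level == 0.0:
            continue
        for au in emotion_map[emo]:
            vals = np.clip(level + rng.normal(0.0, 0.10 * level, size=m), 0.0, 5.0)
            intensity[au][start:start + m] = vals
    df = pd.DataFrame(
        {
            "frame": np.arange(n, dtype=int),
            "timestamp": np.arange(n, dtype=float) / fps,
            "confidence": np.round(rng.uniform(0.90, 1.00, size=n), 3),
            "success": np.ones(n, dtype=int),
        }
    )
    for au in AU_IDS:
        df[f"AU{au:02d}_r"] = intensity[au]
    for au in AU_IDS:
        df[f"AU{au:02d}_c"] = (intensity[au] > AU_ACTIVATION_THRESHOLD).astype(int)
    df.attrs["episodes"] = list(episodes)
    return df


def simulate_pose(
    movement_rate: float,
    duration_s: float,
    fps: float,
    rng: np.random.Generator,
    head_pose_rate: float = LINK_ANCHORS["head_pose_rate"],
) -> pd.DataFrame:
    """Head-pose random walk: translation and independent small-angle rotation.

    Per-frame translation steps are isotropic Gaussian scaled so the expected
    step length equals ``movement_rate`` (tracker units/frame); rotation steps
    likewise with expected length ``head_pose_rate`` (radians/frame).
    """
    if movement_rate < 0 or head_pose_rate < 0:
        raise ValueError("movement rates cannot be negative")
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = int(round(duration_s * fps))
    # E||N(0, s^2 I_3)|| = s * 2 * sqrt(2/pi)
    chi3_mean = 2.0 * np.sqrt(2.0 / np.pi)
    t_steps = rng.normal(0.0, movement_rate / chi3_mean if movement_rate > 0 else 0.0, (max(n - 1, 0), 3))
    r_steps = rng.normal(0.0, head_pose_rate / chi3_mean if head_pose_rate > 0 else 0.0, (max(n - 1, 0), 3))
    if movement_rate == 0:
        t_steps[:] = 0.0
    if head_pose_rate == 0:
        r_steps[:] = 0.0
    t0 = np.array([0.0, 0.0, 400.0]) + rng.normal(0.0, 5.0, 3)
    r0 = rng.normal(0.0, 0.05, 3)
    trans = t0 + np.vstack([np.zeros(3), np.cumsum(t_steps, axis=0)])
    rot = r0 + np.vstack([np.zeros(3), np.cumsum(r_steps, axis=0)])
    return pd.DataFrame(
        {
            "pose_Tx": trans[:, 0],
            "pose_Ty": trans[:, 1],
            "pose_Tz": trans[:, 2],
            "pose_Rx": rot[:, 0],
            "pose_Ry": rot[:, 1],
            "pose_Rz": rot[:, 2],
        }
    )


def simulate_audio(
    voice_fraction: float,
    duration_s: float,
    sample_rate: int,
    rng: np.random.Generator,
) -> AmplitudeSeries:
    """Alternating speech bursts and near-silence at a target duty cycle.

    Speech is white noise at amplitude 0.3; silence at 0.003 (about -40 dB
    relative), far below the detector's 25 dB dynamic threshold.  Total burst
    time / duration = ``voice_fraction`` up to one burst granule.
    """
    if not 0.0 <= voice_fraction <= 1.0:
        raise ValueError("voice_fraction must lie in [0, 1]")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(duration_s * sample_rate))
    x = rng.normal(0.0, 0.003, n)
    bursts: list[tuple[float, float]] = []
    if voice_fraction >= 1.0:
        bursts = [(0.0, duration_s)]
    elif voice_fraction > 0.0:
        cycle = 2.0
        t = 0.0
        while t < duration_s:
            jitter = float(rng.uniform(0.8, 1.2))
            speech_len = min(voice_fraction * cycle * jitter, duration_s - t)
            if speech_len > 0:
                bursts.append((t, t + speech_len))
            t += cycle * jitter
    for s, e in bursts:
        i0, i1 = int(round(s * sample_rate)), min(int(round(e * sample_rate)), n)
        x[i0:i1] = rng.normal(0.0, 0.3, max(i1 - i0, 0))
    return AmplitudeSeries(samples=x, sample_rate=int(sample_rate), bursts=bursts)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class AssessmentRecord:
    """One subject x study-day x stimulus response: frames + audio + metadata."""

    subject_id: str
    study_day: int
    position: int
    stimulus_id: str
    stimulus_class: str
    frames: pd.DataFrame
    audio: AmplitudeSeries


def make_stimulus_pool(config: CohortConfig) -> pd.DataFrame:
    """Synthetic OASIS-like pool: normally distributed raw valence means."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 5]))
    ids = [f"img{i:04d}" for i in range(config.pool_size)]
    raw = rng.normal(4.1, 1.2, config.pool_size)
    return stim.build_pool(ids, raw)


@dataclass
class CohortDataset:
    """A simulated study: schedules and tables, with lazily rendered records."""

    config: CohortConfig
    latents: pd.DataFrame
    madrs: pd.DataFrame
    missingness: pd.DataFrame
    pool: pd.DataFrame
    sequences: list[stim.AssessmentSequence]

    def sequence_table(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sequences], ignore_index=True)

    def iter_records(self) -> Iterator[AssessmentRecord]:
        """Render every scheduled stimulus response, deterministically.

        Each response draws from its own seed stream derived from
        ``(config.seed, subject index, study day, position)``, so records are
        reproducible independent of iteration order.
        """
        cfg = self.config
        lat = self.latents.set_index(["subject_id", "study_day"])
        sid_index = {s: i for i, s in enumerate(_subject_ids(cfg.n_subjects))}
        for seq in self.sequences:
            state = lat.loc[(seq.subject_id, seq.study_day)]
            for pos, image_id, cls in seq.items:
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [int(cfg.seed), 6, sid_index[seq.subject_id], int(seq.study_day), pos]
                    )
                )
                frames = simulate_au_frames(
                    float(state["expressivity_level"]),
                    cfg.response_duration_s,
                    cfg.fps,
                    rng,
                    class_weights=CLASS_EMOTION_WEIGHTS[cls],
                )
                pose = simulate_pose(
                    float(state["movement_rate"]),
                    cfg.response_duration_s,
                    cfg.fps,
                    rng,
                    head_pose_rate=float(state["head_pose_rate"]),
                )
                frames = pd.concat([frames, pose], axis=1)
                audio = simulate_audio(
                    float(state["voice_fraction"]),
                    cfg.response_duration_s,
                    cfg.sample_rate,
                    rng,
                )
                yield AssessmentRecord(
                    subject_id=seq.subject_id,
                    study_day=seq.study_day,
                    position=pos,
                    stimulus_id=image_id,
                    stimulus_class=cls,
                    frames=frames,
                    audio=audio,
                )


def simulate_cohort(config: CohortConfig) -> CohortDataset:
    """Simulate a full study: latents, MADRS, missingness, stimulus schedule.

    Frame/audio records are rendered lazily via
    :meth:`CohortDataset.iter_records` so arbitrarily large cohorts stream to
    disk without holding every response in memory.
    """
    config.validate()
    latents = simulate_latents(config)
    madrs = simulate_madrs(config, latents)
    missing = simulate_missingness(config)
    pool = make_stimulus_pool(config)
    seq_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    present = missing.set_index(["subject_id", "study_day"])["present"]
    sequences = []
    for sid in _subject_ids(config.n_subjects):
        history: set[str] = set()  # no image repeats within a subject's study
        for day in ASSESSMENT_DAYS:
            if not present.loc[(sid, day)]:
                continue
            seq = stim.build_sequence(pool, history, seq_rng, subject_id=sid, study_day=day)
            history.update(seq.image_ids())
            sequences.append(seq)
    return CohortDataset(
        config=config,
        latents=latents,
        madrs=madrs,
        missingness=missing,
        pool=pool,
        sequences=sequences,
    )
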