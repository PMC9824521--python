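"""Synthetic elderly-household cohorts for end-to-end pipeline testing.

The study population this package targets (a handful of elderly households
wearing heart-rate trackers, with annotated activities of daily living and
twice-daily stress questionnaires) has no public dataset, so every stage is
exercised against simulated cohorts carrying the statistical structure the
method assumes:

* a latent daily physical-stress state z in [0, 1] per subject, following a
  clipped AR(1) process so consecutive days share signal;
* gendered activity schedules — sleeping anchored overnight, the waking
  hours tiled by blocks whose total durations are drawn from a per-gender
  Dirichlet (women cook more, men go out more), mirroring the housework
  asymmetry that motivates gender-normalized indicators;
* activity-conditioned RRI samples whose dispersion *decreases* in stress
  (sympathetic dominance shrinks heart-rate variability) while activity
  mean RRI stays fixed; samples are emitted as bpm so the pipeline must
  invert the bpm -> RRI conversion itself;
* 1-5 Likert answers generated by noisily thresholding the latent state:
  the night question (stress felt) increases with z, the morning question
  (felt refreshed, reverse-coded) decreases with z.  Morning answers are
  driven by the *previous* day's state — the morning question looks back
  over yesterday — so day 1 has no morning row;
* optional stress effects on behaviour: later bedtimes (shorter sleep) and
  a tilt of waking time toward going out on stressful days.

Ground-truth latent stress is written to a separate ``cohort_truth.csv``
and never appears in the feature-facing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .activity import ACTIVITIES
from .errors import ConfigError

DAY_SECONDS = 86_400
_DAYTIME_ACTIVITIES = ("bathing", "cooking", "eating", "going_out", "other")

#: Mean daytime minutes per activity and gender.  Invented defaults chosen
#: to reflect the gendered housework split the method is built around; no
#: public distributional data exist for the study population.
DEFAULT_DURATION_PROFILES = {
    "F": {"bathing": 40.0, "cooking": 120.0, "eating": 100.0, "going_out": 180.0, "other": 490.0},
    "M": {"bathing": 30.0, "cooking": 30.0, "eating": 100.0, "going_out": 300.0, "other": 470.0},
}

#: Per-activity mean RRI (ms) and relaxed-state RRI dispersion (ms).
DEFAULT_MEAN_RRI = {
    "sleeping": 1050.0, "bathing": 850.0, "cooking": 800.0,
    "eating": 820.0, "going_out": 720.0, "other": 900.0,
}
DEFAULT_DISPERSION = {
    "sleeping": 60.0, "bathing": 45.0, "cooking": 40.0,
    "eating": 42.0, "going_out": 35.0, "other": 50.0,
}


@dataclass(frozen=True)
class StressProcess:
    """Clipped AR(1) for the latent daily stress state.

    z_d = mean + persistence * (z_{d-1} - mean) + eps,  eps ~ N(0, sd),
    clipped to [0, 1].
    """

    mean: float = 0.5
    persistence: float = 0.55
    innovation_sd: float = 0.18


@dataclass(frozen=True)
class HrvLink:
    """Map from (activity, latent stress) to RRI mean and dispersion.

    sigma(a, z) = dispersion[a] * (1 - dispersion_effect * z): strictly
    decreasing in z for any positive effect.  ``dispersion_effect`` = 0.6
    means HRV at maximal stress is 40% of its relaxed value, in line with
    the halving of short-term variability reported under acute stress.
    """

    mean_rri: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_RRI))
    dispersion: dict = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    dispersion_effect: float = 0.6

    def sigma(self, activity: str, stress: float) -> float:
        return self.dispersion[activity] * (1.0 - self.dispersion_effect * stress)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort.

    Defaults reproduce the study conditions: five households (four couples
    and one single), one month of data, heart rate every 15 s, the six
    activity labels, with modest sensor dropout.
    """

    n_households: int = 5
    singles_fraction: float = 0.2
    n_days: int = 30
    hr_sample_period: int = 15
    activity_set: tuple = ACTIVITIES
    gender_duration_profiles: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DURATION_PROFILES.items()}
    )
    duration_concentration: float = 30.0
    stress_process: StressProcess = field(default_factory=StressProcess)
    hrv_link: HrvLink = field(default_factory=HrvLink)
    #: Multiplicative tilt of the going-out Dirichlet weight with stress.
    duration_effect: float = 0.8
    #: Hours of bedtime delay per unit stress above the midpoint.
    sleep_stress_shift_h: float = 1.5
    likert_thresholds: tuple = (0.35, 0.55, 0.70, 0.80)
    answer_noise_sd: float = 0.08
    missingness: float = 0.02
    start_date: str = "2023-03-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigError("n_households must be >= 1")
        if not 0.0 <= self.singles_fraction <= 1.0:
            raise ConfigError("singles_fraction must be in [0, 1]")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.hr_sample_period < 1 or DAY_SECONDS % self.hr_sample_period:
            raise ConfigError("hr_sample_period must be a positive divisor of 86400")
        if "sleeping" not in self.activity_set:
            raise ConfigError("activity_set must contain 'sleeping'")
        if not 0.0 <= self.stress_process.persistence < 1.0:
            raise ConfigError("stress_process.persistence must be in [0, 1)")
        if self.stress_process.innovation_sd < 0:
            raise ConfigError("stress_process.innovation_sd must be >= 0")
        thr = self.likert_thresholds
        if len(thr) != 4 or any(a >= b for a, b in zip(thr, thr[1:])):
            raise ConfigError("likert_thresholds must be 4 strictly increasing cutpoints")
        if self.answer_noise_sd < 0:
            raise ConfigError("answer_noise_sd must be >= 0")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigError("missingness must be in [0, 1)")
        if not 0.0 <= self.hrv_link.dispersion_effect < 1.0:
            raise ConfigError("hrv_link.dispersion_effect must be in [0, 1)")
        for g, profile in self.gender_duration_profiles.items():
            if any(m < 0 for m in profile.values()):
                raise ConfigError(f"gender_duration_profiles[{g!r}] has negative minutes")


def null_config(**overrides) -> CohortConfig:
    """A cohort whose features carry no stress signal.

    Dispersion, behaviour, and sleep links are all disabled, so the Likert
    labels are pure noise with respect to every feature.
    """
    base = CohortConfig(
        hrv_link=HrvLink(dispersion_effect=0.0),
        duration_effect=0.0,
        sleep_stress_shift_h=0.0,
    )
    return replace(base, **overrides)


@dataclass
class SyntheticCohort:
    """The generated frames, in the four CSV schemas the pipeline consumes."""

    config: CohortConfig
    subjects: pd.DataFrame      # subject_id, gender, household_id
    heart_rate: pd.DataFrame    # subject_id, timestamp, bpm
    activities: pd.DataFrame    # subject_id, start, end, label
    answers: pd.DataFrame       # subject_id, date, question, answer, answered_at
    truth: pd.DataFrame         # subject_id, date, latent_stress (tests only)

    def write(self, out_dir) -> None:
        """Write the cohort as CSV files; ground truth goes to a separate file."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.heart_rate.to_csv(out / "heart_rate.csv", index=False)
        self.activities.to_csv(out / "activities.csv", index=False)
        self.answers.to_csv(out / "answers.csv", index=False)
        self.truth.to_csv(out / "cohort_truth.csv", index=False)


def generate_answer(
    question: str,
    latent_stress: float,
    thresholds,
    noise_sd: float,
    rng: np.random.Generator,
) -> int:
    """One 1-5 Likert answer from the latent stress state.

    The night question bins z + noise by the thresholds; the morning
    question (refreshed?) uses the same bin reverse-coded as 6 - bin.
    """
    noisy = latent_stress + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    bin_ = 1 + int(np.sum(noisy >= np.asarray(thresholds, dtype=float)))
    if question == "NQ":
        return bin_
    if question == "MQ":
        return 6 - bin_
    raise ConfigError(f"question must be 'MQ' or 'NQ', got {question!r}")


def _latent_stress_paths(config: CohortConfig, n_subjects: int, rng) -> np.ndarray:
    sp = config.stress_process
    z = np.empty((n_subjects, config.n_days))
    stationary_sd = sp.innovation_sd / np.sqrt(max(1e-12, 1.0 - sp.persistence**2))
    z0 = rng.normal(sp.mean, stationary_sd, size=n_subjects)
    z[:, 0] = np.clip(z0, 0.0, 1.0)
    for d in range(1, config.n_days):
        eps = rng.normal(0.0, sp.innovation_sd, size=n_subjects)
        z[:, d] = np.clip(sp.mean + sp.persistence * (z[:, d - 1] - sp.mean) + eps, 0.0, 1.0)
    return z


def _schedule_blocks(config, gender, stress, wake_min, bed_min, rng):
    """Tile [wake, bed) minutes with daytime activity blocks."""
    profile = config.gender_duration_profiles[gender]
    acts = [a for a in _DAYTIME_ACTIVITIES if a in config.activity_set]
    means = np.array([profile.get(a, 0.0) for a in acts], dtype=float)
    if config.duration_effect and "going_out" in acts:
        i = acts.index("going_out")
        means[i] *= float(np.exp(config.duration_effect * (stress - 0.5)))
    weights = means / means.sum()
    alphas = np.maximum(weights * config.duration_concentration, 1e-3)
    shares = rng.dirichlet(alphas)
    total = bed_min - wake_min
    minutes = np.floor(shares * total).astype(int)
    # Remainder goes to the catch-all activity so the blocks tile exactly.
    minutes[acts.index("other") if "other" in acts else 0] += total - minutes.sum()
    n_blocks = {"bathing": 1, "cooking": 2, "eating": 2, "going_out": 1, "other": 3}
    blocks = []
    for a, m in zip(acts, minutes):
        if m <= 0:
            continue
        k = min(n_blocks.get(a, 1), m)
        cuts = np.sort(rng.choice(np.arange(1, m), size=k - 1, replace=False)) if k > 1 else []
        pieces = np.diff(np.concatenate([[0], cuts, [m]])).astype(int)
        blocks.extend((a, int(p)) for p in pieces if p > 0)
    order = rng.permutation(len(blocks))
    return [blocks[i] for i in order]


def simulate_day(
    config: CohortConfig,
    gender: str,
    date: pd.Timestamp,
    latent_stress: float,
    rng: np.random.Generator,
):
    """One subject-day: activity intervals tiling the day plus HR samples.

    Sleeping anchors the day at both ends ([00:00, wake) and [bed, 24:00));
    waking hours are tiled by gendered activity blocks.  RRI samples are
    drawn per activity with the configured stress-conditional dispersion
    and emitted as bpm (2 decimals), so downstream code exercises the
    bpm -> RRI inversion.

    Returns ``(intervals, hr_samples, meta)`` where meta carries the wake
    and bed timestamps (questionnaire anchors).
    """
    if not 0.0 <= latent_stress <= 1.0:
        raise ConfigError("latent_stress must be in [0, 1]")
    day = pd.Timestamp(date).normalize()
    wake_min = int(np.clip(round(rng.normal(7 * 60, 20)), 5 * 60 + 30, 9 * 60))
    bed_center = 22.5 * 60 + config.sleep_stress_shift_h * 60 * (latent_stress - 0.5) * 2
    bed_min = int(np.clip(round(rng.normal(bed_center, 15)), 21 * 60, 23 * 60 + 45))
    rows = [("sleeping", 0, wake_min)]
    cursor = wake_min
    for label, m in _schedule_blocks(config, gender, latent_stress, wake_min, bed_min, rng):
        rows.append((label, cursor, cursor + m))
        cursor += m
    rows.append(("sleeping", bed_min, 24 * 60))
    intervals = pd.DataFrame(
        {
            "start": [day + pd.Timedelta(minutes=s) for _, s, _ in rows],
            "end": [day + pd.Timedelta(minutes=e) for _, _, e in rows],
            "label": [lab for lab, _, _ in rows],
        }
    )
    # HR samples on the configured cadence, labelled by containing interval.
    period = config.hr_sample_period
    n = DAY_SECONDS // period
    offsets_s = np.arange(n, dtype=np.int64) * period
    bounds_s = np.array([s * 60 for _, s, _ in rows] + [DAY_SECONDS])
    which = np.searchsorted(bounds_s, offsets_s, side="right") - 1
    labels = np.array([lab for lab, _, _ in rows], dtype=object)[which]
    rri = np.empty(n)
    for lab in np.unique(labels):
        mask = labels == lab
        sigma = config.hrv_link.sigma(lab, latent_stress)
        mean = config.hrv_link.mean_rri[lab]
        rri[mask] = rng.normal(mean, sigma, size=int(mask.sum()))
    rri = np.clip(rri, 300.0, 2000.0)
    bpm = np.round(60000.0 / rri, 2)
    keep = np.ones(n, dtype=bool)
    if config.missingness > 0:
        keep = rng.random(n) >= config.missingness
    hr = pd.DataFrame(
        {
            "timestamp": day + pd.to_timedelta(offsets_s[keep], unit="s"),
            "bpm": bpm[keep],
        }
    )
    meta = {
        "wake": day + pd.Timedelta(minutes=wake_min),
        "bed": day + pd.Timedelta(minutes=bed_min),
    }
    return intervals, hr, meta


def simulate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    n_singles = int(round(config.n_households * config.singles_fraction))
    subjects = []
    for h in range(config.n_households):
        household = f"H{h + 1:02d}"
        if h < n_singles:
            gender = "F" if h % 2 == 0 else "M"
            subjects.append((f"S{len(subjects) + 1:02d}", gender, household))
        else:
            subjects.append((f"S{len(subjects) + 1:02d}", "F", household))
            subjects.append((f"S{len(subjects) + 1:02d}", "M", household))
    subjects_df = pd.DataFrame(subjects, columns=["subject_id", "gender", "household_id"])

    stress_rng = np.random.default_rng([config.seed, 0])
    z = _latent_stress_paths(config, len(subjects), stress_rng)

    start = pd.Timestamp(config.start_date)
    hr_frames, act_frames, ans_rows, truth_rows = [], [], [], []
    for si, (sid, gender, _) in enumerate(subjects):
        for d in range(config.n_days):
            day = start + pd.Timedelta(days=d)
            day_rng = np.random.default_rng([config.seed, 1 + si, d])
            intervals, hr, meta = simulate_day(config, gender, day, float(z[si, d]), day_rng)
            intervals.insert(0, "subject_id", sid)
            hr.insert(0, "subject_id", sid)
            act_frames.append(intervals)
            hr_frames.append(hr)
            truth_rows.append((sid, day.date().isoformat(), float(z[si, d])))
            q_rng = np.random.default_rng([config.seed, 1 + si, d, 9])
            if d > 0:  # morning answer reflects yesterday's state
                mq = generate_answer(
                    "MQ", float(z[si, d - 1]), config.likert_thresholds,
                    config.answer_noise_sd, q_rng,
                )
                ans_rows.append((sid, day.date().isoformat(), "MQ", mq, meta["wake"]))
            nq = generate_answer(
                "NQ", float(z[si, d]), config.likert_thresholds,
                config.answer_noise_sd, q_rng,
            )
            ans_rows.append((sid, day.date().isoformat(), "NQ", nq, meta["bed"]))

    heart_rate = pd.concat(hr_frames, ignore_index=True)
    activities = _merge_adjacent_sleep(pd.concat(act_frames, ignore_index=True))
    answers = pd.DataFrame(
        ans_rows, columns=["subject_id", "date", "question", "answer", "answered_at"]
    )
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "date", "latent_stress"])
    return SyntheticCohort(
        config=config, subjects=subjects_df, heart_rate=heart_rate,
        activities=activities, answers=answers, truth=truth,
    )


def _merge_adjacent_sleep(activities: pd.DataFrame) -> pd.DataFrame:
    """Join the midnight-split sleeping intervals across day boundaries."""
    out = activities.sort_values(["subject_id", "start"], kind="stable").reset_index(drop=True)
    # An interval starting exactly where the previous one ends with the
    # same label extends it (the 23:xx-24:00 + 00:00-wake night sleep).
    merged_rows = []
    for sid, grp in out.groupby("subject_id", sort=False):
        rows = grp.to_dict("records")
        acc = [rows[0]]
        for r in rows[1:]:
            last = acc[-1]
            if r["label"] == last["label"] and r["start"] == last["end"]:
                last["end"] = r["end"]
            else:
                acc.append(r)
        merged_rows.extend(acc)
    return pd.DataFrame(merged_rows)[["subject_id", "start", "end", "label"]].reset_index(drop=True)
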