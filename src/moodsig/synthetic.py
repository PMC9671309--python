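"""Synthetic three-group mood cohorts with group-dependent dynamics and missingness.

The generator emulates the qualitative structure of weekly self-report mood
monitoring in a mixed bipolar-disorder (BD) / healthy-control (HC) /
borderline-personality-disorder (BPD) cohort:

* per-instrument latent trajectories are mean-reverting first-order
  autoregressive processes around group baselines;
* BD participants additionally carry a two-state episode process: episodes
  start with a weekly hazard, last a geometric number of weeks, and shift ASRM
  up (manic) or QIDS/GAD-7 up and EQ-5D down (depressive);
* BPD week-to-week innovation exceeds HC's (mood instability);
* each week's response can go missing with a group-dependent base probability,
  optionally modulated by the current latent distress (an MNAR component), and
  either per instrument or for the whole week at once.

Scores are clipped to instrument ranges and rounded to integers.  The process
is a deliberately simple stand-in for real cohort data, not a fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .encoding import CLASSES, DEFAULT_RANGES, INSTRUMENTS, SENTINEL, MoodStream

__all__ = [
    "GroupDynamics",
    "MissingnessConfig",
    "CohortConfig",
    "amoss_like_config",
    "missingness_only_config",
    "generate_cohort",
    "inject_missing",
    "simulate_cohort",
    "empirical_missing_rates",
]


@dataclass(frozen=True)
class GroupDynamics:
    """Latent score dynamics for one diagnostic group.

    ``baseline`` gives per-instrument resting levels (ASRM, QIDS, EQ-5D,
    GAD-7); ``innovation_sd`` the weekly innovation SD per instrument;
    ``reversion`` the weekly mean-reversion rate in (0, 1].  BD-style episodes
    are controlled by ``episode_hazard`` (weekly probability of starting an
    episode while well), ``episode_mean_weeks`` (geometric mean duration) and
    the manic/depressive score shifts.
    """

    baseline: tuple[float, float, float, float]
    innovation_sd: tuple[float, float, float, float]
    reversion: float = 0.5
    episode_hazard: float = 0.0
    episode_mean_weeks: float = 4.0
    manic_shift: tuple[float, float, float, float] = (8.0, -1.0, 0.0, 0.0)
    depressive_shift: tuple[float, float, float, float] = (0.0, 10.0, -25.0, 8.0)


@dataclass(frozen=True)
class MissingnessConfig:
    """Weekly missing-response model per group.

    ``base_rate`` maps group -> weekly missing probability; ``mnar_coef``
    scales a logistic shift by the participant's standardised latent distress
    (0 gives missingness independent of mood, i.e. MCAR); ``whole_week``
    blanks all four instruments together instead of independently.
    """

    base_rate: dict[str, float] = field(
        default_factory=lambda: {"BD": 0.25, "HC": 0.05, "BPD": 0.40}
    )
    mnar_coef: float = 0.0
    whole_week: bool = False

    def __post_init__(self):
        for g, r in self.base_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {g} must be in [0, 1], got {r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort recipe: group sizes, study length, dynamics and missingness."""

    n_per_group: dict[str, int]
    weeks: int = 52
    dynamics: dict[str, GroupDynamics] = field(default_factory=dict)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0


def _default_dynamics() -> dict[str, GroupDynamics]:
    return {
        # Episodic elevation/depression on a mildly symptomatic base.
        "BD": GroupDynamics(
            baseline=(2.0, 8.0, 75.0, 5.0),
            innovation_sd=(1.2, 2.0, 6.0, 1.5),
            reversion=0.4,
            episode_hazard=0.06,
            episode_mean_weeks=5.0,
        ),
        # Stable, low-symptom scores.
        "HC": GroupDynamics(
            baseline=(1.0, 3.0, 85.0, 2.0),
            innovation_sd=(0.6, 1.0, 3.0, 0.8),
            reversion=0.6,
        ),
        # High week-to-week instability around a distressed base.
        "BPD": GroupDynamics(
            baseline=(2.5, 12.0, 60.0, 9.0),
            innovation_sd=(2.0, 4.5, 12.0, 3.5),
            reversion=0.25,
        ),
    }


def amoss_like_config(
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    weeks: int = 52,
    mnar_coef: float = 0.0,
) -> CohortConfig:
    """Default preset: group sizes (53, 52, 34), 52 weeks, group-distinct
    dynamics and missing rates ordered HC < BD < BPD."""
    return CohortConfig(
        n_per_group=n_per_group or {"BD": 53, "HC": 52, "BPD": 34},
        weeks=weeks,
        dynamics=_default_dynamics(),
        missingness=MissingnessConfig(
            base_rate={"BD": 0.25, "HC": 0.05, "BPD": 0.40}, mnar_coef=mnar_coef
        ),
        seed=seed,
    )


def missingness_only_config(
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    weeks: int = 52,
) -> CohortConfig:
    """Score dynamics identical across groups; only missingness differs.

    Every group follows the HC dynamics, so the score channels alone carry no
    group signal and any discrimination must come from the missingness
    pattern.
    """
    hc = _default_dynamics()["HC"]
    return CohortConfig(
        n_per_group=n_per_group or {"BD": 30, "HC": 30, "BPD": 30},
        weeks=weeks,
        dynamics={g: hc for g in CLASSES},
        missingness=MissingnessConfig(
            base_rate={"BD": 0.25, "HC": 0.05, "BPD": 0.40}
        ),
        seed=seed,
    )


_RANGE_VEC = np.array([DEFAULT_RANGES[n] for n in INSTRUMENTS])


def _simulate_participant(
    dyn: GroupDynamics, weeks: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One participant's latent (W, 4) trajectory and per-week distress."""
    base = np.asarray(dyn.baseline, dtype=float)
    sd = np.asarray(dyn.innovation_sd, dtype=float)
    x = base + rng.normal(0.0, sd)
    shift = np.zeros(4)
    episode_left = 0
    latent = np.empty((weeks, 4))
    for t in range(weeks):
        if dyn.episode_hazard > 0.0:
            if episode_left > 0:
                episode_left -= 1
                if episode_left == 0:
                    shift = np.zeros(4)
            elif rng.random() < dyn.episode_hazard:
                episode_left = 1 + rng.geometric(1.0 / dyn.episode_mean_weeks)
                shift = np.asarray(
                    dyn.manic_shift if rng.random() < 0.5 else dyn.depressive_shift,
                    dtype=float,
                )
        x = x + dyn.reversion * (base - x) + rng.normal(0.0, sd)
        latent[t] = x + shift
    # Standardised distress combines depression, anxiety and (inverted)
    # quality of life on the normalised scale; used by the MNAR mechanism.
    norm = latent / _RANGE_VEC
    distress = norm[:, 1] + norm[:, 3] + (1.0 - norm[:, 2])
    return latent, distress


def generate_cohort(config: CohortConfig) -> tuple[list[MoodStream], dict[str, np.ndarray]]:
    """Generate complete (no-missing) labeled streams plus latent distress.

    Returns ``(streams, distress)`` where ``distress[participant_id]`` is the
    per-week latent distress trace consumed by :func:`inject_missing`'s MNAR
    option.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    dynamics = config.dynamics or _default_dynamics()
    streams: list[MoodStream] = []
    distress_of: dict[str, np.ndarray] = {}
    for group in CLASSES:
        n = config.n_per_group.get(group, 0)
        dyn = dynamics[group]
        for i in range(n):
            pid = f"{group}-{i:03d}"
            latent, distress = _simulate_participant(dyn, config.weeks, rng)
            scores = np.rint(np.clip(latent, 0.0, _RANGE_VEC))
            streams.append(
                MoodStream(
                    participant_id=pid,
                    weeks=np.arange(config.weeks),
                    scores=scores,
                    diagnosis=group,
                )
            )
            distress_of[pid] = distress
    return streams, distress_of


def inject_missing(
    streams: list[MoodStream],
    config: CohortConfig,
    distress: Optional[dict[str, np.ndarray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[MoodStream]:
    """Blank responses to the sentinel according to the missingness model.

    Each week (whole-week mode) or each instrument-week (default) is missing
    independently with probability ``logistic(logit(base) + mnar_coef * z)``,
    where ``z`` is the participant's standardised latent distress that week.
    With ``mnar_coef == 0`` the mechanism reduces to group-dependent MCAR.
    """
    miss = config.missingness
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out: list[MoodStream] = []
    for stream in streams:
        base = miss.base_rate[stream.diagnosis]
        W, C = stream.scores.shape
        if base >= 1.0:
            prob = np.ones(W)
        elif base <= 0.0:
            prob = np.zeros(W)
        elif miss.mnar_coef != 0.0 and distress is not None:
            z = distress[stream.participant_id]
            z = (z - z.mean()) / (z.std() + 1e-12)
            logit = np.log(base / (1.0 - base)) + miss.mnar_coef * z
            prob = 1.0 / (1.0 + np.exp(-logit))
        else:
            prob = np.full(W, base)
        if miss.whole_week:
            mask = (rng.random(W) < prob)[:, None] & np.ones((1, C), dtype=bool)
        else:
            mask = rng.random((W, C)) < prob[:, None]
        scores = stream.scores.copy()
        scores[mask] = SENTINEL
        out.append(replace_scores(stream, scores))
    return out


def replace_scores(stream: MoodStream, scores: np.ndarray) -> MoodStream:
    return MoodStream(
        participant_id=stream.participant_id,
        weeks=stream.weeks.copy(),
        scores=scores,
        diagnosis=stream.diagnosis,
        sentinel=stream.sentinel,
    )


def simulate_cohort(config: CohortConfig) -> list[MoodStream]:
    """Generate a cohort and inject missingness in one call."""
    streams, distress = generate_cohort(config)
    return inject_missing(streams, config, distress=distress)


def empirical_missing_rates(streams: list[MoodStream]) -> dict[str, float]:
    """Observed fraction of missing entries per diagnostic group."""
    rates: dict[str, float] = {}
    for group in CLASSES:
        masks = [s.missing_mask for s in streams if s.diagnosis == group]
        if masks:
            rates[group] = float(np.mean([m.mean() for m in masks]))
    return rates
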