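"""Factorial search-experiment design and a synthetic observer.

One session is the full 2 (enhancement) x 2 (illumination) x 2 (viewing)
x 4 (quadrant) x 10 (texture) crossing = 320 trials, uniformly shuffled.
The synthetic observer stands in for human participants: reaction times
are additive on the millisecond scale (baseline + subject random intercept
+ condition shifts + right-skewed lognormal-shaped noise), truncated at a
20 s timeout; lapses and incorrect responses occur at configurable rates.

Condition shifts default to the observed mean differences of the study
this emulates: a large enhancement cost under monoscopic viewing that
shrinks under stereoscopic viewing, and a directional-illumination
advantage that is larger monoscopically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ENHANCEMENT_LEVELS",
    "ILLUMINATION_LEVELS",
    "VIEWING_LEVELS",
    "QUADRANTS",
    "TrialSpec",
    "TrialRecord",
    "ObserverModel",
    "enumerate_session",
    "simulate_participant",
    "simulate_experiment",
    "records_to_frame",
    "quadrant_of",
    "TRIAL_COLUMNS",
]

ENHANCEMENT_LEVELS = ("absent", "present")
ILLUMINATION_LEVELS = ("ambient", "directional")
VIEWING_LEVELS = ("monoscopic", "stereoscopic")
QUADRANTS = ("TL", "TR", "BL", "BR")
N_TEXTURES = 10
TIMEOUT_MS = 20_000.0

TRIAL_COLUMNS = [
    "participant",
    "enhancement",
    "illumination",
    "viewing",
    "quadrant",
    "texture_id",
    "response",
    "correct",
    "rt_ms",
]


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition labels plus its private random seed."""

    enhancement: str
    illumination: str
    viewing: str
    quadrant: str
    texture_id: int
    trial_seed: int

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.enhancement, self.illumination, self.viewing)


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial; the atom of the statistics pipeline."""

    participant: int
    enhancement: str
    illumination: str
    viewing: str
    quadrant: str
    texture_id: int
    response: str  # a quadrant label or "none"
    correct: bool
    rt_ms: float | None  # None iff response == "none"


def enumerate_session(master_seed: int = 0) -> list[TrialSpec]:
    """All 320 condition combinations in a seed-determined random order."""
    ss = np.random.SeedSequence(master_seed)
    rng = np.random.default_rng(ss)
    combos = list(
        itertools.product(
            ENHANCEMENT_LEVELS,
            ILLUMINATION_LEVELS,
            VIEWING_LEVELS,
            QUADRANTS,
            range(1, N_TEXTURES + 1),
        )
    )
    seeds = rng.integers(0, 2**63 - 1, size=len(combos))
    specs = [
        TrialSpec(
            enhancement=e, illumination=i, viewing=v, quadrant=q,
            texture_id=t, trial_seed=int(s),
        )
        for (e, i, v, q, t), s in zip(combos, seeds)
    ]
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


@dataclass(frozen=True)
class ObserverModel:
    """Additive-shift reaction-time model with subject random intercepts.

    ``enh_cost_*`` are added when enhancement is present (per viewing
    condition); ``light_adv_*`` are subtracted under directional light;
    ``stereo_benefit`` is subtracted under stereoscopic viewing.  Noise is
    a standardized lognormal shape scaled to ``trial_sd`` so the noise-free
    limit is exact and the distribution stays right-skewed.
    """

    baseline_rt: float = 2400.0
    enh_cost_mono: float = 436.39
    enh_cost_stereo: float = 96.40
    light_adv_mono: float = 540.75
    light_adv_stereo: float = 309.97
    stereo_benefit: float = 400.0
    subject_sd: float = 150.0
    effect_sd: float = 300.0  # between-subject s.d. of each condition shift
    trial_sd: float = 500.0
    noise_shape: float = 0.6
    error_rate: float = 0.035
    lapse_rate: float = 0.01
    timeout_ms: float = TIMEOUT_MS
    rt_floor_ms: float = 150.0

    def __post_init__(self) -> None:
        if min(self.subject_sd, self.trial_sd, self.effect_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")

    @classmethod
    def null(cls, **overrides) -> "ObserverModel":
        """No condition effects for any subject (type-I-error calibration).

        Zeroes both the mean shifts and the between-subject effect spread:
        symmetric ms-scale random slopes would acquire a nonzero mean under
        the convex reciprocal transform (Jensen), which is a real effect,
        not a null.
        """
        base = dict(
            enh_cost_mono=0.0, enh_cost_stereo=0.0,
            light_adv_mono=0.0, light_adv_stereo=0.0, stereo_benefit=0.0,
            effect_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def condition_shift(
        self, enhancement, illumination, viewing, slopes: np.ndarray | None = None
    ) -> np.ndarray:
        """Vectorized additive shift (ms) for condition label arrays.

        ``slopes`` is an optional vector of 5 per-subject deviations (ms)
        added to the five shift terms in the order: enhancement cost mono /
        stereo, illumination advantage mono / stereo, stereo benefit.
        """
        if slopes is None:
            slopes = np.zeros(5)
        enh = np.asarray(enhancement) == "present"
        dire = np.asarray(illumination) == "directional"
        ster = np.asarray(viewing) == "stereoscopic"
        shift = np.where(
            enh,
            np.where(
                ster, self.enh_cost_stereo + slopes[1], self.enh_cost_mono + slopes[0]
            ),
            0.0,
        )
        shift = shift - np.where(
            dire,
            np.where(
                ster, self.light_adv_stereo + slopes[3], self.light_adv_mono + slopes[2]
            ),
            0.0,
        )
        shift = shift - np.where(ster, self.stereo_benefit + slopes[4], 0.0)
        return shift


def _standardized_lognormal(rng: np.random.Generator, n: int, shape: float) -> np.ndarray:
    """Lognormal(0, shape) samples standardized to mean 0, s.d. 1."""
    raw = np.exp(shape * rng.standard_normal(n))
    mean = np.exp(shape**2 / 2.0)
    sd = np.sqrt((np.exp(shape**2) - 1.0) * np.exp(shape**2))
    return (raw - mean) / sd


def _simulate_arrays(
    specs_frame: pd.DataFrame, model: ObserverModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate responses for a frame of trial specs (vectorized)."""
    n = len(specs_frame)
    intercept = model.subject_sd * rng.standard_normal()
    slopes = model.effect_sd * rng.standard_normal(5)
    shift = model.condition_shift(
        specs_frame["enhancement"].to_numpy(),
        specs_frame["illumination"].to_numpy(),
        specs_frame["viewing"].to_numpy(),
        slopes=slopes,
    )
    noise = (
        model.trial_sd * _standardized_lognormal(rng, n, model.noise_shape)
        if model.trial_sd > 0
        else np.zeros(n)
    )
    rt = np.maximum(model.baseline_rt + intercept + shift + noise, model.rt_floor_ms)
    lapse = rng.random(n) < model.lapse_rate
    timeout = rt > model.timeout_ms
    no_response = lapse | timeout
    wrong = (rng.random(n) < model.error_rate) & ~no_response
    quad = specs_frame["quadrant"].to_numpy()
    response = quad.copy()
    # uniformly choose among the three wrong quadrants
    offsets = rng.integers(1, 4, size=n)
    qidx = np.array([QUADRANTS.index(q) for q in quad[wrong]], dtype=int)
    response[wrong] = np.array(QUADRANTS)[(qidx + offsets[wrong]) % 4]
    response[no_response] = "none"
    out = specs_frame.copy()
    out["response"] = response
    out["correct"] = (response == quad) & ~no_response
    out["rt_ms"] = np.where(no_response, np.nan, rt)
    return out


def _session_frame(specs: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enhancement": [s.enhancement for s in specs],
            "illumination": [s.illumination for s in specs],
            "viewing": [s.viewing for s in specs],
            "quadrant": [s.quadrant for s in specs],
            "texture_id": [s.texture_id for s in specs],
        }
    )


def simulate_participant(
    specs: list[TrialSpec], model: ObserverModel, participant_seed: int,
    participant: int = 0,
) -> list[TrialRecord]:
    """Simulate one participant's responses to an ordered trial list."""
    rng = np.random.default_rng(np.random.SeedSequence(participant_seed))
    frame = _simulate_arrays(_session_frame(specs), model, rng)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            TrialRecord(
                participant=participant,
                enhancement=row.enhancement,
                illumination=row.illumination,
                viewing=row.viewing,
                quadrant=row.quadrant,
                texture_id=int(row.texture_id),
                response=row.response,
                correct=bool(row.correct),
                rt_ms=None if np.isnan(row.rt_ms) else float(row.rt_ms),
            )
        )
    return records


def simulate_experiment(
    n_participants: int, model: ObserverModel, master_seed: int = 0
) -> pd.DataFrame:
    """Simulate a whole experiment; returns the trial-level data frame."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_participants)
    frames = []
    for pid, child in enumerate(children, start=1):
        sess_ss, sim_ss = child.spawn(2)
        specs = enumerate_session(int(sess_ss.generate_state(1)[0]))
        rng = np.random.default_rng(sim_ss)
        frame = _simulate_arrays(_session_frame(specs), model, rng)
        frame.insert(0, "participant", pid)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Convert TrialRecord objects to the canonical trial data frame."""
    return pd.DataFrame(
        {
            "participant": [r.participant for r in records],
            "enhancement": [r.enhancement for r in records],
            "illumination": [r.illumination for r in records],
            "viewing": [r.viewing for r in records],
            "quadrant": [r.quadrant for r in records],
            "texture_id": [r.texture_id for r in records],
            "response": [r.response for r in records],
            "correct": [r.correct for r in records],
            "rt_ms": [np.nan if r.rt_ms is None else r.rt_ms for r in records],
        }
    )


def quadrant_of(position, bounds) -> str:
    """Quadrant label of a centred XY position within (width, height) bounds.

    Ties on either midline break towards the top-left: x <= 0 counts as
    left, y >= 0 counts as top.
    """
    x, y = position
    w, h = bounds
    if not (abs(x) <= w / 2.0 and abs(y) <= h / 2.0):
        raise ValueError(f"position {position} outside bounds {bounds}")
    horiz = "L" if x <= 0 else "R"
    vert = "T" if y >= 0 else "B"
    return vert + horiz
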