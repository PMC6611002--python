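"""Synthetic state-switching trajectory generator with ground truth.

Animals are simulated as correlated random walks that switch between
discrete behavioral states. Within a state, the heading evolves as

    B[k+1] = B[k] + Normal(0, turn_sd) (+ a large turn of magnitude
             uniform in (90, 180] degrees, either sign, with
             probability large_turn_prob)

and the step length is Normal(speed_mean, speed_sd) floored at zero. State
bout durations are exponential with the state's mean (at least one frame),
matching the two-timescale picture of turn-interval statistics. The true
state of every frame is recorded, so every pipeline stage can be validated
against known ground truth.

The default cohort emulates the worm run/pirouette regime: long, nearly
straight runs (30 s mean, 10 degree heading noise) alternating with short
pirouettes (5 s mean) in which half the frames carry a large reversal-scale
turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Trajectory, TrajectorySet


@dataclass(frozen=True)
class StateSpec:
    """Movement statistics of one behavioral state (frame-based units)."""

    name: str
    speed_mean: float = 1.0
    speed_sd: float = 0.1
    turn_sd: float = 10.0
    large_turn_prob: float = 0.0
    duration_mean: float = 30.0

    def __post_init__(self) -> None:
        if self.duration_mean <= 0 or self.speed_mean < 0 or self.speed_sd < 0 or self.turn_sd < 0:
            raise ValueError("state parameters must be positive")
        if not 0.0 <= self.large_turn_prob <= 1.0:
            raise ValueError("large_turn_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of identically parameterized animals.

    ``transition`` is "alternating" (cycle through states) or a Markov row-
    stochastic matrix. ``condition_effects`` maps "state.param" to a
    multiplicative factor applied for condition B (e.g.
    ``{"run.duration_mean": 2.0}``).
    """

    states: tuple[StateSpec, ...]
    n_animals: int = 50
    n_frames: int = 600
    frame_interval: float = 1.0
    transition: str | np.ndarray = "alternating"
    seed: int = 1
    condition_effects: dict = field(default_factory=dict)

    def with_effects(self) -> "CohortSpec":
        """The condition-B variant of this spec."""
        states = list(self.states)
        for key, factor in self.condition_effects.items():
            state_name, param = key.split(".")
            for i, st in enumerate(states):
                if st.name == state_name:
                    states[i] = replace(st, **{param: getattr(st, param) * factor})
        return replace(self, states=tuple(states), condition_effects={})


def run_pirouette_spec(n_animals: int = 50, n_frames: int = 600, seed: int = 1, **kwargs) -> CohortSpec:
    """The documented default run/pirouette cohort."""
    return CohortSpec(
        states=(
            StateSpec("run", speed_mean=1.0, speed_sd=0.1, turn_sd=10.0, large_turn_prob=0.0, duration_mean=30.0),
            StateSpec("pirouette", speed_mean=1.0, speed_sd=0.1, turn_sd=30.0, large_turn_prob=0.5, duration_mean=5.0),
        ),
        n_animals=n_animals,
        n_frames=n_frames,
        seed=seed,
        **kwargs,
    )


def multispeed_forager_spec(
    speed_means: tuple[float, ...] = (0.1, 1.0, 5.0),
    n_animals: int = 11,
    n_frames: int = 2000,
    seed: int = 1,
) -> CohortSpec:
    """States differing chiefly in speed (rest / walk / swim style)."""
    states = tuple(
        StateSpec(
            f"state{i}",
            speed_mean=s,
            speed_sd=0.15 * s if s > 0 else 0.01,
            turn_sd=20.0,
            duration_mean=60.0,
        )
        for i, s in enumerate(speed_means)
    )
    return CohortSpec(states=states, n_animals=n_animals, n_frames=n_frames, seed=seed)


def _sample_states(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n_states = len(spec.states)
    labels = np.empty(spec.n_frames, dtype=int)
    if isinstance(spec.transition, str):
        if spec.transition != "alternating":
            raise ValueError("transition must be 'alternating' or a matrix")
        matrix = None
    else:
        matrix = np.asarray(spec.transition, dtype=float)
        if matrix.shape != (n_states, n_states) or not np.allclose(matrix.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
    state = int(rng.integers(n_states))
    k = 0
    while k < spec.n_frames:
        duration = max(1, int(np.ceil(rng.exponential(spec.states[state].duration_mean))))
        end = min(spec.n_frames, k + duration)
        labels[k:end] = state
        k = end
        if matrix is None:
            state = (state + 1) % n_states
        else:
            state = int(rng.choice(n_states, p=matrix[state]))
    return labels


def _walk(labels: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    heading = rng.uniform(0.0, 360.0)
    xy = np.zeros((n + 1, 2))
    for k in range(n):
        st = spec.states[labels[k]]
        heading += rng.normal(0.0, st.turn_sd)
        if st.large_turn_prob and rng.random() < st.large_turn_prob:
            heading += rng.choice([-1.0, 1.0]) * rng.uniform(90.0, 180.0)
        heading %= 360.0
        step = max(0.0, rng.normal(st.speed_mean, st.speed_sd))
        rad = np.radians(heading)
        xy[k + 1] = xy[k] + step * np.array([np.sin(rad), np.cos(rad)])
    return xy


def simulate_state_switching(spec: CohortSpec, condition: str | None = None) -> TrajectorySet:
    """Generate a labeled cohort; byte-identical output under a fixed seed.

    Each animal draws from its own substream keyed by (seed, animal), so
    cohorts simulated under the same seed but different state parameters are
    paired animal by animal (common random numbers): in a two-condition
    comparison the arena geography is shared and only the planted parameter
    change separates the conditions.
    """
    trajectories = []
    for a in range(spec.n_animals):
        rng = np.random.default_rng([spec.seed, a])
        labels = _sample_states(spec, rng)
        xy = _walk(labels, spec, rng)
        # frame k's label describes the step into frame k+1; last frame repeats
        frame_labels = np.concatenate([labels, labels[-1:]])
        t = spec.frame_interval * np.arange(spec.n_frames + 1)
        trajectories.append(
            Trajectory(
                animal_id=f"sim{a:03d}",
                t=t,
                xy=xy,
                dialect="planar",
                condition=condition,
                truth_labels=frame_labels,
            )
        )
    return TrajectorySet(trajectories, length_unit="a.u.", time_unit_native="s")


def simulate_multispeed_forager(spec: CohortSpec | None = None) -> TrajectorySet:
    """Labeled cohort whose states differ chiefly in speed."""
    return simulate_state_switching(spec or multispeed_forager_spec())


def simulate_two_condition_cohort(
    spec: CohortSpec | None = None,
    condition_effects: dict | None = None,
    seed: int = 1,
) -> TrajectorySet:
    """Condition A (baseline) and condition B (with planted effects) cohorts.

    Returns one TrajectorySet holding both cohorts with ``condition`` tags
    "A" and "B"; pass it through the state-estimation pipeline and the
    segment-feature builder to obtain a two-condition feature table.
    """
    spec = spec or run_pirouette_spec()
    if condition_effects:
        spec = replace(spec, condition_effects=dict(condition_effects))
    if not spec.condition_effects:
        raise ValueError("condition_effects must be non-empty")
    # same seed for both conditions: common random numbers pair the cohorts
    # animal by animal, so nuisance drift (e.g. where each walk wanders, and
    # with it the odor concentrations experienced) cancels between arms and
    # only the planted parameter change separates the conditions
    spec_a = replace(spec, seed=seed, condition_effects={})
    spec_b = replace(spec.with_effects(), seed=seed)
    set_a = simulate_state_switching(spec_a, condition="A")
    set_b = simulate_state_switching(spec_b, condition="B")
    for tr in set_b:
        tr.animal_id = "B_" + tr.animal_id
    for tr in set_a:
        tr.animal_id = "A_" + tr.animal_id
    return TrajectorySet(
        set_a.trajectories + set_b.trajectories,
        length_unit="a.u.",
        time_unit_native="s",
    )


def two_condition_feature_table(
    spec: CohortSpec | None = None,
    condition_effects: dict | None = None,
    seed: int = 1,
    odor_field=None,
    config=None,
):
    """Planted-effect cohort pushed through the full pipeline.

    Simulates the two conditions, estimates states on the pooled cohort (so
    cluster identities are shared), and returns the per-segment feature
    table with condition labels — ready for information-gain extraction.
    """
    from .states import EstimateConfig, estimate_states, two_way_grouping
    from .worm import LinearOdorField, worm_feature_vector

    trajset = simulate_two_condition_cohort(spec, condition_effects, seed=seed)
    annotation = estimate_states(trajset, config or EstimateConfig(seed=seed))
    # worm-style two-state reading: merge components into run-like (0) and
    # pirouette-like (1) groups so segment durations are not fragmented
    merge = two_way_grouping(annotation.model)
    annotation.labels = [
        np.array([merge[int(c)] for c in lab]) for lab in annotation.labels
    ]
    field_ = odor_field if odor_field is not None else LinearOdorField()
    return worm_feature_vector(annotation, odor_field=field_)


def null_split_feature_table(
    spec: CohortSpec | None = None,
    seed: int = 1,
    odor_field=None,
):
    """Null calibration table: one population, conditions assigned at random.

    Simulates a single cohort, runs the pipeline, and assigns each segment
    row to "A" or "B" by a seeded coin flip. Any extracted feature is then a
    false positive of the extraction procedure, so this calibrates it.
    Splitting one population of data points (rather than simulating two
    cohorts) is the correct null: independently simulated cohorts differ by
    real cohort-level drift (e.g. where the random walks happened to wander,
    hence the odor concentrations they saw), which is a genuine two-sample
    difference, not an extraction error.
    """
    from .states import EstimateConfig, estimate_states, two_way_grouping
    from .worm import LinearOdorField, worm_feature_vector

    spec = spec or run_pirouette_spec(n_animals=100)
    trajset = simulate_state_switching(spec)
    annotation = estimate_states(trajset, EstimateConfig(seed=seed))
    merge = two_way_grouping(annotation.model)
    annotation.labels = [
        np.array([merge[int(c)] for c in lab]) for lab in annotation.labels
    ]
    field_ = odor_field if odor_field is not None else LinearOdorField()
    table = worm_feature_vector(annotation, odor_field=field_)
    rng = np.random.default_rng(seed + 60013)
    table["condition"] = np.where(rng.random(len(table)) < 0.5, "A", "B")
    return table


def to_table(trajset: TrajectorySet) -> pd.DataFrame:
    """Flatten a cohort to the delimited-table layout used by the readers."""
    frames = []
    for tr in trajset:
        rec = {"id": tr.animal_id, "t": tr.t, "x": tr.xy[:, 0], "y": tr.xy[:, 1]}
        if tr.condition is not None:
            rec["condition"] = tr.condition
        if tr.truth_labels is not None:
            rec["state"] = tr.truth_labels
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)
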