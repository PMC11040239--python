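"""Generative simulator for the word-learning / knowledge-judgement /
sampling / test experiment.

Each simulated participant is trained on ``n_objects`` novel labels, gives
one binary knowledge judgement per object, makes ``n_sampling_choices``
sampling choices (weighted towards judged-unknown objects when
``sampling_preference_w`` > 0), answers one test trial per object, rates
confidence in each answer, and completes nine control judgements over five
familiar and four unfamiliar items.

Latent label knowledge is drawn directly from a logit-normal model with
participant and object random intercepts, matching the assumptions of the
downstream mixed-model analyses; the trial-by-trial learning stream is
deliberately not simulated.

Randomness is organized as one substream per participant derived from the
master seed, so enlarging a group never perturbs previously generated
participants.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from udsamp.glmm import inv_logit

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "GROUP_PRESETS",
    "preset_config",
    "simulate_experiment",
    "weighted_choice_without_replacement",
    "substream",
]

RECORD_COLUMNS = [
    "participant_id", "age_group", "object_id", "learned",
    "knowledge_judgement", "times_sampled", "test_correct",
    "confidence_rating",
]
CONTROL_COLUMNS = ["participant_id", "item_id", "item_class", "judged_known"]

N_FAMILIAR = 5
N_UNFAMILIAR = 4

# Illustrative per-group presets: p_learn mirrors the observed group
# accuracies (~0.31 / 0.44 / 0.81); the remaining values are plausible, not
# fitted.
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "5yo": {"p_learn": 0.31, "sampling_preference_w": 0.0,
            "judge_known_given_learned": 0.80,
            "judge_known_given_unlearned": 0.40,
            "p_sure_given_correct": 0.85, "p_sure_given_incorrect": 0.66},
    "6-9yo": {"p_learn": 0.44, "sampling_preference_w": 0.4,
              "judge_known_given_learned": 0.85,
              "judge_known_given_unlearned": 0.35,
              "p_sure_given_correct": 0.91, "p_sure_given_incorrect": 0.61},
    "adult": {"p_learn": 0.81, "sampling_preference_w": 0.6,
              "judge_known_given_learned": 0.90,
              "judge_known_given_unlearned": 0.25,
              "p_sure_given_correct": 0.92, "p_sure_given_incorrect": 0.42},
}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def substream(seed: int, *labels) -> np.random.Generator:
    """Named, reproducible RNG substream of a master seed."""
    key = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


_PROB_FIELDS = (
    "p_learn", "judge_known_given_learned", "judge_known_given_unlearned",
    "p_correct_learned", "p_correct_unlearned_base",
    "p_sure_given_correct", "p_sure_given_incorrect", "control_lapse",
)


@dataclass
class SimulationConfig:
    """Parameters of the generative experiment model.

    ``n_participants`` maps an age-group label to a participant count (a
    bare integer is shorthand for one group labelled ``"all"``).
    ``group_overrides`` may override any behavioural field per group.
    """

    n_participants: Mapping[str, int] | int = 50
    n_objects: int = 6
    n_sampling_choices: int = 3
    p_learn: float = 0.5
    judge_known_given_learned: float = 0.85
    judge_known_given_unlearned: float = 0.30
    sampling_preference_w: float = 0.0
    p_correct_learned: float = 0.9
    p_correct_unlearned_base: float = 1.0 / 6.0
    sampling_boost: float = 0.0
    p_sure_given_correct: float = 0.85
    p_sure_given_incorrect: float = 0.5
    sd_participant: float = 0.0
    sd_object: float = 0.0
    control_lapse: float = 0.05
    allow_resampling: bool = False
    seed: int = 0
    group_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.n_participants, (int, np.integer)):
            self.n_participants = {"all": int(self.n_participants)}
        self.n_participants = dict(self.n_participants)
        self.validate()

    def validate(self) -> None:
        for grp, n in self.n_participants.items():
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise ConfigError(
                    f"n_participants[{grp!r}] must be a positive integer")
        if self.n_objects < 1:
            raise ConfigError("n_objects must be >= 1")
        if not (1 <= self.n_sampling_choices):
            raise ConfigError("n_sampling_choices must be >= 1")
        if (not self.allow_resampling
                and self.n_sampling_choices > self.n_objects):
            raise ConfigError(
                "n_sampling_choices must be <= n_objects without resampling")
        for f in _PROB_FIELDS:
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{f} must lie in [0, 1], got {v}")
        for f in ("sd_participant", "sd_object"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        for grp, over in self.group_overrides.items():
            for k, v in over.items():
                if not hasattr(self, k):
                    raise ConfigError(
                        f"group_overrides[{grp!r}] names unknown field {k!r}")
                if k in _PROB_FIELDS and not (0.0 <= v <= 1.0):
                    raise ConfigError(
                        f"group_overrides[{grp!r}][{k!r}] must lie in [0, 1]")

    def group_value(self, group: str, fieldname: str) -> float:
        over = self.group_overrides.get(group, {})
        return over.get(fieldname, getattr(self, fieldname))

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_participants"] = dict(self.n_participants)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def preset_config(groups: Sequence[str] = ("5yo", "6-9yo", "adult"),
                  n_per_group: int = 50, seed: int = 0,
                  **common) -> SimulationConfig:
    """Config with the illustrative per-age-group behavioural presets."""
    unknown = [g for g in groups if g not in GROUP_PRESETS]
    if unknown:
        raise ConfigError(f"no preset for group(s) {unknown}; "
                          f"known: {sorted(GROUP_PRESETS)}")
    return SimulationConfig(
        n_participants={g: n_per_group for g in groups},
        sd_participant=common.pop("sd_participant", 0.6),
        sd_object=common.pop("sd_object", 0.3),
        seed=seed,
        group_overrides={g: dict(GROUP_PRESETS[g]) for g in groups},
        **common,
    )


def weighted_choice_without_replacement(weights, k: int,
                                        rng: np.random.Generator
                                        ) -> list[int]:
    """Draw ``k`` distinct indices sequentially, each with probability
    proportional to its weight among the items still available
    (Plackett-Luce scheme).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("all weights must be positive and finite")
    if k > w.size:
        raise ValueError(f"cannot draw {k} distinct items from {w.size}")
    remaining = list(range(w.size))
    chosen: list[int] = []
    for _ in range(k):
        probs = w[remaining] / w[remaining].sum()
        pick = rng.choice(len(remaining), p=probs)
        chosen.append(remaining.pop(pick))
    return chosen


def _bern(rng, p, size=None):
    if p <= 0.0:
        return np.zeros(size, dtype=np.int64) if size else 0
    if p >= 1.0:
        return np.ones(size, dtype=np.int64) if size else 1
    out = rng.binomial(1, p, size=size)
    return out if size else int(out)


def _conditional_prob(latent_logit: float, offset: float) -> float:
    """inv-logit(latent + offset) with degenerate endpoints preserved."""
    if not np.isfinite(latent_logit):
        return 1.0 if latent_logit > 0 else 0.0
    return float(inv_logit(latent_logit + offset))


def _safe_logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def simulate_experiment(config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full experiment for every configured group.

    Returns the participant-by-object trial table and the control-trial
    table.  Identical config (including seed) gives bit-identical tables.
    """
    config.validate()
    n_obj = config.n_objects
    object_ids = [f"o{j + 1}" for j in range(n_obj)]

    obj_rng = substream(config.seed, "objects")
    u_obj = obj_rng.normal(0.0, config.sd_object, n_obj) \
        if config.sd_object > 0 else np.zeros(n_obj)

    rec_rows: list[tuple] = []
    ctl_rows: list[tuple] = []
    for group, n_part in config.n_participants.items():
        gv = lambda f: config.group_value(group, f)  # noqa: E731
        for i in range(n_part):
            pid = f"{group}_p{i + 1:04d}"
            rng = substream(config.seed, "participant", group, i)
            u_p = (rng.normal(0.0, config.sd_participant)
                   if config.sd_participant > 0 else 0.0)

            base_learn = _safe_logit(gv("p_learn"))
            learned = np.array([
                _bern(rng, _conditional_prob(base_learn, u_p + u_obj[j]))
                for j in range(n_obj)
            ])
            p_know = np.where(learned == 1,
                              gv("judge_known_given_learned"),
                              gv("judge_known_given_unlearned"))
            judgement = np.array([_bern(rng, p) for p in p_know])

            w = np.exp(gv("sampling_preference_w") * (1.0 - judgement))
            times_sampled = np.zeros(n_obj, dtype=np.int64)
            if config.allow_resampling:
                for _ in range(config.n_sampling_choices):
                    probs = w / w.sum()
                    times_sampled[rng.choice(n_obj, p=probs)] += 1
            else:
                picks = weighted_choice_without_replacement(
                    w, config.n_sampling_choices, rng)
                times_sampled[picks] = 1

            base = np.where(learned == 1,
                            _safe_logit(gv("p_correct_learned")),
                            _safe_logit(gv("p_correct_unlearned_base")))
            correct = np.array([
                _bern(rng, _conditional_prob(
                    base[j], gv("sampling_boost") * times_sampled[j]))
                for j in range(n_obj)
            ])
            p_sure = np.where(correct == 1,
                              gv("p_sure_given_correct"),
                              gv("p_sure_given_incorrect"))
            confidence = np.array([_bern(rng, p) for p in p_sure])

            for j in range(n_obj):
                rec_rows.append((pid, group, object_ids[j], int(learned[j]),
                                 int(judgement[j]), int(times_sampled[j]),
                                 int(correct[j]), int(confidence[j])))

            lapse = gv("control_lapse")
            for j in range(N_FAMILIAR):
                err = _bern(rng, lapse)
                ctl_rows.append((pid, f"fam{j + 1}", "familiar", 1 - err))
            for j in range(N_UNFAMILIAR):
                err = _bern(rng, lapse)
                ctl_rows.append((pid, f"unf{j + 1}", "unfamiliar", err))

    records = pd.DataFrame(rec_rows, columns=RECORD_COLUMNS)
    controls = pd.DataFrame(ctl_rows, columns=CONTROL_COLUMNS)
    return records, controls
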