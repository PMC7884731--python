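"""Trial-sequence generation for the reward x efficacy Stroop studies.

Three study layouts are supported:

* Study 1 — 2 (reward: $0.10 / $1.00) x 2 (efficacy: 0% / 100%) cues,
  4 blocks x 75 trials, cue 1500 ms followed by a 250 ms fixation.
* Study 2 — same 2x2 cues, 8 blocks x 75 trials, cue-to-target with no
  intervening fixation (EEG/pupil recording geometry), 800 ms post-response
  blank before feedback.
* Study 3 — parametric 4x4: rewards $0.10/$0.20/$0.40/$0.80 crossed with
  efficacy 25/50/75/100% over 300 total trials.

Cue conditions are balanced within block up to rounding, as are the Stroop
congruency levels; both orders are shuffled independently per block under the
per-subject seed stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stream
from .evc import CONGRUENCY_LEVELS

__all__ = ["DesignConfig", "TrialSpec", "study_design", "generate_design"]


@dataclass(frozen=True)
class DesignConfig:
    """Layout of one study's trial sequence (per subject)."""

    study: int = 2
    n_subjects: int = 44
    blocks: int = 8
    trials_per_block: int = 75
    reward_levels: tuple = (0.10, 1.00)
    efficacy_levels: tuple = (0.0, 1.0)
    congruency_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    response_deadline_ms: float = 750.0
    recording_window_ms: float = 1000.0
    cue_duration_ms: float = 1500.0
    fixation_ms: float = 0.0
    post_response_blank_ms: float = 800.0
    feedback_duration_ms: float = 750.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study not in (1, 2, 3):
            raise ValueError(f"study must be 1, 2 or 3, got {self.study}")
        if not self.reward_levels or not self.efficacy_levels:
            raise ValueError("reward and efficacy level lists must be nonempty")
        if abs(sum(self.congruency_proportions) - 1.0) > 1e-9:
            raise ValueError("congruency_proportions must sum to 1")

    @property
    def trials_per_subject(self) -> int:
        return self.blocks * self.trials_per_block


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: who, when, and which cue/target it carries."""

    subject: int
    trial: int  # 1-based, chronological within subject
    block: int
    reward: float
    efficacy: float
    congruency: str


_STUDY_DEFAULTS = {
    1: dict(
        study=1, n_subjects=21, blocks=4, trials_per_block=75,
        reward_levels=(0.10, 1.00), efficacy_levels=(0.0, 1.0),
        fixation_ms=250.0, post_response_blank_ms=0.0,
    ),
    2: dict(
        study=2, n_subjects=44, blocks=8, trials_per_block=75,
        reward_levels=(0.10, 1.00), efficacy_levels=(0.0, 1.0),
        fixation_ms=0.0, post_response_blank_ms=800.0,
    ),
    3: dict(
        study=3, n_subjects=35, blocks=4, trials_per_block=75,
        reward_levels=(0.10, 0.20, 0.40, 0.80),
        efficacy_levels=(0.25, 0.50, 0.75, 1.00),
        fixation_ms=250.0, post_response_blank_ms=0.0,
    ),
}


def study_design(study: int, **overrides) -> DesignConfig:
    """DesignConfig with the published defaults for a given study."""
    if study not in _STUDY_DEFAULTS:
        raise ValueError(f"study must be 1, 2 or 3, got {study}")
    cfg = DesignConfig(**_STUDY_DEFAULTS[study])
    return replace(cfg, **overrides) if overrides else cfg


def _balanced_labels(items, counts_total: int, rng: np.random.Generator,
                     proportions=None) -> np.ndarray:
    """Shuffled label vector with each item near its balanced count."""
    items = list(items)
    if proportions is None:
        proportions = [1.0 / len(items)] * len(items)
    base = [int(np.floor(p * counts_total)) for p in proportions]
    labels = [it for it, b in zip(items, base) for _ in range(b)]
    # distribute the rounding remainder over a random draw of items
    short = counts_total - len(labels)
    if short:
        extra = rng.choice(len(items), size=short, replace=False,
                           p=np.asarray(proportions) / sum(proportions))
        labels.extend(items[i] for i in np.atleast_1d(extra))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Generate the full trial table for every subject.

    Returns a chronological DataFrame with one row per trial and columns
    ``subject, trial, block, reward, efficacy, congruency``.  Deterministic
    under ``config.seed``: each subject draws from an independent seed stream.
    """
    cells = [(r, e) for r in config.reward_levels for e in config.efficacy_levels]
    rows = []
    for subject in range(1, config.n_subjects + 1):
        rng = stream(config.seed, "design", subject)
        trial = 1
        for block in range(1, config.blocks + 1):
            n = config.trials_per_block
            cond = _balanced_labels(cells, n, rng)
            cong = _balanced_labels(
                CONGRUENCY_LEVELS, n, rng, config.congruency_proportions
            )
            for (r, e), c in zip(cond, cong):
                rows.append((subject, trial, block, r, e, c))
                trial += 1
    df = pd.DataFrame(
        rows, columns=["subject", "trial", "block", "reward", "efficacy", "congruency"]
    )
    return df
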