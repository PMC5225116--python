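"""N-back task simulator.

Generates sessions of the working-memory task used throughout the
package: a stream of stimuli drawn from eight alternatives, where the
participant must respond whenever the current stimulus equals the one
presented ``N`` positions earlier.  Each stimulus is first drawn
uniformly from the eight alternatives; independently, with probability
1/8, it is then overwritten with the stimulus ``N`` back (a "forced"
match).  For trials with more than ``N`` predecessors the resulting
match probability is ``1 - (7/8)^2 = 23.4375%``.

A session at default settings comprises three stimulus modes (Auditory,
Numeric, Spatial), each with one 100-trial block per load level
``N = 1, 2, 3`` — 900 trials in total.  Simple probabilistic response and
subjective-rating models are provided to populate behavioural fields.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MODES: tuple[str, ...] = ("Auditory", "Numeric", "Spatial")
LEVELS: tuple[int, ...] = (1, 2, 3)
N_STIMULI = 8
FORCED_MATCH_PROB = 1.0 / 8.0

#: Long-run probability that a trial with index > N matches the stimulus
#: N back: 1 - (7/8) * (7/8).
MATCH_PROB = 1.0 - (1.0 - 1.0 / N_STIMULI) * (1.0 - FORCED_MATCH_PROB)

_MODE_ORDERS = tuple(itertools.permutations(MODES))


def _seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int, None, or an existing SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

SESSION_COLUMNS = (
    "participant", "mode", "level", "block_index", "trial_index",
    "stimulus_id", "is_match", "forced", "responded", "subjective_rating",
)


@dataclass(frozen=True)
class StimulusTrial:
    """Single trial record (1-based ``index`` within its block)."""

    index: int
    stimulus_id: int
    is_match: bool
    forced: bool
    responded: bool | None = None


@dataclass
class Block:
    """One contiguous block of trials at a single (mode, level).

    Trial data are stored as arrays; :meth:`trials` provides a per-trial
    record view.
    """

    mode: str
    level: int
    stimulus_ids: np.ndarray
    is_match: np.ndarray
    forced: np.ndarray
    responded: np.ndarray | None = None
    subjective_rating: int | None = None

    def __post_init__(self) -> None:
        n = len(self.stimulus_ids)
        if len(self.is_match) != n or len(self.forced) != n:
            raise ValueError("trial arrays must have equal length")
        if self.subjective_rating is not None and not (
            1 <= self.subjective_rating <= 7
        ):
            raise ValueError("subjective rating must lie in 1..7")

    def __len__(self) -> int:
        return len(self.stimulus_ids)

    @property
    def n_trials(self) -> int:
        return len(self)

    def trials(self) -> list[StimulusTrial]:
        resp = self.responded
        return [
            StimulusTrial(
                index=i + 1,
                stimulus_id=int(self.stimulus_ids[i]),
                is_match=bool(self.is_match[i]),
                forced=bool(self.forced[i]),
                responded=None if resp is None else bool(resp[i]),
            )
            for i in range(len(self))
        ]


@dataclass
class Session:
    participant_id: str
    blocks: list[Block]
    mode_order: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)


@dataclass(frozen=True)
class ResponseModel:
    """Per-level hit and false-alarm probabilities for a simulated responder."""

    hit_prob_by_level: Mapping[int, float]
    false_alarm_prob_by_level: Mapping[int, float]

    def __post_init__(self) -> None:
        for probs in (self.hit_prob_by_level, self.false_alarm_prob_by_level):
            for level, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"probability for level {level} outside [0, 1]: {p}"
                    )


#: Calibration roughly matching observed human behaviour: near-ceiling
#: hits at 1-back degrading with load, with a rising false-alarm rate.
DEFAULT_RESPONSE_MODEL = ResponseModel(
    hit_prob_by_level={1: 0.97, 2: 0.85, 3: 0.65},
    false_alarm_prob_by_level={1: 0.01, 2: 0.04, 3: 0.10},
)


@dataclass(frozen=True)
class RatingModel:
    """Level-conditional distribution over 1..7 subjective-workload ratings.

    Either explicit probability vectors (``probs_by_level``) or a
    discretised clipped normal around ``mean_by_level`` with spread ``sd``.
    """

    mean_by_level: Mapping[int, float] | None = None
    sd: float = 1.0
    probs_by_level: Mapping[int, Sequence[float]] | None = None

    def probs(self, level: int) -> np.ndarray:
        if self.probs_by_level is not None:
            p = np.asarray(self.probs_by_level[level], dtype=float)
            if p.shape != (7,) or np.any(p < 0):
                raise ValueError("rating distribution must be 7 nonnegative weights")
            return p / p.sum()
        if self.mean_by_level is None:
            raise ValueError("rating model needs means or explicit distributions")
        mu = self.mean_by_level[level]
        grid = np.arange(1, 8, dtype=float)
        w = np.exp(-0.5 * ((grid - mu) / self.sd) ** 2)
        return w / w.sum()


#: Means chosen to rise steeply with load across the 1..7 scale.
DEFAULT_RATING_MODEL = RatingModel(mean_by_level={1: 2.0, 2: 3.9, 3: 5.9}, sd=1.0)


@dataclass(frozen=True)
class SessionConfig:
    modes: tuple[str, ...] = MODES
    levels: tuple[int, ...] = LEVELS
    blocks_per_cell: int = 1
    trials_per_block: int = 100

    def __post_init__(self) -> None:
        if self.blocks_per_cell < 1 or self.trials_per_block < 1:
            raise ValueError("blocks_per_cell and trials_per_block must be >= 1")
        for level in self.levels:
            if level not in (1, 2, 3):
                raise ValueError(f"level must be in {{1, 2, 3}}, got {level}")


def generate_block(mode: str, level: int, n_trials: int = 100, seed=None) -> Block:
    """Generate one block of the N-back stimulus stream.

    Each trial's stimulus is drawn uniformly from the 8 alternatives;
    independently with probability 1/8 (skipped for trials with fewer
    than ``level`` predecessors) it is overwritten with the stimulus
    ``level`` positions back in the *presented* sequence.  Matches are
    computed from the final sequence.  Deterministic given ``seed``.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be in {{1, 2, 3}}, got {level!r}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, N_STIMULI + 1, size=n_trials)
    forced = rng.random(n_trials) < FORCED_MATCH_PROB
    forced[:level] = False

    # A forced trial repeats the *presented* stimulus `level` back, which
    # may itself have been forced.  Within each congruence lane mod
    # `level`, every trial therefore shows the draw of the most recent
    # unforced trial in that lane.
    pos = np.arange(n_trials)
    src = np.where(forced, -1, pos)
    stim = np.empty(n_trials, dtype=np.int64)
    for lane_start in range(min(level, n_trials)):
        lane = slice(lane_start, None, level)
        governing = np.maximum.accumulate(src[lane])
        stim[lane] = draws[governing]

    is_match = np.zeros(n_trials, dtype=bool)
    if n_trials > level:
        is_match[level:] = stim[level:] == stim[:-level]
    return Block(mode=mode, level=level, stimulus_ids=stim,
                 is_match=is_match, forced=forced)


def generate_session(
    config: SessionConfig = SessionConfig(),
    seed=None,
    participant_index: int = 0,
    participant_id: str | None = None,
) -> Session:
    """Generate a full session: blocks for every (mode, level) cell.

    Mode order follows a Latin-square rotation selected by
    ``participant_index`` (counterbalancing across participants); levels
    ascend within each mode.  At defaults: 3 modes x 3 levels x 1 block
    x 100 trials = 900 trials.
    """
    if participant_id is None:
        participant_id = f"sim{participant_index:02d}"
    mode_order = _MODE_ORDERS[participant_index % len(_MODE_ORDERS)]
    mode_order = tuple(m for m in mode_order if m in config.modes)
    ss = _seed_sequence(seed)
    blocks: list[Block] = []
    for mode in mode_order:
        for level in sorted(config.levels):
            for _ in range(config.blocks_per_cell):
                (child,) = ss.spawn(1)
                blocks.append(
                    generate_block(mode, level, config.trials_per_block, child)
                )
    return Session(participant_id=participant_id, blocks=blocks,
                   mode_order=mode_order)


def simulate_responses(block: Block, model: ResponseModel = DEFAULT_RESPONSE_MODEL,
                       seed=None) -> Block:
    """Return a copy of ``block`` with ``responded`` drawn from ``model``.

    Responses are independent Bernoulli draws: hit probability on match
    trials, false-alarm probability on non-match trials.
    """
    rng = np.random.default_rng(seed)
    hit = model.hit_prob_by_level[block.level]
    fa = model.false_alarm_prob_by_level[block.level]
    p = np.where(block.is_match, hit, fa)
    responded = rng.random(len(block)) < p
    return replace(block, responded=responded)


def confusion_counts(block: Block) -> tuple[int, int, int]:
    """(TP, FP, FN) response counts for a block with populated responses."""
    if block.responded is None:
        raise ValueError("block has no responses; run simulate_responses first")
    resp = block.responded
    tp = int(np.sum(resp & block.is_match))
    fp = int(np.sum(resp & ~block.is_match))
    fn = int(np.sum(~resp & block.is_match))
    return tp, fp, fn


def block_accuracy(block: Block) -> float:
    """Task accuracy TP / (TP + FP + FN).

    Counts correct responses against both kinds of error; always-respond
    performance therefore converges to the 23.44% match rate, and never
    responding scores 0 whenever any match occurred.  Returns NaN when
    the denominator is zero (no matches and no responses), where the
    ratio is undefined.
    """
    tp, fp, fn = confusion_counts(block)
    denom = tp + fp + fn
    if denom == 0:
        return float("nan")
    return tp / denom


def rate_subjective_workload(block: Block,
                             model: RatingModel = DEFAULT_RATING_MODEL,
                             seed=None) -> int:
    """Draw a 1..7 subjective-workload rating for a block."""
    rng = np.random.default_rng(seed)
    p = model.probs(block.level)
    rating = int(rng.choice(np.arange(1, 8), p=p))
    return int(np.clip(rating, 1, 7))


def simulate_participant(
    config: SessionConfig = SessionConfig(),
    response_model: ResponseModel = DEFAULT_RESPONSE_MODEL,
    rating_model: RatingModel = DEFAULT_RATING_MODEL,
    seed=None,
    participant_index: int = 0,
    participant_id: str | None = None,
) -> Session:
    """Generate a session complete with responses and subjective ratings."""
    ss = _seed_sequence(seed)
    s_stim, s_resp, s_rate = ss.spawn(3)
    session = generate_session(config, s_stim, participant_index, participant_id)
    resp_children = s_resp.spawn(len(session.blocks))
    rate_children = s_rate.spawn(len(session.blocks))
    blocks = []
    for block, rs, ts in zip(session.blocks, resp_children, rate_children):
        block = simulate_responses(block, response_model, rs)
        block.subjective_rating = rate_subjective_workload(block, rating_model, ts)
        blocks.append(block)
    session.blocks = blocks
    return session


def session_to_frame(session: Session) -> pd.DataFrame:
    """Flatten a session into one row per trial (documented column order)."""
    rows = []
    block_counter: dict[tuple[str, int], int] = {}
    for block in session.blocks:
        key = (block.mode, block.level)
        block_counter[key] = block_counter.get(key, 0) + 1
        b_idx = block_counter[key]
        n = len(block)
        resp = (np.full(n, np.nan) if block.responded is None
                else block.responded.astype(int))
        rows.append(pd.DataFrame({
            "participant": session.participant_id,
            "mode": block.mode,
            "level": block.level,
            "block_index": b_idx,
            "trial_index": np.arange(1, n + 1),
            "stimulus_id": block.stimulus_ids,
            "is_match": block.is_match.astype(int),
            "forced": block.forced.astype(int),
            "responded": resp,
            "subjective_rating": (np.nan if block.subjective_rating is None
                                  else block.subjective_rating),
        }))
    return pd.concat(rows, ignore_index=True)[list(SESSION_COLUMNS)]


def frame_to_session(frame: pd.DataFrame) -> Session:
    """Rebuild a :class:`Session` from its per-trial table."""
    blocks = []
    participant = str(frame["participant"].iloc[0])
    mode_order: list[str] = []
    for (mode, level, _b), g in frame.groupby(
        ["mode", "level", "block_index"], sort=False
    ):
        g = g.sort_values("trial_index")
        if mode not in mode_order:
            mode_order.append(mode)
        responded = None
        if not g["responded"].isna().any():
            responded = g["responded"].to_numpy().astype(bool)
        rating = g["subjective_rating"].iloc[0]
        blocks.append(Block(
            mode=str(mode), level=int(level),
            stimulus_ids=g["stimulus_id"].to_numpy(dtype=np.int64),
            is_match=g["is_match"].to_numpy().astype(bool),
            forced=g["forced"].to_numpy().astype(bool),
            responded=responded,
            subjective_rating=None if pd.isna(rating) else int(rating),
        ))
    return Session(participant_id=participant, blocks=blocks,
                   mode_order=tuple(mode_order))


def save_session(session: Session, path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def load_session(path) -> Session:
    return frame_to_session(pd.read_csv(path))
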