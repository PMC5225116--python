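"""Synthetic multi-channel EEG epoch generator.

Real recordings from the workload study were never released, so the
pipeline is exercised on synthetic epochs whose band-power structure is
controlled by a known ground-truth effect map.  Each channel of an epoch
is a sum over the six analysis bands of a narrowband oscillation with a
random phase per trial, plus band-limited broadband noise.  The
oscillation amplitude in band ``b`` of channel ``c`` is calibrated so
that the *extracted* log band power is approximately

    g ~ Normal(baseline[c, b] + slope[c, b] * N,  noise_sd[c, b]^2)

where ``N`` is the task level of the trial.  Controlling log power (not
raw power) makes effect sizes additive through the pipeline's log
transform, and the calibration makes the Welch stage a genuine,
testable transformation from synthesis parameters to features.

The default profile plants nonzero slopes in the beta and gamma bands at
lateral and occipital sites, mirroring where high-frequency power tends
to carry load information; magnitudes are free configuration and no
synthetic result should be read as reproducing human data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (BAND_NAMES, DEFAULT_BANDS, DEFAULT_FS, WELCH_NFFT,
                       band_bins)
from .montage import ACTICAP_32, LATERAL_OCCIPITAL
from .nback import Session, _seed_sequence

EPOCH_SECONDS = 3.0
EPOCH_SAMPLES = int(EPOCH_SECONDS * DEFAULT_FS)  # 750

_BIN_HZ = DEFAULT_FS / WELCH_NFFT


def _band_carrier_hz(band) -> float:
    """Band-centre frequency snapped to the nearest Welch bin centre.

    Snapping keeps spectral leakage symmetric and inside the band, so the
    amplitude calibration below is accurate.
    """
    centre = 0.5 * (band.low_hz + band.high_hz)
    snapped = round(centre / _BIN_HZ) * _BIN_HZ
    return float(min(max(snapped, band.low_hz), band.high_hz))


def _band_calibration() -> dict[str, float]:
    """Per-band factor converting target power to sinusoid amplitude^2/2.

    Mean-over-bins band power of a within-band sinusoid of amplitude A is
    ~ (A^2/2) / (n_bins * df); invert that so extracted power ~= exp(g).
    """
    freqs = np.fft.rfftfreq(WELCH_NFFT, d=1.0 / DEFAULT_FS)
    return {b.name: band_bins(freqs, b).size * _BIN_HZ for b in DEFAULT_BANDS}


_CARRIERS = {b.name: _band_carrier_hz(b) for b in DEFAULT_BANDS}
_CALIBRATION = _band_calibration()

#: Level-independent mean log band power per band; roughly 1/f-shaped.
DEFAULT_BASELINE_BY_BAND: dict[str, float] = {
    "delta": 2.0, "theta": 1.5, "low_alpha": 1.2,
    "high_alpha": 1.0, "beta": 0.5, "gamma": 0.0,
}


@dataclass(frozen=True)
class RelevanceRule:
    """Assign ``slope`` to every (channel, band) pair named; optionally
    restricted to specific task modes (mode-specific signatures)."""

    channels: Sequence[str]
    bands: Sequence[str]
    slope: float
    modes: Sequence[str] | None = None


DEFAULT_RELEVANCE: tuple[RelevanceRule, ...] = (
    RelevanceRule(LATERAL_OCCIPITAL, ("gamma",), slope=0.35),
    RelevanceRule(LATERAL_OCCIPITAL, ("beta",), slope=0.20),
)


@dataclass
class ParticipantProfile:
    """Ground-truth generative parameters for one synthetic participant."""

    channel_names: tuple[str, ...]
    baseline_power: np.ndarray        # (channels, bands) mean log band power
    band_effect_map: np.ndarray       # (channels, bands) slope wrt level N
    noise_sd: np.ndarray              # (channels, bands) trial-to-trial sd
    mode_effect_maps: dict[str, np.ndarray] = field(default_factory=dict)
    noise_floor_sd: float = 0.3       # time-domain sd of broadband noise

    def __post_init__(self) -> None:
        shape = (len(self.channel_names), len(BAND_NAMES))
        for name in ("baseline_power", "band_effect_map", "noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")

    def slopes_for_mode(self, mode: str | None) -> np.ndarray:
        slopes = self.band_effect_map
        if mode is not None and mode in self.mode_effect_maps:
            slopes = slopes + self.mode_effect_maps[mode]
        return slopes

    @property
    def relevant_features(self) -> list[tuple[str, str]]:
        """(channel, band) pairs with a nonzero slope in any mode."""
        total = np.abs(self.band_effect_map).copy()
        for extra in self.mode_effect_maps.values():
            total += np.abs(extra)
        out = []
        for ci, ch in enumerate(self.channel_names):
            for bi, band in enumerate(BAND_NAMES):
                if total[ci, bi] != 0:
                    out.append((ch, band))
        return out


def make_participant_profile(
    channel_names: Sequence[str] = ACTICAP_32,
    relevance_spec: Sequence[RelevanceRule] = DEFAULT_RELEVANCE,
    seed=None,
    noise_sd: float = 0.25,
    baseline_by_band: Mapping[str, float] = DEFAULT_BASELINE_BY_BAND,
    baseline_jitter_sd: float = 0.15,
    noise_floor_sd: float = 0.3,
) -> ParticipantProfile:
    """Build a profile with slopes planted per ``relevance_spec``.

    Baselines are the per-band means plus a small per-channel jitter
    (deterministic given ``seed``).  Unknown channel or band names are
    rejected.
    """
    channel_names = tuple(channel_names)
    if relevance_spec is DEFAULT_RELEVANCE:
        # The stock rules adapt to reduced montages: keep whichever of
        # their sites the montage actually carries.
        relevance_spec = tuple(
            RelevanceRule(tuple(c for c in rule.channels
                                if c in channel_names),
                          rule.bands, rule.slope, rule.modes)
            for rule in DEFAULT_RELEVANCE)
        relevance_spec = tuple(r for r in relevance_spec if r.channels)
    rng = np.random.default_rng(seed)
    shape = (len(channel_names), len(BAND_NAMES))
    baseline = np.array([[baseline_by_band[b] for b in BAND_NAMES]
                         for _ in channel_names])
    baseline = baseline + rng.normal(0.0, baseline_jitter_sd, size=shape)
    slopes = np.zeros(shape)
    mode_maps: dict[str, np.ndarray] = {}
    for rule in relevance_spec:
        bad_ch = [c for c in rule.channels if c not in channel_names]
        if bad_ch:
            raise ValueError(f"unknown channels in relevance spec: {bad_ch}")
        bad_b = [b for b in rule.bands if b not in BAND_NAMES]
        if bad_b:
            raise ValueError(f"unknown bands in relevance spec: {bad_b}")
        ci = [channel_names.index(c) for c in rule.channels]
        bi = [BAND_NAMES.index(b) for b in rule.bands]
        if rule.modes is None:
            for c in ci:
                slopes[c, bi] += rule.slope
        else:
            for mode in rule.modes:
                mode_maps.setdefault(mode, np.zeros(shape))
                for c in ci:
                    mode_maps[mode][c, bi] += rule.slope
    return ParticipantProfile(
        channel_names=channel_names,
        baseline_power=baseline,
        band_effect_map=slopes,
        noise_sd=np.full(shape, float(noise_sd)),
        mode_effect_maps=mode_maps,
        noise_floor_sd=noise_floor_sd,
    )


def synthesize_epoch(profile: ParticipantProfile, level: int,
                     mode: str | None = None, seed=None) -> np.ndarray:
    """One (channels x 750) epoch for a trial at task ``level``.

    Deterministic given ``seed``.  Synthesis stays inside the analysed
    1-40 Hz range; power above 45 Hz is negligible.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(profile.channel_names)
    t = np.arange(EPOCH_SAMPLES) / DEFAULT_FS
    slopes = profile.slopes_for_mode(mode)
    target_log = (profile.baseline_power + slopes * level
                  + rng.normal(0.0, 1.0, size=(n_ch, len(BAND_NAMES)))
                  * profile.noise_sd)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, len(BAND_NAMES)))
    out = np.zeros((n_ch, EPOCH_SAMPLES))
    for bi, band in enumerate(BAND_NAMES):
        amp = np.sqrt(2.0 * np.exp(target_log[:, bi]) * _CALIBRATION[band])
        out += amp[:, None] * np.sin(
            2.0 * np.pi * _CARRIERS[band] * t[None, :] + phases[:, bi:bi + 1]
        )
    if profile.noise_floor_sd > 0:
        white = rng.standard_normal((n_ch, EPOCH_SAMPLES))
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(EPOCH_SAMPLES, d=1.0 / DEFAULT_FS)
        spec[:, (f < 1.0) | (f > 40.0)] = 0.0
        noise = np.fft.irfft(spec, n=EPOCH_SAMPLES, axis=-1)
        sd = noise.std()
        if sd > 0:
            out += profile.noise_floor_sd / sd * noise
    return out


@dataclass
class EpochedSession:
    """Per-trial epochs aligned 1:1 with a simulated session's trials."""

    data: np.ndarray                  # (trials, channels, samples)
    labels: pd.DataFrame              # participant/mode/level/block/trial/subjective
    channel_names: tuple[str, ...]
    fs: float = DEFAULT_FS
    profile_truth: ParticipantProfile | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("epoch count must equal label row count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def synthesize_session_epochs(session: Session, profile: ParticipantProfile,
                              seed=None) -> EpochedSession:
    """One epoch per session trial, labels copied from the trials."""
    ss = _seed_sequence(seed)
    epochs = []
    rows = []
    block_counter: dict[tuple[str, int], int] = {}
    for block in session.blocks:
        key = (block.mode, block.level)
        block_counter[key] = block_counter.get(key, 0) + 1
        b_idx = block_counter[key]
        children = ss.spawn(len(block))
        for i, child in enumerate(children):
            epochs.append(synthesize_epoch(profile, block.level, block.mode, child))
            rows.append({
                "participant": session.participant_id,
                "mode": block.mode,
                "level": block.level,
                "block": b_idx,
                "trial": i + 1,
                "subjective": (np.nan if block.subjective_rating is None
                               else block.subjective_rating),
            })
    n_ch = len(profile.channel_names)
    data = (np.stack(epochs) if epochs
            else np.empty((0, n_ch, EPOCH_SAMPLES)))
    labels = pd.DataFrame(
        rows, columns=["participant", "mode", "level", "block", "trial",
                       "subjective"])
    return EpochedSession(data=data, labels=labels,
                          channel_names=profile.channel_names,
                          profile_truth=profile)


def save_epochs(es: EpochedSession, directory) -> None:
    """Write epochs as an .npy array with a JSON + CSV text sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "epochs.npy", es.data)
    es.labels.to_csv(directory / "labels.csv", index=False)
    meta = {"channel_names": list(es.channel_names), "fs": es.fs,
            "n_trials": int(es.n_trials), "schema_version": 1}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_epochs(directory) -> EpochedSession:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    return EpochedSession(
        data=np.load(directory / "epochs.npy"),
        labels=pd.read_csv(directory / "labels.csv"),
        channel_names=tuple(meta["channel_names"]),
        fs=float(meta["fs"]),
    )
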