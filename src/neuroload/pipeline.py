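"""End-to-end pipeline: simulate -> synthesize -> extract -> evaluate.

A single master seed deterministically spawns one seed per stage and
participant, so identical (config, seed) pairs produce bit-identical
outputs while stages stay individually reproducible for debugging.
Every run directory is stamped with the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import nback, synth
from .config import PipelineConfig
from .evaluation import make_cv_plan, run_cv
from .features import extract_features
from .gpr import GPHyperparams
from .synth import RelevanceRule, make_participant_profile

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _relevance_rules(config: PipelineConfig):
    if config.synthesis.relevance is None:
        return synth.DEFAULT_RELEVANCE
    return tuple(
        RelevanceRule(channels=r.channels, bands=r.bands, slope=r.slope,
                      modes=r.modes)
        for r in config.synthesis.relevance
    )


def _gpr_options(config: PipelineConfig, n_features: int) -> dict:
    g = config.gpr
    return {
        "init_hyper": GPHyperparams.default(
            n_features, length_scale=g.init_length_scale,
            signal_variance=g.init_signal_variance,
            noise_variance=g.init_noise_variance),
        "max_function_evals": g.max_function_evals,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline, writing per-participant artifacts.

    Writes session.csv, features.csv, predictions_<method>.csv and
    metrics.json per participant, plus a run manifest.  Returns a
    summary dict mirroring metrics.json contents.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    summary: dict = {"config_hash": config.config_hash(),
                     "seed": config.seed, "participants": {}}
    (out_dir / "manifest.json").write_text(json.dumps(
        {"config_hash": config.config_hash(), "seed": config.seed,
         "config": config.model_dump()}, indent=2, default=str))

    sim = config.simulation
    session_cfg = nback.SessionConfig(
        modes=sim.modes, levels=sim.levels,
        blocks_per_cell=sim.blocks_per_cell,
        trials_per_block=sim.trials_per_block)

    for p_idx in range(sim.participants):
        p_seed_sim, p_seed_profile, p_seed_synth = master.spawn(3)
        pdir = out_dir / f"participant{p_idx:02d}"
        pdir.mkdir(exist_ok=True)

        try:
            session = nback.simulate_participant(
                session_cfg, seed=p_seed_sim, participant_index=p_idx)
            nback.save_session(session, pdir / "session.csv")
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineStageError("simulate", exc) from exc

        try:
            profile = make_participant_profile(
                channel_names=config.synthesis.channel_names,
                relevance_spec=_relevance_rules(config),
                seed=p_seed_profile,
                noise_sd=config.synthesis.noise_sd,
                noise_floor_sd=config.synthesis.noise_floor_sd)
            epochs = synth.synthesize_session_epochs(session, profile,
                                                     seed=p_seed_synth)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("synthesize", exc) from exc

        try:
            features = extract_features(epochs)
            features.to_csv(pdir / "features.csv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("extract", exc) from exc

        try:
            plan = make_cv_plan(features.labels, k=config.cv.k,
                                buffer=config.cv.buffer)
            metrics = {}
            for method in config.methods:
                opts = (_gpr_options(config, features.n_features)
                        if method == "gpr" else None)
                result = run_cv(features, plan, method=method,
                                label_kind=config.label, gpr_options=opts)
                result.records.to_csv(pdir / f"predictions_{method}.csv",
                                      index=False)
                metrics[method] = result.report.to_dict()
            (pdir / "metrics.json").write_text(
                json.dumps(metrics, indent=2, default=float))
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("evaluate", exc) from exc

        summary["participants"][f"participant{p_idx:02d}"] = metrics
        log.info("participant %d done", p_idx)

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return summary
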