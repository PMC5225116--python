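"""Shared fixtures: small synthetic sessions, features, and CV results.

Expensive objects (trained cross-validation results) are session-scoped
so several test modules can share one GP training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuroload.evaluation import make_cv_plan, run_cv
from neuroload.features import extract_features
from neuroload.nback import SessionConfig, simulate_participant
from neuroload.synth import (RelevanceRule, make_participant_profile,
                             synthesize_session_epochs)

# Six channels keep GP training fast while exercising montage logic:
# four "relevant" lateral/occipital sites and two midline controls.
CHANNELS6 = ("F7", "F8", "O1", "O2", "Cz", "Pz")
RELEVANT6 = ("F7", "F8", "O1", "O2")

PLANTED_RULES = (
    RelevanceRule(RELEVANT6, ("gamma",), slope=0.35),
    RelevanceRule(RELEVANT6, ("beta",), slope=0.20),
)


def make_feature_matrix(rules, trials_per_block=60, channels=CHANNELS6,
                        seed=2024, noise_sd=0.25):
    """Simulate a session, synthesize epochs, and extract features."""
    ss = np.random.SeedSequence(seed)
    s_sess, s_prof, s_epoch = ss.spawn(3)
    session = simulate_participant(
        SessionConfig(trials_per_block=trials_per_block), seed=s_sess)
    profile = make_participant_profile(channels, rules, seed=s_prof,
                                       noise_sd=noise_sd)
    epochs = synthesize_session_epochs(session, profile, seed=s_epoch)
    return extract_features(epochs)


@pytest.fixture(scope="session")
def planted_features():
    """540 trials, 36 features; level signal planted in beta/gamma at
    lateral-occipital sites, identically across task modes."""
    return make_feature_matrix(PLANTED_RULES)


@pytest.fixture(scope="session")
def null_features():
    """Same layout but no level-dependent structure anywhere."""
    return make_feature_matrix(rules=(), seed=4096)


@pytest.fixture(scope="session")
def planted_plan(planted_features):
    return make_cv_plan(planted_features.labels, k=5, buffer=5)


@pytest.fixture(scope="session")
def planted_cv_gpr(planted_features, planted_plan):
    return run_cv(planted_features, planted_plan, method="gpr")


@pytest.fixture(scope="session")
def planted_cv_mlr(planted_features, planted_plan):
    return run_cv(planted_features, planted_plan, method="mlr")
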