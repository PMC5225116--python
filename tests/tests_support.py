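"""Helpers shared across test modules."""

from conftest import CHANNELS6, make_feature_matrix

from neuroload.synth import RelevanceRule

#: Orthogonal level signatures: each task variant carries its level
#: signal in a disjoint channel pair, so nothing transfers across
#: variants.
MODE_SPECIFIC_RULES = (
    RelevanceRule(("F7", "F8"), ("gamma",), slope=0.5, modes=("Auditory",)),
    RelevanceRule(("O1", "O2"), ("gamma",), slope=0.5, modes=("Numeric",)),
    RelevanceRule(("Cz", "Pz"), ("gamma",), slope=0.5, modes=("Spatial",)),
)


def make_mode_specific_features(seed=77, trials_per_block=60):
    return make_feature_matrix(MODE_SPECIFIC_RULES,
                               trials_per_block=trials_per_block,
                               channels=CHANNELS6, seed=seed)
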