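"""Electrode montage definitions.

The default montage is a 32-channel active-electrode laboratory cap
(10-20 layout).  Named subsets approximate the electrode sets of two
reduced consumer/field headsets plus two anatomical regions, and are used
to evaluate how much predictive power survives when features are
restricted to a smaller montage.
"""

from __future__ import annotations

from typing import Sequence

ACTICAP_32: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "PO9", "O1", "O2", "PO10",
)

#: Lateral and occipital sites where level-dependent high-frequency power
#: is planted by the default synthesis profile.
LATERAL_OCCIPITAL: tuple[str, ...] = (
    "F7", "F8", "T7", "T8", "P7", "P8", "PO9", "PO10", "O1", "O2",
)

#: Named channel subsets.  Counts: 9, 16, 9 and 5 channels, i.e. 54, 96,
#: 54 and 30 band-power features at six bands per channel.
MONTAGE_SUBSETS: dict[str, tuple[str, ...]] = {
    # Rapid-deployment headset: midline-heavy, 9 sites.
    "b_alert_x10": ("F3", "F4", "C3", "C4", "P3", "P4", "Fz", "Cz", "POz"),
    # Consumer headset: equatorial/lateral sites, 16 sites.
    "emotiv_epoc": (
        "Fp1", "Fp2", "F7", "F3", "F4", "F8", "FC5", "FC6",
        "T7", "T8", "P7", "P3", "P4", "P8", "O1", "O2",
    ),
    "parietal": ("CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("POz", "PO9", "O1", "O2", "PO10"),
}


def resolve_channel_subset(
    subset: str | Sequence[str], montage: Sequence[str] = ACTICAP_32
) -> tuple[str, ...]:
    """Resolve a named subset or explicit channel list against a montage.

    Raises ``KeyError`` for an unknown subset name and ``ValueError`` for
    channel names absent from the montage.
    """
    if isinstance(subset, str):
        try:
            channels = MONTAGE_SUBSETS[subset]
        except KeyError:
            raise KeyError(
                f"unknown montage subset {subset!r}; "
                f"known: {sorted(MONTAGE_SUBSETS)}"
            ) from None
    else:
        channels = tuple(subset)
    unknown = [ch for ch in channels if ch not in montage]
    if unknown:
        raise ValueError(f"channels not in montage: {unknown}")
    return tuple(channels)
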