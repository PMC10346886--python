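"""The 19-channel international 10-20 scalp montage and its focal-zone geometry.

All analyses reference the raw potentials to FP2 (a forehead electrode with
reliable contact), leaving 18 analysis channels.  Focal seizure onset zones
are described by (lobe, hemisphere) pairs mapped to small electrode subsets.
"""

from __future__ import annotations

# Order follows the conventional 10-20 listing: frontal pole to occiput.
CHANNELS_1020: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

REFERENCE_CHANNEL = "FP2"

#: The 18 channels that remain after re-referencing to FP2.
ANALYSIS_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in CHANNELS_1020 if ch != REFERENCE_CHANNEL
)

FOCUS_ZONES = ("temporal", "frontal", "parietal", "occipital")
HEMISPHERES = ("left", "right")

#: Electrodes over each seizure onset zone.  Lateral temporal chains carry
#: the bulk of temporal-lobe ictal rhythms; midline electrodes are excluded
#: from lateralized zones.  FP2 never appears (it is the reference).
FOCAL_CHANNEL_MAP: dict[tuple[str, str], tuple[str, ...]] = {
    ("temporal", "left"): ("F7", "T3", "T5"),
    ("temporal", "right"): ("F8", "T4", "T6"),
    ("frontal", "left"): ("FP1", "F3", "F7"),
    ("frontal", "right"): ("F4", "F8"),
    ("parietal", "left"): ("C3", "P3"),
    ("parietal", "right"): ("C4", "P4"),
    ("occipital", "left"): ("T5", "O1"),
    ("occipital", "right"): ("T6", "O2"),
}

#: First-neighbour adjacency on the scalp, used for spatial leakage of
#: ictal rhythms onto surrounding electrodes.
ADJACENCY: dict[str, tuple[str, ...]] = {
    "FP1": ("FP2", "F7", "F3"),
    "FP2": ("FP1", "F4", "F8"),
    "F7": ("FP1", "F3", "T3"),
    "F3": ("FP1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("FP2", "Fz", "F8", "C4"),
    "F8": ("FP2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "Cz", "T4", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}


def validate_channels(labels, *, universe: tuple[str, ...] = CHANNELS_1020) -> tuple[str, ...]:
    """Return ``labels`` as a tuple after checking membership and uniqueness."""
    labels = tuple(labels)
    unknown = [ch for ch in labels if ch not in universe]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels")
    return labels
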