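"""64-channel geodesic sensor net: labels, idealized positions, focal sets.

Positions come from the idealized standard montage bundled with MNE
(``GSN-HydroCel-64_1.0``), so no coordinate file ships with this package.
The focal electrode sets are the central clusters contralateral to the
stimulated hand: E22/E25/E26/E27/E28 (left hemisphere, right-hand
stimulation) and E42/E45/E46/E48/E49 (right hemisphere, left-hand
stimulation).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

N_CHANNELS = 64

#: central cluster contralateral to right-hand stimulation (left hemisphere)
LEFT_CENTRAL = ("E22", "E25", "E26", "E27", "E28")
#: central cluster contralateral to left-hand stimulation (right hemisphere)
RIGHT_CENTRAL = ("E42", "E45", "E46", "E48", "E49")

MONTAGE_NAME = "GSN-HydroCel-64_1.0"


def channel_labels() -> list[str]:
    """Labels E1..E64 in montage order."""
    return [f"E{i}" for i in range(1, N_CHANNELS + 1)]


@lru_cache(maxsize=1)
def _positions_cached() -> np.ndarray:
    import mne

    montage = mne.channels.make_standard_montage(MONTAGE_NAME)
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[label] for label in channel_labels()])


def channel_positions() -> np.ndarray:
    """Idealized 3-D electrode positions, metres, shape (64, 3)."""
    return _positions_cached().copy()


def channel_index(labels: str | list[str] | tuple[str, ...]) -> np.ndarray:
    """Map electrode label(s) to 0-based montage indices.

    Raises
    ------
    KeyError
        Naming the first unknown label.
    """
    if isinstance(labels, str):
        labels = [labels]
    lookup = {name: i for i, name in enumerate(channel_labels())}
    out = []
    for label in labels:
        if label not in lookup:
            raise KeyError(f"unknown electrode label {label!r}")
        out.append(lookup[label])
    return np.asarray(out, dtype=int)


def focal_set(condition: str) -> tuple[str, ...]:
    """Contralateral central electrode set for a stimulation condition."""
    if condition.startswith("right"):
        return LEFT_CENTRAL
    if condition.startswith("left"):
        return RIGHT_CENTRAL
    raise ValueError(f"no focal set defined for condition {condition!r}")
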