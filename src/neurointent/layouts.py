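"""2-D sensor layouts for topographic maps and channel bookkeeping.

Coordinates are azimuthal-equidistant projections of idealized scalp
positions onto the unit disc (nose at +y).  They are layout constants for
interpolation and plotting, not digitized positions.
"""

from __future__ import annotations

import numpy as np

# 64-channel montage in anterior-to-posterior order.  Rows follow the
# extended 10-20 naming scheme; "layout order" (frontal first) is the order
# of this list and is what the synthetic generator's responsive-channel
# default refers to.
_EEG_ROWS: list[tuple[str, float, list[str]]] = [
    # (row prefix, fraction of nasion-inion arc from front, lateral labels)
    ("Fp", 0.10, ["Fp1", "Fpz", "Fp2"]),
    ("AF", 0.20, ["AF3", "AFz", "AF4"]),
    ("F", 0.30, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    ("FC", 0.40, ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    ("C", 0.50, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    ("CP", 0.60, ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    ("P", 0.70, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    ("PO", 0.82, ["PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8"]),
    ("O", 0.92, ["O1", "Oz", "O2"]),
    ("I", 1.00, ["CB1", "Iz", "CB2"]),
]


def standard_64_layout() -> tuple[list[str], np.ndarray]:
    """Return (names, xy) for the 64-channel montage, frontal channels first.

    xy is (64, 2) on the unit disc; +y is anterior, +x is right.
    """
    names: list[str] = []
    xy: list[tuple[float, float]] = []
    for _prefix, frac, labels in _EEG_ROWS:
        y = 1.0 - 2.0 * frac
        half_width = np.sqrt(max(1.0 - y * y, 0.05))
        m = len(labels)
        if m == 1:
            xs = np.array([0.0])
        else:
            xs = np.linspace(-half_width, half_width, m)
        for label, x in zip(labels, xs):
            names.append(label)
            xy.append((float(x), float(y)))
    pts = np.asarray(xy, dtype=float)
    assert len(names) == 64
    return names, pts


def fnirs_parietal_layout() -> tuple[list[str], np.ndarray]:
    """48-channel fNIRS layout: two 4x6 patches over bilateral parietal areas.

    Channels 1-24 are left hemisphere (channel 13 near C3), 25-48 right
    (channel 36 near C4).  Coordinates are emitter-detector midpoints on a
    parametric grid in the same unit-disc frame as the EEG layout.
    """
    names: list[str] = []
    xy: list[tuple[float, float]] = []
    for side, x_center in (("L", -0.45), ("R", 0.45)):
        k = 0
        for row in range(4):
            for col in range(6):
                k += 1
                x = x_center + (col - 2.5) * 0.11
                y = 0.25 - row * 0.18
                names.append(f"CH{len(names) + 1:02d}{side}")
                xy.append((float(x), float(y)))
    return names, np.asarray(xy, dtype=float)
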