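"""Idealized spherical EEG montages (10-10 / 10-20 systems).

Electrode positions are constructed by rule on a unit sphere: the row letter
(Fp, AF, F, FC, C, CP, P, PO, O) sets the anterior-posterior arc angle from
the vertex in 18-degree (10%) steps, and the electrode number sets the
lateral arc angle (18 degrees per 10% step; odd = left, even = right,
z = midline).  Lateral row aliases follow the extended 10-20 convention
(T7=C7, FT7=FC7, TP7=CP7).  These are stylized coordinates — adequate for
spline-Laplacian geometry and topography construction, not digitized
positions.

Coordinate frame: x = right, y = anterior, z = up; all positions unit-norm.
"""

from __future__ import annotations

from pathlib import Path
import re

import numpy as np

_ROW_ANGLE = {  # AP arc angle from vertex, degrees (positive = anterior)
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "C": 0.0,
    "CP": -18.0, "P": -36.0, "PO": -54.0, "O": -72.0,
}

_ALIASES = {"T": "C", "FT": "FC", "TP": "CP"}  # lateral row aliases

#: the 56-electrode 10-10 subset used for full-scale simulation (the four
#: inferior parietal electrodes P9-P12 of a 60-channel cap are excluded).
CHANNELS_56 = [
    "Fp1", "Fpz", "Fp2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
]

#: the classic 19-electrode 10-20 montage (used by the desk-scale benchmark).
CHANNELS_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def electrode_position(label: str) -> np.ndarray:
    """Unit-sphere position of a 10-10 electrode label."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unrecognized electrode label: {label!r}")
    row, num = m.group(1), m.group(2)
    row = row[0].upper() + row[1:]
    row = _ALIASES.get(row, row)
    if row not in _ROW_ANGLE:
        raise ValueError(f"unrecognized electrode row in label {label!r}")
    alpha = np.deg2rad(_ROW_ANGLE[row])
    if num == "z":
        beta = 0.0
    else:
        n = int(num)
        side = -1.0 if n % 2 == 1 else 1.0  # odd = left (negative x)
        beta = side * np.deg2rad(18.0 * ((n + 1) // 2))
    # midline point at AP angle alpha, then rotate about the AP (y) axis
    x = np.cos(alpha) * np.sin(beta)
    y = np.sin(alpha)
    z = np.cos(alpha) * np.cos(beta)
    return np.array([x, y, z])


def positions_for(labels) -> np.ndarray:
    """(n, 3) unit-sphere positions for a list of labels."""
    return np.array([electrode_position(lb) for lb in labels])


def standard_1010_56():
    """The 56-channel 10-10 subset: (names, positions)."""
    return list(CHANNELS_56), positions_for(CHANNELS_56)


def standard_1020_19():
    """The 19-channel 10-20 montage: (names, positions)."""
    return list(CHANNELS_19), positions_for(CHANNELS_19)


def write_sfp(path, names, positions) -> None:
    """Write an sfp-style tab-delimited ``name x y z`` file."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(names, positions):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_sfp(path):
    """Read an sfp-style file -> (names, (n, 3) array)."""
    names, rows = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return names, np.array(rows)


def topography(names, positions, focus: str, spread_deg: float = 35.0) -> np.ndarray:
    """Gaussian channel-gain map centred on ``focus``, in [0, 1].

    Gain falls off with great-circle angular distance from the focal
    electrode with the given standard deviation (degrees).
    """
    names = list(names)
    if focus not in names:
        raise ValueError(f"focus electrode {focus!r} not in montage")
    p0 = positions[names.index(focus)]
    cosang = np.clip(positions @ p0, -1.0, 1.0)
    ang = np.rad2deg(np.arccos(cosang))
    return np.exp(-0.5 * (ang / spread_deg) ** 2)
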