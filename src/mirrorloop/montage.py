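"""Idealized spherical 10-10 electrode layout.

Positions are constructed geometrically on the unit sphere following the
extended international 10-20 ("10-10") placement scheme: midline electrodes
sit on the sagittal great circle at 18 degree steps from the vertex, the
temporal ring (Fp1 .. O1 and mirror) sits at 72 degrees inclination, and the
intermediate rows are placed at equal fractions along the great-circle arc
joining their midline electrode to their ring electrode.  Coordinate frame:
+x right, +y anterior, +z up, head radius 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the 48 recording sites of the reference montage, amplifier channel order
CHANNELS_48 = [
    "Fp1", "Fp2", "F5", "F3", "F1", "F2", "F4", "F6",
    "FT7", "FT8", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "T7", "T8", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
]

#: sensorimotor rows used for CSP pattern selection
CENTRAL_ROWS = ("FC", "C", "CP")


def _sph(incl_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at inclination from vertex and azimuth (90 = anterior)."""
    th = np.deg2rad(incl_deg)
    ph = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def _build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # sagittal midline, vertex to +-72 deg in 18 deg (10%) steps
    midline = ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]
    for i, name in enumerate(midline):
        pos[name] = _sph(abs(72 - 18 * i), 90 if i < 4 else (0 if i == 4 else 270))
    # temporal ring at 72 deg inclination, 18 deg azimuthal steps
    left_ring = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
    right_ring = ["Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2"]
    for i, (ln, rn) in enumerate(zip(left_ring, right_ring)):
        pos[ln] = _sph(72, 108 + 18 * i)
        pos[rn] = _sph(72, 72 - 18 * i)
    # intermediate rows: equal arc fractions between midline and ring sites
    rows = {
        "F": ("Fz", "F7", "F8", ["1", "3", "5"]),
        "FC": ("FCz", "FT7", "FT8", ["1", "3", "5"]),
        "C": ("Cz", "T7", "T8", ["1", "3", "5"]),
        "CP": ("CPz", "TP7", "TP8", ["1", "3", "5"]),
        "P": ("Pz", "P7", "P8", ["1", "3", "5"]),
        "PO": ("POz", "PO7", "PO8", ["3"]),
    }
    for row, (mid, lend, rend, digits) in rows.items():
        for k, d in enumerate(digits, start=1):
            frac = k / (len(digits) + 1)
            pos[f"{row}{d}"] = _slerp(pos[mid], pos[lend], frac)
            even = str(int(d) + 1)
            pos[f"{row}{even}"] = _slerp(pos[mid], pos[rend], frac)
    return pos


_ALL_POSITIONS = _build_positions()


@dataclass(frozen=True)
class MontageLayout:
    """Electrode names, unit-sphere positions and the sensorimotor subset."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    central_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must have unit norm")
        unknown = self.central_set - set(self.channel_names)
        if unknown:
            raise ValueError(f"central_set members not in montage: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def central_mask(self) -> np.ndarray:
        return np.array([c in self.central_set for c in self.channel_names])

    def angular_distances(self, name: str) -> np.ndarray:
        """Great-circle distance (radians) from one electrode to all others."""
        dots = self.positions @ self.position(name)
        return np.arccos(np.clip(dots, -1.0, 1.0))


def standard_montage(channels: list[str] | None = None) -> MontageLayout:
    """The 48-channel 10-10 montage (or any subset of known 10-10 labels)."""
    names = list(channels) if channels is not None else list(CHANNELS_48)
    missing = [c for c in names if c not in _ALL_POSITIONS]
    if missing:
        raise ValueError(f"unknown 10-10 labels: {missing}")
    positions = np.array([_ALL_POSITIONS[c] for c in names])
    # row membership: FC*, CP*, or the C row itself (C5..C6, Cz)
    central = frozenset(
        c for c in names
        if c.startswith("FC") or c.startswith("CP")
        or (c.startswith("C") and not c.startswith("CP"))
    )
    return MontageLayout(tuple(names), positions, central)
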