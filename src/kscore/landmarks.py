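"""Canonical landmark vocabulary for the 11-point body model.

The capture convention is a fixed set of 11 landmarks — 5 on the trunk and 6
on the lower extremities — sampled as 3D positions in meters. Axis convention:
X mediolateral, Y vertical (up positive), Z anteroposterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

#: Canonical landmark order; every positions array is T x 11 x 3 in this order.
LANDMARKS: tuple[str, ...] = (
    "neck",
    "shoulder_l",
    "shoulder_r",
    "spine_mid",
    "spine_base",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
)

AXES: tuple[str, ...] = ("x", "y", "z")

#: Flattened coordinate column names in canonical order (33 columns).
COORD_COLUMNS: tuple[str, ...] = tuple(
    f"{lm}_{ax}" for lm in LANDMARKS for ax in AXES
)

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARKS)}

TRUNK_LANDMARKS: tuple[str, ...] = (
    "neck", "shoulder_l", "shoulder_r", "spine_mid", "spine_base",
)
LOWER_EXTREMITY_LANDMARKS: tuple[str, ...] = (
    "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
)


@dataclass(frozen=True)
class LandmarkSet:
    """A named subset of the 11 canonical landmarks.

    Members are stored in canonical order regardless of construction order so
    that flattened coordinate blocks are comparable across trials.
    """

    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        unknown = [m for m in self.members if m not in LANDMARK_INDEX]
        if unknown:
            raise ParameterError(f"unknown landmarks: {unknown}")
        ordered = tuple(lm for lm in LANDMARKS if lm in set(self.members))
        object.__setattr__(self, "members", ordered)

    @property
    def indices(self) -> list[int]:
        """Indices into the canonical 11-landmark axis."""
        return [LANDMARK_INDEX[m] for m in self.members]

    @property
    def coord_indices(self) -> list[int]:
        """Indices into the flattened 33-column coordinate axis."""
        return [3 * LANDMARK_INDEX[m] + a for m in self.members for a in range(3)]

    @property
    def n_coords(self) -> int:
        return 3 * len(self.members)

    def __len__(self) -> int:
        return len(self.members)


FULL_BODY = LandmarkSet("full_body", LANDMARKS)
TRUNK = LandmarkSet("trunk", TRUNK_LANDMARKS)
LOWER_EXTREMITY = LandmarkSet("lower_extremity", LOWER_EXTREMITY_LANDMARKS)

LANDMARK_SETS: dict[str, LandmarkSet] = {
    s.name: s for s in (FULL_BODY, TRUNK, LOWER_EXTREMITY)
}


def get_landmark_set(name: str) -> LandmarkSet:
    try:
        return LANDMARK_SETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown landmark set {name!r}; expected one of {sorted(LANDMARK_SETS)}"
        ) from None
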