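"""Factorial design and angular coordinate system of the rotated-character task.

The experiment shows an alphanumeric character (4, P, or R; canonical or
mirror-inverted) on a table at one of eight orientations, with another person
either absent or seated to the left or right of the table.  All angles are in
degrees: 0 deg is upright to the participant and angles increase
counter-clockwise.  The seated persons view the table from azimuths of 90 deg
(left) and 270 deg (right), perpendicular to the participant, which makes the
character's angular disparity to the participant and to the person exactly
orthogonal predictors over the design cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The eight character orientations, counter-clockwise from upright.
ORIENTATIONS: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

#: Viewing azimuth of each viewer role.
AZIMUTHS: dict[str, float] = {"participant": 0.0, "left": 90.0, "right": 270.0}

CHARACTERS: tuple[str, ...] = ("4", "P", "R")
FORMS: tuple[str, ...] = ("canonical", "mirror")
LOCATIONS: tuple[str, ...] = ("none", "left", "right")
MOVEMENTS: tuple[str, ...] = ("free", "restricted")

N_BLOCKS = 4
TRIALS_PER_BLOCK = 144
TRIALS_PER_PARTICIPANT = N_BLOCKS * TRIALS_PER_BLOCK  # 576


def angular_disparity(theta, phi):
    """Minimal rotation (degrees, 0-180) between orientation ``theta`` and a
    viewpoint's upright direction ``phi``.

    Both arguments are reduced modulo 360; the function is symmetric and
    broadcasts over array inputs.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
        raise ValueError("angular_disparity requires finite angles")
    diff = np.abs(theta - phi) % 360.0
    out = np.minimum(diff, 360.0 - diff)
    return float(out) if out.ndim == 0 else out


def viewpoint_azimuth(role: str) -> float:
    """Azimuth of a viewer role: participant -> 0, left -> 90, right -> 270."""
    try:
        return AZIMUTHS[role]
    except KeyError:
        raise ValueError(f"unknown viewer role {role!r}; expected one of {sorted(AZIMUTHS)}") from None


def self_disparities() -> np.ndarray:
    """Disparity of each of the eight orientations to the participant."""
    return angular_disparity(np.array(ORIENTATIONS, float), 0.0)


def other_disparities(location: str) -> np.ndarray:
    """Disparity of each of the eight orientations to the person at ``location``."""
    return angular_disparity(np.array(ORIENTATIONS, float), viewpoint_azimuth(location))


def _cell_grid() -> pd.DataFrame:
    """The 144 location x character x form x orientation combinations."""
    idx = pd.MultiIndex.from_product(
        [LOCATIONS, CHARACTERS, FORMS, ORIENTATIONS],
        names=["person_location", "character", "form", "orientation_deg"],
    )
    return idx.to_frame(index=False)


def enumerate_design(rng: np.random.Generator, movement_first: str = "free") -> pd.DataFrame:
    """Enumerate one participant's 576-trial session.

    Four blocks of 144 trials alternate movement condition in ABAB order
    (``movement_first`` names block A).  Within each movement condition every
    one of the 144 location x character x form x orientation combinations
    appears exactly twice (once with a male and once with a female actor when
    a person is present); trial order within the condition is pseudorandomised
    from ``rng``.  The trial multiset is therefore identical across seeds.
    """
    if movement_first not in MOVEMENTS:
        raise ValueError(f"movement_first must be one of {MOVEMENTS}")
    order = [movement_first, [m for m in MOVEMENTS if m != movement_first][0]] * 2

    frames = []
    for movement in MOVEMENTS:
        grid = _cell_grid()
        a, b = grid.copy(), grid.copy()
        a["actor_sex"] = np.where(a.person_location == "none", "n/a", "male")
        b["actor_sex"] = np.where(b.person_location == "none", "n/a", "female")
        trials = pd.concat([a, b], ignore_index=True)
        trials = trials.iloc[rng.permutation(len(trials))].reset_index(drop=True)
        trials["movement"] = movement
        frames.append(trials)

    by_movement = {m: f for m, f in zip(MOVEMENTS, frames)}
    cursor = {m: 0 for m in MOVEMENTS}
    blocks = []
    for block_no, movement in enumerate(order, start=1):
        lo = cursor[movement]
        chunk = by_movement[movement].iloc[lo:lo + TRIALS_PER_BLOCK].copy()
        cursor[movement] = lo + TRIALS_PER_BLOCK
        chunk["block"] = block_no
        blocks.append(chunk)

    design = pd.concat(blocks, ignore_index=True)
    design["trial_index"] = np.arange(1, len(design) + 1)
    cols = ["block", "trial_index", "movement", "person_location",
            "actor_sex", "character", "form", "orientation_deg"]
    return design[cols]


def stimulus_identities(design: pd.DataFrame) -> int:
    """Number of distinct (character, form, orientation) stimulus identities."""
    return len(design[["character", "form", "orientation_deg"]].drop_duplicates())
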