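"""Base-pair step and helical-axis parameters, and A/B-form classification.

The step decomposition is a mid-frame (CEHS-style) rotation-vector scheme:
for consecutive pair frames ``(R1, o1)`` and ``(R2, o2)`` the relative
rotation ``R1ᵀR2`` is expressed as a rotation vector whose components *are*
(tilt, roll, twist); the origin displacement expressed in the mid frame
gives (shift, slide, rise).  This convention is exactly invertible, which
the synthetic ensemble generator relies on.  It differs from the
curvilinear-axis convention of Curves+ by small systematic offsets.

Helical-axis parameters come from the screw decomposition of the same
frame-to-frame transform: h-twist is the rotation angle about the local
helical axis, h-rise the translation along it, and x-displacement /
inclination locate and orient the mid base-pair frame relative to the axis.
For an ideal B-form step (pairs perpendicular to the axis) the two sets
coincide; their divergence is the classical A-form diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._geom import matrix_to_rotvec, normalize, rotvec_to_matrix
from .frames import PairFrame

STEP_COLUMNS = ["shift", "slide", "rise", "tilt", "roll", "twist"]
HELICAL_COLUMNS = ["xdisp", "incl", "h_rise", "h_twist"]

#: form-classification thresholds (hybrid-duplex inclination bound; the
#: stricter 15 deg single-stranded RNA variant is selectable)
XDISP_A_MAX = -3.0      # Å
INCL_A_MIN = 10.0       # degrees
INCL_A_MIN_STRICT = 15.0
H_RISE_A_MAX = 3.0      # Å
RISE_MIRROR_TOL = 0.3   # Å, |h_rise - rise| for B
C2_ENDO_MIN_FRACTION = 0.5

#: sugar conformers counted as the B-characteristic "C2'-endo family"
C2_ENDO_FAMILY = {"C2'-endo", "C3'-exo", "C1'-exo"}


@dataclass(frozen=True)
class StepParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])


@dataclass(frozen=True)
class HelAxisParams:
    xdisp: float
    incl: float
    h_rise: float
    h_twist: float


@dataclass(frozen=True)
class FormCall:
    label: str                      # "A" | "B" | "intermediate"
    means: dict


class DegenerateStepError(ValueError):
    pass


def step_parameters(f1: PairFrame, f2: PairFrame) -> StepParams:
    """Six rigid-body parameters of the step between two pair frames."""
    rel = f1.axes.T @ f2.axes
    r = matrix_to_rotvec(rel)
    angle = np.linalg.norm(r)
    if np.degrees(angle) >= 179.0:
        raise DegenerateStepError("anti-parallel pair frames")
    mid = f1.axes @ rotvec_to_matrix(0.5 * r)
    t = mid.T @ (f2.origin - f1.origin)
    tilt, roll, twist = np.degrees(r)
    return StepParams(shift=float(t[0]), slide=float(t[1]), rise=float(t[2]),
                      tilt=float(tilt), roll=float(roll), twist=float(twist))


def rebuild_from_steps(start: PairFrame,
                       steps: Sequence[StepParams]) -> List[PairFrame]:
    """Exact inverse of :func:`step_parameters`; returns all frames."""
    frames = [start]
    for k, s in enumerate(steps):
        if abs(s.twist) >= 180.0:
            raise ValueError("|twist| must be < 180 deg")
        r = np.deg2rad([s.tilt, s.roll, s.twist])
        prev = frames[-1]
        mid = prev.axes @ rotvec_to_matrix(0.5 * r)
        axes = prev.axes @ rotvec_to_matrix(r)
        origin = prev.origin + mid @ np.array([s.shift, s.slide, s.rise])
        frames.append(PairFrame(origin=origin, axes=axes,
                                residues=(("rebuilt", k + 1), ("rebuilt", -(k + 1)))))
    return frames


def helical_axis_parameters(f1: PairFrame, f2: PairFrame) -> HelAxisParams:
    """Screw-axis (helical) parameters of one step.

    The local helical axis is the screw axis of the rigid transform carrying
    frame 1 into frame 2.  Inclination is reported for the mid base-pair
    frame: the angle between its y axis and the plane normal to the helical
    axis, positive when the y axis climbs along the axis.  x-displacement is
    the position of the mid-frame origin relative to the axis, measured
    along the mid-frame x axis projected perpendicular to the axis.
    """
    rel = f1.axes.T @ f2.axes
    r = matrix_to_rotvec(rel)
    angle = np.linalg.norm(r)
    if angle < 1e-6:
        raise DegenerateStepError("zero-rotation step: helical axis undefined")
    mid = f1.axes @ rotvec_to_matrix(0.5 * r)

    # screw axis in lab coordinates (rotation axis is invariant under the
    # half rotation, so f1 and mid give the same lab axis)
    u = normalize(f1.axes @ r)
    if u @ mid[:, 2] < 0:       # orient along the stacking direction
        u = -u
        angle = -angle
    t = f2.origin - f1.origin
    h_rise = float(t @ u)
    h_twist = float(np.degrees(angle))

    # a point on the axis: solve (I - Rg) p = t_perp for p in the plane
    # normal to u, where Rg is the lab-frame rotation
    Rg = f1.axes @ rel @ f1.axes.T
    t_perp = t - h_rise * u
    A = np.eye(3) - Rg
    p = np.linalg.lstsq(A + np.outer(u, u), t_perp, rcond=None)[0]
    axis_point = f1.origin + p - (p @ u) * u

    om = 0.5 * (f1.origin + f2.origin)
    foot = axis_point + ((om - axis_point) @ u) * u
    xh = normalize(mid[:, 0] - (mid[:, 0] @ u) * u)
    xdisp = float((om - foot) @ xh)
    ym = mid[:, 1]
    yh = np.cross(u, xh)
    incl = float(np.degrees(np.arctan2(ym @ u, ym @ yh)))
    return HelAxisParams(xdisp=xdisp, incl=incl, h_rise=h_rise, h_twist=h_twist)


def steps_table(frames: Sequence[PairFrame]) -> pd.DataFrame:
    """All ten parameters for each consecutive step, one row per step."""
    rows = []
    for i in range(len(frames) - 1):
        s = step_parameters(frames[i], frames[i + 1])
        h = helical_axis_parameters(frames[i], frames[i + 1])
        rows.append({"step": i + 1, "shift": s.shift, "slide": s.slide,
                     "rise": s.rise, "tilt": s.tilt, "roll": s.roll,
                     "twist": s.twist, "xdisp": h.xdisp, "incl": h.incl,
                     "h_rise": h.h_rise, "h_twist": h.h_twist})
    return pd.DataFrame(rows)


def interior_steps(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the two terminal steps (fraying-prone outer base pairs)."""
    if len(table) <= 2:
        return table.iloc[0:0]
    return table.iloc[1:-1]


def classify_form(
    step_profile: pd.DataFrame,
    pucker_profile: Optional[Iterable[str]] = None,
    strict_incl: bool = False,
) -> FormCall:
    """A/B-form call from interior-step means and sugar-pucker populations.

    A requires mean xdisp < −3.0 Å, mean inclination > 10 deg (15 deg with
    ``strict_incl``) and mean h-rise < 3.0 Å.  B requires the h-rise/rise
    mirror property (|Δ| < 0.3 Å) plus a C2'-endo-family sugar fraction
    above 0.5.  Anything else — including values exactly on a boundary — is
    called intermediate.
    """
    if step_profile is None or len(step_profile) == 0:
        raise ValueError("empty step profile")
    means = {c: float(step_profile[c].mean())
             for c in STEP_COLUMNS + HELICAL_COLUMNS if c in step_profile}
    names = [n for n in pucker_profile] if pucker_profile is not None else []
    defined = [n for n in names if n]
    frac = (sum(n in C2_ENDO_FAMILY for n in defined) / len(defined)
            if defined else float("nan"))
    means["c2_endo_fraction"] = frac

    incl_min = INCL_A_MIN_STRICT if strict_incl else INCL_A_MIN
    is_a = (means["xdisp"] < XDISP_A_MAX
            and means["incl"] > incl_min
            and means["h_rise"] < H_RISE_A_MAX)
    is_b = (abs(means["h_rise"] - means["rise"]) < RISE_MIRROR_TOL
            and not np.isnan(frac) and frac > C2_ENDO_MIN_FRACTION)
    if is_a:
        label = "A"
    elif is_b:
        label = "B"
    else:
        label = "intermediate"
    return FormCall(label=label, means=means)
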