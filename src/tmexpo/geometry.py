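"""Observed rotational angle of a transmembrane helix.

The helix is viewed down its own principal axis from the N-terminal side
("top view").  In that view the geometric centers of the helix and of the
whole chain's TM region are projected into the plane; the lipid-facing
direction points from the molecule center outward through the helix center.
The rotational angle is measured from the first TM residue's Cα vector
(helix center → first Cα) to the lipid-facing vector, rotating in the sense
that appears clockwise to a viewer on the N-terminal side, and lies in
[0°, 360°).

Sign convention.  With an orthonormal in-plane basis (u, v) chosen so that
u × v equals the N→C axis, increasing atan2(v, u) is counterclockwise seen
from the C-terminal side and therefore clockwise seen from the N-terminal
side.  A right-handed α-helix then advances +100° per residue in this
positive sense, matching the helical-wheel spacing used by the exposure
moment — so observed and moment-predicted angles share one convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from tmexpo.structure_io import ResidueKey, TMHelix


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class TopViewFrame:
    """Axis (unit, N→C) plus an in-plane right-handed basis: u × v = axis."""

    axis: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray


@dataclass(frozen=True)
class RotationalAngle:
    helix_id: str
    angle: float  # degrees in [0, 360)
    defined_from: str  # "observed" | "predicted"
    first_residue: ResidueKey | None = None
    flags: tuple[str, ...] = ()


def principal_axis(ca_coords: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Best-fit direction through an ordered Cα set, oriented N→C.

    The Cα trace is first smoothed with a 4-residue window [1, a, a, 1],
    a = cos 30°/cos 50°, which exactly cancels the 100°-per-residue helical
    harmonic: for an ideal helix the smoothed points fall on the axis, so a
    plain line fit is unbiased even when the helix ends mid-turn.  The axis
    is the dominant right-singular vector of the smoothed, centered trace,
    with its sign fixed to point from the N-terminal half toward the
    C-terminal half.
    """
    pts = np.asarray(ca_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("principal_axis needs >= 3 Cα coordinates")
    if np.allclose(pts - pts.mean(axis=0), 0.0):
        raise GeometryError("degenerate coordinates: all points coincide")
    if pts.shape[0] >= 6:
        a = np.cos(np.deg2rad(30.0)) / np.cos(np.deg2rad(50.0))
        kernel = np.array([1.0, a, a, 1.0])
        kernel /= kernel.sum()
        smooth = np.column_stack(
            [np.convolve(pts[:, k], kernel, mode="valid") for k in range(3)]
        )
    else:
        smooth = pts
    centered = smooth - smooth.mean(axis=0)
    if np.allclose(centered, 0.0):
        centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    half = pts.shape[0] // 2
    n_to_c = pts[half:].mean(axis=0) - pts[:half].mean(axis=0)
    if np.dot(axis, n_to_c) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def build_frame(axis: np.ndarray) -> TopViewFrame:
    """Deterministic top-view frame for an N→C axis (u × v = axis)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # seed with the world axis least aligned with the helix axis
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(axis)))] = 1.0
    u = seed - np.dot(seed, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)  # then u × v = axis
    return TopViewFrame(axis=axis, basis_u=u, basis_v=v)


def topview_project(points: np.ndarray, frame: TopViewFrame) -> np.ndarray:
    """In-plane (u, v) coordinates of 3-D points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.column_stack((pts @ frame.basis_u, pts @ frame.basis_v))


def inplane_angle(vec2: np.ndarray) -> float:
    """Angle of an in-plane vector in the frame's positive (clockwise-from-N)
    sense, degrees in [0, 360)."""
    return float(np.degrees(np.arctan2(vec2[1], vec2[0])) % 360.0)


def lipid_facing_direction(helix_center: np.ndarray,
                           molecule_center: np.ndarray) -> np.ndarray:
    """Outward unit 2-vector from the molecule center through the helix."""
    d = np.asarray(helix_center, dtype=float) - np.asarray(molecule_center, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise GeometryError("helix center coincides with molecule center; "
                            "lipid-facing direction undefined")
    return d / norm


def observed_rotation(helix: TMHelix,
                      ca_by_residue: Mapping[ResidueKey, np.ndarray],
                      chain_tm_calphas: Mapping[ResidueKey, np.ndarray]) -> RotationalAngle:
    """Observed rotational angle of one helix.

    ``ca_by_residue`` maps this helix's residues to Cα coordinates;
    ``chain_tm_calphas`` holds the Cα of *all* annotated TM residues of the
    chain unit (atoms outside the membrane segments already removed), which
    define the molecule center.
    """
    flags: list[str] = []
    helix_cas = [(r.key, ca_by_residue[r.key]) for r in helix.residues
                 if r.key in ca_by_residue]
    if len(helix_cas) < 3:
        raise GeometryError(
            f"helix {helix.annotation.chain}:{helix.annotation.helix_index} "
            "has fewer than 3 Cα atoms"
        )
    first_key, first_ca = helix_cas[0]
    if helix.residues and helix.residues[0].key != first_key:
        flags.append("first_residue_fallback")

    coords = np.array([c for _, c in helix_cas])
    frame = build_frame(principal_axis(coords))

    helix_center = topview_project(coords, frame).mean(axis=0)
    mol_pts = np.array(list(chain_tm_calphas.values()))
    molecule_center = topview_project(mol_pts, frame).mean(axis=0)

    lipid = lipid_facing_direction(helix_center, molecule_center)
    first_vec = topview_project(first_ca, frame)[0] - helix_center
    if np.linalg.norm(first_vec) < 1e-9:
        raise GeometryError("first-residue Cα projects onto the helix center")

    angle = (inplane_angle(lipid) - inplane_angle(first_vec)) % 360.0
    if angle >= 360.0:  # float edge: x % 360 can round to 360 exactly
        angle = 0.0
    helix_id = f"{helix.annotation.chain}:{helix.annotation.helix_index}"
    return RotationalAngle(helix_id=helix_id, angle=angle,
                           defined_from="observed", first_residue=first_key,
                           flags=tuple(flags))


def observed_rotations(helices: Sequence[TMHelix],
                       tm_calphas: Mapping[ResidueKey, np.ndarray]) -> list[RotationalAngle]:
    """Observed angles for all helices of one chain unit, sharing the
    TM-only molecule center."""
    out = []
    for helix in helices:
        ca_local = {r.key: tm_calphas[r.key] for r in helix.residues
                    if r.key in tm_calphas}
        out.append(observed_rotation(helix, ca_local, tm_calphas))
    return out
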