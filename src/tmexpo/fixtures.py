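"""Synthetic structures and profiles with planted ground truth.

Every stage of the pipeline can be exercised without downloading real
structures: ideal α-helices (canonical Cα geometry: 1.5 Å rise, 100° twist,
2.3 Å radius) assembled into bundles whose rotational angles are known by
construction; periodic exposure profiles with a planted phase; and
chain-grouped training sets whose rASA targets are a smooth function of a
planted helical wheel.

The ideal helix is right-handed and its residues advance +100° per residue
in the top-view frame's positive sense, so the construction, the observed-
angle geometry and the exposure moment all share one angular convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tmexpo import features as ft
from tmexpo.structure_io import (
    Atom,
    StructureModel,
    THREE_TO_ONE,
    TMHelix,
    TMHelixAnnotation,
    extract_helices,
    vdw_radius,
)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

RISE_PER_RESIDUE = 1.5  # Å
TWIST_PER_RESIDUE = 100.0  # degrees
CA_RADIUS = 2.3  # Å


@dataclass(frozen=True)
class HelixSpec:
    n_residues: int
    rise: float = RISE_PER_RESIDUE
    twist: float = TWIST_PER_RESIDUE
    ca_radius: float = CA_RADIUS
    position: tuple[float, float] = (0.0, 0.0)  # in-plane (x, y), Å
    offset: float = 0.0  # axial rotation of residue 1, degrees
    sequence: str | None = None  # default poly-Ala

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("a helix needs at least 3 residues")
        seq = self.seq
        if len(seq) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        if any(aa not in ONE_TO_THREE for aa in seq):
            raise ValueError("sequence must use standard one-letter codes")

    @property
    def seq(self) -> str:
        return self.sequence or "A" * self.n_residues


@dataclass(frozen=True)
class PlantedProfile:
    n: int
    phase: float  # degrees
    baseline: float = 0.5
    amplitude: float = 0.4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("profile needs at least one residue")
        if not (0.0 <= self.baseline - self.amplitude
                and self.baseline + self.amplitude <= 1.0):
            raise ValueError("baseline ± amplitude must stay in [0, 1]")


def _wheel_angles(spec: HelixSpec) -> np.ndarray:
    return np.deg2rad(spec.offset + spec.twist * np.arange(spec.n_residues))


def ideal_helix_calphas(spec: HelixSpec) -> np.ndarray:
    """Cα coordinates of the ideal helix, axis along +z, N-terminus at z=0."""
    a = _wheel_angles(spec)
    x = spec.position[0] + spec.ca_radius * np.cos(a)
    y = spec.position[1] + spec.ca_radius * np.sin(a)
    z = spec.rise * np.arange(spec.n_residues, dtype=float)
    return np.column_stack((x, y, z))


# local-frame heavy-atom offsets (radial, tangential, axial), Å; approximate
# α-helix backbone geometry — adequate for parsing/SASA/geometry fixtures.
_BACKBONE_OFFSETS = {
    "N": (-0.25, -0.75, -1.15),
    "C": (-0.25, 0.85, 1.05),
    "O": (-1.05, 0.95, 1.55),
    "CB": (1.35, -0.55, -0.35),
}


def ideal_helix_atoms(spec: HelixSpec, chain: str = "A",
                      start_resnum: int = 1) -> list[Atom]:
    """Heavy atoms (N, CA, C, O, and CB except Gly) of the ideal helix."""
    cas = ideal_helix_calphas(spec)
    angles = _wheel_angles(spec)
    atoms: list[Atom] = []
    for i, (ca, ang) in enumerate(zip(cas, angles)):
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        tang = np.array([-np.sin(ang), np.cos(ang), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        resname = ONE_TO_THREE[spec.seq[i]]
        key = (chain, start_resnum + i, "")

        def mk(name: str, pos: np.ndarray, element: str) -> Atom:
            return Atom(name=name, element=element, coord=pos,
                        vdw_radius=vdw_radius(element, name),
                        residue_key=key, residue_name=resname)

        atoms.append(mk("N", ca + _off("N", radial, tang, axial), "N"))
        atoms.append(mk("CA", ca, "C"))
        atoms.append(mk("C", ca + _off("C", radial, tang, axial), "C"))
        atoms.append(mk("O", ca + _off("O", radial, tang, axial), "O"))
        if resname != "GLY":
            atoms.append(mk("CB", ca + _off("CB", radial, tang, axial), "C"))
    return atoms


def _off(name: str, radial, tang, axial) -> np.ndarray:
    r, t, z = _BACKBONE_OFFSETS[name]
    return r * radial + t * tang + z * axial


def ideal_helix(spec: HelixSpec, chain: str = "A",
                start_resnum: int = 1) -> StructureModel:
    return StructureModel(
        atoms=ideal_helix_atoms(spec, chain, start_resnum),
        chains={chain},
        provenance={"fixture": "ideal_helix", "n": spec.n_residues},
    )


def _ring_mean(spec: HelixSpec) -> np.ndarray:
    a = _wheel_angles(spec)
    return spec.ca_radius * np.array([np.cos(a).mean(), np.sin(a).mean()])


def helix_bundle(specs: Sequence[HelixSpec], chain: str = "A",
                 resnum_stride: int = 100
                 ) -> tuple[StructureModel, list[TMHelixAnnotation], list[float]]:
    """Bundle of parallel ideal helices in one chain.

    Returns the structure, its TM annotations and the analytic ground-truth
    rotational angle of each helix (first-residue wheel position versus the
    outward direction from the bundle's Cα center, both exact from the
    construction — no axis fitting involved).
    """
    if len(specs) < 2:
        raise ValueError("a bundle needs at least 2 helices")
    positions = [tuple(np.round(s.position, 9)) for s in specs]
    if len(set(positions)) != len(positions):
        raise ValueError("helix in-plane positions must be distinct")

    atoms: list[Atom] = []
    annotations: list[TMHelixAnnotation] = []
    for j, spec in enumerate(specs):
        start = 1 + j * resnum_stride
        atoms.extend(ideal_helix_atoms(spec, chain, start))
        annotations.append(
            TMHelixAnnotation(chain=chain, helix_index=j + 1, start=start,
                              end=start + spec.n_residues - 1)
        )
    structure = StructureModel(atoms=atoms, chains={chain},
                               provenance={"fixture": "helix_bundle"})

    # analytic truth: all axes are +z, so the world xy-plane is every
    # helix's top view (with u x v = +z, matching geometry.build_frame)
    centers = [np.asarray(s.position) + _ring_mean(s) for s in specs]
    weights = np.array([s.n_residues for s in specs], dtype=float)
    molecule_center = np.average(centers, axis=0, weights=weights)
    truths: list[float] = []
    for spec, center in zip(specs, centers):
        lipid = center - molecule_center
        if np.linalg.norm(lipid) < 1e-9:
            raise ValueError("helix center coincides with bundle center")
        first = (np.asarray(spec.position)
                 + spec.ca_radius * np.array([np.cos(np.deg2rad(spec.offset)),
                                              np.sin(np.deg2rad(spec.offset))])
                 - center)
        ang = (np.degrees(np.arctan2(lipid[1], lipid[0]))
               - np.degrees(np.arctan2(first[1], first[0]))) % 360.0
        truths.append(float(ang) if ang < 360.0 else 0.0)
    return structure, annotations, truths


def periodic_rasa(profile: PlantedProfile) -> np.ndarray:
    """Exposure profile ``baseline + amplitude*cos((i-1)*100° - phase)``
    plus optional clamped Gaussian noise.  For n a multiple of 18 the
    noiseless moment direction equals the planted phase exactly."""
    i = np.arange(profile.n, dtype=float)
    theta = np.deg2rad(i * TWIST_PER_RESIDUE - profile.phase)
    scores = profile.baseline + profile.amplitude * np.cos(theta)
    if profile.noise_sigma > 0:
        rng = np.random.default_rng(profile.seed)
        scores = scores + rng.normal(0.0, profile.noise_sigma, profile.n)
        if np.any(scores < 0) or np.any(scores > 1):
            import logging

            logging.getLogger(__name__).warning(
                "noisy profile clamped to [0, 1]"
            )
        scores = np.clip(scores, 0.0, 1.0)
    return scores


def bundle_helices(structure: StructureModel,
                   annotations: Sequence[TMHelixAnnotation]) -> list[TMHelix]:
    """Convenience: extract TMHelix records from a fixture bundle."""
    return extract_helices(structure, annotations)


def synth_training_set(n_chains: int = 5, residues_per_chain: int = 36,
                       noise_sigma: float = 0.0, seed: int = 0,
                       amplitude: float = 0.4, baseline: float = 0.4):
    """Chain-grouped dataset whose rASA targets follow a planted helical
    wheel and whose feature windows carry the same signal through a
    synthetic PSSM, so that regression models can recover it.

    Returns a ``DatasetSplit`` (deterministic for a fixed seed).
    """
    from tmexpo.svm_models import DatasetSplit

    if n_chains < 2:
        raise ValueError("need at least 2 chains for chain-wise splits")
    if residues_per_chain < ft.WINDOW_LENGTH:
        raise ValueError("chains must be at least one window long")
    rng = np.random.default_rng(seed)
    vectors, labels, targets, groups = [], [], [], []
    for c in range(n_chains):
        phase = float(rng.uniform(0.0, 360.0))
        profile = PlantedProfile(n=residues_per_chain, phase=phase,
                                 baseline=baseline, amplitude=amplitude,
                                 noise_sigma=noise_sigma,
                                 seed=int(rng.integers(2 ** 31)))
        rasa = periodic_rasa(profile)
        # synthetic PSSM: column values encode the target smoothly
        pssm = np.zeros((residues_per_chain, 20))
        pssm[:, 0] = 4.0 * (rasa - 0.5)  # strong signal channel
        pssm[:, 1] = 2.0 * (0.5 - rasa)
        seq = "A" * residues_per_chain
        ctx = ft.ChainContext(sequence=seq, pssm=pssm)
        vecs = ft.encode_chain(ctx)
        vectors.append(vecs)
        targets.extend(rasa.tolist())
        labels.extend(DatasetSplit.labels_from_targets(rasa))
        groups.extend([f"chain{c}"] * residues_per_chain)
    return DatasetSplit(vectors=np.vstack(vectors), labels=labels,
                        targets=np.array(targets), groups=groups)


# ---------------------------------------------------------------------------
# extended Gly-X-Gly reference peptides

def extended_tripeptide(residue_name: str) -> StructureModel:
    """Extended (φ=ψ≈180°) Gly-X-Gly tripeptide with ideal all-atom side
    chains from the chemical component dictionary; hydrogens stripped.

    Used to compute the bundled reference ASA table: the central residue's
    area in this conformation is its maximum-exposure reference.
    """
    from biotite.structure.info import residue as ccd_residue

    names = ["GLY", residue_name, "GLY"]
    atoms: list[Atom] = []
    spacing = 3.63  # Cα–Cα distance in an extended chain, Å
    for idx, resname in enumerate(names):
        tmpl = ccd_residue(resname)
        heavy = (tmpl.element != "H")
        coords = tmpl.coord[heavy]
        labels = [str(n) for n in tmpl.atom_name[heavy]]
        if "OXT" in labels:
            keep = [i for i, n in enumerate(labels) if n != "OXT"]
            coords = coords[keep]
            labels = [labels[i] for i in keep]
        elements = [str(e) for e in tmpl.element[heavy]]
        elements = [e for e, n in zip(elements, [str(n) for n in tmpl.atom_name[heavy]])
                    if n != "OXT"]
        # place the residue in an extended-chain frame: N->C along +x,
        # alternating side-chain direction to avoid clashes
        n_i = labels.index("N")
        ca_i = labels.index("CA")
        c_i = labels.index("C")
        x_axis = coords[c_i] - coords[n_i]
        x_axis = x_axis / np.linalg.norm(x_axis)
        cb_dir = coords[ca_i] - (coords[n_i] + coords[c_i]) / 2.0
        cb_dir = cb_dir - np.dot(cb_dir, x_axis) * x_axis
        nrm = np.linalg.norm(cb_dir)
        y_axis = cb_dir / nrm if nrm > 1e-6 else _any_perp(x_axis)
        if idx % 2 == 1:
            y_axis = -y_axis
        z_axis = np.cross(x_axis, y_axis)
        rot = np.vstack((x_axis, y_axis, z_axis))  # world->local rows
        local = (coords - coords[ca_i]) @ rot.T
        placed = local + np.array([idx * spacing, 0.0, 0.0])
        for name, el, pos in zip(labels, elements, placed):
            atoms.append(
                Atom(name=name, element=el, coord=np.asarray(pos, dtype=float),
                     vdw_radius=vdw_radius(el, name),
                     residue_key=("A", idx + 1, ""), residue_name=resname)
            )
    return StructureModel(atoms=atoms, chains={"A"},
                          provenance={"fixture": "extended_tripeptide",
                                      "residue": residue_name})


def _any_perp(v: np.ndarray) -> np.ndarray:
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(v)))] = 1.0
    p = seed - np.dot(seed, v) * v
    return p / np.linalg.norm(p)


def compute_gxg_reference(probe_radius: float = 2.0,
                          n_points: int = 960) -> dict[str, float]:
    """Reference ASA of each residue type X in extended Gly-X-Gly, Å²."""
    from tmexpo.sasa import compute_asa

    table: dict[str, float] = {}
    for one, three in sorted(ONE_TO_THREE.items()):
        st = extended_tripeptide(three)
        asa = compute_asa(st, probe_radius=probe_radius, n_points=n_points)
        table[three] = asa.per_residue[("A", 2, "")]
    return table
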