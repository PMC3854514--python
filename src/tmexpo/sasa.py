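"""Accessible surface area by a rolling spherical probe.

Dot-sphere (Shrake–Rupley-style) sampling: each atom's sphere of radius
``vdw + probe`` is covered with a deterministic Fibonacci-spiral point set;
points not buried inside any neighbour's expanded sphere are accessible,
and the atom's area is the accessible fraction of its sphere area.  The
default probe of 2.0 Å mimics the -CH2 group of a lipid hydrocarbon chain
(rather than the 1.4 Å water probe), which is the appropriate environment
for transmembrane residues.

Relative ASA (rASA) divides a residue's area by its reference area in an
extended Gly-X-Gly tripeptide; residues with rASA below 5 % are classified
as buried (B), otherwise exposed (E).
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from tmexpo.structure_io import ResidueKey, StructureModel, TMHelix

DEFAULT_PROBE_RADIUS = 2.0  # Å, -CH2 mimic
DEFAULT_N_POINTS = 960
BURIAL_THRESHOLD = 0.05
INTERFACE_TOLERANCE = 1e-3


@dataclass
class AsaResult:
    per_atom: dict[int, float]  # atom index in structure -> Å²
    per_residue: dict[ResidueKey, float]
    probe_radius: float
    n_points: int


@dataclass
class RasaProfile:
    """Per-residue rASA values and burial labels for one helix."""

    helix: TMHelix
    rasa: np.ndarray  # fractions, same order as helix.residues
    labels: list[str] = field(default_factory=list)  # 'B' / 'E'
    excluded_mask: np.ndarray | None = None

    def __post_init__(self):
        self.rasa = np.asarray(self.rasa, dtype=float)
        if self.rasa.size != self.helix.n_residues:
            raise ValueError("rasa length must equal helix length")
        if not self.labels:
            self.labels = [classify_burial(v) for v in self.rasa]
        if self.excluded_mask is None:
            self.excluded_mask = np.zeros(self.rasa.size, dtype=bool)


@functools.lru_cache(maxsize=4)
def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral covering of the unit sphere."""
    if n < 10:
        raise ValueError("n_points must be at least 10")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_asa(structure: StructureModel,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_N_POINTS) -> AsaResult:
    """Per-atom and per-residue accessible surface area, Å²."""
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 10:
        raise ValueError("n_points must be at least 10 for a usable estimate")
    atoms = structure.atoms
    if not atoms:
        raise ValueError("empty structure")

    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    sphere = unit_sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    per_atom: dict[int, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i, atom in enumerate(atoms):
        r = radii[i]
        pts = coords[i] + r * sphere
        # candidate occluders: spheres that can reach this atom's surface
        nbrs = [j for j in tree.query_ball_point(coords[i], r + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * r * r * accessible.sum() / n_points
        per_atom[i] = float(area)
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + float(area)
    return AsaResult(per_atom=per_atom, per_residue=per_residue,
                     probe_radius=probe_radius, n_points=n_points)


@functools.lru_cache(maxsize=4)
def load_reference_table(name: str = "gxg_reference_probe2.0.tsv") -> dict[str, float]:
    """Extended Gly-X-Gly reference areas (Å²) bundled with the package.

    The default table was computed with this package's own sampler on
    extended Gly-X-Gly tripeptides built from ideal residue geometries, at
    the default 2.0 Å probe (see docs/methods.md).
    """
    table: dict[str, float] = {}
    with resources.files("tmexpo.data").joinpath(name).open() as fh:
        rows = (ln for ln in fh if not ln.startswith("#"))
        for row in csv.DictReader(rows, delimiter="\t"):
            table[row["residue"]] = float(row["reference_asa"])
    if len(table) < 20 or min(table.values()) <= 0:
        raise ValueError(f"reference table {name} incomplete or non-positive")
    return table


def relative_asa(asa: float, residue_name: str,
                 reference: Mapping[str, float] | None = None,
                 clamp: bool = False) -> float:
    """ASA divided by the residue's extended Gly-X-Gly reference area.

    Values can exceed 1 for distorted conformations; set ``clamp=True`` where
    a downstream profile requires [0, 1].
    """
    reference = reference if reference is not None else load_reference_table()
    if residue_name not in reference:
        raise KeyError(f"no reference ASA for residue {residue_name!r}")
    r = asa / reference[residue_name]
    return float(min(max(r, 0.0), 1.0)) if clamp else float(r)


def classify_burial(rasa: float, threshold: float = BURIAL_THRESHOLD) -> str:
    """'B' (buried) iff rASA < threshold, else 'E' (exposed); the 5 % rule
    is strict, so rASA exactly at the threshold is exposed."""
    if rasa < 0:
        raise ValueError("rasa must be >= 0")
    return "B" if rasa < threshold else "E"


def interface_exclusion(rasa_subunit: Mapping[ResidueKey, float],
                        rasa_complex: Mapping[ResidueKey, float],
                        missing_atoms: set[ResidueKey] | None = None,
                        tolerance: float = INTERFACE_TOLERANCE) -> dict[ResidueKey, bool]:
    """Mask residues whose rASA changes between the single subunit and the
    full complex (inter-chain interface residues), plus residues with
    missing atoms.  Such residues are excluded from training/evaluation:
    their true exposure is ambiguous from a single-chain sequence."""
    if set(rasa_subunit) != set(rasa_complex):
        raise ValueError("subunit and complex profiles cover different residues")
    missing_atoms = missing_atoms or set()
    return {
        key: (abs(rasa_subunit[key] - rasa_complex[key]) > tolerance
              or key in missing_atoms)
        for key in rasa_subunit
    }


def helix_rasa_profiles(structure: StructureModel, helices: Sequence[TMHelix],
                        probe_radius: float = DEFAULT_PROBE_RADIUS,
                        n_points: int = DEFAULT_N_POINTS,
                        reference: Mapping[str, float] | None = None,
                        clamp: bool = True) -> list[RasaProfile]:
    """rASA profiles of annotated helices from one ASA computation over the
    whole structure.  Residues missing from the coordinates get rASA 0 and
    an exclusion flag."""
    asa = compute_asa(structure, probe_radius=probe_radius, n_points=n_points)
    reference = reference if reference is not None else load_reference_table()
    profiles = []
    for helix in helices:
        vals = np.zeros(helix.n_residues)
        excl = np.zeros(helix.n_residues, dtype=bool)
        for i, res in enumerate(helix.residues):
            if res.missing or res.key not in asa.per_residue:
                excl[i] = True
                continue
            if not res.complete:
                excl[i] = True
            if res.name in reference:
                vals[i] = relative_asa(asa.per_residue[res.key], res.name,
                                       reference, clamp=clamp)
        profiles.append(RasaProfile(helix=helix, rasa=vals, excluded_mask=excl))
    return profiles


def write_residue_tsv(path: str | Path, structure: StructureModel,
                      asa: AsaResult, reference: Mapping[str, float] | None = None,
                      excluded: Mapping[ResidueKey, bool] | None = None) -> None:
    """Per-residue TSV: chain, resnum, icode, resname, ASA, rASA, label, excluded."""
    reference = reference if reference is not None else load_reference_table()
    excluded = excluded or {}
    residues = structure.residues()
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tresname\tasa\trasa\tlabel\texcluded\n")
        for key in sorted(residues, key=lambda k: (k[0], k[1], k[2])):
            name = residues[key][0].residue_name
            area = asa.per_residue.get(key, 0.0)
            if name in reference:
                r = relative_asa(area, name, reference)
                label = classify_burial(min(r, 1.0))
                r_str = f"{r:.4f}"
            else:
                r_str, label = "NA", "NA"
            fh.write(
                f"{key[0]}\t{key[1]}\t{key[2]}\t{name}\t{area:.2f}\t{r_str}\t"
                f"{label}\t{int(bool(excluded.get(key, False)))}\n"
            )
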