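"""Coordinate input and transmembrane-segment assembly.

Reads PDB-format files (via gemmi), assigns van der Waals radii from a
bundled table, resolves alternate locations to the highest-occupancy
conformer, and cuts annotated transmembrane segments out of each chain with
per-residue completeness flags.  Hydrogens are ignored and HETATM records
are excluded from protein residues (X-ray membrane-protein structures
rarely model hydrogens; the radii convention follows NACCESS).
"""

from __future__ import annotations

import json
import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


class StructureFormatError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    vdw_radius: float  # Å
    residue_key: ResidueKey
    residue_name: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.coord)):
            raise StructureFormatError(f"non-finite coordinate for atom {self.name}")
        if self.vdw_radius <= 0:
            raise StructureFormatError(f"non-positive VDW radius for atom {self.name}")


@dataclass
class StructureModel:
    atoms: list[Atom]
    chains: set[str]
    provenance: dict = field(default_factory=dict)

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.residue_key[0] == chain]

    def subset(self, chains: Iterable[str]) -> "StructureModel":
        keep = set(chains)
        missing = keep - self.chains
        if missing:
            raise KeyError(f"chains not in structure: {sorted(missing)}")
        atoms = [a for a in self.atoms if a.residue_key[0] in keep]
        return StructureModel(atoms=atoms, chains=keep,
                              provenance=dict(self.provenance, subset=sorted(keep)))

    def residues(self) -> dict[ResidueKey, list[Atom]]:
        out: dict[ResidueKey, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out


@dataclass(frozen=True)
class TMHelixAnnotation:
    chain: str
    helix_index: int  # 1-based from the N-terminus
    start: int
    end: int  # inclusive residue numbers, coordinate-file numbering

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationError(
                f"chain {self.chain} helix {self.helix_index}: start > end"
            )


@dataclass(frozen=True)
class HelixResidue:
    name: str  # 3-letter code
    key: ResidueKey
    has_ca: bool
    complete: bool  # all expected heavy atoms present
    missing: bool = False  # residue absent from the coordinate file


@dataclass
class TMHelix:
    annotation: TMHelixAnnotation
    residues: list[HelixResidue]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@functools.lru_cache(maxsize=1)
def load_vdw_radii() -> dict:
    with resources.files("tmexpo.data").joinpath("vdw_radii.json").open() as fh:
        return json.load(fh)


def vdw_radius(element: str, atom_name: str, table: dict | None = None) -> float:
    table = table or load_vdw_radii()
    el = element.upper().strip()
    if atom_name in table.get("atom_names", {}):
        return float(table["atom_names"][atom_name])
    if el in table["elements"]:
        return float(table["elements"][el])
    raise StructureFormatError(
        f"no VDW radius for atom {atom_name!r} (element {element!r})"
    )


@functools.lru_cache(maxsize=64)
def expected_heavy_atoms(residue_name: str) -> frozenset[str]:
    """Heavy atoms expected for a standard residue (CCD ideal geometry,
    terminal OXT excluded)."""
    from biotite.structure.info import residue as ccd_residue

    try:
        tmpl = ccd_residue(residue_name)
    except Exception:
        return frozenset()
    names = {
        str(n)
        for n, el in zip(tmpl.atom_name, tmpl.element)
        if str(el).upper() != "H" and str(n) != "OXT"
    }
    return frozenset(names)


def read_structure(path: str | Path, model: int | None = None,
                   radii_table: dict | None = None) -> StructureModel:
    """Load ATOM records of one model from a PDB-format file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order); hydrogens and HETATM records are skipped.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # gemmi raises RuntimeError on parse failures
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    st.setup_entities()
    model_idx = 0 if model is None else model - 1
    if not 0 <= model_idx < len(st):
        raise StructureFormatError(f"{path}: model {model} not present")
    mdl = st[model_idx]

    atoms: list[Atom] = []
    chains: set[str] = set()
    for chain in mdl:
        for res in chain:
            if res.het_flag != "A":  # HETATM excluded from protein residues
                continue
            key: ResidueKey = (
                chain.name,
                res.seqid.num,
                (res.seqid.icode or " ").strip(),
            )
            # resolve altlocs: group by atom name, keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.is_hydrogen:  # gemmi >= 0.7: property
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                el = at.element.name
                atoms.append(
                    Atom(
                        name=at.name,
                        element=el,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=vdw_radius(el, at.name, radii_table),
                        residue_key=key,
                        residue_name=res.name,
                    )
                )
            chains.add(chain.name)
    if not atoms:
        raise StructureFormatError(f"{path}: no ATOM records in selected model")
    return StructureModel(
        atoms=atoms,
        chains=chains,
        provenance={"path": str(path), "model": model_idx + 1},
    )


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal fixed-width PDB file (ATOM records only)."""
    lines = []
    serial = 0
    for a in structure.atoms:
        serial += 1
        chain, resnum, icode = a.residue_key
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4.4s} {a.residue_name:<3s} {chain[:1]}"
            f"{resnum:4d}{(icode or ' '):1s}   "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tm_annotations(path: str | Path) -> list[TMHelixAnnotation]:
    """Read TM-segment annotations from a TSV (chain, helix_index, start, end).

    Lines starting with '#' are comments; a header line with those column
    names is accepted.  Helices of one chain must be sorted and
    non-overlapping.
    """
    anns: list[TMHelixAnnotation] = []
    for ln_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fields[0] == "chain":  # header
            continue
        if len(fields) < 4:
            raise AnnotationError(f"{path}:{ln_no}: expected 4 columns, got {len(fields)}")
        try:
            ann = TMHelixAnnotation(
                chain=fields[0],
                helix_index=int(fields[1]),
                start=int(fields[2]),
                end=int(fields[3]),
            )
        except ValueError as exc:
            raise AnnotationError(f"{path}:{ln_no}: {exc}") from exc
        anns.append(ann)
    validate_annotations(anns)
    return anns


def validate_annotations(anns: Sequence[TMHelixAnnotation]) -> None:
    by_chain: dict[str, list[TMHelixAnnotation]] = {}
    for a in anns:
        by_chain.setdefault(a.chain, []).append(a)
    for chain, items in by_chain.items():
        items_sorted = sorted(items, key=lambda a: a.start)
        if [a.helix_index for a in items_sorted] != sorted(a.helix_index for a in items):
            raise AnnotationError(f"chain {chain}: helix indices not ordered with position")
        for prev, cur in zip(items_sorted, items_sorted[1:]):
            if cur.start <= prev.end:
                raise AnnotationError(
                    f"chain {chain}: helices {prev.helix_index} and "
                    f"{cur.helix_index} overlap ({prev.start}-{prev.end} vs "
                    f"{cur.start}-{cur.end})"
                )


def extract_helices(structure: StructureModel,
                    annotations: Sequence[TMHelixAnnotation]) -> list[TMHelix]:
    """Cut annotated TM segments from the structure, flagging residues that
    are missing entirely or missing heavy atoms (these are excluded from
    training data downstream, never silently dropped)."""
    validate_annotations(annotations)
    residues = structure.residues()
    by_chain: dict[str, dict[int, tuple[ResidueKey, list[Atom]]]] = {}
    for key, atoms in residues.items():
        by_chain.setdefault(key[0], {})[key[1]] = (key, atoms)

    helices: list[TMHelix] = []
    for ann in annotations:
        if ann.chain not in structure.chains:
            raise AnnotationError(f"annotation chain {ann.chain!r} not in structure")
        chain_res = by_chain.get(ann.chain, {})
        recs: list[HelixResidue] = []
        for num in range(ann.start, ann.end + 1):
            if num not in chain_res:
                recs.append(
                    HelixResidue(
                        name="UNK", key=(ann.chain, num, ""), has_ca=False,
                        complete=False, missing=True,
                    )
                )
                continue
            key, atoms = chain_res[num]
            names = {a.name for a in atoms}
            expected = expected_heavy_atoms(atoms[0].residue_name)
            complete = bool(expected) and expected <= names
            recs.append(
                HelixResidue(
                    name=atoms[0].residue_name, key=key,
                    has_ca="CA" in names, complete=complete,
                )
            )
        helices.append(TMHelix(annotation=ann, residues=recs))
    return helices


def tm_calpha_coords(structure: StructureModel,
                     helices: Sequence[TMHelix]) -> dict[ResidueKey, np.ndarray]:
    """Cα coordinates of all annotated TM residues (atoms outside the
    annotated membrane segments are ignored)."""
    wanted = {r.key for h in helices for r in h.residues if r.has_ca}
    out: dict[ResidueKey, np.ndarray] = {}
    for a in structure.atoms:
        if a.name == "CA" and a.residue_key in wanted:
            out[a.residue_key] = a.coord
    return out
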