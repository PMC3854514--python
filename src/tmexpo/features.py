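"""Fixed-layout feature vectors over a 17-residue sliding window.

Each transmembrane residue is encoded from the 17-mer centered on it.
Three feature groups are used: (i) contact-related biochemical properties
(volume, polarity, charge class, interhelical contact propensity), (ii)
evolutionary information (a 20-column PSSM profile plus a per-column
conservation score), and (iii) structure-related scales (membrane-insertion
free energy, amphiphilicity, turn propensity).  Every feature is mapped to
[0, 1]: bounded properties are divided by their table maximum (volume by
237.2 of Tyr, contact propensity by 1.43 of Cys, turn propensity by 2.7 of
Pro), unbounded ones pass through a sigmoid, and charge is the discrete
{1, 0.5, 0} code for positive/neutral/negative residues.

Window positions that fall off the chain are padded with 0.5, except the
charge, contact-propensity and volume slots, which are padded with 0.

The per-position layout is

    [PSSM x 20, conservation, volume, polarity, charge, contact,
     energy, amphiphilicity, turn]

giving 28 values per position and 17 x 28 = 476 per window.  The layout is
versioned (``SCHEMA_VERSION``); models refuse vectors from another schema.
"""

from __future__ import annotations

import json
import functools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "tmexpo-features-1"
WINDOW_LENGTH = 17
N_PER_POSITION = 28
VECTOR_DIM = WINDOW_LENGTH * N_PER_POSITION

#: PSI-BLAST ASCII matrix column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: BLOSUM62-style background amino-acid frequencies (conservation default).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_PAD = {"pssm": 0.5, "conservation": 0.5, "volume": 0.0, "polarity": 0.5,
        "charge": 0.0, "contact": 0.0, "energy": 0.5,
        "amphiphilicity": 0.5, "turn": 0.5}

POSITION_FIELDS = (
    [f"pssm_{aa}" for aa in PSSM_ALPHABET]
    + ["conservation", "volume", "polarity", "charge", "contact",
       "energy", "amphiphilicity", "turn"]
)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyTables:
    volume: dict[str, float]
    polarity: dict[str, float]
    charge: dict[str, float]
    contact: dict[str, float]
    energy: dict[str, float]
    amphiphilicity: dict[str, float]
    turn: dict[str, float]
    version: int = 1


@functools.lru_cache(maxsize=1)
def load_property_tables() -> PropertyTables:
    """Bundled property tables; the printed normalization anchors are
    verified on every load."""
    with resources.files("tmexpo.data").joinpath("property_tables.json").open() as fh:
        raw = json.load(fh)
    tables = PropertyTables(
        volume=raw["volume"], polarity=raw["polarity"], charge=raw["charge"],
        contact=raw["contact"], energy=raw["energy"],
        amphiphilicity=raw["amphiphilicity"], turn=raw["turn"],
        version=raw["version"],
    )
    for name, table, res, anchor in (
        ("volume", tables.volume, "Y", 237.2),
        ("contact", tables.contact, "C", 1.43),
        ("turn", tables.turn, "P", 2.7),
    ):
        if not math.isclose(table[res], anchor) or max(table.values()) != table[res]:
            raise ValueError(f"{name} table anchor violated: expected max "
                             f"{anchor} at {res}")
    for name in ("volume", "polarity", "charge", "contact", "energy",
                 "amphiphilicity", "turn"):
        if set(getattr(tables, name)) < set(PSSM_ALPHABET):
            raise ValueError(f"{name} table does not cover all 20 residues")
    return tables


def sigmoid_encode(value: float, sign_convention: str = "minus") -> float:
    """``1 - 1/(1 + exp(-v))`` ("minus", used for PSSM/polarity/energy) or
    ``1 - 1/(1 + exp(+v))`` ("plus", used for amphiphilicity)."""
    v = float(value)
    if not math.isfinite(v):
        raise ValueError("value must be finite")
    if sign_convention == "minus":
        return 1.0 - 1.0 / (1.0 + math.exp(-v))
    if sign_convention == "plus":
        return 1.0 - 1.0 / (1.0 + math.exp(v))
    raise ValueError(f"unknown sign convention {sign_convention!r}")


def linear_encode(value: float, anchor: float) -> float:
    if anchor <= 0:
        raise ValueError("anchor must be positive")
    x = float(value) / float(anchor)
    if x < 0.0 or x > 1.0:
        logger.warning("linear feature %.4g outside [0,1]; clamped", x)
        x = min(max(x, 0.0), 1.0)
    return x


def charge_encode(residue: str, charge_table: dict[str, float] | None = None) -> float:
    table = charge_table if charge_table is not None else load_property_tables().charge
    if residue not in table:
        logger.warning("nonstandard residue %r: charge treated as neutral", residue)
        return 0.5
    return float(table[residue])


# ---------------------------------------------------------------------------
# evolutionary inputs

def read_pssm(path: str | Path) -> tuple[str, np.ndarray]:
    """Parse a PSI-BLAST ASCII PSSM; returns (sequence, n x 20 scores in
    A R N D C Q E G H I L K M F P S T W Y V order)."""
    seq: list[str] = []
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
            seq.append(parts[1])
            rows.append([float(x) for x in parts[2:22]])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return "".join(seq), np.array(rows, dtype=float)


def write_pssm(path: str | Path, sequence: str, matrix: np.ndarray) -> None:
    """Write a minimal PSI-BLAST-style ASCII PSSM (round-trips read_pssm)."""
    m = np.asarray(matrix)
    if m.shape != (len(sequence), 20):
        raise ValueError("matrix must be len(sequence) x 20")
    lines = ["", "Last position-specific scoring matrix computed",
             "           " + "  ".join(PSSM_ALPHABET)]
    for i, (aa, row) in enumerate(zip(sequence, m), start=1):
        vals = " ".join(f"{int(round(v)):3d}" for v in row)
        lines.append(f"{i:5d} {aa} {vals} " + " ".join(["0.0"] * 2))
    Path(path).write_text("\n".join(lines) + "\n")


def read_msa(path: str | Path) -> list[str]:
    """Aligned sequences from a FASTA multiple sequence alignment."""
    aln = AlignIO.read(str(path), "fasta")
    return [str(rec.seq).upper() for rec in aln]


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Jensen–Shannon divergence (base-2 logs, bounded by 1 at lam=0.5)."""
    r = lam * p + (1.0 - lam) * q
    return float(_entropy(r) - lam * _entropy(p) - (1.0 - lam) * _entropy(q))


def conservation_scores(msa: Sequence[str],
                        positions: Sequence[int] | None = None,
                        background: dict[str, float] | None = None) -> np.ndarray:
    """Per-column conservation as the raw Jensen–Shannon divergence between
    the column's residue distribution and a background distribution, scaled
    by the column's non-gap fraction; in [0, 1].  All-gap columns score 0.
    """
    if not msa:
        raise ValueError("empty MSA")
    ncol = len(msa[0])
    if any(len(s) != ncol for s in msa):
        raise ValueError("MSA sequences differ in length")
    bg_map = background or BLOSUM62_BACKGROUND
    bg = np.array([bg_map[a] for a in PSSM_ALPHABET], dtype=float)
    bg = bg / bg.sum()
    cols = range(ncol) if positions is None else positions
    idx = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}
    out = []
    for c in cols:
        counts = np.zeros(20)
        n_tot = 0
        for s in msa:
            aa = s[c]
            n_tot += 1
            if aa in idx:
                counts[idx[aa]] += 1
        n_res = counts.sum()
        if n_res == 0:
            logger.warning("all-gap MSA column %d scored 0", c)
            out.append(0.0)
            continue
        p = counts / n_res
        score = js_divergence(p, bg) * (n_res / n_tot)
        out.append(min(max(score, 0.0), 1.0))
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# window encoding

@dataclass
class ChainContext:
    """Everything known about one chain needed to encode its residues."""

    sequence: str
    pssm: np.ndarray  # len(sequence) x 20
    conservation: np.ndarray | None = None  # len(sequence), in [0, 1]
    tables: PropertyTables | None = None

    def __post_init__(self):
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.shape != (len(self.sequence), 20):
            raise SchemaError(
                f"PSSM shape {self.pssm.shape} does not match sequence length "
                f"{len(self.sequence)}"
            )
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if self.conservation.shape != (len(self.sequence),):
                raise SchemaError("conservation length mismatch")
        if self.tables is None:
            self.tables = load_property_tables()


@dataclass(frozen=True)
class FeatureWindow:
    center: int
    vector: np.ndarray  # (476,)
    schema_version: str = SCHEMA_VERSION


def _position_features(ctx: ChainContext, pos: int) -> list[float]:
    t = ctx.tables
    if pos < 0 or pos >= len(ctx.sequence):  # off-chain padding
        return ([_PAD["pssm"]] * 20
                + [_PAD["conservation"], _PAD["volume"], _PAD["polarity"],
                   _PAD["charge"], _PAD["contact"], _PAD["energy"],
                   _PAD["amphiphilicity"], _PAD["turn"]])
    aa = ctx.sequence[pos]
    if aa not in t.volume:
        logger.warning("nonstandard residue %r at %d encoded as padding", aa, pos)
        return _position_features(ctx, -1)
    feats = [sigmoid_encode(v, "minus") for v in ctx.pssm[pos]]
    cons = (float(ctx.conservation[pos]) if ctx.conservation is not None
            else 0.5)  # neutral when no alignment is available
    feats.append(cons)
    feats.append(linear_encode(t.volume[aa], t.volume["Y"]))
    feats.append(sigmoid_encode(t.polarity[aa], "minus"))
    feats.append(charge_encode(aa, t.charge))
    feats.append(linear_encode(t.contact[aa], t.contact["C"]))
    feats.append(sigmoid_encode(t.energy[aa], "minus"))
    feats.append(sigmoid_encode(t.amphiphilicity[aa], "plus"))
    feats.append(linear_encode(t.turn[aa], t.turn["P"]))
    return feats


def encode_window(ctx: ChainContext, center: int,
                  window_length: int = WINDOW_LENGTH) -> FeatureWindow:
    """Feature vector for the window centered on ``center`` (0-based)."""
    if not 0 <= center < len(ctx.sequence):
        raise IndexError(f"center {center} outside chain of length {len(ctx.sequence)}")
    if window_length % 2 != 1:
        raise ValueError("window length must be odd")
    half = window_length // 2
    vec: list[float] = []
    for pos in range(center - half, center + half + 1):
        vec.extend(_position_features(ctx, pos))
    arr = np.array(vec, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise AssertionError("encoded feature outside [0, 1]")
    return FeatureWindow(center=center, vector=arr)


def encode_chain(ctx: ChainContext, positions: Sequence[int] | None = None) -> np.ndarray:
    """Stack of window vectors for the requested (default: all) positions."""
    positions = range(len(ctx.sequence)) if positions is None else positions
    return np.array([encode_window(ctx, p).vector for p in positions])


def write_feature_tsv(path: str | Path, vectors: np.ndarray,
                      ids: Sequence[str] | None = None) -> None:
    vectors = np.atleast_2d(vectors)
    header = ["id"] + [f"p{p:02d}_{f}" for p in range(WINDOW_LENGTH)
                       for f in POSITION_FIELDS]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, row in enumerate(vectors):
            rid = ids[i] if ids is not None else str(i)
            fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
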