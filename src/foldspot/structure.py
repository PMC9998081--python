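"""Residue/atom data model for protein structures and complexes.

Parses and writes fixed-width PDB (wwPDB v3.3 columns), represents
structures at residue resolution with named per-residue feature tracks,
and answers geometric queries (distance matrices, chain-to-chain
distances, interface residues).

Conventions:

* Only ATOM records of the first MODEL enter the residue sequence;
  HETATM groups, waters and hydrogens are excluded.
* For alternate locations the first-seen conformer wins.
* Residues are addressed by their 0-based position in file order
  (``Fold`` behaves like a sequence); author numbering and insertion
  codes are kept as metadata.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Atom",
    "Residue",
    "Fold",
    "Complex",
    "AlphaFoldModel",
    "PDBParseError",
    "EmptyStructureError",
    "MissingAtomError",
    "parse_pdb",
    "write_pdb",
    "sequence",
    "remove_chains",
    "ca_coords",
    "distance_matrix",
    "distance_to_chain",
    "interface_residues",
    "load_alphafold",
]


class PDBParseError(ValueError):
    """A PDB line could not be parsed; the message names the line number."""


class EmptyStructureError(ValueError):
    """The source contained no usable ATOM records."""


class MissingAtomError(KeyError):
    """A residue lacks a required atom (e.g. CA)."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0  # doubles as pLDDT for predicted models
    is_hetero: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite reals")
        self.name = self.name.strip()
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    author_number: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    index: int = -1  # 0-based position in the Fold's linear order

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingAtomError(
            f"residue {self.index} ({self.res_name} /{self.chain_id}:"
            f"{self.author_number}{self.insertion_code}) has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_coords(self) -> np.ndarray:
        xyz = [a.coords for a in self.atoms if a.is_heavy]
        if not xyz:  # hydrogen-only residue: fall back to all atoms
            xyz = [a.coords for a in self.atoms]
        return np.asarray(xyz)


def _coerce_residues(residues: list[Residue]) -> list[Residue]:
    for i, r in enumerate(residues):
        r.index = i
    return residues


class Fold:
    """An ordered residue-level protein structure with feature tracks.

    Construct from a PDB file path, PDB-format text, or a residue list::

        model = Fold("structure.pdb")
        len(model)          # number of residues
        model.chains        # ordered chain identifiers
    """

    def __init__(self, source, tracks: dict | None = None, provenance: str = ""):
        if isinstance(source, (str, os.PathLike)):
            parsed = parse_pdb(source)
            self.residues = parsed.residues
            self.source = parsed.source
        elif isinstance(source, (list, tuple)):
            self.residues = _coerce_residues(list(source))
            self.source = provenance or "<residues>"
        else:
            raise TypeError("Fold source must be a path, PDB text, or residue list")
        self.tracks: dict[str, np.ndarray] = {}
        for name, values in (tracks or {}).items():
            self.annotate_(name, values)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    # -- annotation surface (tracks) ------------------------------------
    def annotate_(self, name: str, values) -> "Fold":
        """Attach (or overwrite) a named per-residue feature track in place."""
        arr = _track_values(self, values)
        if arr.shape[0] != len(self):
            raise ValueError(
                f"track {name!r} has length {arr.shape[0]}, "
                f"structure has {len(self)} residues"
            )
        self.tracks[name] = arr
        return self

    def annotate_many_(self, named_values: dict) -> "Fold":
        """Attach several tracks at once (insertion order preserved)."""
        for name, values in named_values.items():
            self.annotate_(name, values)
        return self


def _track_values(fold: Fold, values) -> np.ndarray:
    """Coerce a track source to a numeric vector.

    Accepts plain sequences, hotspot results (contribute hot flags as
    0/1) and cluster labels (contribute integer labels).
    """
    if hasattr(values, "hot"):  # HotspotResult
        return np.asarray(values.hot, dtype=float).astype(int).astype(float)
    if hasattr(values, "labels"):  # ClusterLabels
        return np.asarray(values.labels, dtype=float)
    return np.asarray(values, dtype=float)


class Complex(Fold):
    """A multi-chain structure; supports concise chain removal.

    ``cx - "AB"`` (or ``cx -= "AB"``) returns a complex lacking chains
    A and B, with residue indices recomputed.
    """

    def __sub__(self, chain_ids: str) -> "Complex":
        return remove_chains(self, chain_ids)

    __isub__ = __sub__


class AlphaFoldModel(Fold):
    """A predicted structure whose B-factor column stores per-residue pLDDT."""

    def __init__(self, source):
        super().__init__(source)
        plddt = np.array([r.atoms[0].b_factor for r in self.residues])
        bad = (plddt < 0) | (plddt > 100)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} residue(s) carry pLDDT outside [0, 100]; "
                "values kept as read",
                stacklevel=2,
            )
            self.source += " [plddt-out-of-range]"
        self.plddt = plddt
        self.annotate_("plddt", plddt)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _read_source(source) -> str:
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and not source.startswith(("ATOM", "HETATM", "MODEL", "HEADER"))
    ):
        try:
            with open(source) as fh:
                return fh.read()
        except OSError as exc:
            raise IOError(f"cannot read PDB source {source!r}: {exc}") from exc
    return str(source)


def parse_pdb(source) -> Fold:
    """Parse PDB-format text (or a path to it) into a :class:`Fold`.

    Only ATOM records of the first MODEL are kept; HETATM records are
    excluded from the residue sequence; the first-seen altloc conformer
    wins.  Raises :class:`PDBParseError` naming the offending 1-based
    line number on malformed fixed-width fields, and
    :class:`EmptyStructureError` if no ATOM records are found.
    """
    text = _read_source(source)
    residues: list[Residue] = []
    res_key_to_pos: dict[tuple, int] = {}
    in_model = 0  # 0 = no MODEL seen yet (single-model file)
    done = False
    for lineno, line in enumerate(io.StringIO(text), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                done = True
            continue
        if rec.startswith("ENDMDL"):
            done = True
            continue
        if done or not rec.startswith("ATOM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or " "
            resseq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            element = line[76:78].strip() if len(line) >= 77 else ""
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
        if not element:
            element = "".join(c for c in name if c.isalpha())[:1]
        if element.upper() == "H":
            continue  # hydrogens excluded from the residue sequence
        atom = Atom(serial, name, element, (x, y, z), occ, bfac, is_hetero=False)
        key = (chain_id, resseq, icode)
        if key not in res_key_to_pos:
            res_key_to_pos[key] = len(residues)
            residues.append(Residue(chain_id, resseq, res_name, [atom], icode))
        else:
            res = residues[res_key_to_pos[key]]
            # first-seen conformer wins for alternate locations
            if altloc and res.has_atom(name):
                continue
            if not res.has_atom(name):
                res.atoms.append(atom)
    if not residues:
        raise EmptyStructureError("no ATOM records found in PDB source")
    fold = Fold(residues)
    fold.source = str(source)[:60] if isinstance(source, (str, os.PathLike)) and "\n" not in str(source) else "<text>"
    return fold


def write_pdb(fold: Fold) -> str:
    """Serialize a fold as fixed-width PDB ATOM records.

    Coordinates carry 3 decimals; one TER per chain; END terminator.
    """
    if len(fold) == 0:
        raise EmptyStructureError("cannot write an empty structure")
    lines: list[str] = []
    serial = 0
    prev_chain = None
    for res in fold.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.res_name:>3s} {res.chain_id:1s}"
                f"{res.author_number:4d}{res.insertion_code or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def sequence(fold: Fold, chain: str) -> str:
    """One-letter amino-acid sequence of a chain; unknown residues map to X."""
    if chain not in fold.chains:
        raise KeyError(f"chain {chain!r} not present (have {fold.chains})")
    return "".join(
        protein_letters_3to1.get(r.res_name, "X")
        for r in fold.residues
        if r.chain_id == chain
    )


def remove_chains(cx: Fold, chain_ids: str) -> Complex:
    """Return a complex lacking the listed chains; indices recomputed, tracks dropped."""
    have = set(cx.chains)
    missing = [c for c in chain_ids if c not in have]
    if missing:
        raise KeyError(f"chain(s) {''.join(missing)!r} not present (have {cx.chains})")
    drop = set(chain_ids)
    kept = [
        Residue(r.chain_id, r.author_number, r.res_name, list(r.atoms), r.insertion_code)
        for r in cx.residues
        if r.chain_id not in drop
    ]
    if not kept:
        raise EmptyStructureError("removing those chains leaves no residues")
    out = Complex(kept)
    out.source = cx.source
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def ca_coords(fold: Fold, fallback: str | None = None) -> np.ndarray:
    """n x 3 matrix of CA coordinates (Angstrom), row i = residue i.

    A residue lacking a CA atom is an error naming the residue, unless
    ``fallback="first-atom"`` is explicitly enabled.
    """
    rows = []
    for r in fold.residues:
        if r.has_atom("CA"):
            rows.append(r.atom("CA").coords)
        elif fallback == "first-atom":
            rows.append(r.atoms[0].coords)
        else:
            raise MissingAtomError(
                f"residue {r.index} ({r.res_name} /{r.chain_id}:{r.author_number}) "
                "lacks a CA atom; pass fallback='first-atom' to use its first atom"
            )
    return np.asarray(rows, dtype=float)


def distance_matrix(fold: Fold, mode: str = "ca") -> np.ndarray:
    """Symmetric n x n residue distance matrix (Angstrom), zero diagonal.

    ``"ca"``: CA-CA Euclidean distance.  ``"min_heavy"``: minimum over
    heavy-atom pairs (element != H).
    """
    from scipy.spatial.distance import cdist, squareform, pdist

    if len(fold) == 0:
        raise EmptyStructureError("empty structure")
    if mode == "ca":
        return squareform(pdist(ca_coords(fold)))
    if mode == "min_heavy":
        coords = []
        owner = []
        for r in fold.residues:
            xyz = r.heavy_coords()
            coords.append(xyz)
            owner.extend([r.index] * len(xyz))
        allxyz = np.vstack(coords)
        owner = np.asarray(owner)
        d = cdist(allxyz, allxyz)
        n = len(fold)
        out = np.full((n, n), np.inf)
        np.minimum.at(out, (owner[:, None], owner[None, :]), d)
        np.fill_diagonal(out, 0.0)
        return out
    raise ValueError(f"unknown distance mode {mode!r} (use 'ca' or 'min_heavy')")


def distance_to_chain(cx: Fold, query_chain: str, target_chain: str) -> np.ndarray:
    """Per-residue minimum heavy-atom distance from query-chain residues
    to any heavy atom of the target chain (Angstrom)."""
    from scipy.spatial.distance import cdist

    chains = cx.chains
    for c in (query_chain, target_chain):
        if c not in chains:
            raise KeyError(f"chain {c!r} not present (have {chains})")
    if query_chain == target_chain:
        raise ValueError("query and target chain must be distinct")
    target_xyz = np.vstack(
        [r.heavy_coords() for r in cx.residues if r.chain_id == target_chain]
    )
    out = []
    for r in cx.residues:
        if r.chain_id != query_chain:
            continue
        out.append(cdist(r.heavy_coords(), target_xyz).min())
    return np.asarray(out)


def interface_residues(cx: Fold, chain_a: str, chain_b: str, cutoff: float = 5.0) -> np.ndarray:
    """0-based fold indices of chain_a residues within ``cutoff`` Angstrom
    (minimum heavy-atom distance) of chain_b."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = distance_to_chain(cx, chain_a, chain_b)
    a_indices = np.array([r.index for r in cx.residues if r.chain_id == chain_a])
    return a_indices[d <= cutoff]


def load_alphafold(source) -> AlphaFoldModel:
    """Load a predicted structure whose B-factor column stores pLDDT."""
    return AlphaFoldModel(source)
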