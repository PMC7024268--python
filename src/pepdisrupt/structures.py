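"""Structure and ensemble data model with PDB / FASTA input and output.

The in-memory model is deliberately small: chains of residues of atoms,
keeping the author-assigned (PDB) residue numbering throughout, because the
biology of the Hsp90-Cdc37 interface is discussed in author numbering
(Y4, S13, L119, N130, ...).  A conformational ensemble is an ordered list of
frames that share one topology, standing in for an MD trajectory stored as a
multi-model PDB.

PDB parsing and writing are delegated to :mod:`gemmi`; this module only
converts to and from the local dataclasses, resolves alternate locations
(highest occupancy wins, ties by first encountered) and maps phosphorylated
residues (SEP/TPO/PTR) onto their parent amino acid with a ``phospho``
modification tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Ensemble",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "chain_sequence",
    "read_fasta",
    "write_fasta",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: phosphorylated residue variants -> (parent one-letter, modification label)
PHOSPHO_RESIDUES = {"SEP": "S", "TPO": "T", "PTR": "Y"}


class PDBParseError(ValueError):
    """A PDB file could not be parsed; carries the offending line number."""


class TopologyError(ValueError):
    """Frames of an ensemble do not share chain/residue/atom identities."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"atom {self.name!r} has empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    number: int
    name3: str
    icode: str = ""
    one_letter: str = "X"
    modification: str | None = None  # None | "phospho" | other label
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.modification == "phospho" and self.one_letter not in "STY":
            raise ValueError(
                f"phospho modification on {self.one_letter} "
                f"({self.name3} {self.chain_id}{self.number}); only S/T/Y allowed"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def label(self) -> str:
        """Residue label in the Table-1 style, e.g. ``VAL318`` or ``pSER13``."""
        prefix = "p" if self.modification == "phospho" else ""
        name3 = ONE_TO_THREE.get(self.one_letter, self.name3)
        return f"{prefix}{name3}{self.number}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if keys != sorted(keys):
            self.residues = sorted(self.residues, key=lambda r: r.key)
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue numbers in chain {self.id!r}")

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.label!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def iter_residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        wanted = None if chain_ids is None else set(chain_ids)
        for c in self.chains:
            if wanted is None or c.id in wanted:
                yield from c.residues

    def topology_key(self) -> tuple:
        """Hashable identity of chains/residues/atoms ignoring coordinates."""
        return tuple(
            (c.id, tuple((r.number, r.icode, r.name3, tuple(a.name for a in r.atoms))
                         for r in c.residues))
            for c in self.chains
        )

    def copy(self) -> "Structure":
        return Structure(
            chains=[
                Chain(c.id, [
                    replace(r, atoms=[Atom(a.name, a.element, a.position.copy())
                                      for a in r.atoms])
                    for r in c.residues
                ])
                for c in self.chains
            ],
            label=self.label,
        )


@dataclass
class Ensemble:
    frames: list[Structure]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        key0 = self.frames[0].topology_key()
        for i, fr in enumerate(self.frames[1:], start=2):
            if fr.topology_key() != key0:
                raise TopologyError(f"frame {i} topology differs from frame 1")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> Structure:
        return self.frames[0]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB reading


def _validate_atom_records(path: Path) -> None:
    # gemmi is permissive; do a cheap coordinate-field sanity pass so that a
    # truncated/garbled ATOM record is reported with its line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}:{lineno}: truncated ATOM/HETATM record")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBParseError(
                            f"{path}:{lineno}: unparseable coordinate field "
                            f"{line[lo:hi]!r}"
                        ) from None


def _resolve_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winners
    winners = set(id(a) for a in best.values())
    return [a for a in res if id(a) in winners]


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue:
    name3 = res.name.strip()
    if name3 in PHOSPHO_RESIDUES:
        one, mod = PHOSPHO_RESIDUES[name3], "phospho"
    else:
        one, mod = THREE_TO_ONE.get(name3, "X"), None
    atoms = [
        Atom(a.name, a.element.name or "X", np.array([a.pos.x, a.pos.y, a.pos.z]))
        for a in _resolve_altloc(res)
    ]
    icode = res.seqid.icode.strip()
    return Residue(chain_id=chain_id, number=res.seqid.num, name3=name3,
                   icode=icode, one_letter=one, modification=mod, atoms=atoms)


def read_pdb(path: str | Path) -> Ensemble:
    """Read a single- or multi-model PDB file into an :class:`Ensemble`.

    One frame per MODEL block (a single frame when the file has none).
    Author numbering and insertion codes are preserved; HETATM residues are
    kept with one-letter code 'X' unless a phospho mapping (SEP/TPO/PTR)
    applies.  Waters are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_atom_records(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.remove_waters()
    frames = []
    for model in st:
        chains = []
        for ch in model:
            residues = [_convert_residue(ch.name, r) for r in ch]
            residues = [r for r in residues if r.atoms]
            if residues:
                chains.append(Chain(ch.name, residues))
        frames.append(Structure(chains=chains, label=path.stem))
    if not frames:
        raise PDBParseError(f"{path}: no models with atoms")
    return Ensemble(frames=frames)


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(ensemble: Ensemble | Structure, path: str | Path) -> Path:
    """Write an ensemble (or a single structure) as a (multi-model) PDB file.

    Round trip guarantee: ``read_pdb(write_pdb(e))`` reproduces chain,
    residue and atom identities exactly and coordinates to 0.001 A (the PDB
    fixed-width precision).
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble(frames=[ensemble])
    st = gemmi.Structure()
    st.name = ensemble.topology.label or "pepdisrupt"
    for frame in ensemble:
        model = gemmi.Model(len(st) + 1)
        for chain in frame.chains:
            gch = gemmi.Chain(chain.id)
            for res in chain:
                gres = gemmi.Residue()
                gres.name = res.name3
                gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
                gres.het_flag = "A" if res.name3 in THREE_TO_ONE else "H"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = 1.0
                    gres.add_atom(ga)
                gch.add_residue(gres)
            model.add_chain(gch)
        st.add_model(model)
    st.setup_entities()
    path = Path(path)
    doc = st.make_pdb_string()
    path.write_text(doc)
    return path


# ---------------------------------------------------------------------------
# Sequences


def chain_sequence(
    structure: Structure,
    chain_id: str,
    span: tuple[int, int] | None = None,
) -> str:
    """One-letter sequence of a chain, optionally restricted to a residue-number span.

    The sequence is ordered by (residue number, insertion code).  Modified
    residues contribute their parent one-letter code; inspect
    ``Residue.modification`` for the annotation.
    """
    chain = structure.chain(chain_id)
    residues = chain.residues
    if span is not None:
        lo, hi = span
        if chain.residue(lo) is None or chain.residue(hi) is None:
            raise KeyError(f"span endpoint {lo}-{hi} absent from chain {chain_id!r}")
        residues = [r for r in residues if lo <= r.number <= hi]
    return "".join(r.one_letter for r in residues)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
    return Path(path)
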