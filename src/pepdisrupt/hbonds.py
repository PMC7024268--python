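"""Geometric hydrogen-bond detection and ensemble persistence analysis.

Cryo-EM derived structures carry no hydrogens, so bonds are detected from
heavy atoms only: a donor-acceptor pair is bonded when the donor-acceptor
distance is at most 3.5 A and the antecedent-donor-acceptor angle is at
least 120 degrees.  Both thresholds are configurable via
:class:`HBondCriteria`.

Persistence (occupancy) of a bond over a conformational ensemble is the
percentage of frames in which the geometric criterion holds — the quantity
commonly tabulated for MD trajectories of protein-protein complexes (e.g.
"VAL318:MET128  99.76").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Ensemble, Residue, Structure

__all__ = [
    "HBondCriteria",
    "HBondPair",
    "PersistenceRecord",
    "detect_hbonds",
    "persistence",
    "persistence_table",
    "aggregate_residue_level",
    "iter_donors",
    "iter_acceptors",
]

# Donor atoms per residue type: atom name -> antecedent atom name.
# Backbone N (antecedent CA) applies to every residue type.
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "S": {"OG": "CB"},
    "T": {"OG1": "CB"},
    "Y": {"OH": "CZ"},
    "K": {"NZ": "CE"},
    "R": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "N": {"ND2": "CG"},
    "Q": {"NE2": "CD"},
    "H": {"ND1": "CG", "NE2": "CE1"},
    "W": {"NE1": "CD1"},
}

# Acceptor atoms per residue type; backbone O applies to every residue.
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "H": ("ND1", "NE2"),
    "M": ("SD",),
}

#: additional acceptors on phosphorylated S/T/Y (phosphate oxygens; PDB
#: names vary: O1P/O2P/O3P or OP1/OP2/OP3, plus the bridging OG/OG1/OH)
_PHOSPHO_ACCEPTOR_NAMES = {"O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom geometric criterion for hydrogen bonding."""
    max_distance: float = 3.5   # A, donor to acceptor
    min_angle: float = 120.0    # degrees, antecedent-donor-acceptor

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if not (0 < self.min_angle <= 180):
            raise ValueError("min_angle must be in (0, 180]")


@dataclass(frozen=True)
class _Site:
    chain_id: str
    res_number: int
    icode: str
    res_label: str
    atom_name: str
    position: tuple[float, float, float]
    antecedent: tuple[float, float, float] | None = None

    @property
    def label(self) -> str:
        return f"{self.res_label}@{self.atom_name}"


@dataclass
class HBondPair:
    donor: _Site
    acceptor: _Site
    distance: float
    angle: float

    @property
    def label(self) -> str:
        """Atom-level pair label, e.g. ``VAL318@N:MET128@O``."""
        return f"{self.donor.label}:{self.acceptor.label}"

    @property
    def residue_label(self) -> str:
        """Residue-level pair label, e.g. ``VAL318:MET128``."""
        return f"{self.donor.res_label}:{self.acceptor.res_label}"


@dataclass
class PersistenceRecord:
    pair_label: str
    percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError(f"percent out of [0,100]: {self.percent}")


def iter_donors(residue: Residue) -> Iterable[tuple[str, str | None]]:
    """Yield (donor atom name, antecedent atom name) typed for this residue."""
    if residue.atom("N") is not None:
        yield "N", "CA"
    for atom_name, antecedent in _SIDECHAIN_DONORS.get(residue.one_letter, {}).items():
        if residue.atom(atom_name) is not None:
            yield atom_name, antecedent


def iter_acceptors(residue: Residue) -> Iterable[str]:
    """Yield acceptor atom names typed for this residue."""
    if residue.atom("O") is not None:
        yield "O"
    for atom_name in _SIDECHAIN_ACCEPTORS.get(residue.one_letter, ()):
        if residue.atom(atom_name) is not None:
            yield atom_name
    if residue.modification == "phospho":
        for atom in residue.atoms:
            if atom.name in _PHOSPHO_ACCEPTOR_NAMES:
                yield atom.name


def _collect_sites(structure: Structure, chain_ids: Iterable[str]):
    donors: list[_Site] = []
    acceptors: list[_Site] = []
    for res in structure.iter_residues(chain_ids):
        for atom_name, antecedent_name in iter_donors(res):
            atom = res.atom(atom_name)
            ante = res.atom(antecedent_name) if antecedent_name else None
            donors.append(_Site(
                res.chain_id, res.number, res.icode, res.label, atom_name,
                tuple(atom.position),
                tuple(ante.position) if ante is not None else None,
            ))
        for atom_name in iter_acceptors(res):
            atom = res.atom(atom_name)
            acceptors.append(_Site(
                res.chain_id, res.number, res.icode, res.label, atom_name,
                tuple(atom.position),
            ))
    return donors, acceptors


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _bonds_between(donors, acceptors, criteria: HBondCriteria) -> list[HBondPair]:
    if not donors or not acceptors:
        return []
    acc_xyz = np.array([a.position for a in acceptors])
    tree = cKDTree(acc_xyz)
    out = []
    for donor in donors:
        dpos = np.asarray(donor.position)
        for ai in tree.query_ball_point(dpos, r=criteria.max_distance):
            acc = acceptors[ai]
            apos = np.asarray(acc.position)
            dist = float(np.linalg.norm(apos - dpos))
            if donor.antecedent is not None:
                angle = _angle_deg(np.asarray(donor.antecedent), dpos, apos)
                if angle < criteria.min_angle:
                    continue
            else:
                angle = float("nan")
            out.append(HBondPair(donor, acc, dist, angle))
    return out


def detect_hbonds(
    structure: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondPair]:
    """All inter-group donor/acceptor pairs satisfying the geometric criterion.

    Both donor-in-A/acceptor-in-B and donor-in-B/acceptor-in-A pairs are
    reported, so the result is symmetric in group order up to the
    donor/acceptor roles.  Groups must be disjoint, non-empty and present.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"chain groups overlap: {group_a & group_b}")
    for cid in group_a | group_b:
        if not structure.has_chain(cid):
            raise KeyError(f"no chain {cid!r} in structure")
    donors_a, acceptors_a = _collect_sites(structure, group_a)
    donors_b, acceptors_b = _collect_sites(structure, group_b)
    bonds = _bonds_between(donors_a, acceptors_b, criteria)
    bonds += _bonds_between(donors_b, acceptors_a, criteria)
    bonds.sort(key=lambda b: b.label)
    return bonds


def persistence(
    ensemble: Ensemble,
    group_a: Iterable[str],
    group_b: Iterable[str],
    criteria: HBondCriteria = HBondCriteria(),
    min_percent: float = 0.0,
) -> list[PersistenceRecord]:
    """Per-bond occupancy percentages across an ensemble.

    For every atom-level donor/acceptor pair bonded in at least one frame,
    ``percent = 100 * frames_bonded / n_frames``.  Records below
    ``min_percent`` are dropped; the rest are sorted by descending percent,
    ties broken by pair label.
    """
    counts: Counter[str] = Counter()
    for frame in ensemble:
        seen = {b.label for b in detect_hbonds(frame, group_a, group_b, criteria)}
        counts.update(seen)
    n = ensemble.n_frames
    records = [
        PersistenceRecord(label, 100.0 * c / n)
        for label, c in counts.items()
        if 100.0 * c / n >= min_percent
    ]
    records.sort(key=lambda r: (-r.percent, r.pair_label))
    return records


def aggregate_residue_level(records: Sequence[PersistenceRecord]) -> list[PersistenceRecord]:
    """Collapse atom-level records to residue pairs, keeping the max occupancy."""
    best: dict[str, float] = {}
    for rec in records:
        donor, acceptor = rec.pair_label.split(":")
        key = f"{donor.split('@')[0]}:{acceptor.split('@')[0]}"
        best[key] = max(best.get(key, 0.0), rec.percent)
    out = [PersistenceRecord(k, v) for k, v in best.items()]
    out.sort(key=lambda r: (-r.percent, r.pair_label))
    return out


def persistence_table(records: Sequence[PersistenceRecord], path: str | Path) -> Path:
    """Write records as a two-column TSV (pair label, percent to 2 decimals)."""
    path = Path(path)
    lines = ["pair\tpercent"]
    lines += [f"{r.pair_label}\t{r.percent:.2f}" for r in records]
    path.write_text("\n".join(lines) + "\n")
    return path
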