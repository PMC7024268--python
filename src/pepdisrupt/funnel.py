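"""Coarse-grained peptide-receptor scoring and binding-funnel analysis.

The binding funnel of a peptide is the relationship between the energy of a
conformation and its Calpha RMSD from the bound (anchor) pose.  A steep
funnel — energy rising quickly as the peptide leaves the anchor — indicates
robust binding; for peptides of length 10-15 a funnel slope above five is
used as the binder heuristic.

Because the original interface-crawling tool's energy function is
unpublished, this module declares its own coarse-grained three-term model,
reported in "model energy units":

    E = w_hbond * N_hbond + w_contact * sum(contact compatibility) + w_clash * N_clash

where N_hbond counts satisfied geometric hydrogen bonds between receptor and
peptide, the contact sum runs over receptor-peptide residue pairs with any
heavy-atom pair within 6.5 A weighted by a hydrophobicity-compatibility
table (Kyte-Doolittle derived), and N_clash counts heavy-atom pairs closer
than 2.5 A.  The model's absolute values are NOT comparable to published
energy scales; the slope-threshold binder rule, which is scale-free in
spirit, is what transfers.

Alternative conformations around the anchor are generated by an RRT
(rapidly exploring random tree): each node is produced by one bounded random
move — rigid-body translation/rotation or a backbone-dihedral twist — from
the tree node nearest a randomly sampled goal pose.  Funnel steepness is the
ordinary-least-squares slope of (energy - anchor energy) against RMSD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .structures import Chain, Structure

__all__ = [
    "EnergyWeights",
    "FunnelSample",
    "FunnelStats",
    "RRTParams",
    "BinderCall",
    "CLASH_DISTANCE",
    "CONTACT_DISTANCE",
    "score_pose",
    "rrt_explore",
    "funnel_steepness",
    "is_binder",
    "hydrophobicity_compatibility",
]

CONTACT_DISTANCE = 6.5  # A, heavy-atom residue-pair contact
CLASH_DISTANCE = 2.5    # A, heavy-atom steric clash

# Kyte-Doolittle hydropathy, rescaled below to [0, 1]
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def _hydro01(aa: str) -> float:
    return (_KYTE_DOOLITTLE.get(aa, -0.4) + 4.5) / 9.0


def hydrophobicity_compatibility(aa1: str, aa2: str) -> float:
    """Pairwise contact compatibility in [0, 1].

    Product of the two residues' hydropathies rescaled to [0, 1]: burying
    two hydrophobic residues against each other scores high, pairing two
    strongly polar residues scores low.
    """
    return _hydro01(aa1) * _hydro01(aa2)


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the three-term model, in model energy units.

    Attractive terms are negative, the clash penalty positive.
    """
    w_hbond: float = -2.0
    w_contact: float = -0.5
    w_clash: float = 10.0

    def __post_init__(self) -> None:
        if self.w_hbond >= 0 or self.w_contact >= 0 or self.w_clash <= 0:
            raise ValueError("require w_hbond < 0, w_contact < 0, w_clash > 0")


@dataclass
class FunnelSample:
    """One explored conformation: peptide coordinates, RMSD to anchor, energy."""
    conformation: np.ndarray | None  # (n_atoms, 3) peptide coordinates
    rmsd: float
    energy: float


@dataclass
class FunnelStats:
    slope: float          # model energy units per A
    intercept: float
    r_squared: float
    n_samples: int
    binder: "BinderCall | None" = None


class BinderCall(enum.Enum):
    BINDER = "binder"
    NON_BINDER = "non-binder"
    NOT_CALIBRATED = "not-calibrated"  # slope rule only calibrated for 10-15-mers

    def __bool__(self) -> bool:
        return self is BinderCall.BINDER


@dataclass(frozen=True)
class RRTParams:
    max_nodes: int = 500
    translation_step: float = 0.5   # A
    rotation_step: float = 5.0      # degrees, rigid-body
    dihedral_step: float = 10.0     # degrees, backbone twist
    rmsd_max: float = 3.0           # A, exploration radius
    clash_rejection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_nodes < 1:
            raise ValueError("max_nodes >= 1 required")
        if min(self.translation_step, self.rotation_step, self.dihedral_step) <= 0:
            raise ValueError("all step sizes must be > 0")


# ---------------------------------------------------------------------------
# Scoring


def _chain_heavy_coords(chain: Chain) -> tuple[np.ndarray, list[int], list[str]]:
    """Heavy-atom coordinates with per-atom residue index and residue letter."""
    coords, res_idx, letters = [], [], []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.is_heavy:
                coords.append(atom.position)
                res_idx.append(i)
                letters.append(res.one_letter)
    return np.asarray(coords, dtype=float), res_idx, letters


def _receptor_heavy(receptor: Structure, receptor_chains: Sequence[str] | None):
    coords, res_letters, res_ids = [], [], []
    chains = receptor.chains if receptor_chains is None else [
        receptor.chain(c) for c in receptor_chains
    ]
    for ch in chains:
        for res in ch.residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    coords.append(atom.position)
                    res_letters.append(res.one_letter)
                    res_ids.append((ch.id, res.number, res.icode))
    return np.asarray(coords, dtype=float), res_letters, res_ids


def score_pose(
    receptor: Structure,
    peptide: Chain,
    weights: EnergyWeights = EnergyWeights(),
    receptor_chains: Sequence[str] | None = None,
) -> float:
    """Energy of a peptide conformation against a rigid receptor.

    ``E = w_hbond*N_hb + w_contact*sum(compat) + w_clash*N_clash``; exactly
    zero when the peptide is out of range of every term.  Deterministic.
    """
    if not peptide.residues or not any(r.atoms for r in peptide.residues):
        raise ValueError("empty peptide")
    from .hbonds import HBondCriteria, detect_hbonds

    rec_xyz, rec_letters, rec_ids = _receptor_heavy(receptor, receptor_chains)
    pep_xyz, pep_res_idx, pep_letters = _chain_heavy_coords(peptide)
    if rec_xyz.size == 0:
        return 0.0

    tree = cKDTree(rec_xyz)

    # contact term: one count per (receptor residue, peptide residue) pair
    # with any heavy-atom pair within CONTACT_DISTANCE
    pairs = tree.query_ball_point(pep_xyz, r=CONTACT_DISTANCE)
    contact_sum = 0.0
    seen: set[tuple] = set()
    n_clash = 0
    for p_i, neighbours in enumerate(pairs):
        for r_i in neighbours:
            key = (rec_ids[r_i], pep_res_idx[p_i])
            if key not in seen:
                seen.add(key)
                contact_sum += hydrophobicity_compatibility(
                    rec_letters[r_i], pep_letters[p_i])
            if np.linalg.norm(rec_xyz[r_i] - pep_xyz[p_i]) < CLASH_DISTANCE:
                n_clash += 1

    # hydrogen-bond term between the receptor chains and the peptide chain
    scoring_struct = Structure(
        chains=[receptor.chain(c) for c in (receptor_chains or
                                            [c.id for c in receptor.chains])]
        + [peptide],
        label="scoring",
    )
    hbonds = detect_hbonds(
        scoring_struct,
        group_a={c.id for c in scoring_struct.chains if c.id != peptide.id},
        group_b={peptide.id},
        criteria=HBondCriteria(),
    )
    return (weights.w_hbond * len(hbonds)
            + weights.w_contact * contact_sum
            + weights.w_clash * n_clash)


# ---------------------------------------------------------------------------
# RRT exploration


def _peptide_coords(chain: Chain) -> np.ndarray:
    return np.array([a.position for r in chain.residues for a in r.atoms])


def _set_peptide_coords(chain: Chain, coords: np.ndarray) -> None:
    i = 0
    for res in chain.residues:
        for atom in res.atoms:
            atom.position = coords[i].copy()
            i += 1


def _ca_indices(chain: Chain) -> list[int]:
    idx, i = [], 0
    for res in chain.residues:
        for atom in res.atoms:
            if atom.name == "CA":
                idx.append(i)
            i += 1
    return idx


def _ca_rmsd(a: np.ndarray, b: np.ndarray, ca_idx: list[int]) -> float:
    d = a[ca_idx] - b[ca_idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _backbone_bonds(chain: Chain) -> list[tuple[int, int, int]]:
    """Rotatable backbone bonds as (pivot_atom, axis_atom, first_downstream_atom_index)."""
    bonds = []
    flat_index: dict[tuple[int, str], int] = {}
    i = 0
    for ri, res in enumerate(chain.residues):
        for atom in res.atoms:
            flat_index[(ri, atom.name)] = i
            i += 1
    n_atoms = i
    for ri, res in enumerate(chain.residues[:-1]):
        # rotate everything after this residue about its CA-C bond (psi-like)
        ca = flat_index.get((ri, "CA"))
        c = flat_index.get((ri, "C"))
        if ca is not None and c is not None:
            first_down = min(
                (v for (rj, _), v in flat_index.items() if rj > ri),
                default=n_atoms,
            )
            bonds.append((ca, c, first_down))
    return bonds


def rrt_explore(
    receptor: Structure,
    peptide: Chain,
    params: RRTParams = RRTParams(),
    weights: EnergyWeights = EnergyWeights(),
    receptor_chains: Sequence[str] | None = None,
) -> list[FunnelSample]:
    """Grow a random tree of peptide conformations around the anchor pose.

    Returns one :class:`FunnelSample` per accepted node (the anchor is node
    0 at RMSD 0).  All samples stay within ``params.rmsd_max`` of the anchor;
    when clash rejection is on, nodes with any receptor-peptide heavy-atom
    pair closer than 2.5 A are discarded.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    anchor = _peptide_coords(peptide)
    if anchor.size == 0:
        raise ValueError("peptide has no atoms")
    ca_idx = _ca_indices(peptide) or list(range(len(anchor)))
    bonds = _backbone_bonds(peptide)

    rec_xyz, _, rec_ids = _receptor_heavy(receptor, receptor_chains)
    rec_tree = cKDTree(rec_xyz) if rec_xyz.size else None

    def min_clash_pair(coords: np.ndarray):
        if rec_tree is None:
            return None
        dists, idx = rec_tree.query(coords)
        worst = int(np.argmin(dists))
        if dists[worst] < CLASH_DISTANCE:
            return rec_ids[idx[worst]], worst, float(dists[worst])
        return None

    clash0 = min_clash_pair(anchor)
    if clash0 is not None and params.clash_rejection:
        rec_id, pep_atom, d = clash0
        raise ValueError(
            f"anchor pose clashes: receptor atom of residue {rec_id} vs "
            f"peptide atom index {pep_atom} at {d:.2f} A"
        )

    work = Chain(peptide.id, [r for r in peptide.residues])  # shared atoms; coords swapped in/out

    def energy_of(coords: np.ndarray) -> float:
        _set_peptide_coords(work, coords)
        return score_pose(receptor, work, weights, receptor_chains)

    nodes = [anchor]
    samples = [FunnelSample(anchor.copy(), 0.0, energy_of(anchor))]
    centroid = anchor.mean(axis=0)

    while len(nodes) < params.max_nodes:
        # random goal: rigid transform of the anchor inside the rmsd_max ball
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        goal_shift = direction * params.rmsd_max * rng.random()
        goal = anchor + goal_shift

        # nearest node to the goal (Calpha RMSD metric)
        dists = [_ca_rmsd(n, goal, ca_idx) for n in nodes]
        near = nodes[int(np.argmin(dists))]

        move = rng.choice(3, p=[0.6, 0.2, 0.2])
        new = near.copy()
        if move == 0:  # translation toward the goal, truncated to step size
            delta = goal.mean(axis=0) - near.mean(axis=0)
            norm = np.linalg.norm(delta)
            if norm < 1e-12:
                continue
            new = near + delta / norm * min(norm, params.translation_step)
        elif move == 1:  # rigid-body rotation about the peptide centroid
            axis = rng.normal(size=3)
            angle = np.deg2rad(params.rotation_step) * (2 * rng.random() - 1)
            rot = _rotation_matrix(axis, angle)
            c = near.mean(axis=0)
            new = (near - c) @ rot.T + c
        else:  # backbone dihedral twist
            if not bonds:
                continue
            piv, ax, down = bonds[rng.integers(len(bonds))]
            angle = np.deg2rad(params.dihedral_step) * (2 * rng.random() - 1)
            axis = near[ax] - near[piv]
            if np.linalg.norm(axis) < 1e-9:
                continue
            rot = _rotation_matrix(axis, angle)
            new = near.copy()
            new[down:] = (near[down:] - near[ax]) @ rot.T + near[ax]

        rmsd = _ca_rmsd(new, anchor, ca_idx)
        if rmsd > params.rmsd_max:
            continue
        if params.clash_rejection and min_clash_pair(new) is not None:
            continue
        nodes.append(new)
        samples.append(FunnelSample(new, rmsd, energy_of(new)))

    _set_peptide_coords(work, anchor)  # restore the anchor pose
    return samples


# ---------------------------------------------------------------------------
# Funnel statistics


def funnel_steepness(
    samples: Sequence[FunnelSample],
    rmsd_window: tuple[float, float] | None = None,
) -> FunnelStats:
    """OLS slope of (energy - anchor energy) against RMSD within a window.

    The anchor energy is taken from the minimum-RMSD sample.  Requires at
    least two in-window samples with distinct RMSD values.
    """
    if rmsd_window is not None:
        lo, hi = rmsd_window
        inside = [s for s in samples if lo <= s.rmsd <= hi]
    else:
        inside = list(samples)
    if len(inside) < 2:
        raise ValueError("need at least two samples inside the RMSD window")
    anchor_energy = min(inside, key=lambda s: s.rmsd).energy
    x = np.array([s.rmsd for s in inside])
    y = np.array([s.energy - anchor_energy for s in inside])
    if np.ptp(x) == 0:
        raise ValueError("degenerate funnel: all samples at the same RMSD")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    return FunnelStats(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=r2, n_samples=len(inside))


BINDER_SLOPE_THRESHOLD = 5.0
BINDER_LENGTH_RANGE = (10, 15)


def is_binder(stats_or_slope: FunnelStats | float, peptide_length: int) -> BinderCall:
    """Binder heuristic: funnel slope above five, calibrated for 10-15-mers.

    Outside the calibrated length range the call is
    :attr:`BinderCall.NOT_CALIBRATED` (a distinct third state), never a
    hard yes/no.
    """
    slope = stats_or_slope.slope if isinstance(stats_or_slope, FunnelStats) else float(stats_or_slope)
    lo, hi = BINDER_LENGTH_RANGE
    if not (lo <= peptide_length <= hi):
        return BinderCall.NOT_CALIBRATED
    return BinderCall.BINDER if slope > BINDER_SLOPE_THRESHOLD else BinderCall.NON_BINDER
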