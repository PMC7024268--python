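"""Synthetic fixtures: toy complexes, programmed-occupancy ensembles, funnel
samples and multiple sequence alignments.

The MD trajectory behind real interface occupancy tables is never shipped
with a paper, so every downstream stage of this package is exercised on
synthetic systems with *known* ground truth:

* :func:`make_toy_complex` builds a two-chain receptor-groove/peptide complex
  from idealized backbone geometry (side chains reduced to a Cbeta
  pseudo-atom).  Each groove position donates one backbone N-H...O=C
  hydrogen bond to the peptide, mimicking the beta-strand pairing seen at
  chaperone-co-chaperone interfaces.
* :func:`make_ensemble` turns one structure into a multi-frame ensemble in
  which each requested hydrogen bond is present in a Binomial(n_frames, p)
  number of frames — the analysis must then recover p as its occupancy.
* :func:`make_funnel_samples` draws energy-vs-RMSD points from a known
  linear funnel, so slope estimators can be validated against the truth.
* :func:`make_msa` emits an alignment whose per-column conservation is
  programmed, for testing conservation scoring.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .funnel import FunnelSample
from .structures import Atom, Chain, Ensemble, Residue, Structure, ONE_TO_THREE

__all__ = [
    "OccupancySpec",
    "make_toy_complex",
    "make_ensemble",
    "make_funnel_samples",
    "make_msa",
]

# extended-strand geometry (A); approximately ideal backbone dimensions
_RISE = 3.8          # Calpha-Calpha rise per residue
_N_OFFSET = np.array([-1.19, 0.85, 0.0])   # CA -> N (length 1.46)
_C_OFFSET = np.array([1.26, 0.85, 0.0])    # CA -> C (length 1.52)
_O_FROM_C = 1.23                           # C=O bond length
_CB_OFFSET = np.array([0.0, -0.95, 1.10])  # CA -> CB pseudo side chain
_GROOVE_GAP = 2.80   # receptor N to peptide O hydrogen-bond distance
_RECEPTOR_ALPHABET = "ADEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class OccupancySpec:
    """Programmed occupancy for one donor/acceptor pair.

    Sites are (chain id, residue number, atom name) triples; ``p`` is the
    target fraction of frames in which the bond holds.
    """
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"occupancy p out of [0,1]: {self.p}")

    @property
    def label(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d[0]}{d[1]}@{d[2]}:{a[0]}{a[1]}@{a[2]}"


def _make_residue(chain_id: str, number: int, letter: str, ca: np.ndarray,
                  flip_y: bool = False) -> Residue:
    s = -1.0 if flip_y else 1.0
    yflip = np.array([1.0, s, 1.0])
    # the carbonyl O always points +y: toward the receptor on the peptide
    # strand (forming the groove H-bond) and away from the interface on the
    # receptor strand (keeping the interchain gap >= 2.2 A)
    atoms = [
        Atom("N", "N", ca + _N_OFFSET * yflip),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", ca + _C_OFFSET * yflip),
        Atom("O", "O", ca + _C_OFFSET * yflip + np.array([0.0, _O_FROM_C, 0.0])),
    ]
    if letter != "G":
        atoms.append(Atom("CB", "C", ca + _CB_OFFSET * yflip))
    return Residue(chain_id=chain_id, number=number, name3=ONE_TO_THREE[letter],
                   one_letter=letter, atoms=atoms)


def make_toy_complex(receptor_size: int, peptide_seq: str, seed: int = 0) -> Structure:
    """Two-chain toy complex: receptor chain ``R`` grooving peptide chain ``P``.

    The peptide lies in an extended conformation along x with its carbonyl
    oxygens pointing at the receptor strand; for every peptide residue the
    facing receptor backbone nitrogen sits 2.8 A from the peptide oxygen,
    forming a persistent N-H...O hydrogen bond (the "groove" contact).  No
    interchain heavy-atom pair comes closer than 2.2 A.  Deterministic for a
    fixed seed.
    """
    if len(peptide_seq) < 3:
        raise ValueError("peptide must have at least 3 residues")
    if receptor_size < len(peptide_seq):
        raise ValueError("receptor must be at least as long as the peptide")
    bad = set(peptide_seq) - set(ONE_TO_THREE)
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    receptor_seq = "".join(rng.choice(list(_RECEPTOR_ALPHABET), size=receptor_size))

    peptide = Chain("P", [
        _make_residue("P", i + 1, letter, np.array([_RISE * i, 0.0, 0.0]))
        for i, letter in enumerate(peptide_seq)
    ])
    # receptor strand above the peptide, x-shifted so each receptor N faces a
    # peptide O; carbonyls and side chains point away from the interface
    base_y = _C_OFFSET[1] + _O_FROM_C + _GROOVE_GAP + abs(_N_OFFSET[1])  # 5.73
    receptor = Chain("R", [
        _make_residue("R", j + 1, letter,
                      np.array([_RISE * j + 2.45, base_y, 0.0]), flip_y=True)
        for j, letter in enumerate(receptor_seq)
    ])
    return Structure(chains=[receptor, peptide], label=f"toy-{len(peptide_seq)}mer")


def groove_hbond_specs(structure: Structure, p: float | Sequence[float]) -> list[OccupancySpec]:
    """Occupancy specs for the designed receptor-N -> peptide-O groove bonds."""
    pep = structure.chain("P")
    ps = [p] * len(pep) if np.isscalar(p) else list(p)
    if len(ps) != len(pep):
        raise ValueError("need one occupancy per peptide residue")
    return [
        OccupancySpec(donor=("R", res.number, "N"),
                      acceptor=("P", res.number, "O"), p=float(pi))
        for res, pi in zip(pep.residues, ps)
    ]


def make_ensemble(
    structure: Structure,
    n_frames: int,
    specs: Sequence[OccupancySpec],
    jitter_sigma: float = 0.05,
    seed: int = 0,
    break_distance: float = 4.5,
) -> Ensemble:
    """Ensemble in which each spec'd bond holds in ~Binomial(n_frames, p) frames.

    Bond breaking displaces the acceptor along the donor->acceptor axis to
    ``break_distance`` (default: 1 A beyond the 3.5 A distance cutoff), which
    fails the geometric criterion regardless of angle convention.  All atoms
    not involved in a spec (nor in a spec'd residue) receive isotropic
    Gaussian jitter of ``jitter_sigma`` so programmed states are never
    silently flipped.
    """
    if n_frames < 1:
        raise ValueError("n_frames >= 1 required")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(seed)

    # resolve spec atoms once against the template topology
    resolved = []
    protected: set[tuple[str, int]] = set()
    for spec in specs:
        sites = []
        for chain_id, res_num, atom_name in (spec.donor, spec.acceptor):
            res = structure.chain(chain_id).residue(res_num)
            if res is None or res.atom(atom_name) is None:
                raise KeyError(f"spec references missing atom "
                               f"{chain_id}{res_num}@{atom_name}")
            sites.append((chain_id, res_num, atom_name))
            protected.add((chain_id, res_num))
        resolved.append((sites[0], sites[1], spec.p))

    frames = []
    for _ in range(n_frames):
        frame = structure.copy()
        for res in frame.iter_residues():
            if (res.chain_id, res.number) in protected:
                continue
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, jitter_sigma, 3)
        for donor_site, acceptor_site, p in resolved:
            if rng.random() < p:
                continue  # bond kept this frame
            donor = frame.chain(donor_site[0]).residue(donor_site[1]).atom(donor_site[2])
            acceptor = frame.chain(acceptor_site[0]).residue(acceptor_site[1]).atom(acceptor_site[2])
            axis = acceptor.position - donor.position
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                axis, norm = np.array([0.0, 1.0, 0.0]), 1.0
            acceptor.position = donor.position + axis / norm * break_distance
        frames.append(frame)
    return Ensemble(frames=frames)


def make_funnel_samples(
    slope: float,
    noise_sigma: float,
    n: int,
    rmsd_max: float,
    seed: int = 0,
) -> list[FunnelSample]:
    """Energy-vs-RMSD samples from a known linear funnel.

    RMSD uniform on [0, rmsd_max]; energy = slope * RMSD + N(0, noise_sigma).
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if rmsd_max <= 0:
        raise ValueError("rmsd_max must be > 0")
    rng = np.random.default_rng(seed)
    rmsd = rng.uniform(0.0, rmsd_max, size=n)
    energy = slope * rmsd + (rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0
                             else np.zeros(n))
    return [FunnelSample(None, float(r), float(e)) for r, e in zip(rmsd, energy)]


def make_msa(
    reference_seq: str,
    n_seqs: int,
    conservation: Sequence[float],
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Alignment with programmed per-column conservation; record 0 is the reference.

    Column i of every non-reference sequence matches the reference with
    probability ``conservation[i]`` and is otherwise a uniformly random
    *different* amino acid.
    """
    conservation = list(conservation)
    if len(conservation) != len(reference_seq):
        raise ValueError("conservation length must equal sequence length")
    if any(not (0.0 <= c <= 1.0) for c in conservation):
        raise ValueError("conservation values must lie in [0,1]")
    rng = np.random.default_rng(seed)
    alphabet = sorted(ONE_TO_THREE)
    records = [("reference", reference_seq)]
    for k in range(1, n_seqs):
        seq = []
        for ref_aa, cons in zip(reference_seq, conservation):
            if rng.random() < cons:
                seq.append(ref_aa)
            else:
                others = [a for a in alphabet if a != ref_aa]
                seq.append(others[rng.integers(len(others))])
        records.append((f"seq{k}", "".join(seq)))
    return records
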