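"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's search structures (KD-trees, beam
search) and recompute everything with plain double loops; the donor/acceptor
typing tables are shared with the package because the typing is part of the
problem statement, not of the algorithm under test.
"""

import math

import numpy as np

from pepdisrupt.hbonds import iter_acceptors, iter_donors
from pepdisrupt.funnel import (CLASH_DISTANCE, CONTACT_DISTANCE,
                               hydrophobicity_compatibility)

# standard amino-acid residue masses (Da), average and monoisotopic;
# independent frozen table for cross-checking composition-level arithmetic
RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVG, WATER_MONO = 18.0153, 18.01056
AMIDE_AVG, AMIDE_MONO = -0.9847, -0.98402


def peptide_mass_oracle(sequence, amide=False, average=False):
    table = RESIDUE_AVG if average else RESIDUE_MONO
    m = sum(table[a] for a in sequence) + (WATER_AVG if average else WATER_MONO)
    if amide:
        m += AMIDE_AVG if average else AMIDE_MONO
    return m


def _angle(a, b, c):
    v1, v2 = np.asarray(a) - np.asarray(b), np.asarray(c) - np.asarray(b)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def hbonds_oracle(structure, group_a, group_b, max_distance=3.5, min_angle=120.0):
    """All inter-group bonded (donor residue label, donor atom, acceptor
    residue label, acceptor atom) tuples by exhaustive double loop."""
    found = set()
    for donors_from, acceptors_from in ((group_a, group_b), (group_b, group_a)):
        for dres in structure.iter_residues(donors_from):
            for datom_name, ante_name in iter_donors(dres):
                datom = dres.atom(datom_name)
                ante = dres.atom(ante_name) if ante_name else None
                for ares in structure.iter_residues(acceptors_from):
                    for aatom_name in iter_acceptors(ares):
                        aatom = ares.atom(aatom_name)
                        d = np.linalg.norm(aatom.position - datom.position)
                        if d > max_distance:
                            continue
                        if ante is not None and _angle(
                                ante.position, datom.position,
                                aatom.position) < min_angle:
                            continue
                        found.add((dres.label, datom_name, ares.label, aatom_name))
    return found


def interface_oracle(structure, receptor_chains, ligand_chain, cutoff):
    """Ligand residue numbers in contact, by all-pairs distance scan."""
    rec_atoms = [a for cid in receptor_chains
                 for r in structure.chain(cid).residues
                 for a in r.atoms if a.is_heavy]
    out = []
    for res in structure.chain(ligand_chain).residues:
        hit = any(
            np.linalg.norm(a.position - b.position) <= cutoff
            for a in res.atoms if a.is_heavy for b in rec_atoms)
        if hit:
            out.append(res.number)
    return out


def score_oracle(structure, receptor_chains, peptide_chain, weights):
    """Term-by-term energy by exhaustive double loops (no KD-tree)."""
    rec_res = [r for cid in receptor_chains
               for r in structure.chain(cid).residues]
    pep_res = peptide_chain.residues
    n_clash, contact_sum = 0, 0.0
    for rr in rec_res:
        for pr in pep_res:
            dists = [np.linalg.norm(a.position - b.position)
                     for a in rr.atoms if a.is_heavy
                     for b in pr.atoms if b.is_heavy]
            if not dists:
                continue
            n_clash += sum(d < CLASH_DISTANCE for d in dists)
            if min(dists) <= CONTACT_DISTANCE:
                contact_sum += hydrophobicity_compatibility(
                    rr.one_letter, pr.one_letter)
    from pepdisrupt.structures import Structure
    scoring = Structure(
        chains=[structure.chain(c) for c in receptor_chains] + [peptide_chain])
    n_hb = len(hbonds_oracle(scoring, set(receptor_chains), {peptide_chain.id}))
    return (weights.w_hbond * n_hb + weights.w_contact * contact_sum
            + weights.w_clash * n_clash)
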