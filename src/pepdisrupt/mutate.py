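"""Conservation-guided mutation optimization of a peptide candidate.

Starting from an excised interface peptide, a beam search explores sets of
point substitutions (up to ``max_mutations``) that improve a combined
objective of binding energy and funnel steepness.  Evolutionary information
enters as a per-position conservation profile derived from a multiple
sequence alignment of the ligand protein: substitutions are drawn from a
BLOSUM62-guided allowed set and their contribution to the objective is
weighted by the conservation of the position, so poorly conserved positions
are effectively never mutated (prior proportional to conservation).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .design import PeptideCandidate
from .funnel import (EnergyWeights, RRTParams, funnel_steepness, rrt_explore,
                     score_pose)
from .structures import Chain, ONE_TO_THREE, Structure

__all__ = [
    "ConservationProfile",
    "MutationProposal",
    "conservation_scores",
    "enumerate_variants",
    "allowed_substitutions",
    "optimize",
    "hamming",
    "derive_variant_seed",
]

AMINO_ACIDS = sorted(ONE_TO_THREE)


@dataclass
class ConservationProfile:
    """Per-position conservation scores in [0, 1]; 1 = fully conserved."""
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("conservation scores must lie in [0,1]")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, i: int) -> float:
        return float(self.scores[i])


@dataclass(frozen=True)
class MutationProposal:
    position: int       # 1-based peptide index
    from_residue: str
    to_residue: str
    d_energy: float     # candidate energy minus input energy (negative = better)
    d_steepness: float  # candidate steepness minus input steepness
    objective: float    # conservation-weighted combined improvement

    def __post_init__(self) -> None:
        if self.from_residue == self.to_residue:
            raise ValueError("proposal must change the residue")


def conservation_scores(
    msa: Sequence[tuple[str, str]] | Sequence[str],
    method: str = "reference_frequency",
) -> ConservationProfile:
    """Per-column conservation of an alignment whose first record is the reference.

    ``reference_frequency`` (default): the fraction of sequences carrying the
    reference residue in that column.  ``entropy``: one minus the normalized
    Shannon entropy of the column, an alternative that does not privilege
    the reference.
    """
    seqs = [s[1] if isinstance(s, tuple) else str(s) for s in msa]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences have unequal lengths")
    cols = np.array([list(s) for s in seqs])
    if method == "reference_frequency":
        ref = cols[0]
        scores = (cols == ref).mean(axis=0)
    elif method == "entropy":
        scores = np.empty(length)
        for i in range(length):
            _, counts = np.unique(cols[:, i], return_counts=True)
            p = counts / counts.sum()
            h = -(p * np.log2(p)).sum()
            scores[i] = 1.0 - h / np.log2(20)
    else:
        raise ValueError(f"unknown conservation method {method!r}")
    return ConservationProfile(scores)


def enumerate_variants(
    sequence: str,
    positions: Sequence[int],
    allowed: Mapping[int, Sequence[str]],
) -> list[str]:
    """Cartesian product of allowed residues over the given 1-based positions."""
    if not positions:
        return [sequence]
    for pos in positions:
        if not (1 <= pos <= len(sequence)):
            raise IndexError(f"position {pos} outside sequence")
        if not allowed.get(pos):
            raise ValueError(f"empty allowed set at position {pos}")
    variants = []
    for combo in itertools.product(*(allowed[p] for p in positions)):
        seq = list(sequence)
        for pos, aa in zip(positions, combo):
            seq[pos - 1] = aa
        variants.append("".join(seq))
    return variants


def allowed_substitutions(wild_type: str, top_n: int = 5) -> list[str]:
    """The ``top_n`` highest-scoring alternatives to a residue under BLOSUM62."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    scored = sorted(
        ((blosum[wild_type, aa], aa) for aa in AMINO_ACIDS if aa != wild_type),
        key=lambda t: (-t[0], t[1]),
    )
    return [aa for _, aa in scored[:top_n]]


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    return sum(a != b for a, b in zip(seq_a, seq_b))


def derive_variant_seed(seed: int, sequence: str) -> int:
    """Stable per-variant RNG seed (< 2**31) for steepness re-evaluation."""
    return (zlib.crc32(sequence.encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def _mutated_anchor(anchor: Chain, index: int, new_aa: str) -> Chain:
    """Anchor with the residue identity at 1-based ``index`` replaced.

    Side chains are pseudo-atom level, so coordinates are kept; only the
    residue identity (hence contact compatibility and donor/acceptor typing)
    changes.
    """
    residues = []
    for k, res in enumerate(anchor.residues, start=1):
        if k == index:
            res = replace(res, name3=ONE_TO_THREE[new_aa], one_letter=new_aa,
                          modification=None,
                          atoms=[type(a)(a.name, a.element, a.position.copy())
                                 for a in res.atoms])
        residues.append(res)
    return Chain(anchor.id, residues)


@dataclass
class _BeamState:
    sequence: str
    anchor: Chain
    mutations: tuple[MutationProposal, ...]
    energy: float
    steepness: float | None = None
    objective: float = 0.0


def optimize(
    candidate: PeptideCandidate,
    profile: ConservationProfile,
    receptor: Structure,
    weights: EnergyWeights = EnergyWeights(),
    rrt_params: RRTParams | None = None,
    beam_width: int = 10,
    max_mutations: int = 2,
    seed: int = 0,
    lambda_steepness: float = 1.0,
    allowed: Mapping[int, Sequence[str]] | None = None,
    receptor_chains: Sequence[str] | None = None,
) -> tuple[list[tuple[MutationProposal, ...]], PeptideCandidate]:
    """Beam search over mutation sets improving energy and funnel steepness.

    The objective of a mutation set is
    ``(E_input - E_variant) + lambda * (steepness_variant - steepness_input)``,
    multiplied by the product of the conservation scores of the mutated
    positions (prior proportional to conservation: a position scored 0 is
    never mutated).  Steepness is re-evaluated only for beam survivors, by a
    short RRT run seeded deterministically per variant; pass
    ``rrt_params=None`` or ``lambda_steepness=0`` for an energy-only search.
    Returns the ranked mutation sets and the best candidate found — never
    worse than the input.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    if max_mutations < 0:
        raise ValueError("max_mutations must be >= 0")
    if candidate.anchor is None:
        raise ValueError("candidate must carry an anchor pose")
    if len(profile) != len(candidate.sequence):
        raise ValueError("profile length must equal peptide length")

    seq0 = candidate.sequence
    use_steepness = lambda_steepness != 0 and rrt_params is not None

    def eval_energy(anchor: Chain) -> float:
        return score_pose(receptor, anchor, weights, receptor_chains)

    def eval_steepness(anchor: Chain, sequence: str) -> float:
        params = replace(rrt_params, seed=derive_variant_seed(seed, sequence))
        samples = rrt_explore(receptor, anchor, params, weights, receptor_chains)
        return funnel_steepness(samples).slope

    e0 = candidate.binding_energy if candidate.binding_energy is not None \
        else eval_energy(candidate.anchor)
    s0 = eval_steepness(candidate.anchor, seq0) if use_steepness else 0.0

    if allowed is None:
        allowed = {i + 1: allowed_substitutions(aa) for i, aa in enumerate(seq0)}

    root = _BeamState(seq0, candidate.anchor, (), e0, s0 if use_steepness else None, 0.0)
    if max_mutations == 0:
        return [], candidate

    def cons_weight(mutations: tuple[MutationProposal, ...]) -> float:
        w = 1.0
        for m in mutations:
            w *= profile[m.position - 1]
        return w

    beam = [root]
    best = root
    finished: list[_BeamState] = []
    for _ in range(max_mutations):
        expansions: dict[str, _BeamState] = {}
        for state in beam:
            mutated_positions = {m.position for m in state.mutations}
            for pos in range(1, len(seq0) + 1):
                if pos in mutated_positions or profile[pos - 1] <= 0:
                    continue
                wt = state.sequence[pos - 1]
                for aa in allowed.get(pos, ()):
                    if aa == wt:
                        continue
                    new_anchor = _mutated_anchor(state.anchor, pos, aa)
                    e = eval_energy(new_anchor)
                    prop = MutationProposal(pos, wt, aa, e - e0, 0.0, 0.0)
                    muts = state.mutations + (prop,)
                    seq = state.sequence[:pos - 1] + aa + state.sequence[pos:]
                    # energy-only partial objective for pruning
                    partial = cons_weight(muts) * (e0 - e)
                    cand_state = _BeamState(seq, new_anchor, muts, e, None, partial)
                    prev = expansions.get(seq)
                    if prev is None or cand_state.objective > prev.objective:
                        expansions[seq] = cand_state
        if not expansions:
            break
        survivors = sorted(expansions.values(),
                           key=lambda s: (-s.objective, s.sequence))[:beam_width]
        for state in survivors:
            d_energy = state.energy - e0
            if use_steepness:
                state.steepness = eval_steepness(state.anchor, state.sequence)
                d_steep = state.steepness - s0
            else:
                d_steep = 0.0
            raw = -d_energy + lambda_steepness * d_steep
            state.objective = cons_weight(state.mutations) * raw
            state.mutations = tuple(
                MutationProposal(m.position, m.from_residue, m.to_residue,
                                 d_energy, d_steep, state.objective)
                for m in state.mutations
            )
            if state.objective > best.objective or (
                    state.objective == best.objective
                    and state.sequence < best.sequence and best is not root):
                best = state
        finished.extend(survivors)
        beam = survivors

    finished.sort(key=lambda s: (-s.objective, s.sequence))
    proposals = [s.mutations for s in finished if s.mutations]

    if best is root or best.objective <= 0:
        return proposals, candidate
    best_candidate = PeptideCandidate(
        sequence=best.sequence,
        label=(candidate.label + "-opt") if candidate.label else "optimized",
        source_spans=candidate.source_spans,
        anchor=best.anchor,
        binding_energy=best.energy,
        funnel_steepness=best.steepness,
        c_term_amide=candidate.c_term_amide,
        position_map=dict(candidate.position_map),
    )
    return proposals, best_candidate
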