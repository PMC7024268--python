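"""Interface peptide design: contact detection, stretch excision, joining
and phosphomimetic substitution.

The design logic mirrors how linear-peptide disruptors of a protein-protein
interface are derived from a complex structure: find the ligand-side
residues in contact with the receptor, group them into contiguous sequence
stretches, slide windows over those stretches to excise candidate peptides
(each keeping its parent coordinates as an anchor pose and an initial
binding-energy score), optionally join two stretches that are adjacent in
space into a single longer design, and mimic a phosphoserine by substituting
aspartate or glutamate at the phosphosite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .funnel import EnergyWeights, score_pose
from .structures import Chain, Residue, Structure, chain_sequence

__all__ = [
    "InterfaceSpan",
    "PeptideCandidate",
    "interface_residues",
    "contiguous_stretches",
    "excise_windows",
    "join_stretches",
    "phosphomimetic",
    "build_position_map",
    "rank_candidates",
]

DEFAULT_CONTACT_CUTOFF = 5.0  # A, heavy-atom


@dataclass(frozen=True)
class InterfaceSpan:
    chain_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideCandidate:
    """A designed linear peptide with provenance and scores.

    ``anchor`` holds the excised atoms (a Chain) in the receptor frame when
    the candidate came out of a structure; purely sequence-level designs
    carry ``anchor=None`` and ``source="designed"``.
    """
    sequence: str
    label: str = ""
    source_spans: tuple[InterfaceSpan, ...] = ()
    anchor: Chain | None = None
    binding_energy: float | None = None
    funnel_steepness: float | None = None
    c_term_amide: bool = False
    #: maps source residue numbers to 1-based peptide indices
    position_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("candidate sequence must be non-empty")

    @property
    def source(self) -> str:
        return "designed" if not self.source_spans else "excised"

    def __len__(self) -> int:
        return len(self.sequence)


def interface_residues(
    structure: Structure,
    receptor_chains: Sequence[str],
    ligand_chain: str,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Residue]:
    """Ligand residues with at least one heavy atom within the cutoff of any
    receptor heavy atom."""
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be > 0")
    rec_xyz = [
        a.position
        for cid in receptor_chains
        for r in structure.chain(cid).residues
        for a in r.atoms if a.is_heavy
    ]
    ligand = structure.chain(ligand_chain)
    if not rec_xyz:
        return []
    tree = cKDTree(np.asarray(rec_xyz))
    out = []
    for res in ligand.residues:
        heavy = [a.position for a in res.atoms if a.is_heavy]
        if heavy and np.any(tree.query(np.asarray(heavy))[0] <= contact_cutoff):
            out.append(res)
    return out


def contiguous_stretches(residues: Sequence[Residue], max_gap: int = 0) -> list[InterfaceSpan]:
    """Group residues of one chain into maximal runs of consecutive numbers.

    Two consecutive members belong to the same stretch when their residue
    numbers differ by at most ``max_gap + 1``; e.g. numbers {4..15, 119..130}
    at ``max_gap=0`` give the two spans 4-15 and 119-130.
    """
    if not residues:
        return []
    chains = {r.chain_id for r in residues}
    if len(chains) > 1:
        raise ValueError(f"residues span multiple chains: {sorted(chains)}")
    ordered = sorted(residues, key=lambda r: r.key)
    runs: list[list[Residue]] = [[ordered[0]]]
    for res in ordered[1:]:
        if res.number - runs[-1][-1].number <= max_gap + 1:
            runs[-1].append(res)
        else:
            runs.append([res])
    return [
        InterfaceSpan(
            chain_id=run[0].chain_id,
            start=run[0].number,
            end=run[-1].number,
            sequence="".join(r.one_letter for r in run),
        )
        for run in runs
    ]


def excise_windows(
    structure: Structure,
    ligand_chain: str,
    spans: Sequence[InterfaceSpan],
    lengths: tuple[int, int],
    receptor_chains: Sequence[str] | None = None,
    weights: EnergyWeights = EnergyWeights(),
) -> list[PeptideCandidate]:
    """Slide windows of every requested length over each span and excise
    candidates with their anchor pose and binding energy.

    A span shorter than the minimum window length is skipped with a warning.
    When ``receptor_chains`` is given each candidate is scored in place with
    :func:`pepdisrupt.funnel.score_pose`.
    """
    lo, hi = lengths
    if not (3 <= lo <= hi <= 30):
        raise ValueError(f"window lengths must lie within [3, 30], got {lengths}")
    ligand = structure.chain(ligand_chain)
    candidates = []
    for span in spans:
        span_res = [r for r in ligand.residues if span.start <= r.number <= span.end]
        if len(span_res) < lo:
            warnings.warn(
                f"span {span.chain_id}:{span.start}-{span.end} shorter than "
                f"minimum window length {lo}; skipped",
                stacklevel=2,
            )
            continue
        for length in range(lo, min(hi, len(span_res)) + 1):
            for i in range(len(span_res) - length + 1):
                window = span_res[i:i + length]
                anchor = Chain(ligand_chain, [
                    Residue(
                        chain_id=r.chain_id, number=r.number, name3=r.name3,
                        icode=r.icode, one_letter=r.one_letter,
                        modification=r.modification,
                        atoms=[type(a)(a.name, a.element, a.position.copy())
                               for a in r.atoms],
                    )
                    for r in window
                ])
                cand = PeptideCandidate(
                    sequence="".join(r.one_letter for r in window),
                    label=f"{ligand_chain}{window[0].number}-{window[-1].number}",
                    source_spans=(InterfaceSpan(
                        span.chain_id, window[0].number, window[-1].number,
                        "".join(r.one_letter for r in window)),),
                    anchor=anchor,
                    position_map={r.number: k + 1 for k, r in enumerate(window)},
                )
                if receptor_chains is not None:
                    cand.binding_energy = score_pose(
                        structure, anchor, weights, receptor_chains)
                candidates.append(cand)
    return candidates


def rank_candidates(candidates: Sequence[PeptideCandidate]) -> list[PeptideCandidate]:
    """Rank by model binding energy ascending, ties by sequence."""
    return sorted(
        candidates,
        key=lambda c: (c.binding_energy if c.binding_energy is not None else 0.0,
                       c.sequence),
    )


def join_stretches(
    seq_a: str,
    seq_b: str,
    n_term_extension: str = "",
    c_term_amide: bool = False,
    spans: Sequence[InterfaceSpan] = (),
    label: str = "",
) -> PeptideCandidate:
    """Join two interface stretches into one linear design.

    The designed sequence is ``n_term_extension + seq_a + seq_b``; a
    C-terminal amide (the standard product of solid-phase synthesis on a
    Rink amide resin) is recorded as a modification flag.  When source spans
    are supplied, a residue-number -> peptide-index map is attached so that
    phosphosites can be addressed by their author numbering.
    """
    if not seq_a or not seq_b:
        raise ValueError("both stretch sequences must be non-empty")
    sequence = n_term_extension + seq_a + seq_b
    return PeptideCandidate(
        sequence=sequence,
        label=label or f"joined-{len(sequence)}mer",
        source_spans=tuple(spans),
        c_term_amide=c_term_amide,
        position_map=build_position_map(spans, len(n_term_extension)) if spans else {},
    )


def build_position_map(spans: Sequence[InterfaceSpan], n_term_extension_len: int = 0) -> dict[int, int]:
    """Map source residue numbers onto 1-based peptide indices after joining."""
    mapping: dict[int, int] = {}
    offset = n_term_extension_len
    for span in spans:
        for k, number in enumerate(range(span.start, span.end + 1)):
            mapping[number] = offset + k + 1
        offset += len(span)
    return mapping


PHOSPHORYLATABLE = set("STY")
PHOSPHOMIMETIC_REPLACEMENTS = set("SDE")


def phosphomimetic(
    sequence: str,
    source_position: int,
    position_map: dict[int, int],
    replacement: str,
) -> str:
    """Substitute a phosphosite by S (identity), D or E.

    Aspartate/glutamate carry a negative charge at physiological pH and are
    the standard proxies for a phosphorylated serine when synthesizing
    unphosphorylated peptide; replacement 'S' leaves the sequence unchanged.
    """
    if replacement not in PHOSPHOMIMETIC_REPLACEMENTS:
        raise ValueError(f"replacement must be one of S/D/E, got {replacement!r}")
    if source_position not in position_map:
        raise KeyError(f"source position {source_position} not in position map")
    index = position_map[source_position]  # 1-based
    if not (1 <= index <= len(sequence)):
        raise IndexError(f"mapped index {index} outside sequence of length {len(sequence)}")
    original = sequence[index - 1]
    if original not in PHOSPHORYLATABLE:
        raise ValueError(
            f"residue {original!r} at mapped position {index} is not phosphorylatable")
    return sequence[:index - 1] + replacement + sequence[index:]
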