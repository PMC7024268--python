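"""Synthesis-facing peptide characterization: masses and ESI charge series.

Computes average and monoisotopic molecular masses of linear peptides with
C-terminal amidation (the product of Fmoc synthesis on a Rink amide resin)
and optional phosphorylation, plus the multiply protonated ESI-MS series
[M+nH]n+ observed in positive-ion mode at m/z = (M + n*m_H)/n.

Mass arithmetic is done at the elemental-composition level through
pyteomics, so the amide correction is exactly the OH -> NH2 substitution
(-0.98402 Da monoisotopic) and a phosphosite adds HPO3 (+79.96633 Da
monoisotopic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "ModifiedPeptide",
    "MassReport",
    "PROTON_MASS",
    "average_mass",
    "monoisotopic_mass",
    "esi_series",
    "mass_report",
]

PROTON_MASS = 1.00728  # Da

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

# elemental deltas applied to the free-acid peptide composition
_AMIDE_DELTA = {"N": 1, "H": 1, "O": -1}      # COOH -> CONH2
_PHOSPHO_DELTA = {"H": 1, "P": 1, "O": 3}     # +HPO3


@dataclass(frozen=True)
class ModifiedPeptide:
    """A linear peptide with terminal state and per-position modifications.

    ``modifications`` maps 1-based positions to modification labels; only
    ``"phospho"`` (legal on S/T/Y) is currently recognized.
    """
    sequence: str
    c_term_amide: bool = False
    modifications: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CANONICAL
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty sequence")
        for pos, label in self.modifications.items():
            if not (1 <= pos <= len(self.sequence)):
                raise IndexError(f"modification position {pos} outside sequence")
            if label != "phospho":
                raise ValueError(f"unknown modification {label!r}")
            if self.sequence[pos - 1] not in "STY":
                raise ValueError(
                    f"phospho on {self.sequence[pos - 1]!r} at position {pos}; "
                    "only S/T/Y allowed")


def _coerce(peptide: ModifiedPeptide | str, c_term_amide: bool = False,
            modifications: Mapping[int, str] | None = None) -> ModifiedPeptide:
    if isinstance(peptide, ModifiedPeptide):
        return peptide
    return ModifiedPeptide(peptide, c_term_amide, modifications or {})


def _composition(peptide: ModifiedPeptide) -> _pmass.Composition:
    comp = _pmass.Composition(sequence=peptide.sequence)
    if peptide.c_term_amide:
        comp += _AMIDE_DELTA
    for _ in [p for p, label in peptide.modifications.items() if label == "phospho"]:
        comp += _PHOSPHO_DELTA
    return comp


def average_mass(peptide: ModifiedPeptide | str, c_term_amide: bool = False,
                 modifications: Mapping[int, str] | None = None) -> float:
    """Average (isotope-abundance-weighted) molecular mass in Da."""
    pep = _coerce(peptide, c_term_amide, modifications)
    return _pmass.calculate_mass(composition=_composition(pep), average=True)


def monoisotopic_mass(peptide: ModifiedPeptide | str, c_term_amide: bool = False,
                      modifications: Mapping[int, str] | None = None) -> float:
    """Monoisotopic molecular mass in Da."""
    pep = _coerce(peptide, c_term_amide, modifications)
    return _pmass.calculate_mass(composition=_composition(pep), average=False)


def esi_series(mass_da: float, charges: Sequence[int] = (1, 2, 3, 4)) -> dict[int, float]:
    """m/z of the [M+nH]n+ ions: (M + n * 1.00728) / n for each charge n."""
    out = {}
    for n in charges:
        if n < 1:
            raise ValueError(f"charge must be >= 1, got {n}")
        out[n] = (mass_da + n * PROTON_MASS) / n
    return out


@dataclass
class MassReport:
    """Masses and per-charge ESI m/z series for one peptide (a Table-row analogue)."""
    sequence: str
    c_term_amide: bool
    average: float
    monoisotopic: float
    esi_average: dict[int, float]
    esi_monoisotopic: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "c_term_amide": self.c_term_amide,
            "average_mass": round(self.average, 4),
            "monoisotopic_mass": round(self.monoisotopic, 4),
            "esi_average": {str(n): round(v, 4) for n, v in self.esi_average.items()},
            "esi_monoisotopic": {str(n): round(v, 4)
                                 for n, v in self.esi_monoisotopic.items()},
        }


def mass_report(
    sequence: str,
    c_term_amide: bool = True,
    modifications: Mapping[int, str] | None = None,
    charges: Sequence[int] = (1, 2, 3, 4),
) -> MassReport:
    """Assemble both masses and their ESI charge series for one peptide.

    Experimental characterization tables are ambiguous about whether a
    quoted molecular weight is average or monoisotopic, so the report
    carries both and an m/z series for each.
    """
    pep = ModifiedPeptide(sequence, c_term_amide, modifications or {})
    avg = average_mass(pep)
    mono = monoisotopic_mass(pep)
    return MassReport(
        sequence=sequence,
        c_term_amide=c_term_amide,
        average=avg,
        monoisotopic=mono,
        esi_average=esi_series(avg, charges),
        esi_monoisotopic=esi_series(mono, charges),
    )
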