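"""End-to-end orchestration: hbonds -> excise -> funnel -> optimize -> chem.

A :class:`DesignConfig` (parsed from a flat TOML file or built in code)
drives the five stages; every stage writes its TSV/JSON artifacts into the
output directory as it completes, so a failing stage leaves earlier outputs
on disk.  One master seed derives all stage seeds, making re-runs with the
same config byte-identical on all tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

from . import __version__
from .chem import mass_report
from .design import (DEFAULT_CONTACT_CUTOFF, contiguous_stretches,
                     excise_windows, interface_residues, rank_candidates)
from .funnel import (EnergyWeights, RRTParams, funnel_steepness, is_binder,
                     rrt_explore)
from .hbonds import HBondCriteria, persistence, persistence_table
from .mutate import ConservationProfile, conservation_scores, optimize
from .structures import read_pdb, read_fasta

logger = logging.getLogger("pepdisrupt")

__all__ = ["DesignConfig", "RunReport", "PipelineStageError",
           "parse_config", "serialize_config", "run_pipeline"]

STAGES = ("hbonds", "excise", "funnel", "optimize", "chem")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DesignConfig:
    structure: str = ""
    ensemble: str = ""              # optional multi-model PDB
    msa: str = ""                   # optional FASTA alignment
    receptor_chains: tuple[str, ...] = ("R",)
    ligand_chain: str = "P"
    hbond_max_distance: float = 3.5
    hbond_min_angle: float = 120.0
    min_percent: float = 0.0
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    length_min: int = 10
    length_max: int = 15
    w_hbond: float = -2.0
    w_contact: float = -0.5
    w_clash: float = 10.0
    rrt_max_nodes: int = 500
    rrt_translation_step: float = 0.5
    rrt_rotation_step: float = 5.0
    rrt_dihedral_step: float = 10.0
    rrt_rmsd_max: float = 3.0
    beam_width: int = 10
    max_mutations: int = 2
    lambda_steepness: float = 1.0
    optimizer_rrt_nodes: int = 100  # short RRT for steepness re-evaluation
    seed: int = 0
    output_dir: str = "pepdisrupt-out"
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.receptor_chains, (list, str)):
            chains = (self.receptor_chains.split(",")
                      if isinstance(self.receptor_chains, str)
                      else self.receptor_chains)
            self.receptor_chains = tuple(c.strip() for c in chains if c.strip())
        if isinstance(self.skip_stages, (list, str)):
            skips = (self.skip_stages.split(",") if isinstance(self.skip_stages, str)
                     else self.skip_stages)
            self.skip_stages = tuple(s.strip() for s in skips if s.strip())
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip_stages: {sorted(unknown)}")

    @property
    def weights(self) -> EnergyWeights:
        return EnergyWeights(self.w_hbond, self.w_contact, self.w_clash)

    @property
    def criteria(self) -> HBondCriteria:
        return HBondCriteria(self.hbond_max_distance, self.hbond_min_angle)

    def rrt_params(self, seed: int, max_nodes: int | None = None) -> RRTParams:
        return RRTParams(
            max_nodes=max_nodes or self.rrt_max_nodes,
            translation_step=self.rrt_translation_step,
            rotation_step=self.rrt_rotation_step,
            dihedral_step=self.rrt_dihedral_step,
            rmsd_max=self.rrt_rmsd_max,
            seed=seed,
        )


def parse_config(path: str | Path) -> DesignConfig:
    """Parse a flat TOML key-value file; unknown keys are an error."""
    raw = tomllib.loads(Path(path).read_text())
    known = {f.name: f for f in fields(DesignConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        f = known[key]
        if f.type in ("int",) and isinstance(value, float) and not value.is_integer():
            raise TypeError(f"config key {key!r}: expected integer, got {value!r}")
        kwargs[key] = value
    try:
        return DesignConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise type(exc)(f"invalid config: {exc}") from exc


def serialize_config(config: DesignConfig) -> str:
    """Flat TOML text that :func:`parse_config` parses back to an equal config."""
    lines = []
    for f in fields(DesignConfig):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = list(value)
        lines.append(f"{f.name} = {json.dumps(value)}")
    return "\n".join(lines) + "\n"


@dataclass
class RunReport:
    config: DesignConfig
    persistence_records: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    funnel_stats: dict = field(default_factory=dict)
    proposals: list = field(default_factory=list)
    mass_reports: list = field(default_factory=list)
    stages_run: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package": "pepdisrupt",
                "version": __version__,
                "seed": self.config.seed,
                "config": dataclasses.asdict(self.config),
            },
            "stages_run": self.stages_run,
            "persistence": [
                {"pair": r.pair_label, "percent": round(r.percent, 2)}
                for r in self.persistence_records
            ],
            "candidates": [
                {"label": c.label, "sequence": c.sequence,
                 "energy": None if c.binding_energy is None
                 else round(c.binding_energy, 6)}
                for c in self.candidates
            ],
            "funnel": self.funnel_stats,
            "proposals": self.proposals,
            "masses": self.mass_reports,
        }


def _stage_seed(master: int, stage: str) -> int:
    return (master * 10007 + STAGES.index(stage) + 1) % (2 ** 31)


def run_pipeline(config: DesignConfig) -> RunReport:
    """Execute the design pipeline; see module docstring for stage order."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    logger.info(
        "defaults in effect: hbond criteria (%.2f A, %.1f deg), contact "
        "cutoff %.2f A, weights (hb=%.2f, ct=%.2f, cl=%.2f), RRT steps "
        "(%.2f A, %.1f deg, %.1f deg), seed %d",
        config.hbond_max_distance, config.hbond_min_angle,
        config.contact_cutoff, config.w_hbond, config.w_contact,
        config.w_clash, config.rrt_translation_step, config.rrt_rotation_step,
        config.rrt_dihedral_step, config.seed)

    structure = read_pdb(config.structure).topology
    if not structure.has_chain(config.ligand_chain):
        raise KeyError(f"no ligand chain {config.ligand_chain!r} in "
                       f"{config.structure}")
    for cid in config.receptor_chains:
        if not structure.has_chain(cid):
            raise KeyError(f"no receptor chain {cid!r} in {config.structure}")

    def run_stage(name: str) -> bool:
        if name in config.skip_stages:
            logger.info("stage %s skipped by config", name)
            return False
        logger.info("stage %s", name)
        report.stages_run.append(name)
        return True

    try:
        if config.ensemble and run_stage("hbonds"):
            ensemble = read_pdb(config.ensemble)
            records = persistence(
                ensemble, set(config.receptor_chains), {config.ligand_chain},
                config.criteria, config.min_percent)
            report.persistence_records = records
            persistence_table(records, outdir / "persistence.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("hbonds", exc) from exc

    best = None
    try:
        if run_stage("excise"):
            contacts = interface_residues(
                structure, config.receptor_chains, config.ligand_chain,
                config.contact_cutoff)
            spans = contiguous_stretches(contacts)
            lengths = (config.length_min, config.length_max)
            candidates = excise_windows(
                structure, config.ligand_chain, spans, lengths,
                receptor_chains=config.receptor_chains, weights=config.weights)
            candidates = rank_candidates(candidates)
            report.candidates = candidates
            lines = ["label\tspan\tsequence\tenergy"]
            for c in candidates:
                span = ",".join(f"{s.chain_id}:{s.start}-{s.end}"
                                for s in c.source_spans)
                lines.append(f"{c.label}\t{span}\t{c.sequence}\t"
                             f"{c.binding_energy:.6f}")
            (outdir / "candidates.tsv").write_text("\n".join(lines) + "\n")
            best = candidates[0] if candidates else None
    except Exception as exc:
        raise PipelineStageError("excise", exc) from exc

    try:
        if best is not None and run_stage("funnel"):
            params = config.rrt_params(_stage_seed(config.seed, "funnel"))
            samples = rrt_explore(structure, best.anchor, params,
                                  config.weights, config.receptor_chains)
            stats = funnel_steepness(samples)
            stats.binder = is_binder(stats, len(best))
            best.funnel_steepness = stats.slope
            report.funnel_stats = {
                "candidate": best.label,
                "slope": round(stats.slope, 6),
                "intercept": round(stats.intercept, 6),
                "r_squared": round(stats.r_squared, 6),
                "n_samples": stats.n_samples,
                "binder": stats.binder.value,
            }
            lines = ["rmsd\tenergy"]
            lines += [f"{s.rmsd:.6f}\t{s.energy:.6f}" for s in samples]
            (outdir / "funnel.tsv").write_text("\n".join(lines) + "\n")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("funnel", exc) from exc

    optimized = None
    try:
        if best is not None and run_stage("optimize"):
            if config.msa:
                profile = conservation_scores(read_fasta(config.msa))
                if len(profile) != len(best):
                    # MSA covers the ligand chain; cut the window's columns
                    lo = best.source_spans[0].start
                    first = structure.chain(config.ligand_chain).residues[0].number
                    start = lo - first
                    profile = ConservationProfile(
                        profile.scores[start:start + len(best)])
            else:
                profile = ConservationProfile([1.0] * len(best))
            proposals, optimized = optimize(
                best, profile, structure,
                weights=config.weights,
                rrt_params=config.rrt_params(
                    _stage_seed(config.seed, "optimize"),
                    max_nodes=config.optimizer_rrt_nodes),
                beam_width=config.beam_width,
                max_mutations=config.max_mutations,
                seed=_stage_seed(config.seed, "optimize"),
                lambda_steepness=config.lambda_steepness,
                receptor_chains=config.receptor_chains,
            )
            report.proposals = [
                [{"position": m.position, "from": m.from_residue,
                  "to": m.to_residue, "objective": round(m.objective, 6)}
                 for m in mset]
                for mset in proposals
            ]
            lines = ["rank\tmutations\tobjective"]
            for i, mset in enumerate(proposals, 1):
                muts = ",".join(f"{m.from_residue}{m.position}{m.to_residue}"
                                for m in mset)
                lines.append(f"{i}\t{muts}\t{mset[0].objective:.6f}")
            (outdir / "proposals.tsv").write_text("\n".join(lines) + "\n")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("optimize", exc) from exc

    try:
        if run_stage("chem"):
            targets = [c for c in (best, optimized) if c is not None]
            reports = [mass_report(c.sequence, c_term_amide=True) for c in targets]
            report.mass_reports = [r.to_dict() for r in reports]
            lines = ["sequence\taverage\tmonoisotopic\tmh1"]
            for r in reports:
                lines.append(f"{r.sequence}\t{r.average:.2f}\t"
                             f"{r.monoisotopic:.2f}\t{r.esi_monoisotopic[1]:.2f}")
            (outdir / "masses.tsv").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise PipelineStageError("chem", exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return report
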