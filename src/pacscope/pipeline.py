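"""End-to-end orchestration: simulate -> detect -> reorganize -> digest -> propagate.

A :class:`RunConfig` fully determines a run given identical inputs; the
:class:`RunManifest` written at the end snapshots the config, checksums
every artefact and records the headline results, so two runs with the same
config and seed are comparable field by field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import detect as _detect
from . import digest as _digest
from . import io as _io
from . import phylo as _phylo
from . import simulate as _sim

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "StageError",
    "validate_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """A configuration value failed validation; the message names the field."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` has the why."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline parameters with study-condition defaults."""

    # stage toggles
    do_simulate: bool = True
    do_detect: bool = True
    do_reorganize: bool = True
    do_digest: bool = True
    do_propagate: bool = False
    write_reads: bool = True  # FASTQ/SAM output for the simulated library

    # simulator
    strategy: str = "headful_pac"
    genome_length: int = _sim.DEFAULT_GENOME_LENGTH
    gc: float = _sim.DEFAULT_GC
    pac_position: int = 1
    headful_factor: float = 1.04
    headful_sd_frac: float = 0.005
    series_length: int = 4
    dtr_length: int = 500
    overhang_length: int = 12
    frag_mean: float = 550.0
    frag_sd: float = 55.0
    read_length: int = 251
    depth: float = 200.0

    # detector thresholds
    min_ratio: float = 5.0
    min_top_count: int = 20
    max_poisson_p: float = 1e-6
    dtr_coverage_factor: float = 1.5

    # digestion criteria
    gel_min: int = 250
    gel_max: int = 10_000
    distinguish_tol: float = 0.15
    faint_max: int = 400

    # propagation
    support_threshold: float = 95.0

    # external inputs (used when the corresponding stage is not simulated)
    genome_path: Optional[str] = None
    alignments_path: Optional[str] = None
    tree_path: Optional[str] = None
    labels_path: Optional[str] = None

    seed: int = 1
    out_dir: str = "pacscope_run"

    def check(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError("gc must be within [0, 1]")
        if self.genome_length < 1:
            raise ConfigError("genome_length must be >= 1")
        if self.headful_factor <= 1.0:
            raise ConfigError(
                "headful_factor must exceed 1 (the headful must exceed the genome length)"
            )
        if not 1 <= self.pac_position <= self.genome_length:
            raise ConfigError("pac_position must lie within the genome")
        for name in ("depth", "frag_mean", "frag_sd", "read_length", "series_length",
                     "min_ratio", "min_top_count", "max_poisson_p", "dtr_coverage_factor",
                     "gel_min", "gel_max", "distinguish_tol", "faint_max",
                     "dtr_length", "overhang_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.support_threshold <= 100:
            raise ConfigError("support_threshold must be within [0, 100]")
        try:
            _sim.Strategy(self.strategy)
        except ValueError:
            raise ConfigError(
                f"strategy must be one of {[s.value for s in _sim.Strategy]}"
            ) from None


def validate_config(raw: str | dict | None) -> RunConfig:
    """Build a RunConfig from YAML text or a dict; unknown keys are errors."""
    if raw is None:
        data: dict[str, Any] = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of parameter: value")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**data)
    cfg.check()
    return cfg


@dataclass
class RunManifest:
    config: dict
    checksums: dict[str, str] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stages_run: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order under ``config.out_dir``.

    A stage failure raises :class:`StageError` naming the stage; artefacts
    from completed stages are retained.
    """
    config.check()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))

    def checkpoint(path: Path) -> None:
        manifest.checksums[path.name] = _sha256(path)

    genome: Optional[_sim.CircularGenome] = None
    alignments = None
    call: Optional[_detect.TerminiCall] = None

    def stage(name):
        def deco(fn):
            if not getattr(config, f"do_{name}", True):
                return None
            t0 = time.perf_counter()
            _log(f"[pacscope] {name} ...")
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 — rewrapped with the stage name
                raise StageError(name, exc) from exc
            manifest.stages_run.append(name)
            _log(f"[pacscope] {name} done in {time.perf_counter() - t0:.1f}s")
            return None
        return deco

    @stage("simulate")
    def _simulate():
        nonlocal genome, alignments
        H = int(round(config.headful_factor * config.genome_length))
        sim = _sim.simulate(
            config.strategy,
            genome_length=config.genome_length,
            gc=config.gc,
            seed=config.seed,
            depth=config.depth,
            frag_mean=config.frag_mean,
            frag_sd=config.frag_sd,
            read_length=config.read_length,
            pac_position=config.pac_position,
            headful_length=H,
            headful_sd=config.headful_sd_frac * H,
            series_length=config.series_length,
            dtr_length=config.dtr_length,
            overhang_length=config.overhang_length,
        )
        genome, alignments = sim.genome, sim.reads
        _io.write_fasta(genome, out / "reference.fasta")
        checkpoint(out / "reference.fasta")
        _io.write_manifest_tsv(sim.molecules, config.strategy, out / "molecules.tsv")
        checkpoint(out / "molecules.tsv")
        _io.write_alignment_tsv(sim.reads, out / "alignments.tsv")
        checkpoint(out / "alignments.tsv")
        if config.write_reads:
            for p in _io.write_fastq_pair(sim.reads, genome, out / "reads"):
                checkpoint(p)
            _io.write_sam(sim.reads, genome, out / "alignments.sam")
            checkpoint(out / "alignments.sam")
        manifest.results["n_molecules"] = len(sim.molecules)
        manifest.results["n_reads"] = len(sim.reads)

    def _load_inputs():
        nonlocal genome, alignments
        if genome is None:
            if not config.genome_path:
                raise ValueError("genome_path required when the simulate stage is off")
            genome = _io.read_fasta(config.genome_path)
        if alignments is None:
            if not config.alignments_path:
                raise ValueError("alignments_path required when the simulate stage is off")
            ap = str(config.alignments_path)
            if ap.endswith((".sam", ".bam")):
                alignments = _io.read_sam_alignments(ap)
            else:
                alignments = _io.read_alignment_tsv(ap)

    @stage("detect")
    def _detect_stage():
        nonlocal call
        _load_inputs()
        profiles = _detect.compute_spc(alignments, genome.length)
        params = _detect.DetectionParams(
            min_ratio=config.min_ratio,
            min_top_count=config.min_top_count,
            max_poisson_p=config.max_poisson_p,
            dtr_coverage_factor=config.dtr_coverage_factor,
        )
        call = _detect.detect_termini(profiles, params)
        if profiles.n_alignments == 0:
            manifest.warnings.append("zero alignments: termini call is UNDETERMINED")
        _io.write_profiles_tsv(profiles, out / "spc.tsv")
        checkpoint(out / "spc.tsv")
        _io.write_call_json(call, out / "call.json")
        checkpoint(out / "call.json")
        manifest.results["strategy_call"] = call.strategy_call
        if call.pac:
            manifest.results["pac_position"] = call.pac.position
            manifest.results["peak_ratio"] = call.pac.ratio
        if call.left_terminus:
            manifest.results["left_terminus"] = call.left_terminus.position
            manifest.results["right_terminus"] = call.right_terminus.position
        manifest.results["mean_depth"] = round(call.mean_depth, 1)
        if call.low_coverage_warning:
            manifest.warnings.append(
                f"mean depth {call.mean_depth:.0f}x below "
                f"{_detect.LOW_COVERAGE_DEPTH:.0f}x; termini calls may be unreliable"
            )

    reorganized: Optional[str] = None

    @stage("reorganize")
    def _reorganize():
        nonlocal reorganized
        if call is None or genome is None:
            raise ValueError("reorganize requires the detect stage (or a pac call)")
        peak = call.pac or call.left_terminus
        if peak is None:
            manifest.warnings.append("no terminus detected; genome left unrotated")
            reorganized = genome.sequence
            return
        reorganized = _detect.reorganize(genome.sequence, peak.position, peak.strand)
        reorg = _sim.CircularGenome(id=f"{genome.id}_pac_organized", sequence=reorganized)
        _io.write_fasta(reorg, out / "reorganized.fasta")
        checkpoint(out / "reorganized.fasta")
        manifest.results["reorganized_at"] = peak.position

    @stage("digest")
    def _digest_stage():
        target = reorganized if reorganized is not None else (
            genome.sequence if genome else None
        )
        if target is None:
            raise ValueError("digest requires a genome")
        criteria = _digest.SelectionCriteria(
            gel_min=config.gel_min,
            gel_max=config.gel_max,
            distinguish_tol=config.distinguish_tol,
            faint_max=config.faint_max,
        )
        reports = _digest.select_enzymes(target, criteria=criteria)
        with open(out / "digest.json", "w") as fh:
            json.dump([r.as_dict() for r in reports], fh, indent=2)
            fh.write("\n")
        checkpoint(out / "digest.json")
        best = reports[0]
        manifest.results["chosen_enzyme"] = best.enzyme.name
        manifest.results["pac_fragment_length"] = best.pac_fragment_length
        for rep in reports:
            if _digest.FLAG_NO_SITES in rep.flags:
                manifest.warnings.append(f"{rep.enzyme.name}: no recognition sites")

    @stage("propagate")
    def _propagate():
        if not config.tree_path or not config.labels_path:
            raise ValueError("propagate requires tree_path and labels_path")
        labels = _phylo.read_label_table(config.labels_path)
        tree = _phylo.read_tree(Path(config.tree_path).read_text(), labels)
        result = _phylo.propagate_labels(tree, config.support_threshold)
        with open(out / "clades.json", "w") as fh:
            json.dump(result.as_dict(), fh, indent=2)
            fh.write("\n")
        checkpoint(out / "clades.json")
        report = _phylo.clade_report(result, tree)
        report.to_csv(out / "clade_report.tsv", sep="\t", index=False)
        checkpoint(out / "clade_report.tsv")
        manifest.results["propagation"] = {
            "n_propagated": len(result.assigned),
            "n_conflicts": len(result.conflicts),
            "n_unassigned": len(result.unassigned_tips),
        }
        for strat, tip, lab in result.conflicts:
            manifest.warnings.append(
                f"strategy '{strat}' clade impure: {tip} is labeled '{lab}'"
            )

    manifest.write(out / "manifest.json")
    return manifest
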