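"""Pipeline orchestration: simulate -> analyze -> report.

``run_all`` wires the simulator to the three analysis stages and writes
every artifact (FASTA/FASTQ/SAM/BED/TSV/JSON) plus a machine-parseable
run report. Outputs carry no timestamps, so a fixed seed yields
byte-identical runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._util import sha256_of_text
from . import dgr as dgr_mod
from . import packaging as pkg_mod
from . import simcore
from . import transposition as tx_mod
from .config import AnalysisParams, SimConfig

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def prevalence(positives: int, total: int) -> int:
    """Percentage of positives, rounded half away from zero to an integer."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= positives <= total):
        raise ValueError("positives must be in [0, total]")
    x = 100.0 * positives / total
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class RunConfig:
    """Everything a full run needs: simulation, analysis and stage toggles."""

    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    outdir: Path = Path("prophagedyn_out")
    run_transposition: bool = True
    run_dgr: bool = True
    run_packaging: bool = True
    n_amplicon_reads: int = 1_000

    def config_hash(self) -> str:
        payload = self.sim.to_json() + json.dumps(
            {
                "analysis": self.analysis.__dict__,
                "stages": [self.run_transposition, self.run_dgr, self.run_packaging],
                "n_amplicon_reads": self.n_amplicon_reads,
            },
            sort_keys=True,
        )
        return sha256_of_text(payload)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_all(cfg: RunConfig) -> dict:
    """Execute enabled stages in dependency order and write all artifacts.

    Returns the run report (also written as ``report.json``). On stage
    failure, partial outputs are retained next to a ``FAILED_<stage>``
    marker file and a :class:`StageError` is raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": cfg.sim.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            def wrapper():
                try:
                    logger.info("[%s] running", name)
                    return fn()
                except Exception as exc:
                    (outdir / f"FAILED_{name}").write_text(f"{type(exc).__name__}: {exc}\n")
                    raise StageError(f"stage '{name}' failed: {exc}") from exc

            return wrapper

        return deco

    @_stage("simulate-genome")
    def _genome():
        genome = simcore.make_genome(cfg.sim)
        genome.write_fasta(outdir / "chromosome.fasta", outdir / "prophage.fasta")
        return genome

    genome = _genome()
    (outdir / "config.json").write_text(cfg.sim.to_json() + "\n")

    if cfg.run_transposition:

        @_stage("transposition")
        def _transposition():
            truth = simcore.plant_transpositions(genome, cfg.sim.n_events, cfg.sim.seed, cfg.sim)
            paths = simcore.emit_junction_reads(genome, truth, cfg.sim, outdir)
            table = tx_mod.detect_junctions(
                paths["sam"],
                genome.chromosome_seq,
                min_clip=cfg.analysis.min_clip,
                exclude_interval=(
                    genome.prophage_interval[0] - cfg.sim.read_length,
                    genome.prophage_interval[1] + cfg.sim.read_length,
                ),
            )
            tx_mod.junction_report(
                table, bed_path=outdir / "junctions.bed", tsv_path=outdir / "junctions_summary.tsv"
            )
            detected = {(int(r.coordinate), r.orientation) for r in table.rows.itertuples()}
            planted = set(truth.junctions)
            return {
                "total_events": table.total_events,
                "total_supporting_reads": table.total_supporting_reads,
                "discarded_multi": table.discarded_multi,
                "discarded_nomatch": table.discarded_nomatch,
                "fraction_multi": table.fraction_multi,
                "planted_events": len(planted),
                "recovered_planted": len(detected & planted),
                "false_positives": len(detected - planted),
            }

        report["stages"]["transposition"] = _transposition()

    if cfg.run_dgr:

        @_stage("dgr")
        def _dgr():
            paths = simcore.emit_vr_amplicons(genome, cfg.sim, cfg.n_amplicon_reads, outdir)
            matrix, profile, call = dgr_mod.analyze_amplicons(
                paths["fastq"],
                genome.vr_seq,
                genome.tr_sequence,
                genome.primer_fwd,
                genome.primer_rev,
                min_spanning=cfg.analysis.min_spanning,
            )
            profile.to_frame(matrix).to_csv(outdir / "vr_profile.tsv", sep="\t", index=False)
            (outdir / "activity_call.json").write_text(call.to_json() + "\n")
            enrichment, finite = dgr_mod.fold_enrichment(profile)
            return {
                "n_spanning_reads": matrix.n_spanning_reads,
                "n_discarded_length": matrix.n_discarded_length,
                "mean_pi_A": call.mean_pi_A,
                "mean_pi_nonA": call.mean_pi_nonA,
                "sd_pi_nonA": call.sd_pi_nonA,
                "threshold": call.threshold,
                "active": call.active,
                "status": call.status,
                "fold_enrichment": enrichment if finite else None,
            }

        report["stages"]["dgr"] = _dgr()

    if cfg.run_packaging:

        @_stage("packaging")
        def _packaging():
            paths, _truth = simcore.emit_capsid_reads(genome, cfg.sim, outdir, write_fastq=False)
            profile, summary = pkg_mod.analyze_packaging(
                paths["sam"],
                genome.prophage_interval,
                len(genome.chromosome_seq),
                window=cfg.analysis.window,
                frac_threshold=cfg.analysis.frac_threshold,
                flank_min_frac=cfg.analysis.flank_min_frac,
                margin=cfg.analysis.coverage_margin,
            )
            profile.to_frame().to_csv(outdir / "capsid_coverage.tsv", sep="\t", index=False)
            (outdir / "packaging_summary.json").write_text(summary.to_json() + "\n")
            return json.loads(summary.to_json())

        report["stages"]["packaging"] = _packaging()

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
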