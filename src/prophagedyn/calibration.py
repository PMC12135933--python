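"""Parameter-recovery experiments over the simulator's ground truth.

These routines run the full analysis pipelines on freshly simulated
data and compare the results against the planted parameters: the false
positive/negative rates of the DGR activity call, exact recovery of
planted transposition junctions, and recovery of the packaging
survival ratio and host-flank extents. They back both the test suite
and the reproduction script.
"""

from __future__ import annotations

import math
from pathlib import Path

from . import dgr as dgr_mod
from . import packaging as pkg_mod
from . import simcore
from . import transposition as tx_mod
from ._util import stage_rng
from .config import SimConfig


def activity_calibration(
    mu_targeted: float,
    eps_background: float,
    n_datasets: int = 200,
    n_reads: int = 100,
    seed: int = 1,
    min_spanning: int = 30,
) -> float:
    """Fraction of simulated amplicon datasets called DGR-active.

    Each dataset is ``n_reads`` full-span amplicons at the given
    per-read targeted substitution rate and per-base background rate,
    pushed through primer anchoring, allele counting, per-site pi and
    the two-standard-deviation activity rule. With ``mu_targeted=0``
    this measures the false-call rate of the rule under background
    error alone.
    """
    cfg = SimConfig(mu_targeted=mu_targeted, eps_background=eps_background, seed=seed)
    genome = simcore.make_genome(cfg)
    active = 0
    for i in range(n_datasets):
        rng = stage_rng(seed, "amplicons", i)
        reads = simcore.simulate_amplicon_reads(genome, cfg, n_reads, rng=rng)
        segments = dgr_mod.extract_vr_reads(reads, cfg.primer_fwd, cfg.primer_rev)
        matrix = dgr_mod.build_allele_matrix(segments, genome.vr_seq)
        profile = dgr_mod.site_diversity(matrix, genome.targeted_positions)
        call = dgr_mod.call_activity(profile, min_spanning=min_spanning)
        active += int(call.status == "ok" and call.active)
    return active / n_datasets


def junction_recovery(seed: int, workdir: str | Path, n_events: int = 100) -> dict:
    """Plant junctions, emit clipped reads, detect, and compare exactly."""
    cfg = SimConfig(seed=seed, n_events=n_events)
    genome = simcore.make_genome(cfg)
    truth = simcore.plant_transpositions(genome, n_events, seed, cfg)
    paths = simcore.emit_junction_reads(genome, truth, cfg, workdir)
    s, e = genome.prophage_interval
    table = tx_mod.detect_junctions(
        paths["sam"],
        genome.chromosome_seq,
        exclude_interval=(s - cfg.read_length, e + cfg.read_length),
    )
    detected = {(int(r.coordinate), r.orientation) for r in table.rows.itertuples()}
    planted = set(truth.junctions)
    return {
        "planted": len(planted),
        "detected": table.total_events,
        "recovered": len(detected & planted),
        "false_positives": len(detected - planted),
        "fraction_multi": table.fraction_multi,
    }


def packaging_recovery(seed: int, workdir: str | Path) -> dict:
    """Recover the packaging survival ratio and flank extents from reads.

    The termination hazard is calibrated so that surviving the full
    hazard region has probability 1/40; the ideal left/right coverage
    ratio is therefore ``(1 - h)^(-hazard_region)``.
    """
    cfg = SimConfig(seed=seed)
    genome = simcore.make_genome(cfg)
    paths, truth = simcore.emit_capsid_reads(genome, cfg, workdir, write_fastq=False)
    profile, summary = pkg_mod.analyze_packaging(
        paths["sam"], genome.prophage_interval, cfg.chromosome_length
    )
    ideal = (1.0 - cfg.hazard) ** (-cfg.hazard_region)
    return {
        "end_ratio": summary.end_ratio,
        "ideal_ratio": ideal,
        "flank5_support": summary.flank5.support,
        "flank5_mode": summary.flank5.flank_mode,
        "flank3_extent": summary.flank3_extent,
        "flank3_censored": summary.flank3_censored,
        "n_reads": summary.n_mapped,
        "n_molecules": len(truth.molecule_lengths),
    }


def fold_enrichment_recovery(seed: int, n_reads: int = 4_000) -> dict:
    """Estimated vs closed-form targeted/background mutation enrichment.

    Under the simulator's substitution model the expected non-reference
    frequency is ``eps*(1-mu) + mu*(1-eps/3)`` at targeted positions and
    ``eps`` elsewhere.
    """
    cfg = SimConfig(seed=seed)
    genome = simcore.make_genome(cfg)
    rng = stage_rng(seed, "amplicons")
    reads = simcore.simulate_amplicon_reads(genome, cfg, n_reads, rng=rng)
    segments = dgr_mod.extract_vr_reads(reads, cfg.primer_fwd, cfg.primer_rev)
    matrix = dgr_mod.build_allele_matrix(segments, genome.vr_seq)
    profile = dgr_mod.site_diversity(matrix, genome.targeted_positions)
    ratio, finite = dgr_mod.fold_enrichment(profile)
    mu, eps = cfg.mu_targeted, cfg.eps_background
    expected = (eps * (1 - mu) + mu * (1 - eps / 3)) / eps
    return {
        "fold_enrichment": ratio if finite else math.inf,
        "expected": expected,
        "n_reads": matrix.n_spanning_reads,
    }
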