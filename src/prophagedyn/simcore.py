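"""Synthetic genomes, molecules and reads with known ground truth.

Three read-generating stages share one :class:`GenomeModel`:

* junction reads spanning planted replicative-transposition joints,
  emitted as prophage alignments with a leading soft clip that carries
  the chromosomal flank;
* amplicon reads over the DGR variable repeat (VR) with
  adenine-templated hypermutation on top of a uniform background error
  channel;
* capsid reads from a left-initiated headful packaging process with a
  29-31 bp 5' host flank, a per-base termination hazard over the first
  15 kb of the prophage, and a 1-2.3 kb 3' host flank on molecules
  that survive the hazard region.

All stages are deterministic for a fixed master seed; each derives its
generator from the master seed via a fixed stage offset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import BASES, ChunkedWriter, random_dna, revcomp, stage_rng, write_fasta
from .config import ConfigError, SimConfig

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeModel:
    """Host chromosome with an embedded prophage, VR/TR annotation and primers."""

    chromosome_seq: str
    prophage_interval: tuple[int, int]
    vr_interval: tuple[int, int]  # 0-based half-open, within the prophage
    tr_sequence: str
    targeted_positions: np.ndarray  # 0-based indices within the VR
    primer_fwd: str
    primer_rev: str

    @property
    def prophage_seq(self) -> str:
        s, e = self.prophage_interval
        return self.chromosome_seq[s:e]

    @property
    def vr_seq(self) -> str:
        s, e = self.vr_interval
        return self.prophage_seq[s:e]

    @property
    def amplicon_seq(self) -> str:
        """Reference amplicon: primer_fwd + VR + revcomp(primer_rev)."""
        return self.primer_fwd + self.vr_seq + revcomp(self.primer_rev)

    def write_fasta(self, chromosome_path: str | Path, prophage_path: str | Path | None = None) -> None:
        write_fasta(chromosome_path, [("chromosome", self.chromosome_seq)])
        if prophage_path is not None:
            write_fasta(prophage_path, [("prophage", self.prophage_seq)])


@dataclass
class SimTruth:
    """Planted parameters and events, for parameter-recovery tests."""

    junctions: list[tuple[int, str]] = field(default_factory=list)
    mu_targeted: float = 0.0
    eps_background: float = 0.0
    hazard: float = 0.0
    molecule_lengths: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["junctions"] = [[int(c), o] for c, o in self.junctions]
        return json.dumps(d)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def write_bed(self, path: str | Path, name_prefix: str = "junction") -> None:
        """Truth junctions as BED (chrom, start, start+1, name, score, strand)."""
        with open(path, "w") as fh:
            for i, (c, orient) in enumerate(self.junctions):
                fh.write(f"chromosome\t{c}\t{c + 1}\t{name_prefix}_{i}\t0\t{orient}\n")


def make_genome(cfg: SimConfig) -> GenomeModel:
    """Draw a uniform-random chromosome and write in the prophage landmarks.

    The VR is initialised equal to the TR (so "non-reference" and
    "DGR-mutated" coincide at simulation start) and the amplicon primers
    are placed immediately flanking it: ``primer_fwd`` ends at the VR
    start and ``revcomp(primer_rev)`` begins at the VR end.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "genome")
    chrom = np.frombuffer(random_dna(rng, cfg.chromosome_length).encode(), dtype=np.uint8).copy()

    ps = cfg.prophage_start
    vr_start = ps + cfg.vr_offset
    vr_end = vr_start + cfg.vr_length
    chrom[vr_start:vr_end] = np.frombuffer(cfg.tr_sequence.encode(), dtype=np.uint8)
    fwd = cfg.primer_fwd.encode()
    chrom[vr_start - len(fwd) : vr_start] = np.frombuffer(fwd, dtype=np.uint8)
    rc_rev = revcomp(cfg.primer_rev).encode()
    chrom[vr_end : vr_end + len(rc_rev)] = np.frombuffer(rc_rev, dtype=np.uint8)

    targeted = np.flatnonzero(np.frombuffer(cfg.tr_sequence.encode(), dtype=np.uint8) == ord("A"))
    return GenomeModel(
        chromosome_seq=chrom.tobytes().decode(),
        prophage_interval=(ps, ps + cfg.prophage_length),
        vr_interval=(cfg.vr_offset, cfg.vr_offset + cfg.vr_length),
        tr_sequence=cfg.tr_sequence,
        targeted_positions=targeted,
        primer_fwd=cfg.primer_fwd,
        primer_rev=cfg.primer_rev,
    )


def eligible_junction_positions(genome: GenomeModel, cfg: SimConfig) -> np.ndarray:
    """Chromosome positions where a new junction may be planted.

    Excludes the resident prophage plus a read-length margin on each side
    (clips from reads near the native locus would recover the native
    junction, not a new insertion) and a clip-length margin at the
    chromosome ends so every clip window stays in bounds.
    """
    s, e = genome.prophage_interval
    margin = cfg.read_length
    kmax = cfg.clip_length_range[1]
    pos = np.arange(kmax, len(genome.chromosome_seq) - kmax)
    keep = (pos < s - margin) | (pos >= e + margin)
    return pos[keep]


def plant_transpositions(genome: GenomeModel, n_events: int, seed: int, cfg: SimConfig) -> SimTruth:
    """Plant ``n_events`` distinct junctions uniformly outside the prophage.

    The junction coordinate convention is: for '+' orientation, the last
    chromosomal base before the inserted prophage copy; for '-', the
    first chromosomal base adjacent to the prophage start in read
    orientation. The resident copy is untouched (replicative, not
    cut-and-paste).
    """
    rng = stage_rng(seed, "transposition")
    eligible = eligible_junction_positions(genome, cfg)
    if n_events > len(eligible):
        raise ConfigError(
            f"n_events {n_events} exceeds {len(eligible)} eligible chromosome positions"
        )
    coords = rng.choice(eligible, size=n_events, replace=False)
    orients = np.where(rng.integers(0, 2, size=n_events) == 0, "+", "-")
    return SimTruth(
        junctions=[(int(c), str(o)) for c, o in zip(coords, orients)],
        mu_targeted=cfg.mu_targeted,
        eps_background=cfg.eps_background,
        hazard=cfg.hazard,
    )


def _sam_header(ref_name: str, ref_len: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{ref_name}\tLN:{ref_len}"


def emit_junction_reads(
    genome: GenomeModel,
    truth: SimTruth,
    cfg: SimConfig,
    outdir: str | Path,
    prefix: str = "junctions",
) -> dict[str, Path]:
    """Emit junction-spanning reads as FASTQ plus prophage-aligned SAM.

    Each read is ``host_flank + prophage[0 : read_length - k]`` with the
    k-base flank soft-clipped in the SAM record (CIGAR ``kS mM``,
    position 1). A truth BED of the planted junctions is written
    alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(cfg.seed, "junction_reads")
    chrom = genome.chromosome_seq
    pro = genome.prophage_seq
    R = cfg.read_length
    kmin, kmax = cfg.clip_length_range

    fq_path = outdir / f"{prefix}.fastq"
    sam_path = outdir / f"{prefix}.sam"
    bed_path = outdir / f"{prefix}_truth.bed"
    qual = "I" * R
    with ChunkedWriter(fq_path) as fq, ChunkedWriter(sam_path) as sam:
        sam.write(_sam_header("prophage", len(pro)))
        for i, (c, orient) in enumerate(truth.junctions):
            ks = rng.integers(kmin, kmax + 1, size=cfg.reads_per_event)
            for j, k in enumerate(ks):
                k = int(k)
                if orient == "+":
                    clip = chrom[c + 1 - k : c + 1]
                else:
                    clip = revcomp(chrom[c : c + k])
                read = clip + pro[: R - k]
                name = f"junc_{i}_{j}"
                fq.write(f"@{name}\n{read}\n+\n{qual}")
                sam.write(f"{name}\t0\tprophage\t1\t60\t{k}S{R - k}M\t*\t0\t0\t{read}\t{qual}")
    truth.write_bed(bed_path)
    return {"fastq": fq_path, "sam": sam_path, "truth_bed": bed_path}


def simulate_amplicon_reads(
    genome: GenomeModel,
    cfg: SimConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Generate VR amplicon reads in memory.

    Each read spans ``primer_fwd + VR + revcomp(primer_rev)``. At every
    DGR-targeted VR position the base is replaced, with probability
    ``mu_targeted``, by a uniform draw from the other three bases;
    independently, *every* read position (primers included) suffers a
    background substitution with probability ``eps_background``.
    Alternate reads are emitted reverse-complemented.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "amplicons")
    ref = genome.amplicon_seq
    L = len(ref)
    reads = np.tile(np.frombuffer(ref.encode(), dtype=np.uint8), (n_reads, 1))

    def substitute(mask: np.ndarray) -> None:
        # replace masked cells by a uniform draw from the other three bases
        idx = np.nonzero(mask)
        if idx[0].size == 0:
            return
        cur = reads[idx]
        # map current base to its index in BASES, then shift by 1..3
        base_index = np.zeros_like(cur)
        for bi, b in enumerate(BASES.encode()):
            base_index[cur == b] = bi
        shift = rng.integers(1, 4, size=cur.size)
        reads[idx] = _BASE_ARR[(base_index + shift) % 4]

    targeted_cols = len(genome.primer_fwd) + genome.targeted_positions
    if cfg.mu_targeted > 0 and targeted_cols.size:
        mask = np.zeros((n_reads, L), dtype=bool)
        mask[:, targeted_cols] = rng.random((n_reads, targeted_cols.size)) < cfg.mu_targeted
        substitute(mask)
    if cfg.eps_background > 0:
        substitute(rng.random((n_reads, L)) < cfg.eps_background)

    out = []
    for i in range(n_reads):
        seq = reads[i].tobytes().decode()
        out.append(revcomp(seq) if i % 2 else seq)
    return out


def emit_vr_amplicons(
    genome: GenomeModel,
    cfg: SimConfig,
    n_reads: int,
    outdir: str | Path,
    prefix: str = "amplicons",
) -> dict[str, Path]:
    """Emit VR amplicon reads to FASTQ (see :func:`simulate_amplicon_reads`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fq_path = outdir / f"{prefix}.fastq"
    reads = simulate_amplicon_reads(genome, cfg, n_reads)
    with ChunkedWriter(fq_path) as fq:
        for i, seq in enumerate(reads):
            fq.write(f"@amp_{i}\n{seq}\n+\n{'I' * len(seq)}")
    return {"fastq": fq_path}


def simulate_capsid_molecules(
    genome: GenomeModel, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw packaged-molecule intervals [start, end) on the chromosome.

    Packaging starts 29-31 bp (``flank5_range``) upstream of the
    prophage and proceeds rightward. Within the first ``hazard_region``
    bases of the prophage it terminates independently before each base
    with probability ``hazard`` (geometric survival); molecules that
    clear the hazard region complete the prophage and append a uniform
    ``flank3_range`` host flank.
    """
    ps, pe = genome.prophage_interval
    N = cfg.n_capsids
    lf5 = rng.integers(cfg.flank5_range[0], cfg.flank5_range[1] + 1, size=N)
    if cfg.hazard > 0:
        extent = rng.geometric(cfg.hazard, size=N) - 1
    else:
        extent = np.full(N, cfg.hazard_region, dtype=np.int64)
    survived = extent >= cfg.hazard_region
    extent = np.where(survived, pe - ps, extent)
    lf3 = np.zeros(N, dtype=np.int64)
    n_surv = int(survived.sum())
    if n_surv:
        lf3[survived] = rng.integers(cfg.flank3_range[0], cfg.flank3_range[1] + 1, size=n_surv)
    starts = ps - lf5
    ends = np.minimum(ps + extent + lf3, len(genome.chromosome_seq))
    return starts.astype(np.int64), ends.astype(np.int64)


def emit_capsid_reads(
    genome: GenomeModel,
    cfg: SimConfig,
    outdir: str | Path,
    prefix: str = "capsids",
    write_fastq: bool = True,
) -> tuple[dict[str, Path], SimTruth]:
    """Emit capsid reads as chromosome-aligned SAM (and optionally FASTQ).

    Library model (single-end): each molecule yields one terminus-anchored
    read starting at its 5' end -- the terminal sonication fragment,
    which carries the discrete host-flank signal -- plus interior reads
    whose starts are uniform over the molecule at a mean per-base rate of
    ``capsid_read_depth / capsid_read_length``. Reads are truncated at
    the molecule 3' end and dropped below ``min_capsid_read_length``.
    Alternate records carry the reverse-strand flag; coordinates are
    unaffected.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(cfg.seed, "capsids")
    chrom = genome.chromosome_seq
    R = cfg.capsid_read_length
    rate = cfg.capsid_read_depth / R

    starts, ends = simulate_capsid_molecules(genome, cfg, rng)
    lengths = ends - starts
    truth = SimTruth(
        mu_targeted=cfg.mu_targeted,
        eps_background=cfg.eps_background,
        hazard=cfg.hazard,
        molecule_lengths=[int(v) for v in lengths],
    )

    # terminal reads: one per molecule, anchored at the molecule 5' end
    term_start = starts
    term_len = np.minimum(R, lengths)

    # interior reads: Poisson counts, uniform offsets in [1, length - 1]
    n_interior = rng.poisson(rate * np.maximum(lengths - 1, 0))
    mol_idx = np.repeat(np.arange(cfg.n_capsids), n_interior)
    rel = 1 + (rng.random(mol_idx.size) * (lengths[mol_idx] - 1)).astype(np.int64)
    int_start = starts[mol_idx] + rel
    int_len = np.minimum(R, ends[mol_idx] - int_start)

    read_start = np.concatenate([term_start, int_start])
    read_len = np.concatenate([term_len, int_len])
    keep = read_len >= cfg.min_capsid_read_length
    read_start, read_len = read_start[keep], read_len[keep]
    order = np.argsort(read_start, kind="stable")
    read_start, read_len = read_start[order], read_len[order]

    sam_path = outdir / f"{prefix}.sam"
    fq_path = outdir / f"{prefix}.fastq" if write_fastq else None
    fq = ChunkedWriter(fq_path) if write_fastq else None
    with ChunkedWriter(sam_path) as sam:
        sam.write(_sam_header("chromosome", len(chrom)))
        for i in range(read_start.size):
            s = int(read_start[i])
            ln = int(read_len[i])
            seq = chrom[s : s + ln]
            flag = 16 if i % 2 else 0
            qual = "I" * ln
            sam.write(f"capsid_{i}\t{flag}\tchromosome\t{s + 1}\t60\t{ln}M\t*\t0\t0\t{seq}\t{qual}")
            if fq is not None:
                fq.write(f"@capsid_{i}\n{revcomp(seq) if flag else seq}\n+\n{qual}")
    if fq is not None:
        fq.close()
    truth.write_json(outdir / f"{prefix}_truth.json")
    paths = {"sam": sam_path, "truth_json": outdir / f"{prefix}_truth.json"}
    if fq_path is not None:
        paths["fastq"] = fq_path
    return paths, truth
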