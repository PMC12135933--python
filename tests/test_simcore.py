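"""Simulator invariants: determinism, genome layout, read construction."""

import numpy as np
import pysam
import pytest

from prophagedyn import ConfigError, SimConfig, make_genome, plant_transpositions, simcore
from prophagedyn._util import revcomp, stage_rng


class TestMakeGenome:
    def test_deterministic_fasta(self, default_cfg, tmp_path):
        g1 = make_genome(default_cfg)
        g2 = make_genome(default_cfg)
        g1.write_fasta(tmp_path / "a.fa")
        g2.write_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_layout_invariants(self, default_cfg, default_genome):
        g = default_genome
        s, e = g.prophage_interval
        assert (s, e) == (5_000, 45_000)
        assert g.prophage_seq == g.chromosome_seq[s:e]
        # VR initialised from the TR, primers immediately flanking
        assert g.vr_seq == default_cfg.tr_sequence
        vs, ve = g.vr_interval
        assert g.prophage_seq[vs - len(g.primer_fwd) : vs] == g.primer_fwd
        assert g.prophage_seq[ve : ve + len(g.primer_rev)] == revcomp(g.primer_rev)

    def test_targeted_positions_are_tr_adenines(self, default_cfg, default_genome):
        expected = [i for i, b in enumerate(default_cfg.tr_sequence) if b == "A"]
        assert list(default_genome.targeted_positions) == expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prophage_start": 20_000, "prophage_length": 40_000},  # overflows chromosome
            {"vr_offset": 39_950},  # VR overflows prophage
            {"tr_sequence": "ACGT"},  # TR/VR length mismatch
            {"mu_targeted": 1.5},
            {"clip_length_range": (0, 10)},
            {"clip_length_range": (20, 200)},  # clip >= read_length
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)


class TestPlantTranspositions:
    def test_cardinality_distinct_and_excluded(self, default_cfg, default_genome):
        truth = plant_transpositions(default_genome, 100, 1, default_cfg)
        coords = [c for c, _ in truth.junctions]
        assert len(coords) == 100
        assert len(set(coords)) == 100
        s, e = default_genome.prophage_interval
        m = default_cfg.read_length
        assert all(c < s - m or c >= e + m for c in coords)

    def test_deterministic(self, default_cfg, default_genome):
        t1 = plant_transpositions(default_genome, 50, 3, default_cfg)
        t2 = plant_transpositions(default_genome, 50, 3, default_cfg)
        assert t1.junctions == t2.junctions

    def test_capacity_error(self, small_cfg, small_genome):
        with pytest.raises(ConfigError):
            plant_transpositions(small_genome, 10**6, 1, small_cfg)


@pytest.fixture(scope="module")
def emitted(tmp_path_factory, default_cfg, default_genome):
    truth = plant_transpositions(default_genome, 30, 1, default_cfg)
    out = tmp_path_factory.mktemp("junc")
    paths = simcore.emit_junction_reads(default_genome, truth, default_cfg, out)
    return truth, paths


class TestJunctionReads:
    def test_sam_records_valid_and_clips_match_chromosome(self, emitted, default_cfg, default_genome):
        truth, paths = emitted
        chrom = default_genome.chromosome_seq
        by_event = dict(enumerate(truth.junctions))
        n = 0
        with pysam.AlignmentFile(str(paths["sam"]), "r") as sam:
            for rec in sam:
                n += 1
                cig = rec.cigartuples
                assert sum(ln for _, ln in cig) == default_cfg.read_length
                assert rec.reference_start == 0
                op, k = cig[0]
                assert op == 4 and cig[1][0] == 0  # kS mM
                event = int(rec.query_name.split("_")[1])
                c, orient = by_event[event]
                clip = rec.query_sequence[:k]
                if orient == "+":
                    assert clip == chrom[c + 1 - k : c + 1]
                else:
                    assert clip == revcomp(chrom[c : c + k])
                # aligned portion is the prophage 5' end
                assert rec.query_sequence[k:] == default_genome.prophage_seq[: default_cfg.read_length - k]
        assert n == 30 * default_cfg.reads_per_event

    def test_truth_bed_cardinality(self, emitted):
        truth, paths = emitted
        lines = paths["truth_bed"].read_text().splitlines()
        assert len(lines) == len(truth.junctions) == 30


class TestAmplicons:
    def test_null_mutagenesis_reproduces_reference(self, default_genome):
        cfg = SimConfig(mu_targeted=0.0, eps_background=0.0, seed=1)
        reads = simcore.simulate_amplicon_reads(default_genome, cfg, 10)
        ref = default_genome.amplicon_seq
        assert all(r == ref or revcomp(r) == ref for r in reads)
        # exactly half reverse-complemented
        assert sum(r != ref for r in reads) == 5

    def test_saturating_mutagenesis_hits_every_targeted_position(self, default_genome):
        cfg = SimConfig(mu_targeted=1.0, eps_background=0.0, seed=1)
        reads = simcore.simulate_amplicon_reads(default_genome, cfg, 200)
        ref = default_genome.amplicon_seq
        fwd = [r if r[:5] == ref[:5] else revcomp(r) for r in reads]
        off = len(default_genome.primer_fwd)
        for p in default_genome.targeted_positions:
            assert all(r[off + p] != ref[off + p] for r in fwd)

    def test_targeted_mutation_rate_matches_binomial(self, default_genome):
        """Non-reference counts at targeted sites follow Binomial(n, mu)."""
        cfg = SimConfig(mu_targeted=0.1, eps_background=0.0, seed=1)
        n = 10_000
        reads = simcore.simulate_amplicon_reads(default_genome, cfg, n)
        ref = default_genome.amplicon_seq
        fwd = [r if r[:5] == ref[:5] else revcomp(r) for r in reads]
        arr = np.frombuffer("".join(fwd).encode(), np.uint8).reshape(n, len(ref))
        refarr = np.frombuffer(ref.encode(), np.uint8)
        nonref = (arr != refarr).sum(axis=0)
        off = len(default_genome.primer_fwd)
        sd = np.sqrt(n * 0.1 * 0.9)
        for p in default_genome.targeted_positions:
            assert abs(nonref[off + p] - n * 0.1) <= 3 * sd


class TestCapsids:
    def test_no_termination_spans_everything(self, default_genome):
        cfg = SimConfig(hazard=0.0, seed=1, n_capsids=200)
        rng = stage_rng(1, "capsids")
        starts, ends = simcore.simulate_capsid_molecules(default_genome, cfg, rng)
        ps, pe = default_genome.prophage_interval
        assert (starts <= ps - 29).all() and (starts >= ps - 31).all()
        assert (ends >= pe + cfg.flank3_range[0]).all()
        assert (ends <= pe + cfg.flank3_range[1]).all()

    def test_molecule_starts_within_flank_window(self, default_cfg, default_genome):
        rng = stage_rng(1, "capsids")
        starts, _ = simcore.simulate_capsid_molecules(default_genome, default_cfg, rng)
        ps = default_genome.prophage_interval[0]
        assert set(ps - starts) == {29, 30, 31}

    def test_survival_matches_geometric_law(self, default_genome):
        """Fraction of molecules reaching prophage offset x is (1-h)^min(x+1, 15kb)."""
        cfg = SimConfig(seed=1, n_capsids=20_000)
        rng = stage_rng(1, "capsids")
        starts, ends = simcore.simulate_capsid_molecules(default_genome, cfg, rng)
        ps = default_genome.prophage_interval[0]
        n = cfg.n_capsids
        for x in [0, 500, 2_000, 8_000, 14_999, 20_000]:
            p = (1 - cfg.hazard) ** min(x + 1, cfg.hazard_region)
            observed = (ends > ps + x).sum() / n
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * sd + 1e-9

    def test_emission_deterministic_and_sam_valid(self, tmp_path, small_cfg, small_genome):
        p1, _ = simcore.emit_capsid_reads(small_genome, small_cfg, tmp_path / "a")
        p2, _ = simcore.emit_capsid_reads(small_genome, small_cfg, tmp_path / "b")
        assert p1["sam"].read_bytes() == p2["sam"].read_bytes()
        with pysam.AlignmentFile(str(p1["sam"]), "r") as sam:
            L = sam.lengths[0]
            for rec in sam:
                assert len(rec.query_sequence) == rec.query_alignment_length
                assert 0 <= rec.reference_start and rec.reference_end <= L
                assert len(rec.query_sequence) >= small_cfg.min_capsid_read_length
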