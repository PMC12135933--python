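"""Junction detection: clip extraction, exact relocation, aggregation."""

from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from prophagedyn import (
    SimConfig,
    call_junctions,
    detect_junctions,
    extract_clips,
    junction_report,
    locate_unique,
    make_genome,
    plant_transpositions,
    simcore,
)
from prophagedyn.simcore import SimTruth
from prophagedyn.transposition import ClipFragment
from prophagedyn._util import random_dna, revcomp

import numpy as np


def naive_scan(fragment: str, genome: str) -> list[tuple[int, int, str]]:
    """Independent all-positions slice-scan oracle for exact matching."""
    k = len(fragment)
    rc = revcomp(fragment)
    hits = [(i, i + k, "+") for i in range(len(genome) - k + 1) if genome[i : i + k] == fragment]
    hits += [(i, i + k, "-") for i in range(len(genome) - k + 1) if genome[i : i + k] == rc]
    return hits


def write_sam(path: Path, records: list[str], ref: str = "prophage", ln: int = 1000) -> Path:
    lines = [f"@HD\tVN:1.6", f"@SQ\tSN:{ref}\tLN:{ln}"] + records
    path.write_text("\n".join(lines) + "\n")
    return path


class TestExtractClips:
    def test_leading_clip_at_prophage_start(self, tmp_path):
        seq = "A" * 100
        sam = write_sam(tmp_path / "a.sam", [f"r1\t0\tprophage\t1\t60\t30S70M\t*\t0\t0\t{seq}\t*"])
        frags, skipped = extract_clips(sam)
        assert skipped == 0
        assert len(frags) == 1
        assert frags[0].side == "prophage-start" and frags[0].length == 30

    def test_short_clip_dropped(self, tmp_path):
        seq = "A" * 100
        sam = write_sam(tmp_path / "a.sam", [f"r1\t0\tprophage\t1\t60\t10S90M\t*\t0\t0\t{seq}\t*"])
        frags, _ = extract_clips(sam, min_clip=15)
        assert frags == []

    def test_trailing_clip_at_prophage_end_with_side_both(self, tmp_path):
        seq = "C" * 100
        # 70M ends exactly at the reference 3' terminus (pos 931 + 70 = 1001)
        sam = write_sam(tmp_path / "a.sam", [f"r1\t0\tprophage\t931\t60\t70M30S\t*\t0\t0\t{seq}\t*"])
        assert extract_clips(sam, side="prophage-start")[0] == []
        frags, _ = extract_clips(sam, side="both")
        assert len(frags) == 1 and frags[0].side == "prophage-end"

    def test_unmapped_and_interior_records_ignored(self, tmp_path):
        seq = "G" * 100
        sam = write_sam(
            tmp_path / "a.sam",
            [
                f"r1\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*",  # unmapped
                f"r2\t0\tprophage\t50\t60\t30S70M\t*\t0\t0\t{seq}\t*",  # clip not at terminus
            ],
        )
        frags, _ = extract_clips(sam)
        assert frags == []


class TestLocateUnique:
    @given(st.data())
    def test_agrees_with_naive_scan(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        genome = random_dna(rng, data.draw(st.integers(200, 2_000)))
        k = data.draw(st.integers(5, 25))
        if data.draw(st.booleans()):
            start = data.draw(st.integers(0, len(genome) - k))
            frag = genome[start : start + k]
            if data.draw(st.booleans()):
                frag = revcomp(frag)
        else:
            frag = random_dna(rng, k)
        hits = [(h.start, h.end, h.strand) for h in locate_unique(frag, genome)]
        assert sorted(hits) == sorted(naive_scan(frag, genome))

    def test_overlapping_occurrences_enumerated(self):
        hits = locate_unique("AAA", "AAAAA")
        assert len([h for h in hits if h.strand == "+"]) == 3


class TestCallJunctions:
    CHROM = random_dna(np.random.default_rng(5), 5_000)

    def test_plus_strand_coordinate_is_last_base(self):
        frag = ClipFragment("r1", "prophage-start", self.CHROM[1001:1031])
        table = call_junctions([frag], self.CHROM)
        row = table.rows.iloc[0]
        assert (row.coordinate, row.orientation, row.read_count) == (1030, "+", 1)

    def test_minus_strand_coordinate_is_first_base(self):
        frag = ClipFragment("r1", "prophage-start", revcomp(self.CHROM[2000:2030]))
        table = call_junctions([frag], self.CHROM)
        row = table.rows.iloc[0]
        assert (row.coordinate, row.orientation) == (2000, "-")

    def test_identical_junctions_aggregate(self):
        frags = [ClipFragment(f"r{i}", "prophage-start", self.CHROM[100:130]) for i in range(3)]
        table = call_junctions(frags, self.CHROM)
        assert table.total_events == 1
        assert int(table.rows.iloc[0].read_count) == 3

    def test_multi_hit_fragments_discarded(self):
        chrom = self.CHROM + self.CHROM[300:340] + self.CHROM[-50:]
        frag = ClipFragment("r1", "prophage-start", chrom[300:340])
        table = call_junctions([frag], chrom)
        assert table.total_events == 0 and table.discarded_multi == 1

    def test_no_hit_fragments_tallied(self):
        table = call_junctions([ClipFragment("r1", "prophage-start", "N" * 20)], self.CHROM)
        assert table.total_events == 0 and table.discarded_nomatch == 1


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    cfg = SimConfig(seed=11)
    genome = make_genome(cfg)
    truth = plant_transpositions(genome, 100, cfg.seed, cfg)
    out = tmp_path_factory.mktemp("recovery")
    paths = simcore.emit_junction_reads(genome, truth, cfg, out)
    return cfg, genome, truth, paths


class TestRecovery:
    def test_perfect_recovery_exact_coordinates(self, sim):
        cfg, genome, truth, paths = sim
        s, e = genome.prophage_interval
        table = detect_junctions(
            paths["sam"],
            genome.chromosome_seq,
            exclude_interval=(s - cfg.read_length, e + cfg.read_length),
        )
        detected = {(int(r.coordinate), r.orientation) for r in table.rows.itertuples()}
        assert detected == set(truth.junctions)
        assert table.discarded_multi == 0

    def test_min_clip_monotonicity(self, sim):
        _, genome, _, paths = sim
        events = [
            detect_junctions(paths["sam"], genome.chromosome_seq, min_clip=mc).total_events
            for mc in (15, 25, 35, 45)
        ]
        assert events == sorted(events, reverse=True)

    def test_all_plus_orientations_yield_only_plus_rows(self, tmp_path):
        cfg = SimConfig(seed=13, n_events=20)
        genome = make_genome(cfg)
        base = plant_transpositions(genome, 20, cfg.seed, cfg)
        truth = SimTruth(
            junctions=[(c, "+") for c, _ in base.junctions],
            mu_targeted=0, eps_background=0, hazard=0,
        )
        paths = simcore.emit_junction_reads(genome, truth, cfg, tmp_path)
        table = detect_junctions(paths["sam"], genome.chromosome_seq)
        assert set(table.rows["orientation"]) == {"+"}


class TestJunctionReport:
    def test_empty_table(self, tmp_path):
        table = call_junctions([], "ACGT" * 100)
        summary = junction_report(table, bed_path=tmp_path / "j.bed", tsv_path=tmp_path / "j.tsv")
        assert summary["total_events"].iloc[0] == 0
        assert (tmp_path / "j.bed").read_text() == ""

    def test_bed_matches_rows_and_fraction_reported(self, tmp_path):
        chrom = random_dna(np.random.default_rng(6), 3_000)
        frags = [ClipFragment(f"r{i}", "prophage-start", chrom[s : s + 25]) for i, s in enumerate((10, 500, 900))]
        table = call_junctions(frags, chrom)
        summary = junction_report(table, bed_path=tmp_path / "j.bed")
        assert len((tmp_path / "j.bed").read_text().splitlines()) == table.total_events == 3
        assert summary["fraction_multi"].iloc[0] == 0.0
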