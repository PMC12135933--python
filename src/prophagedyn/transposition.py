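"""Replicative-transposition junction detection from soft-clipped reads.

Reads from a strain whose prophage has transposed carry, at the read
end adjacent to the prophage terminus, a soft-clipped fragment of the
new chromosomal flank. Relocating those clips by exact full-length
matching (the in-silico equivalent of 100%-identity, 100%-coverage
short-read BLAST) yields the novel phage-host junction coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from ._util import revcomp

SOFT_CLIP = 4  # pysam CIGAR operation code


@dataclass
class ClipFragment:
    """A soft-clipped read fragment at a prophage terminus."""

    read_id: str
    side: str  # "prophage-start" | "prophage-end"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Hit:
    """Exact occurrence of a clip (or its reverse complement) on the chromosome."""

    start: int  # 0-based half-open, forward strand
    end: int
    strand: str  # "+" | "-"


@dataclass
class JunctionTable:
    """Distinct (coordinate, orientation) junctions with supporting-read counts."""

    rows: pd.DataFrame  # columns: coordinate, orientation, read_count
    discarded_multi: int = 0
    discarded_nomatch: int = 0
    discarded_native: int = 0
    n_fragments: int = 0
    skipped_records: int = 0

    @property
    def total_events(self) -> int:
        return len(self.rows)

    @property
    def total_supporting_reads(self) -> int:
        return int(self.rows["read_count"].sum()) if len(self.rows) else 0

    @property
    def fraction_multi(self) -> float:
        return self.discarded_multi / self.n_fragments if self.n_fragments else 0.0


def extract_clips(
    sam_path: str | Path,
    min_clip: int = 15,
    side: str = "prophage-start",
) -> tuple[list[ClipFragment], int]:
    """Soft-clipped segments adjacent to the prophage terminus.

    ``side`` selects ``prophage-start`` (leading clip of reads aligned at
    prophage position 0), ``prophage-end`` (trailing clip of reads whose
    alignment reaches the reference 3' terminus) or ``both``. Clips
    shorter than ``min_clip`` are dropped; records with malformed or
    missing CIGAR/sequence are skipped and counted.

    Returns ``(fragments, skipped_record_count)``.
    """
    if side not in ("prophage-start", "prophage-end", "both"):
        raise ValueError(f"unknown side selector: {side}")
    fragments: list[ClipFragment] = []
    skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples
            seq = rec.query_sequence
            if not cig or seq is None:
                skipped += 1
                continue
            if side in ("prophage-start", "both"):
                op, ln = cig[0]
                if op == SOFT_CLIP and ln >= min_clip and rec.reference_start == 0:
                    fragments.append(ClipFragment(rec.query_name, "prophage-start", seq[:ln].upper()))
            if side in ("prophage-end", "both"):
                op, ln = cig[-1]
                ref_len = ref_lengths.get(rec.reference_name)
                if (
                    op == SOFT_CLIP
                    and ln >= min_clip
                    and ref_len is not None
                    and rec.reference_end == ref_len
                ):
                    fragments.append(ClipFragment(rec.query_name, "prophage-end", seq[-ln:].upper()))
    return fragments, skipped


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_unique(fragment: ClipFragment | str, chromosome: str) -> list[Hit]:
    """All exact occurrences of the fragment or its reverse complement.

    Overlapping occurrences are enumerated; coordinates are 0-based
    half-open on the forward strand. Zero or multiple hits are normal
    outcomes, resolved by :func:`call_junctions`.
    """
    seq = fragment.sequence if isinstance(fragment, ClipFragment) else fragment
    k = len(seq)
    hits = [Hit(i, i + k, "+") for i in _find_all(chromosome, seq)]
    rc = revcomp(seq)
    hits += [Hit(i, i + k, "-") for i in _find_all(chromosome, rc)]
    return hits


def call_junctions(
    fragments: list[ClipFragment],
    chromosome: str,
    exclude_interval: tuple[int, int] | None = None,
    skipped_records: int = 0,
) -> JunctionTable:
    """Aggregate uniquely relocated clips into a junction table.

    Fragments with zero or multiple exact hits are discarded into the
    respective tallies. For a '+' strand hit the junction coordinate is
    the hit's last base (``end - 1``, the last chromosomal position of
    the aligned clip); for a '-' strand hit it is the hit's first base
    (the base adjacent to the prophage start in read orientation).
    Junction coordinates inside ``exclude_interval`` (the resident
    prophage locus plus a margin) reflect the native junction and are
    discarded separately.
    """
    multi = nomatch = native = 0
    counts: dict[tuple[int, str], int] = {}
    for frag in fragments:
        hits = locate_unique(frag, chromosome)
        if len(hits) == 0:
            nomatch += 1
            continue
        if len(hits) > 1:
            multi += 1
            continue
        hit = hits[0]
        coord = hit.end - 1 if hit.strand == "+" else hit.start
        if exclude_interval is not None:
            lo, hi = exclude_interval
            if lo <= coord < hi:
                native += 1
                continue
        key = (coord, hit.strand)
        counts[key] = counts.get(key, 0) + 1
    rows = pd.DataFrame(
        [(c, o, n) for (c, o), n in sorted(counts.items())],
        columns=["coordinate", "orientation", "read_count"],
    )
    return JunctionTable(
        rows=rows,
        discarded_multi=multi,
        discarded_nomatch=nomatch,
        discarded_native=native,
        n_fragments=len(fragments),
        skipped_records=skipped_records,
    )


def detect_junctions(
    sam_path: str | Path,
    chromosome: str,
    min_clip: int = 15,
    side: str = "prophage-start",
    exclude_interval: tuple[int, int] | None = None,
) -> JunctionTable:
    """End-to-end detection: extract clips, relocate, aggregate."""
    fragments, skipped = extract_clips(sam_path, min_clip=min_clip, side=side)
    return call_junctions(
        fragments, chromosome, exclude_interval=exclude_interval, skipped_records=skipped
    )


def junction_report(
    table: JunctionTable,
    bed_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
    chrom_name: str = "chromosome",
) -> pd.DataFrame:
    """Write junctions as BED and a TSV summary; returns the summary frame."""
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i, row in table.rows.iterrows():
                c = int(row["coordinate"])
                fh.write(
                    f"{chrom_name}\t{c}\t{c + 1}\tjunction_{i}\t"
                    f"{int(row['read_count'])}\t{row['orientation']}\n"
                )
    summary = pd.DataFrame(
        {
            "total_events": [table.total_events],
            "total_supporting_reads": [table.total_supporting_reads],
            "discarded_multi": [table.discarded_multi],
            "discarded_nomatch": [table.discarded_nomatch],
            "discarded_native": [table.discarded_native],
            "fraction_multi": [table.fraction_multi],
            "n_fragments": [table.n_fragments],
            "skipped_records": [table.skipped_records],
        }
    )
    if tsv_path is not None:
        summary.to_csv(tsv_path, sep="\t", index=False)
    return summary
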