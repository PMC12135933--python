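"""Headful-packaging characterisation from capsid-read alignments.

Coverage of capsid DNA over the prophage and its host flanks reveals
where packaging starts, how far it proceeds, and how much host DNA is
co-packaged: a left/right coverage asymmetry across the prophage, a
discrete distribution of 5' host-flank sizes at the packaging
initiation site, and a decaying coverage tail past the prophage 3' end
bounding the co-packaged 3' host fragment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam


@dataclass
class CoverageProfile:
    """Per-base depth over a chromosome region, with a normalized view.

    ``norm_depth`` is depth divided by the number of reads mapped in the
    region, making profiles comparable across sequencing depths.
    """

    region: tuple[int, int]  # 0-based half-open on the chromosome
    depth: np.ndarray
    n_mapped: int
    zero_mapped: bool = False

    @property
    def norm_depth(self) -> np.ndarray:
        if self.n_mapped == 0:
            return np.zeros_like(self.depth, dtype=float)
        return self.depth / self.n_mapped

    def norm_at(self, interval: tuple[int, int]) -> np.ndarray:
        """Normalized depth over a chromosome sub-interval of the region."""
        lo, hi = interval
        s, e = self.region
        if lo < s or hi > e:
            raise ValueError(f"interval [{lo}, {hi}) outside profiled region [{s}, {e})")
        return self.norm_depth[lo - s : hi - s]

    def to_frame(self) -> pd.DataFrame:
        s, e = self.region
        return pd.DataFrame(
            {
                "position": np.arange(s, e),
                "depth": self.depth,
                "norm_depth": self.norm_depth,
            }
        )


def load_alignments(sam_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Aligned reference spans (start, end arrays, 0-based half-open).

    Soft/hard-clipped bases are outside the reference span and never
    contribute. Records with deletions or skips are expanded into their
    match blocks so deleted bases do not contribute either.
    """
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = rec.cigarstring or ""
            if "D" in cigar or "N" in cigar:
                for bs, be in rec.get_blocks():
                    starts.append(bs)
                    ends.append(be)
            else:
                starts.append(rec.reference_start)
                ends.append(rec.reference_end)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def region_coverage(
    alignments: str | Path | tuple[np.ndarray, np.ndarray],
    region: tuple[int, int],
) -> CoverageProfile:
    """Per-base depth over ``region`` from aligned match segments.

    ``alignments`` is a SAM path or precomputed (starts, ends) span
    arrays. ``n_mapped`` counts reads whose alignment overlaps the
    region.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError(f"invalid region [{lo}, {hi})")
    if isinstance(alignments, (str, Path)):
        starts, ends = load_alignments(alignments)
    else:
        starts, ends = alignments
    overlap = (starts < hi) & (ends > lo)
    s = np.clip(starts[overlap], lo, hi)
    e = np.clip(ends[overlap], lo, hi)
    diff = np.zeros(hi - lo + 1, dtype=np.int64)
    np.add.at(diff, s - lo, 1)
    np.add.at(diff, e - lo, -1)
    depth = np.cumsum(diff[:-1])
    n_mapped = int(overlap.sum())
    return CoverageProfile(
        region=(lo, hi), depth=depth, n_mapped=n_mapped, zero_mapped=(n_mapped == 0)
    )


def end_ratio(
    profile: CoverageProfile,
    prophage_interval: tuple[int, int],
    window: int = 500,
) -> tuple[float, bool]:
    """Mean normalized depth of the prophage left window over the right.

    Returns ``(ratio, is_finite)``; zero right-window coverage yields an
    infinite flagged ratio.
    """
    ps, pe = prophage_interval
    if pe - ps < 2 * window:
        raise ValueError("prophage shorter than two end windows")
    left = float(profile.norm_at((ps, ps + window)).mean())
    right = float(profile.norm_at((pe - window, pe)).mean())
    if right == 0.0:
        return float("inf"), False
    return left / right, True


@dataclass
class FlankHistogram:
    """5' host-flank sizes of packaging-initiation reads."""

    counts: dict[int, int]  # flank size (bases) -> read count
    support: list[int]  # sizes retained by the spike filter
    flank_min: int | None
    flank_max: int | None
    flank_mode: int | None
    min_frac: float
    empty: bool = False


def five_prime_flanks(
    alignments: str | Path | tuple[np.ndarray, np.ndarray],
    prophage_start: int,
    min_frac: float = 0.10,
) -> FlankHistogram:
    """Host-flank size distribution at the packaging initiation site.

    For reads starting upstream of ``prophage_start`` whose alignment
    reaches it, records ``prophage_start - alignment_start``. Molecule
    5' termini produce discrete spikes in this histogram; sizes whose
    count is below ``min_frac`` of the modal count are fragmentation
    background and are excluded from the reported support.
    """
    if isinstance(alignments, (str, Path)):
        starts, ends = load_alignments(alignments)
    else:
        starts, ends = alignments
    qual = (starts < prophage_start) & (ends > prophage_start)
    flanks = prophage_start - starts[qual]
    if flanks.size == 0:
        return FlankHistogram({}, [], None, None, None, min_frac, empty=True)
    sizes, counts = np.unique(flanks, return_counts=True)
    hist = {int(s): int(c) for s, c in zip(sizes, counts)}
    cutoff = min_frac * counts.max()
    support = sorted(int(s) for s, c in hist.items() if c >= cutoff)
    mode = int(sizes[np.argmax(counts)])
    return FlankHistogram(
        counts=hist,
        support=support,
        flank_min=support[0],
        flank_max=support[-1],
        flank_mode=mode,
        min_frac=min_frac,
    )


def three_prime_extent(
    profile: CoverageProfile,
    prophage_end: int,
    frac_threshold: float = 0.01,
    interior_window: int = 100,
) -> tuple[int, bool]:
    """Extent of co-packaged host DNA past the prophage 3' end.

    Returns the smallest distance d at which normalized depth at
    ``prophage_end + d`` drops below ``frac_threshold`` times the mean
    over the ``interior_window`` bases just inside the prophage 3' end,
    as ``(extent, censored)``; if the threshold is never crossed within
    the profiled region, the profiled distance is returned with
    ``censored=True``.
    """
    interior = float(profile.norm_at((prophage_end - interior_window, prophage_end)).mean())
    threshold = frac_threshold * interior
    _, hi = profile.region
    tail = profile.norm_at((prophage_end, hi))
    below = tail < threshold
    if not below.any():
        return int(hi - prophage_end), True
    return int(np.argmax(below)), False


@dataclass
class PackagingSummary:
    """Joint summary of the packaging end analysis."""

    end_ratio: float
    end_ratio_finite: bool
    window: int
    flank5: FlankHistogram
    flank3_extent: int
    flank3_censored: bool
    n_mapped: int

    def to_json(self) -> str:
        d = {
            "end_ratio": self.end_ratio if np.isfinite(self.end_ratio) else None,
            "end_ratio_finite": self.end_ratio_finite,
            "window": self.window,
            "flank5_min": self.flank5.flank_min,
            "flank5_max": self.flank5.flank_max,
            "flank5_mode": self.flank5.flank_mode,
            "flank5_support": self.flank5.support,
            "flank5_sizes": {str(k): v for k, v in sorted(self.flank5.counts.items())},
            "flank3_extent": self.flank3_extent,
            "flank3_censored": self.flank3_censored,
            "n_mapped": self.n_mapped,
        }
        return json.dumps(d)


def analyze_packaging(
    sam_path: str | Path,
    prophage_interval: tuple[int, int],
    chromosome_length: int,
    window: int = 500,
    frac_threshold: float = 0.01,
    flank_min_frac: float = 0.10,
    margin: int = 3_000,
) -> tuple[CoverageProfile, PackagingSummary]:
    """Full packaging pipeline over the prophage plus ``margin`` flanks."""
    ps, pe = prophage_interval
    region = (max(0, ps - margin), min(chromosome_length, pe + margin))
    spans = load_alignments(sam_path)
    profile = region_coverage(spans, region)
    ratio, finite = end_ratio(profile, prophage_interval, window=window)
    flank5 = five_prime_flanks(spans, ps, min_frac=flank_min_frac)
    extent, censored = three_prime_extent(profile, pe, frac_threshold=frac_threshold)
    summary = PackagingSummary(
        end_ratio=ratio,
        end_ratio_finite=finite,
        window=window,
        flank5=flank5,
        flank3_extent=extent,
        flank3_censored=censored,
        n_mapped=profile.n_mapped,
    )
    return profile, summary
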