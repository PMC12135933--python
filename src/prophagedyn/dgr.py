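"""DGR hypermutation quantification and activity calling.

The variable repeat (VR) of a diversity-generating retroelement is
hypermutated at positions templated by adenines in the template repeat
(TR). From full-span amplicon reads this module builds a per-position
allele matrix, computes per-site nucleotide diversity

    pi = 1 - (fA^2 + fT^2 + fC^2 + fG^2),

and calls the DGR active when the mean pi over targeted (TR adenine)
positions exceeds the mean over non-targeted positions by more than two
sample standard deviations of the latter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from ._util import BASES, revcomp

logger = logging.getLogger(__name__)

_BASE_TO_COL = {b: i for i, b in enumerate(BASES)}


class AlignmentLengthError(ValueError):
    """TR/VR length mismatch; sequences must be pre-aligned and gap-free."""


class EmptyMatrixError(ValueError):
    """No retained segments; downstream statistics are undefined."""


def targeted_positions(tr: str, vr: str) -> np.ndarray:
    """0-based indices where the template repeat has an adenine.

    ``tr`` and ``vr`` must already be aligned and gap-free; a length
    mismatch raises rather than triggering any re-alignment.
    """
    if len(tr) != len(vr):
        raise AlignmentLengthError(f"TR length {len(tr)} != VR length {len(vr)}")
    return np.flatnonzero(np.frombuffer(tr.upper().encode(), dtype=np.uint8) == ord("A"))


def _iter_read_seqs(reads: str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        with pysam.FastxFile(str(reads)) as fh:
            for rec in fh:
                yield rec.sequence
    else:
        yield from reads


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def extract_vr_reads(
    reads: str | Path | Iterable[str], primer_fwd: str, primer_rev: str
) -> list[str]:
    """Collect reads spanning the complete VR, oriented to the forward strand.

    A read is kept when it contains exactly one occurrence of
    ``primer_fwd`` followed by exactly one occurrence of
    ``revcomp(primer_rev)`` (or the mirror image on the opposite
    strand); the inter-primer segment is returned. Reads with multiple
    primer hits, or matching in both orientations, are dropped.
    """
    if not primer_fwd or not primer_rev:
        raise ValueError("primers must be non-empty")
    rc_rev = revcomp(primer_rev)
    if primer_fwd == rc_rev:
        raise ValueError("primer_fwd equals revcomp(primer_rev); orientation is ambiguous")

    def segment(seq: str) -> str | None:
        f = _find_all(seq, primer_fwd)
        r = _find_all(seq, rc_rev)
        if len(f) == 1 and len(r) == 1 and f[0] + len(primer_fwd) <= r[0]:
            return seq[f[0] + len(primer_fwd) : r[0]]
        return None

    segments = []
    for seq in _iter_read_seqs(reads):
        seq = seq.upper()
        fwd = segment(seq)
        rev = segment(revcomp(seq))
        if (fwd is None) == (rev is None):  # neither, or ambiguous both
            continue
        segments.append(fwd if fwd is not None else rev)
    if not segments:
        logger.warning("extract_vr_reads: no reads spanned the complete VR")
    return segments


@dataclass
class AlleleMatrix:
    """Per-VR-position counts of A/C/G/T from full-span, gap-free segments."""

    counts: np.ndarray  # shape (vr_length, 4), columns in BASES order
    reference: str
    n_spanning_reads: int
    n_discarded_length: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(len(self.reference)))
        df["reference"] = list(self.reference)
        return df


def build_allele_matrix(vr_segments: Iterable[str], vr_reference: str) -> AlleleMatrix:
    """Count alleles positionally from forward-oriented VR segments.

    Only segments whose length equals the reference length are counted
    (the DGR channel is substitution-only); length-discordant segments
    are indel evidence and are discarded and tallied.
    """
    L = len(vr_reference)
    kept, discarded = [], 0
    for seg in vr_segments:
        if len(seg) == L:
            kept.append(seg.upper())
        else:
            discarded += 1
    if not kept:
        raise EmptyMatrixError("no segments matched the VR reference length")
    arr = np.frombuffer("".join(kept).encode(), dtype=np.uint8).reshape(len(kept), L)
    counts = np.zeros((L, 4), dtype=np.int64)
    for base, col in _BASE_TO_COL.items():
        counts[:, col] = (arr == ord(base)).sum(axis=0)
    return AlleleMatrix(
        counts=counts,
        reference=vr_reference.upper(),
        n_spanning_reads=len(kept),
        n_discarded_length=discarded,
    )


@dataclass
class DiversityProfile:
    """Per-position nucleotide diversity over the VR."""

    pi: np.ndarray  # NaN where coverage is zero
    targeted: np.ndarray  # boolean mask
    nonref_freq: np.ndarray  # NaN where coverage is zero
    coverage: np.ndarray
    n_spanning_reads: int

    def to_frame(self, matrix: AlleleMatrix | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": np.arange(self.pi.size),
                "coverage": self.coverage,
                "pi": self.pi,
                "targeted": self.targeted,
                "nonref_freq": self.nonref_freq,
            }
        )
        if matrix is not None:
            for base, col in _BASE_TO_COL.items():
                df[base] = matrix.counts[:, col]
            df["reference"] = list(matrix.reference)
        return df


def site_diversity(matrix: AlleleMatrix, targeted: np.ndarray) -> DiversityProfile:
    """Per-position pi = 1 - sum of squared allele frequencies.

    Positions with zero coverage are flagged NaN and excluded from all
    downstream means.
    """
    cov = matrix.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = matrix.counts / cov[:, None]
        pi = 1.0 - (freqs**2).sum(axis=1)
    ref_cols = np.array([_BASE_TO_COL[b] for b in matrix.reference])
    nonref = 1.0 - freqs[np.arange(len(ref_cols)), ref_cols]
    pi[cov == 0] = np.nan
    nonref[cov == 0] = np.nan
    mask = np.zeros(len(ref_cols), dtype=bool)
    mask[np.asarray(targeted, dtype=int)] = True
    return DiversityProfile(
        pi=pi,
        targeted=mask,
        nonref_freq=nonref,
        coverage=matrix.coverage,
        n_spanning_reads=matrix.n_spanning_reads,
    )


@dataclass
class ActivityCall:
    """Outcome of the two-standard-deviation DGR activity rule."""

    mean_pi_A: float
    mean_pi_nonA: float
    sd_pi_nonA: float
    threshold: float
    active: bool
    status: str  # "ok" | "insufficient_coverage" | "not_evaluable"
    n_spanning_reads: int
    min_spanning: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps({k: (v if not isinstance(v, float) or np.isfinite(v) else None) for k, v in d.items()})


def call_activity(profile: DiversityProfile, min_spanning: int = 30) -> ActivityCall:
    """Call DGR activity: mean(pi, A) > mean(pi, nonA) + 2 * sd(pi, nonA).

    The standard deviation is the sample sd (n-1 denominator) over
    non-targeted positions. Calls require ``min_spanning`` full-span
    reads and at least two non-targeted positions with coverage; NaN
    (zero-coverage) positions are excluded from both means.
    """
    pi_a = profile.pi[profile.targeted]
    pi_non = profile.pi[~profile.targeted]
    pi_a = pi_a[~np.isnan(pi_a)]
    pi_non = pi_non[~np.isnan(pi_non)]

    def _call(status: str, active: bool = False, **kw) -> ActivityCall:
        return ActivityCall(
            mean_pi_A=kw.get("mean_pi_A", float("nan")),
            mean_pi_nonA=kw.get("mean_pi_nonA", float("nan")),
            sd_pi_nonA=kw.get("sd_pi_nonA", float("nan")),
            threshold=kw.get("threshold", float("nan")),
            active=active,
            status=status,
            n_spanning_reads=profile.n_spanning_reads,
            min_spanning=min_spanning,
        )

    if profile.n_spanning_reads < min_spanning:
        return _call("insufficient_coverage")
    if pi_a.size == 0 or pi_non.size < 2:
        return _call("not_evaluable")
    mean_a = float(pi_a.mean())
    mean_non = float(pi_non.mean())
    sd_non = float(pi_non.std(ddof=1))
    threshold = mean_non + 2.0 * sd_non
    return _call(
        "ok",
        active=mean_a > threshold,
        mean_pi_A=mean_a,
        mean_pi_nonA=mean_non,
        sd_pi_nonA=sd_non,
        threshold=threshold,
    )


def fold_enrichment(profile: DiversityProfile) -> tuple[float, bool]:
    """Ratio of mean non-reference frequency, targeted over non-targeted.

    Returns ``(ratio, is_finite)``; a zero denominator yields
    ``(inf, False)`` rather than raising.
    """
    t = profile.nonref_freq[profile.targeted]
    n = profile.nonref_freq[~profile.targeted]
    t = t[~np.isnan(t)]
    n = n[~np.isnan(n)]
    if t.size == 0 or n.size == 0:
        raise ValueError("both targeted and non-targeted positions are required")
    denom = float(n.mean())
    if denom == 0.0:
        return float("inf"), False
    return float(t.mean()) / denom, True


def analyze_amplicons(
    reads: str | Path | Iterable[str],
    vr_reference: str,
    tr_sequence: str,
    primer_fwd: str,
    primer_rev: str,
    min_spanning: int = 30,
) -> tuple[AlleleMatrix, DiversityProfile, ActivityCall]:
    """Full DGR pipeline: primer anchoring -> allele matrix -> pi -> call."""
    segments = extract_vr_reads(reads, primer_fwd, primer_rev)
    matrix = build_allele_matrix(segments, vr_reference)
    profile = site_diversity(matrix, targeted_positions(tr_sequence, vr_reference))
    call = call_activity(profile, min_spanning=min_spanning)
    return matrix, profile, call
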