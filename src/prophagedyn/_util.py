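"""Shared sequence and randomness helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Fixed stage offsets: every emitter derives its generator from the master
# seed via SeedSequence(master, spawn_key=(offset, ...)), so each stage is
# independently reproducible.
STAGE_OFFSETS = {
    "genome": 1,
    "transposition": 2,
    "junction_reads": 3,
    "amplicons": 4,
    "capsids": 5,
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def stage_rng(master_seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Derive a stage-specific generator from the master seed.

    ``extra`` indices allow families of independent replicates (e.g. one
    generator per simulated dataset) that remain reproducible from the
    single master seed.
    """
    offset = STAGE_OFFSETS[stage]
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(offset, *extra))
    return np.random.default_rng(ss)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


class ChunkedWriter:
    """Buffered line writer for bulk FASTQ/SAM emission."""

    def __init__(self, path: str | Path, chunk: int = 100_000):
        self._fh = open(path, "w")
        self._buf: list[str] = []
        self._chunk = chunk

    def write(self, line: str) -> None:
        self._buf.append(line)
        if len(self._buf) >= self._chunk:
            self.flush()

    def flush(self) -> None:
        if self._buf:
            self._fh.write("\n".join(self._buf) + "\n")
            self._buf.clear()

    def close(self) -> None:
        self.flush()
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
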