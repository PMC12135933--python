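"""Simulation and run configuration.

The defaults encode the mechanistic constants of the modelled system: a
Mu-like transposable prophage whose headful packaging starts 29-31 bp
upstream of the prophage 5' end, terminates stochastically within the
first 15 kb, and co-packages 1-2.3 kb of host DNA at the 3' end of
fully packaged molecules; and a diversity-generating retroelement (DGR)
that substitutes bases in the variable repeat (VR) at positions that
are adenines in the template repeat (TR).
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

#: Synthetic default template repeat: 120 nt, 39 adenines (32.5%),
#: adenine-rich as is typical for DGR template repeats.
DEFAULT_TR = (
    "GTGAATATTCAAACCCTTGTAAGAACCTGCCAAAGACATAATCTGGACCTCGACAATCTG"
    "GGGACACATAGATGATTTGAATCATGGCCAATCCAGACAATGCCTCGGCCGTATAGTACT"
)

#: Conserved primers flanking the VR used to collect full-span amplicon reads.
DEFAULT_PRIMER_FWD = "ATATCCACTGCCTCC"
DEFAULT_PRIMER_REV = "GCCAGACGAGAACCG"

#: Per-base packaging termination hazard calibrated so that survival of the
#: full 15 kb hazard region is 1/40 (the observed left/right coverage ratio).
DEFAULT_HAZARD = math.log(40.0) / 15_000.0


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic genome, molecule and read generator."""

    chromosome_length: int = 50_000
    prophage_length: int = 40_000
    prophage_start: int = 5_000
    vr_length: int = 120
    vr_offset: int = 30_000
    tr_sequence: str = DEFAULT_TR
    primer_fwd: str = DEFAULT_PRIMER_FWD
    primer_rev: str = DEFAULT_PRIMER_REV
    # DGR amplicon stage
    mu_targeted: float = 0.02
    eps_background: float = 0.001
    # transposition stage
    n_events: int = 100
    reads_per_event: int = 3
    read_length: int = 100
    clip_length_range: tuple[int, int] = (20, 40)
    # capsid stage
    n_capsids: int = 15_000
    hazard: float = DEFAULT_HAZARD
    hazard_region: int = 15_000
    flank5_range: tuple[int, int] = (29, 31)
    flank3_range: tuple[int, int] = (1_000, 2_300)
    capsid_read_depth: float = 1.0
    capsid_read_length: int = 50
    min_capsid_read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.clip_length_range = tuple(int(v) for v in self.clip_length_range)
        self.flank5_range = tuple(int(v) for v in self.flank5_range)
        self.flank3_range = tuple(int(v) for v in self.flank3_range)
        self.tr_sequence = self.tr_sequence.upper()
        self.primer_fwd = self.primer_fwd.upper()
        self.primer_rev = self.primer_rev.upper()
        self.validate()

    def validate(self) -> None:
        for name in (
            "chromosome_length",
            "prophage_length",
            "vr_length",
            "read_length",
            "capsid_read_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.prophage_start and self.prophage_end <= self.chromosome_length):
            raise ConfigError(
                "prophage interval "
                f"[{self.prophage_start}, {self.prophage_end}) does not fit in "
                f"chromosome of length {self.chromosome_length}"
            )
        if not (0 <= self.vr_offset and self.vr_offset + self.vr_length <= self.prophage_length):
            raise ConfigError("vr_offset: VR interval does not fit in prophage")
        if self.vr_offset < len(self.primer_fwd):
            raise ConfigError("vr_offset: no room for primer_fwd upstream of the VR")
        if self.vr_offset + self.vr_length + len(self.primer_rev) > self.prophage_length:
            raise ConfigError("vr_offset: no room for primer_rev downstream of the VR")
        if len(self.tr_sequence) != self.vr_length:
            raise ConfigError(
                f"tr_sequence length {len(self.tr_sequence)} != vr_length {self.vr_length}"
            )
        for name in ("mu_targeted", "eps_background", "hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.clip_length_range[0] < 1:
            raise ConfigError("clip_length_range: minimum clip must be >= 1")
        if self.clip_length_range[0] > self.clip_length_range[1]:
            raise ConfigError("clip_length_range: min > max")
        if self.clip_length_range[1] >= self.read_length:
            raise ConfigError("clip_length_range: max clip must be < read_length")
        for name in ("flank5_range", "flank3_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ConfigError(f"{name}: invalid range [{lo}, {hi}]")

    @property
    def prophage_end(self) -> int:
        return self.prophage_start + self.prophage_length

    @property
    def prophage_interval(self) -> tuple[int, int]:
        return (self.prophage_start, self.prophage_end)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _coerce(raw: str, py_type) -> object:
    raw = raw.strip()
    if py_type is int:
        return int(raw)
    if py_type is float:
        return float(raw)
    if py_type is str:
        return raw
    # tuple ranges written as "lo,hi" or "lo-hi"
    sep = "," if "," in raw else "-"
    lo, hi = raw.split(sep)
    return (int(lo), int(hi))


# Analysis parameters shared by the pipeline and the CLI.
@dataclass
class AnalysisParams:
    min_clip: int = 15
    min_spanning: int = 30
    window: int = 500
    frac_threshold: float = 0.01
    flank_min_frac: float = 0.10
    coverage_margin: int = 3_000


def read_config(path: str | Path) -> tuple[SimConfig, AnalysisParams, dict]:
    """Parse an INI-style config with [sim], [analysis] and [run] sections.

    Returns the simulation config, analysis parameters and a dict of raw
    [run] options (stage toggles, output paths) for the pipeline.
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    with open(path) as fh:
        parser.read_file(fh)

    sim_fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    sim_kwargs = {}
    if parser.has_section("sim"):
        for key, raw in parser.items("sim"):
            if key not in sim_fields:
                raise ConfigError(f"unknown [sim] key: {key}")
            f = sim_fields[key]
            py_type = type(f.default) if f.default is not dataclasses.MISSING else int
            sim_kwargs[key] = _coerce(raw, py_type)
    sim = SimConfig(**sim_kwargs)

    ana_fields = {f.name: f for f in dataclasses.fields(AnalysisParams)}
    ana_kwargs = {}
    if parser.has_section("analysis"):
        for key, raw in parser.items("analysis"):
            if key not in ana_fields:
                raise ConfigError(f"unknown [analysis] key: {key}")
            ana_kwargs[key] = _coerce(raw, type(ana_fields[key].default))
    ana = AnalysisParams(**ana_kwargs)

    run = dict(parser.items("run")) if parser.has_section("run") else {}
    return sim, ana, run
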