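"""Synthetic data for desk-scale polishing experiments, plus the evaluator.

The generator emulates the inputs of a long-read polishing run: a
uniform random reference, long reads corrupted with per-base
substitution/insertion/deletion errors at configurable coverage, an
erroneous draft backbone (the stand-in for an assembler's contig), and
optionally accurate "NGS contig" queries for the hybrid mode.  Two
presets match the error regimes of the targeted platforms: ``pacbio``
(~15% total error, indel-dominated: sub 0.01 / ins 0.09 / del 0.05) and
``nanopore`` (~40%: sub 0.12 / ins 0.08 / del 0.20).

Read start positions are drawn from ``[-(L-1), G-1]`` and clipped to the
reference, so coverage is uniform across the whole target — the regime
of polishing a contig whose supporting reads extend past its ends.

``error_rate`` is a desk-scale replacement for a whole-genome diff
tool: a global edit alignment of consensus vs. truth, counting
(mismatches + insertions + deletions) / alignment columns, with an
n-base gap counting as n errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import edlib
import numpy as np

from .io_formats import SequenceRecord, revcomp

__all__ = [
    "SimConfig",
    "ReadPlacement",
    "simulate_genome",
    "simulate_reads",
    "simulate_hq_queries",
    "make_draft_backbone",
    "error_rate",
    "error_counts",
    "PRESETS",
]

# (sub_rate, ins_rate, del_rate)
PRESETS = {
    "pacbio": (0.01, 0.09, 0.05),
    "nanopore": (0.12, 0.08, 0.20),
}

_BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# independent RNG streams per operation, all keyed off SimConfig.seed
_STREAM_GENOME = 0
_STREAM_READS = 1
_STREAM_HQ = 2
_STREAM_DRAFT = 3


@dataclass
class SimConfig:
    """Error-profile, coverage and length parameters of one simulation."""

    genome_length: int = 20000
    coverage: float = 30.0
    read_length_mean: float = 2000.0
    read_length_sd: float = 500.0
    sub_rate: float = 0.01
    ins_rate: float = 0.09
    del_rate: float = 0.05
    hq_coverage: float = 0.0
    hq_length: int = 2000
    hq_prefix: str = "hq"
    min_read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        try:
            sub, ins, dele = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None
        return cls(sub_rate=sub, ins_rate=ins, del_rate=dele, **overrides)


@dataclass(frozen=True)
class ReadPlacement:
    """True origin of a simulated read, for diagnostics."""

    name: str
    start: int
    end: int
    strand: str


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def corrupt(sequence: str, sub: float, ins: float, dele: float,
            rng: np.random.Generator) -> str:
    """Inject errors: per base delete w.p. ``dele``, else substitute w.p.
    ``sub`` (to a different base); independently insert uniform bases
    after the position, geometrically repeated w.p. ``ins``."""
    n = len(sequence)
    if n == 0:
        return ""
    dels = rng.random(n) < dele
    subs = rng.random(n) < sub
    sub_off = rng.integers(1, 4, size=n)
    if ins > 0:
        ins_counts = rng.geometric(1.0 - ins, size=n) - 1
        ins_bases = rng.integers(0, 4, size=int(ins_counts.sum()))
    else:
        ins_counts = np.zeros(n, dtype=np.int64)
        ins_bases = np.empty(0, dtype=np.int64)
    out: List[str] = []
    ii = 0
    for p in range(n):
        if not dels[p]:
            base = sequence[p]
            if subs[p]:
                base = _BASES[(_BASE_INDEX.get(base, 0) + sub_off[p]) % 4]
            out.append(base)
        c = int(ins_counts[p])
        if c:
            out.extend(_BASES[b] for b in ins_bases[ii : ii + c])
            ii += c
    return "".join(out)


def simulate_genome(config: SimConfig) -> SequenceRecord:
    """Uniform i.i.d. A/C/G/T reference; deterministic per seed."""
    rng = _rng(config, _STREAM_GENOME)
    codes = rng.integers(0, 4, size=config.genome_length)
    sequence = bytes(_CODE_TO_BASE[codes]).decode()
    return SequenceRecord(name="genome", sequence=sequence)


def _sample_segments(
    genome: SequenceRecord,
    coverage: float,
    length_mean: float,
    length_sd: float,
    min_length: int,
    rng: np.random.Generator,
) -> List[Tuple[int, int, str]]:
    """(start, end, strand) tuples until total bases >= coverage * G."""
    G = len(genome)
    target = coverage * G
    total = 0.0
    segments: List[Tuple[int, int, str]] = []
    while total < target:
        length = max(int(rng.normal(length_mean, length_sd)), min_length)
        length = min(length, G) if G >= min_length else G
        start = int(rng.integers(-(length - 1), G)) if length > 1 else int(
            rng.integers(0, G)
        )
        s, e = max(0, start), min(G, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        if e - s < min(min_length, G):
            continue
        segments.append((s, e, strand))
        total += e - s
    return segments


def simulate_reads(
    genome: SequenceRecord, config: SimConfig
) -> Tuple[List[SequenceRecord], List[ReadPlacement]]:
    """Error-injected long reads at the configured coverage.

    Both strands are equiprobable; true placements are returned for
    diagnostics.  Deterministic per seed.
    """
    rng = _rng(config, _STREAM_READS)
    reads: List[SequenceRecord] = []
    placements: List[ReadPlacement] = []
    segments = _sample_segments(
        genome,
        config.coverage,
        config.read_length_mean,
        config.read_length_sd,
        config.min_read_length,
        rng,
    )
    for idx, (s, e, strand) in enumerate(segments):
        segment = genome.sequence[s:e]
        if strand == "-":
            segment = revcomp(segment)
        errored = corrupt(
            segment, config.sub_rate, config.ins_rate, config.del_rate, rng
        )
        if not errored:
            continue
        name = f"read{idx:05d}"
        reads.append(SequenceRecord(name=name, sequence=errored))
        placements.append(ReadPlacement(name=name, start=s, end=e, strand=strand))
    return reads, placements


def simulate_hq_queries(
    genome: SequenceRecord, config: SimConfig
) -> List[SequenceRecord]:
    """Error-free high-quality queries (the NGS stand-in) at hq_coverage.

    Names carry ``config.hq_prefix`` so the consensus engine can apply
    the hybrid boost to the edges they support.
    """
    if config.hq_coverage <= 0:
        return []
    rng = _rng(config, _STREAM_HQ)
    segments = _sample_segments(
        genome,
        config.hq_coverage,
        float(config.hq_length),
        0.1 * config.hq_length,
        config.min_read_length,
        rng,
    )
    queries: List[SequenceRecord] = []
    for idx, (s, e, strand) in enumerate(segments):
        segment = genome.sequence[s:e]
        if strand == "-":
            segment = revcomp(segment)
        queries.append(
            SequenceRecord(name=f"{config.hq_prefix}{idx:05d}", sequence=segment)
        )
    return queries


def make_draft_backbone(
    genome: SequenceRecord,
    config: SimConfig,
    rates: Optional[Tuple[float, float, float]] = None,
) -> SequenceRecord:
    """The genome corrupted with an error profile (default: the read
    profile), i.e. a realistic erroneous draft for polishing."""
    sub, ins, dele = rates if rates is not None else (
        config.sub_rate,
        config.ins_rate,
        config.del_rate,
    )
    rng = _rng(config, _STREAM_DRAFT)
    draft = corrupt(genome.sequence, sub, ins, dele, rng)
    if not draft:
        raise ValueError("draft backbone came out empty; lower the error rates")
    return SequenceRecord(name="backbone", sequence=draft)


def error_counts(
    consensus: SequenceRecord, truth: SequenceRecord
) -> Tuple[int, int]:
    """(errors, alignment columns) of a global edit alignment."""
    if not consensus.sequence or not truth.sequence:
        raise ValueError("sequences must be non-empty")
    result = edlib.align(
        consensus.sequence, truth.sequence, mode="NW", task="path"
    )
    return result["editDistance"], _cigar_columns(result["cigar"])


def error_rate(consensus: SequenceRecord, truth: SequenceRecord) -> float:
    """Per-base error of consensus vs. truth.

    Global (Needleman-Wunsch-style) edit alignment; the rate is
    (mismatches + insertions + deletions) / alignment columns, so an
    n-base gap counts as n errors.
    """
    errors, columns = error_counts(consensus, truth)
    return errors / columns


def _cigar_columns(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total
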