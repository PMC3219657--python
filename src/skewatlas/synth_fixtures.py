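"""Synthetic genomes and tracks with known ground truth.

The generator emulates prokaryotic GC-skew polarity: on the replichore
running clockwise from the replication origin (oriC) to the terminus, G
is sampled more often than C by a programmed excess; on the other
replichore the excess is reversed.  The cumulative GC skew of such a
chromosome is Lambda-shaped when the sequence starts at oriC, V-shaped
when it starts at the terminus, and a shifted Lambda/V otherwise, so
`locate_extrema` on the cumulative skew should recover the programmed
oriC.  Bases are sampled independently (no dinucleotide structure);
this keeps the ground truth analytically controllable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .genome_io import GenomicFeature, SequenceRecord
from .properties import PropertyTrack

_BASES = np.array(list("ACGT"))


@dataclass
class SkewGenomeSpec:
    """Parameters of a synthetic chromosome with programmed skew polarity.

    skew_strength is the relative G-over-C excess on the leading
    strand: P(G) - P(C) = skew_strength * gc_content there (reversed on
    the lagging replichore).  noise_sd adds per-base Gaussian jitter to
    the local skew; period (bp) optionally superimposes a sinusoidal
    modulation of the skew at that wavelength.
    """

    length: int = 200_000
    oric_pos: int = 1
    ter_pos: int = 100_000
    skew_strength: float = 0.3
    gc_content: float = 0.5
    noise_sd: float = 0.0
    period: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.oric_pos == self.ter_pos:
            raise ValueError("oric_pos and ter_pos must differ")
        if not 0.0 < self.skew_strength <= 0.5 and self.skew_strength != 0.0:
            raise ValueError("skew_strength must be 0 or in (0, 0.5]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for pos in (self.oric_pos, self.ter_pos):
            if not 1 <= pos <= self.length:
                raise ValueError("oriC/terminus positions must lie on the sequence")


def make_skewed_genome(spec: SkewGenomeSpec) -> SequenceRecord:
    """Sample a circular chromosome per the spec; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    pos = np.arange(1, spec.length + 1)
    # leading replichore: clockwise from oriC to ter (wrapping)
    if spec.oric_pos < spec.ter_pos:
        leading = (pos >= spec.oric_pos) & (pos < spec.ter_pos)
    else:
        leading = (pos >= spec.oric_pos) | (pos < spec.ter_pos)
    skew = np.where(leading, spec.skew_strength, -spec.skew_strength)
    if spec.period:
        skew = skew + spec.skew_strength * 0.5 * np.sin(2 * np.pi * pos / spec.period)
    if spec.noise_sd > 0:
        skew = skew + rng.normal(0.0, spec.noise_sd, size=spec.length)
    skew = np.clip(skew, -0.95, 0.95)
    gc = spec.gc_content
    p_g = gc * (1.0 + skew) / 2.0
    p_c = gc * (1.0 - skew) / 2.0
    p_a = np.full(spec.length, (1.0 - gc) / 2.0)
    # cumulative thresholds over (A, C, G, T)
    u = rng.random(spec.length)
    c1 = p_a
    c2 = c1 + p_c
    c3 = c2 + p_g
    idx = (u >= c1).astype(np.int8) + (u >= c2).astype(np.int8) + (u >= c3).astype(np.int8)
    residues = "".join(_BASES[idx])
    return SequenceRecord(
        id=f"synth-skew-{spec.seed}",
        name=f"synthetic skewed genome (oriC={spec.oric_pos}, ter={spec.ter_pos})",
        residues=residues,
        topology="circular",
    )


def make_periodic_track(
    n_windows: int,
    period_windows: int,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    window_size: int = 1000,
    name: str = "synthetic periodic",
) -> PropertyTrack:
    """Sinusoidal property track plus seeded Gaussian noise."""
    if period_windows < 2:
        raise ValueError("period_windows must be >= 2")
    rng = np.random.default_rng(seed)
    i = np.arange(n_windows)
    values = amplitude * np.cos(2 * np.pi * i / period_windows)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_windows)
    starts = (1 + i * window_size).tolist()
    return PropertyTrack.from_values(
        name=name, seq_id=f"synth-periodic-{seed}", window_size=window_size,
        step=window_size, starts=starts, values=values.tolist(),
    )


def make_genbank_fixture(
    record: SequenceRecord, features: list[GenomicFeature], path: str | Path
) -> Path:
    """Write a minimal valid GenBank flat file that read_genbank round-trips.

    Origin-spanning features (start > end on a circular record) are
    emitted as join(start..L, 1..end) compound locations.
    """
    path = Path(path)
    bio = BioSeqRecord(
        Seq(record.residues), id=record.id, name=record.id.split(".")[0][:16] or "SYNTH",
        description=record.name,
    )
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = record.topology
    for f in features:
        strand = {"+": 1, "-": -1, ".": None}[f.strand]
        if f.start <= f.end:
            location = SimpleLocation(f.start - 1, f.end, strand=strand)
        else:
            if record.topology != "circular":
                raise ValueError("origin-spanning feature on a linear record")
            location = CompoundLocation([
                SimpleLocation(f.start - 1, record.length, strand=strand),
                SimpleLocation(0, f.end, strand=strand),
            ])
        qualifiers = {}
        if f.label:
            qualifiers["gene"] = [f.label]
        bio.features.append(SeqFeature(location, type=f.category, qualifiers=qualifiers))
    SeqIO.write([bio], str(path), "genbank")
    return path


def write_fasta(record: SequenceRecord, path: str | Path) -> Path:
    """Write a SequenceRecord as single-record FASTA."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{record.id} {record.name}\n")
        for i in range(0, record.length, 70):
            fh.write(record.residues[i : i + 70] + "\n")
    return path
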