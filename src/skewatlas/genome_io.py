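"""Sequence and track I/O: GenBank, FASTA, and the GDF track-exchange dialect.

Coordinates are 1-based inclusive throughout the data model (GenBank
convention).  On circular sequences a feature may span the origin, in
which case ``start > end`` and the feature wraps through position 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .properties import PropertyTrack

logger = logging.getLogger(__name__)

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


@dataclass
class SequenceRecord:
    """A chromosome or plasmid sequence with identity and topology."""

    id: str
    name: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        self.residues = self.residues.upper()

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GenomicFeature:
    """A positional annotation on one sequence.

    ``start > end`` is only legal on circular sequences and denotes an
    origin-spanning feature.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    category: str = "custom"
    color: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1, got {self.start}..{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")


@dataclass
class FeatureTrack:
    """An ordered collection of features from a single sequence."""

    name: str
    seq_id: str
    features: list[GenomicFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.seq_id != self.seq_id:
                raise ValueError(
                    f"feature seq_id {f.seq_id!r} does not match track seq_id {self.seq_id!r}"
                )

    def __len__(self) -> int:
        return len(self.features)


def _location_to_coords(location, seq_len: int) -> tuple[int, int]:
    """Convert a Biopython location to 1-based inclusive (start, end).

    A compound location whose parts wrap through the origin is collapsed
    to a single origin-spanning (start, end) pair with start > end.
    """
    if isinstance(location, CompoundLocation):
        parts = sorted(location.parts, key=lambda p: int(p.start))
        # wrap: the part touching the sequence end joins the part at position 1
        ordered = list(location.parts)
        first, last = ordered[0], ordered[-1]
        if int(first.start) > int(last.end) or (
            int(first.end) == seq_len and int(last.start) == 0
        ):
            return int(first.start) + 1, int(last.end)
        return int(parts[0].start) + 1, int(parts[-1].end)
    return int(location.start) + 1, int(location.end)


def read_genbank(path: str | Path) -> tuple[SequenceRecord, list[GenomicFeature]]:
    """Read a GenBank flat file into a record plus CDS/tRNA/rRNA features.

    Topology is taken from the LOCUS line (default linear).  Features
    with unparseable locations are skipped with a warning; a missing
    sequence block is a hard error.
    """
    rec = SeqIO.read(str(path), "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no sequence (empty ORIGIN)")
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    record = SequenceRecord(
        id=rec.id, name=rec.description or rec.name, residues=str(rec.seq), topology=topology
    )
    features: list[GenomicFeature] = []
    for f in rec.features:
        if f.type not in _FEATURE_TYPES:
            continue
        if f.location is None:
            logger.warning("%s: skipping %s feature with unparseable location", path, f.type)
            continue
        start, end = _location_to_coords(f.location, record.length)
        strand = {1: "+", -1: "-"}.get(f.location.strand, ".")
        label = ""
        for key in ("gene", "locus_tag", "product"):
            if key in f.qualifiers:
                label = f.qualifiers[key][0]
                break
        features.append(
            GenomicFeature(
                seq_id=record.id, start=start, end=end, strand=strand,
                label=label, category=f.type,
            )
        )
    return record, features


def read_fasta(path: str | Path, topology: str = "linear") -> SequenceRecord:
    """Read a single-record FASTA file.

    The record id is the first whitespace-delimited header token; the
    remainder of the header becomes the display name.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single-record FASTA, found {len(records)} records")
    rec = records[0]
    return SequenceRecord(
        id=rec.id, name=rec.description or rec.id,
        residues=str(rec.seq), topology=topology,
    )


# ---------------------------------------------------------------------------
# GDF: the tab-delimited track exchange dialect.
#
# A historical format of the same name was never publicly archived;
# this dialect is this package's own stand-in, fully specified here:
#   - UTF-8 TSV; lines starting with '#' are comments, except the
#     mandatory header '#gdf<TAB>feature|property<TAB>seq_id<TAB>seq_length'.
#   - feature rows:  start  end  strand(+|-|.)  label  color(hex or .)
#   - property rows: start  end  value
#   - rows sorted by start.
# ---------------------------------------------------------------------------


def write_gdf(track, path: str | Path, seq_length: int | None = None) -> Path:
    """Write a FeatureTrack or PropertyTrack as a GDF file."""
    from .properties import PropertyTrack

    path = Path(path)
    lines: list[str] = []
    if isinstance(track, PropertyTrack):
        if seq_length is None:
            seq_length = track.coverage_length
        lines.append(f"#gdf\tproperty\t{track.seq_id}\t{seq_length}")
        for start, value in zip(track.starts, track.values):
            end = min(start + track.window_size - 1, seq_length)
            lines.append(f"{start}\t{end}\t{value!r}")
    elif isinstance(track, FeatureTrack):
        if seq_length is None:
            seq_length = max((f.end for f in track.features), default=1)
            seq_length = max(seq_length, max((f.start for f in track.features), default=1))
        lines.append(f"#gdf\tfeature\t{track.seq_id}\t{seq_length}")
        for f in sorted(track.features, key=lambda f: f.start):
            color = f.color if f.color else "."
            lines.append(f"{f.start}\t{f.end}\t{f.strand}\t{f.label}\t{color}")
    else:
        raise TypeError(f"cannot write {type(track).__name__} as GDF")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_gdf(path: str | Path, name: str | None = None):
    """Read a GDF file into a FeatureTrack or PropertyTrack.

    The track name defaults to the file stem.  Mixed feature/property
    rows and malformed rows are rejected with the offending line number.
    """
    from .properties import PropertyTrack

    path = Path(path)
    if name is None:
        name = path.stem
    kind = seq_id = None
    seq_length = 0
    feature_rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#gdf\t"):
                parts = line.split("\t")
                if len(parts) != 4 or parts[1] not in ("feature", "property"):
                    raise ValueError(f"{path}:{lineno}: malformed GDF header")
                kind, seq_id, seq_length = parts[1], parts[2], int(parts[3])
                continue
            if line.startswith("#"):
                continue
            if kind is None:
                raise ValueError(f"{path}:{lineno}: data row before GDF header")
            cols = line.split("\t")
            expected = 5 if kind == "feature" else 3
            if len(cols) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} columns for {kind} row, got {len(cols)}"
                )
            feature_rows.append((lineno, cols))

    if kind is None:
        raise ValueError(f"{path}: missing GDF header line")

    if kind == "feature":
        features = []
        for lineno, cols in feature_rows:
            start, end = int(cols[0]), int(cols[1])
            features.append(
                GenomicFeature(
                    seq_id=seq_id, start=start, end=end, strand=cols[2],
                    label=cols[3], color=None if cols[4] == "." else cols[4],
                )
            )
        return FeatureTrack(name=name, seq_id=seq_id, features=features)

    starts: list[int] = []
    values: list[float] = []
    window = None
    for lineno, cols in feature_rows:
        start, end = int(cols[0]), int(cols[1])
        if end < start:
            raise ValueError(f"{path}:{lineno}: end < start in property row")
        try:
            value = float(cols[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric value {cols[2]!r}") from None
        if window is None:
            window = end - start + 1
        starts.append(start)
        values.append(value)
    if not starts:
        raise ValueError(f"{path}: property GDF has no value rows")
    step = starts[1] - starts[0] if len(starts) > 1 else window
    return PropertyTrack.from_values(
        name=name, seq_id=seq_id, window_size=window, step=step,
        starts=starts, values=values,
    )


def extract_strand_tracks(
    features: list[GenomicFeature], name_prefix: str = "CDS"
) -> tuple[FeatureTrack, FeatureTrack]:
    """Partition CDS features into forward and reverse strand tracks.

    Non-CDS features are ignored.  Strandless CDS features are assigned
    to the forward track with a warning.
    """
    cds = [f for f in features if f.category == "CDS"]
    seq_id = cds[0].seq_id if cds else (features[0].seq_id if features else "unknown")
    forward = [f for f in cds if f.strand == "+"]
    reverse = [f for f in cds if f.strand == "-"]
    strandless = [f for f in cds if f.strand == "."]
    if strandless:
        logger.warning("%d strandless CDS features assigned to the forward track", len(strandless))
        forward = sorted(forward + strandless, key=lambda f: f.start)
    return (
        FeatureTrack(name=f"{name_prefix} forward", seq_id=seq_id, features=forward),
        FeatureTrack(name=f"{name_prefix} reverse", seq_id=seq_id, features=reverse),
    )
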