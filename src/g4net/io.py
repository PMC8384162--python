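"""Genomic interval, sequence and coverage-track I/O.

Coordinates are 0-based half-open (BED convention) everywhere. DNA windows
are always taken from the reference strand: the model does not treat the
two strands differently, and complementary motifs are merged downstream by
motif clustering rather than by read-time reverse complementing.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval, optionally with a peak summit.

    ``summit_offset`` is the offset of the summit from ``start``
    (narrowPeak column 10); ``summit`` gives the absolute coordinate.
    """

    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    score: float | None = None
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit_offset is not None:
            if self.summit_offset < 0 or self.start + self.summit_offset >= self.end:
                raise ValueError(
                    f"summit offset {self.summit_offset} outside interval "
                    f"{self.chrom}:{self.start}-{self.end}"
                )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit coordinate; interval midpoint when no summit is recorded."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class OneHotSequence:
    """L x 4 one-hot encoding of a DNA string, columns ordered (A, C, G, T).

    Letters outside {A, C, G, T} (N, IUPAC ambiguity codes) encode as
    all-zero rows so the convolution stays well defined.
    """

    matrix: np.ndarray
    source: str

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.source), 4):
            raise ValueError("matrix shape does not match source length")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_regions(path: str | Path, format: str = "bed") -> list[GenomicRegion]:
    """Read intervals from a BED3/BED6 or ENCODE narrowPeak file.

    narrowPeak rows must have >= 10 columns; column 10 (the summit offset
    from the interval start) is kept, with -1 meaning "no summit called".
    Malformed rows raise with the 1-based line number.
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown region format {format!r}")
    regions: list[GenomicRegion] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "narrowPeak" and len(fields) < 10:
                    raise ValueError(
                        f"narrowPeak row has {len(fields)} columns, need >= 10"
                    )
                if len(fields) < 3:
                    raise ValueError("need at least 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
                summit = None
                if format == "narrowPeak":
                    raw = int(fields[9])
                    summit = raw if raw >= 0 else None
                regions.append(
                    GenomicRegion(chrom, start, end, summit, score, strand, name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return regions


def write_regions(
    regions: Iterable[GenomicRegion], path: str | Path, format: str = "bed"
) -> None:
    """Write intervals as BED6 or 10-column narrowPeak."""
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown region format {format!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in regions:
            score = "." if r.score is None else f"{r.score:g}"
            cols = [r.chrom, str(r.start), str(r.end), r.name, score, r.strand]
            if format == "narrowPeak":
                summit = -1 if r.summit_offset is None else r.summit_offset
                cols += ["-1", "-1", "-1", str(summit)]
            fh.write("\t".join(cols) + "\n")


def fetch_sequence(region: GenomicRegion, genome) -> str:
    """Extract the reference-strand sequence of a region, uppercased.

    ``genome`` is a mapping chrom -> str (toy genomes) or a
    ``pyfaidx.Fasta`` handle. Raises on unknown chromosomes and
    out-of-bounds intervals.
    """
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} absent from genome")
    record = genome[region.chrom]
    length = len(record)
    if region.end > length:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {length}"
        )
    seq = record[region.start : region.end]
    if not isinstance(seq, str):  # pyfaidx.Sequence
        seq = str(seq)
    return seq.upper()


def one_hot_encode(seq: str) -> OneHotSequence:
    """Encode DNA as an L x 4 matrix with column order (A, C, G, T)."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    seq = seq.upper()
    idx = np.fromiter(
        (_BASE_INDEX.get(b, 4) for b in seq), dtype=np.int64, count=len(seq)
    )
    matrix = np.zeros((len(seq), 5), dtype=np.float32)
    matrix[np.arange(len(seq)), idx] = 1.0
    return OneHotSequence(matrix[:, :4], seq)


def one_hot_decode(encoded: OneHotSequence | np.ndarray) -> str:
    """Invert :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = encoded.matrix if isinstance(encoded, OneHotSequence) else encoded
    letters = []
    for row in matrix:
        if row.sum() == 0:
            letters.append("N")
        else:
            letters.append(BASES[int(np.argmax(row))])
    return "".join(letters)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode_batch(sequences: Iterable[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L, 4) float32 array."""
    mats = [one_hot_encode(s).matrix for s in sequences]
    return np.stack(mats).astype(np.float32)


@dataclass
class SignalTrack:
    """Piecewise-constant coverage (bedGraph semantics).

    Per chromosome: sorted, non-overlapping intervals with finite
    non-negative values; uncovered bases count as zero.
    """

    intervals: dict = field(default_factory=dict)  # chrom -> (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"invalid signal value {value} at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            values = np.array([r[2] for r in rows], dtype=np.float64)
            track.intervals[chrom] = (starts, ends, values)
        return track

    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "SignalTrack":
        records = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}, line {lineno}: need 4 columns")
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
        return cls.from_records(records)

    @classmethod
    def read_bigwig(cls, path: str | Path) -> "SignalTrack":
        """Optional convenience reader; requires pyBigWig."""
        import pyBigWig  # noqa: deferred optional dependency

        bw = pyBigWig.open(str(path))
        records = []
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                records.append((chrom, start, end, float(value)))
        bw.close()
        return cls.from_records(records)

    def write_bedgraph(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for chrom in sorted(self.intervals):
                starts, ends, values = self.intervals[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def mean_signal(self, region: GenomicRegion) -> float:
        """Length-weighted mean signal over a region; zero off-track.

        Unknown chromosomes warn and return 0 so that genome-wide scans
        survive contigs missing from a particular accessibility track.
        """
        if region.chrom not in self.intervals:
            warnings.warn(
                f"chromosome {region.chrom!r} absent from signal track; "
                "using mean signal 0",
                stacklevel=2,
            )
            return 0.0
        starts, ends, values = self.intervals[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            overlap = min(int(ends[i]), region.end) - max(int(starts[i]), region.start)
            if overlap > 0:
                total += overlap * float(values[i])
        return total / region.length


def mean_signal(region: GenomicRegion, track: SignalTrack) -> float:
    """Module-level convenience wrapper for :meth:`SignalTrack.mean_signal`."""
    return track.mean_signal(region)


def read_fasta(path: str | Path) -> Mapping[str, str]:
    """Load a (small) FASTA into memory as chrom -> sequence."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_genome(path: str | Path):
    """Open an indexed FASTA with pyfaidx (builds the .fai if needed)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=False)
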