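"""Readers and writers for the genomic formats the pipeline touches.

Coordinate conventions follow bedtools: BED intervals are 0-based
half-open, FASTA positions are 0-based.  Strand is mandatory on every
interval because every downstream computation is orientation-critical;
a ``.`` strand is a hard error, never silently defaulted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(dict):
    """Mapping of contig id -> uppercase DNA string over {A,C,G,T,N}."""

    def __setitem__(self, key: str, value: str) -> None:
        if not key:
            raise ValueError("contig id must be non-empty")
        if key in self:
            raise ValueError(f"duplicate contig {key!r}")
        value = value.upper()
        bad = set(value) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {key!r} contains non-IUPAC character(s): "
                + ", ".join(sorted(bad))
            )
        super().__setitem__(key, value)


@dataclass(frozen=True)
class Site:
    """One BED6 record; 0-based half-open, strand-aware."""

    contig: str
    start: int
    end: int
    name: str
    score: float
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.name!r}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end (got {self.start} >= {self.end}) for {self.name!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"strand required: got {self.strand!r} for {self.name!r} "
                "(must be '+' or '-')"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SiteSet:
    """Ordered collection of strand-aware binding-site intervals."""

    records: list[Site] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Site]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def read_genome(path: str | Path) -> GenomeSequence:
    """Parse a (multi-record) FASTA file into a :class:`GenomeSequence`.

    The contig id is the header token before the first whitespace.
    Sequences are uppercased.  Duplicate ids, an empty file and
    characters outside {A,C,G,T,N} are hard errors.
    """
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = str(record.seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sites(path: str | Path) -> SiteSet:
    """Parse a BED6 file; record order is preserved verbatim.

    Lines must carry >= 6 tab-separated fields.  start >= end and a
    strand other than '+'/'-' are hard errors naming the line number.
    """
    records: list[Site] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns (BED6), "
                    f"got {len(fields)}"
                )
            contig, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            try:
                records.append(Site(contig, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return SiteSet(records)


def write_sites(sites: SiteSet, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for s in sites:
            score = int(s.score) if float(s.score).is_integer() else s.score
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.name}\t{score}\t{s.strand}\n")


def write_profile(profile, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write a positional profile as TSV: offset, raw_density,
    smoothed_density, z (z column empty when no permutation null was
    computed).  Numeric columns carry >= 10 significant digits so a
    read-back reproduces the profile at that precision.  Optional
    ``comments`` become leading ``#`` lines.
    """
    if len(profile.offsets) == 0:
        raise ValueError("cannot write an empty profile")
    buf = io.StringIO()
    for c in comments:
        buf.write(f"# {c}\n")
    buf.write("offset\traw_density\tsmoothed_density\tz\n")
    smoothed = profile.smoothed_density
    z = profile.z
    for i, o in enumerate(profile.offsets):
        s = "" if smoothed is None else f"{smoothed[i]:.12g}"
        zz = "" if z is None else f"{z[i]:.12g}"
        buf.write(f"{o}\t{profile.raw_density[i]:.12g}\t{s}\t{zz}\n")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_profile(path: str | Path):
    """Read back a profile TSV written by :func:`write_profile`."""
    from .motif_profile import PositionalProfile  # local import: avoid cycle
    import numpy as np

    offsets, raw, smoothed, z = [], [], [], []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            offsets.append(int(fields[0]))
            raw.append(float(fields[1]))
            smoothed.append(float(fields[2]) if fields[2] else np.nan)
            z.append(float(fields[3]) if len(fields) > 3 and fields[3] else np.nan)
    if header is None or not offsets:
        raise ValueError(f"no profile rows in {path}")
    smoothed_arr = None if all(np.isnan(smoothed)) else np.asarray(smoothed)
    z_arr = None if all(np.isnan(z)) else np.asarray(z)
    return PositionalProfile(
        offsets=np.asarray(offsets, dtype=int),
        raw_density=np.asarray(raw),
        smoothed_density=smoothed_arr,
        z=z_arr,
        n_sites=0,
        meta={"source": str(path)},
    )
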