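"""Positional density of polyA-signal motifs around binding-site anchors.

The core computation: take strand-aware binding sites, extract the
flanking sequence in RNA 5'->3' orientation around each site's start
(its 5' end on the transcript), scan for the consensus polyadenylation
hexamers, and report per-offset motif density normalised by the number
of sites.  Increasing offsets always point transcriptionally
downstream; minus-strand flanks are reverse-complemented genome
sequence.

A permutation null (per-window circular sequence rotation, which
preserves each window's base composition) supplies per-offset
z-scores; and :func:`cross_site_profile` computes the positional
density of one factor's binding starts relative to another's, with the
same normalisation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomic_io import GenomeSequence, Site, SiteSet, reverse_complement

#: The five consensus polyadenylation-signal hexamers (DNA sense strand).
DEFAULT_PAS_MOTIFS = ("AATAAA", "ATTAAA", "AAATAA", "ATAAAA", "ATAAAT")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENC_TABLE[ord(_b)] = _c


class MotifSet(tuple):
    """Immutable set of uppercase DNA motifs (length >= 4, no duplicates)."""

    def __new__(cls, motifs: Sequence[str] = DEFAULT_PAS_MOTIFS):
        motifs = tuple(m.upper() for m in motifs)
        if len(set(motifs)) != len(motifs):
            raise ValueError("duplicate motifs")
        for m in motifs:
            if len(m) < 4:
                raise ValueError(f"motif {m!r} shorter than 4 nt")
            if set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} has characters outside ACGT")
        return super().__new__(cls, motifs)

    @property
    def max_length(self) -> int:
        return max(len(m) for m in self)


@dataclass(frozen=True)
class FlankWindow:
    """2F nt of sequence around one site's anchor, RNA 5'->3' oriented.

    Offsets run -F .. F-1 with the anchor base at offset 0; on the
    minus strand the sequence is the reverse complement of the genome,
    so larger offsets are always downstream on the transcript.
    """

    site_name: str
    flank: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank:
            raise ValueError(
                f"window {self.site_name!r}: sequence length {len(self.sequence)} "
                f"!= 2F = {2 * self.flank}"
            )

    def offset_to_index(self, offset: int) -> int:
        return offset + self.flank


@dataclass
class PositionalProfile:
    """Per-offset motif (or co-binding) density, occurrences per site."""

    offsets: np.ndarray
    raw_density: np.ndarray
    n_sites: int
    smoothed_density: np.ndarray | None = None
    z: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.raw_density = np.asarray(self.raw_density, dtype=float)
        if self.offsets.shape != self.raw_density.shape:
            raise ValueError("offsets and raw_density must have the same shape")
        if np.any(self.raw_density < 0):
            raise ValueError("raw_density must be non-negative")

    @property
    def flank(self) -> int:
        return -int(self.offsets[0])

    def density_at(self, offset: int) -> float:
        idx = np.searchsorted(self.offsets, offset)
        if idx >= len(self.offsets) or self.offsets[idx] != offset:
            raise KeyError(offset)
        return float(self.raw_density[idx])

    def argmax_offset(self, smoothed: bool = True) -> int:
        """Offset of the profile maximum; ties resolve to the smallest offset."""
        values = (
            self.smoothed_density
            if smoothed and self.smoothed_density is not None
            else self.raw_density
        )
        return int(self.offsets[int(np.argmax(values))])


def anchor_position(site: Site) -> int:
    """Genomic coordinate of the site's 5' end in RNA orientation.

    '+' -> start; '-' -> end - 1.
    """
    return site.start if site.strand == "+" else site.end - 1


def extract_flanks(
    sites: SiteSet, genome: GenomeSequence, flank: int = 100
) -> tuple[list[FlankWindow], int]:
    """Extract 2F-nt oriented windows around every site anchor.

    Plus strand: genome[anchor-F : anchor+F].  Minus strand: reverse
    complement of genome[anchor-F+1 : anchor+F+1], so offset ``o``
    reads the genomic base at ``anchor - o`` (complemented).  Sites
    whose window would cross a contig boundary are dropped and counted.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    windows: list[FlankWindow] = []
    n_dropped = 0
    for site in sites:
        if site.contig not in genome:
            raise KeyError(f"contig {site.contig!r} not in genome")
        contig_seq = genome[site.contig]
        anchor = anchor_position(site)
        if site.strand == "+":
            lo, hi = anchor - flank, anchor + flank
            if lo < 0 or hi > len(contig_seq):
                n_dropped += 1
                continue
            seq = contig_seq[lo:hi]
        else:
            lo, hi = anchor - flank + 1, anchor + flank + 1
            if lo < 0 or hi > len(contig_seq):
                n_dropped += 1
                continue
            seq = reverse_complement(contig_seq[lo:hi])
        windows.append(FlankWindow(site.name, flank, seq))
    if sites.records and not windows:
        raise ValueError("all sites dropped: every window crosses a contig boundary")
    return windows, n_dropped


def scan_motif_starts(
    window: FlankWindow, motifs: MotifSet | Sequence[str] = DEFAULT_PAS_MOTIFS
) -> list[tuple[int, str]]:
    """All exact, possibly overlapping motif occurrences in one window.

    Returns (start offset, motif) pairs, sorted by offset then motif.
    A position may emit several motifs; any N in the candidate span
    means no match (N equals nothing).
    """
    motifs = MotifSet(motifs)
    seq = window.sequence
    hits: list[tuple[int, str]] = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append((start - window.flank, motif))
            start = seq.find(motif, start + 1)
    hits.sort()
    return hits


def _encode_windows(windows: Sequence[FlankWindow]) -> np.ndarray:
    """Stack window sequences into an (n, 2F) uint8 code matrix."""
    flank = windows[0].flank
    for w in windows:
        if w.flank != flank:
            raise ValueError("all windows must share the same flank F")
    raw = np.frombuffer(
        ("".join(w.sequence for w in windows)).encode("ascii"), dtype=np.uint8
    )
    return _ENC_TABLE[raw].reshape(len(windows), 2 * flank)


def _match_counts(encoded: np.ndarray, motifs: MotifSet) -> np.ndarray:
    """Total motif-start count per window position, summed over motifs.

    Vectorised over the whole window stack; positions where no full
    motif fits contribute zero.
    """
    n, width = encoded.shape
    counts = np.zeros(width, dtype=np.int64)
    for motif in motifs:
        k = len(motif)
        if k > width:
            continue
        codes = [_BASE_CODE[b] for b in motif]
        hit = encoded[:, 0 : width - k + 1] == codes[0]
        for j in range(1, k):
            hit &= encoded[:, j : width - k + 1 + j] == codes[j]
        counts[0 : width - k + 1] += hit.sum(axis=0)
    return counts


def aggregate_density(
    windows: Sequence[FlankWindow],
    motifs: MotifSet | Sequence[str] = DEFAULT_PAS_MOTIFS,
) -> PositionalProfile:
    """Per-offset motif density: total match starts / number of windows."""
    if not windows:
        raise ValueError("no windows to aggregate")
    motifs = MotifSet(motifs)
    flank = windows[0].flank
    if flank < motifs.max_length:
        raise ValueError("flank smaller than the longest motif")
    encoded = _encode_windows(windows)
    counts = _match_counts(encoded, motifs)
    offsets = np.arange(-flank, flank)
    return PositionalProfile(
        offsets=offsets,
        raw_density=counts / len(windows),
        n_sites=len(windows),
        meta={"motifs": tuple(motifs), "total_matches": int(counts.sum())},
    )


def smooth_profile(profile: PositionalProfile, window: int = 11) -> PositionalProfile:
    """Centred moving average; at the edges the window truncates to the
    offsets that exist.  Returns a new profile; raw_density unchanged.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if not 1 <= window <= len(profile.offsets):
        raise ValueError("smoothing window must be within 1..n_offsets")
    kernel = np.ones(window)
    sums = np.convolve(profile.raw_density, kernel, mode="same")
    norms = np.convolve(np.ones_like(profile.raw_density), kernel, mode="same")
    return PositionalProfile(
        offsets=profile.offsets.copy(),
        raw_density=profile.raw_density.copy(),
        smoothed_density=sums / norms,
        z=None if profile.z is None else profile.z.copy(),
        n_sites=profile.n_sites,
        meta={**profile.meta, "smooth_window": window},
    )


def permutation_z(
    windows: Sequence[FlankWindow],
    motifs: MotifSet | Sequence[str] = DEFAULT_PAS_MOTIFS,
    n_perm: int = 1000,
    seed: int = 0,
) -> PositionalProfile:
    """Observed profile plus per-offset z-scores against a rotation null.

    Each null replicate independently circularly rotates every window's
    sequence by a uniform random shift (preserving its base
    composition), then re-aggregates.  z = (obs - mean_null) / sd_null
    with sd over replicates (ddof=1); z := 0 where sd == 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    motifs = MotifSet(motifs)
    profile = aggregate_density(windows, motifs)
    encoded = _encode_windows(windows)
    n, width = encoded.shape
    rng = np.random.default_rng(seed)
    cols = np.arange(width)
    acc = np.zeros(width)
    acc2 = np.zeros(width)
    for _ in range(n_perm):
        shifts = rng.integers(0, width, size=n)
        rotated = encoded[np.arange(n)[:, None], (cols[None, :] + shifts[:, None]) % width]
        null = _match_counts(rotated, motifs) / n
        acc += null
        acc2 += null * null
    mean_null = acc / n_perm
    var_null = (acc2 - n_perm * mean_null**2) / (n_perm - 1)
    sd_null = np.sqrt(np.clip(var_null, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_null > 0, (profile.raw_density - mean_null) / sd_null, 0.0)
    profile.z = z
    profile.meta.update(n_perm=n_perm, seed=seed)
    return profile


def cross_site_profile(
    anchor_sites: SiteSet, query_sites: SiteSet, flank: int = 100
) -> PositionalProfile:
    """Density of query-site anchors at each offset relative to anchor
    sites, in the anchor's RNA orientation.

    Only same-contig, same-strand pairs count.  Plus-strand anchors:
    offset = query_anchor - anchor; minus strand: offset = anchor -
    query_anchor.  Density is normalised by the number of anchor sites.
    """
    if not anchor_sites.records or not query_sites.records:
        raise ValueError("both site sets must be non-empty")
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for q in query_sites:
        by_key[(q.contig, q.strand)].append(anchor_position(q))
    sorted_queries = {k: np.sort(np.asarray(v)) for k, v in by_key.items()}

    offsets = np.arange(-flank, flank)
    counts = np.zeros(2 * flank, dtype=np.int64)
    for a in anchor_sites:
        positions = sorted_queries.get((a.contig, a.strand))
        if positions is None:
            continue
        anchor = anchor_position(a)
        if a.strand == "+":
            lo, hi = anchor - flank, anchor + flank  # genomic [lo, hi)
            sel = positions[np.searchsorted(positions, lo) : np.searchsorted(positions, hi)]
            rel = sel - anchor
        else:
            lo, hi = anchor - flank + 1, anchor + flank + 1
            sel = positions[np.searchsorted(positions, lo) : np.searchsorted(positions, hi)]
            rel = anchor - sel
        np.add.at(counts, rel + flank, 1)
    return PositionalProfile(
        offsets=offsets,
        raw_density=counts / len(anchor_sites),
        n_sites=len(anchor_sites),
        meta={"kind": "cross_site", "total_matches": int(counts.sum())},
    )
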