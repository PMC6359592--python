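"""Restriction-fragment model of a genomic locus.

A 3C experiment is read out per restriction fragment: the bait (promoter)
fragment is fixed and every other fragment's ligation frequency with it is
measured.  This module digests a locus sequence in silico with a single
restriction enzyme (HindIII by default), assigns each fragment a signed
distance in kilobases from the transcription start site (negative =
upstream in gene orientation), and answers point-to-fragment queries.

Coordinates are 0-based, half-open throughout; BED is used on disk.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InvalidInputError, OutOfRangeError

_VALID_STRANDS = {"+", "-", "."}
_SEQ_ALPHABET = set("ACGTN")
_MOTIF_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InvalidInputError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise InvalidInputError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise InvalidInputError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment between consecutive enzyme cut sites.

    ``tss_distance_kb`` is the signed distance from the fragment midpoint to
    the TSS in kilobases, oriented so that negative always means upstream of
    the gene regardless of which genomic strand the gene lies on.  It is
    ``None`` until :func:`assign_tss_distances` fills it in.
    """

    fragment_id: int
    interval: GenomicInterval
    tss_distance_kb: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint


@dataclass
class LocusModel:
    """Ordered fragment tiling of a locus plus the bait/TSS geometry."""

    fragments: list[RestrictionFragment]
    tss: GenomicInterval
    gene_strand: str
    bait_fragment_id: int
    annotations: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_strand not in {"+", "-"}:
            raise InvalidInputError("gene_strand must be '+' or '-'")
        ids = [f.fragment_id for f in self.fragments]
        if self.bait_fragment_id not in ids:
            raise InvalidInputError(
                f"bait_fragment_id {self.bait_fragment_id} not among fragments"
            )

    @property
    def span(self) -> GenomicInterval:
        first, last = self.fragments[0], self.fragments[-1]
        return GenomicInterval(first.interval.chrom, first.interval.start, last.interval.end)

    @property
    def bait_fragment(self) -> RestrictionFragment:
        return self.fragments[self.bait_fragment_id - self.fragments[0].fragment_id]

    def fragment(self, fragment_id: int) -> RestrictionFragment:
        frag = self.fragments[fragment_id - self.fragments[0].fragment_id]
        if frag.fragment_id != fragment_id:
            raise InvalidInputError(f"no fragment with id {fragment_id}")
        return frag


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise InvalidInputError("sequence is empty")
    seq = sequence.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise InvalidInputError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


def find_motif_positions(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) occurrences of ``motif`` in ``sequence``.

    The sequence may contain N; N never matches any motif base, which makes
    the digestion conservative in ambiguous regions.
    """
    seq = _validate_sequence(sequence)
    motif = motif.upper()
    if len(motif) < 4:
        raise InvalidInputError(f"motif must be at least 4 bp, got {motif!r}")
    if set(motif) - _MOTIF_ALPHABET:
        raise InvalidInputError(f"motif must contain only A/C/G/T, got {motif!r}")
    positions: list[int] = []
    start = 0
    while True:
        hit = seq.find(motif, start)
        if hit < 0:
            break
        positions.append(hit)
        start = hit + 1
    return positions


def digest_sequence(
    sequence: str,
    motif: str = "AAGCTT",
    *,
    chrom: str = "locus",
    cut_offset: int = 0,
) -> list[RestrictionFragment]:
    """Digest ``sequence`` at every occurrence of ``motif``.

    Returns k+1 fragments for k motif occurrences; fragments tile
    ``[0, len(sequence))`` exactly.  ``cut_offset`` places the fragment
    boundary within the motif (0 = motif start; HindIII's A^AGCTT sticky end
    would be offset 1).  Sub-motif resolution never matters downstream, so
    the default keeps boundaries at motif starts.
    """
    seq = _validate_sequence(sequence)
    positions = find_motif_positions(seq, motif)
    if not 0 <= cut_offset < len(motif):
        raise InvalidInputError(f"cut_offset must be in [0, {len(motif)}), got {cut_offset}")
    cuts = sorted({p + cut_offset for p in positions if 0 < p + cut_offset < len(seq)})
    bounds = [0, *cuts, len(seq)]
    return [
        RestrictionFragment(i, GenomicInterval(chrom, lo, hi))
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def assign_tss_distances(
    fragments: Sequence[RestrictionFragment],
    tss: GenomicInterval | int,
    gene_strand: str,
) -> list[RestrictionFragment]:
    """Fill ``tss_distance_kb`` on every fragment.

    distance = (midpoint - tss) / 1000, with the sign flipped for genes on
    the minus strand so that negative always means upstream of the gene.
    """
    if gene_strand not in {"+", "-"}:
        raise InvalidInputError("gene_strand must be '+' or '-'")
    tss_pos = tss.start if isinstance(tss, GenomicInterval) else int(tss)
    lo = fragments[0].interval.start
    hi = fragments[-1].interval.end
    if not lo <= tss_pos < hi:
        raise OutOfRangeError(f"TSS position {tss_pos} outside locus span [{lo}, {hi})")
    sign = 1.0 if gene_strand == "+" else -1.0
    return [
        replace(f, tss_distance_kb=sign * (f.midpoint - tss_pos) / 1000.0)
        for f in fragments
    ]


def locate_fragment(locus: LocusModel, position: int) -> int:
    """Fragment id of the unique fragment with start <= position < end."""
    span = locus.span
    if not span.start <= position < span.end:
        raise OutOfRangeError(
            f"position {position} outside locus span [{span.start}, {span.end})"
        )
    starts = [f.interval.start for f in locus.fragments]
    idx = bisect.bisect_right(starts, position) - 1
    return locus.fragments[idx].fragment_id


def build_locus_model(
    sequence: str,
    tss_position: int,
    gene_strand: str = "+",
    *,
    motif: str = "AAGCTT",
    chrom: str = "locus",
    cut_offset: int = 0,
    annotations: Mapping[str, GenomicInterval] | None = None,
) -> LocusModel:
    """Digest a sequence and assemble the full locus model.

    The bait fragment is the one containing the TSS.
    """
    fragments = digest_sequence(sequence, motif, chrom=chrom, cut_offset=cut_offset)
    tss = GenomicInterval(chrom, tss_position, tss_position + 1, gene_strand)
    fragments = assign_tss_distances(fragments, tss, gene_strand)
    locus = LocusModel(
        fragments=fragments,
        tss=tss,
        gene_strand=gene_strand,
        bait_fragment_id=0,
        annotations=dict(annotations or {}),
    )
    locus.bait_fragment_id = locate_fragment(locus, tss_position)
    return locus


# ---------------------------------------------------------------------------
# I/O


def read_locus_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (record id, sequence).

    Multi-record files are rejected: the locus model covers one contiguous
    region only.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(
            f"{path}: expected a single locus record, found {len(records)}"
        )
    return records[0].id, str(records[0].seq).upper()


def write_fragments_bed(locus: LocusModel, path: str | Path) -> None:
    """BED6: name = fragment_id, score = 0, strand = gene strand."""
    with open(path, "w") as fh:
        for f in locus.fragments:
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}"
                f"\t{f.fragment_id}\t0\t{locus.gene_strand}\n"
            )


def read_fragments_bed(path: str | Path) -> list[RestrictionFragment]:
    """Re-read a fragment BED written by :func:`write_fragments_bed`."""
    fragments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            fragments.append(RestrictionFragment(int(name), GenomicInterval(chrom, start, end)))
    return fragments


def write_intervals_bed(intervals: Mapping[str, GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in intervals.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def fragments_table(locus: LocusModel) -> pd.DataFrame:
    """Tabular view: fragment_id, chrom, start, end, length, tss_distance_kb."""
    return pd.DataFrame(
        {
            "fragment_id": [f.fragment_id for f in locus.fragments],
            "chrom": [f.interval.chrom for f in locus.fragments],
            "start": [f.interval.start for f in locus.fragments],
            "end": [f.interval.end for f in locus.fragments],
            "length": [f.length for f in locus.fragments],
            "tss_distance_kb": [f.tss_distance_kb for f in locus.fragments],
        }
    )


def write_fragments_tsv(locus: LocusModel, path: str | Path) -> None:
    fragments_table(locus).to_csv(path, sep="\t", index=False)
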