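"""Projection of genomic annotation into transcript space and site flagging.

Conserved-region and AGO CLIP intervals arrive either in genomic
coordinates (requiring an exon model for projection) or directly in
transcript-local coordinates. Flags are tri-state: True / False / unknown
(``None``) — a transcript absent from an annotation source stays unknown
rather than being scored False.

Flag semantics: conservation requires the whole seed region to sit inside a
single retained conserved block (blocks shorter than 8 bases are dropped,
matching the source filter "length 8 bases or more"); AGO support requires
at least one base of overlap between the seed region and any AGO interval,
since CLIP cluster boundaries are fuzzy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class TranscriptInterval:
    """Half-open interval in transcript-local (spliced) coordinates."""

    transcript_id: str
    start: int
    end: int
    source_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.transcript_id}: invalid transcript interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def project_to_transcript(
    model: TranscriptModel, intervals: Iterable[GenomicInterval]
) -> list[TranscriptInterval]:
    """Map genomic intervals onto the spliced transcript.

    Each genomic interval is clipped against every exon; the overlap is
    converted to spliced coordinates via cumulative exon offsets. On
    minus-strand transcripts coordinates are reversed so that position 0 is
    the transcript 5' end. Intervals spanning an intron yield one
    TranscriptInterval per exon overlap; purely intronic or zero-length
    overlaps vanish. Intervals on a different chromosome are skipped with a
    warning.
    """
    L = model.spliced_length
    # cumulative spliced offset of each exon start, in genomic order
    offsets = []
    acc = 0
    for ex in model.exons:
        offsets.append(acc)
        acc += len(ex)
    out: list[TranscriptInterval] = []
    for iv in intervals:
        if iv.chrom != model.chrom:
            warnings.warn(
                f"{model.transcript_id}: skipping interval on {iv.chrom} "
                f"(transcript is on {model.chrom})",
                stacklevel=2,
            )
            continue
        for ex, off in zip(model.exons, offsets):
            lo = max(iv.start, ex.start)
            hi = min(iv.end, ex.end)
            if lo >= hi:
                continue
            plus_start = off + (lo - ex.start)
            plus_end = off + (hi - ex.start)
            if model.strand == "-":
                start, end = L - plus_end, L - plus_start
            else:
                start, end = plus_start, plus_end
            out.append(TranscriptInterval(model.transcript_id, start, end, iv.label))
    out.sort(key=lambda t: (t.transcript_id, t.start, t.end))
    return out


def transcript_position_to_genomic(model: TranscriptModel, pos: int) -> int:
    """Genomic coordinate of one transcript-local position (projection inverse)."""
    if not 0 <= pos < model.spliced_length:
        raise ValueError(f"position {pos} outside transcript of length {model.spliced_length}")
    plus_pos = model.spliced_length - 1 - pos if model.strand == "-" else pos
    acc = 0
    for ex in model.exons:
        if plus_pos < acc + len(ex):
            return ex.start + (plus_pos - acc)
        acc += len(ex)
    raise AssertionError("unreachable: exon lengths sum to spliced length")


def _trees_by_transcript(
    intervals: Iterable[TranscriptInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.transcript_id, IntervalTree()).addi(iv.start, iv.end)
    return trees


def mark_conserved(
    sites: pd.DataFrame,
    conserved: Sequence[TranscriptInterval],
    min_block_len: int = 8,
    covered_transcripts: set[str] | None = None,
) -> pd.DataFrame:
    """Set the ``conserved`` flag on a site table.

    A site is conserved iff its seed region [t_start, t_end) is entirely
    contained in one conserved block of length >= ``min_block_len``. Sites
    of transcripts with no conservation data keep flag unknown (``None``).
    ``covered_transcripts`` defaults to the transcripts appearing in the
    supplied interval list (before the length filter).
    """
    if covered_transcripts is None:
        covered_transcripts = {iv.transcript_id for iv in conserved}
    retained = [iv for iv in conserved if len(iv) >= min_block_len]
    trees = _trees_by_transcript(retained)
    out = sites.copy()
    flags: list[bool | None] = []
    for tid, start, end in zip(out["transcript_id"], out["t_start"], out["t_end"]):
        if tid not in covered_transcripts:
            flags.append(None)
            continue
        tree = trees.get(tid)
        contained = False
        if tree is not None:
            contained = any(iv.begin <= start and end <= iv.end for iv in tree.overlap(start, end))
        flags.append(contained)
    out["conserved"] = flags
    return out


def mark_ago_supported(
    sites: pd.DataFrame,
    ago: Sequence[TranscriptInterval],
    covered_transcripts: set[str] | None = None,
) -> pd.DataFrame:
    """Set the ``ago_supported`` flag: >= 1 base of seed/AGO-interval overlap."""
    if covered_transcripts is None:
        covered_transcripts = {iv.transcript_id for iv in ago}
    trees = _trees_by_transcript(ago)
    out = sites.copy()
    flags: list[bool | None] = []
    for tid, start, end in zip(out["transcript_id"], out["t_start"], out["t_end"]):
        if tid not in covered_transcripts:
            flags.append(None)
            continue
        tree = trees.get(tid)
        flags.append(bool(tree is not None and tree.overlap(start, end)))
    out["ago_supported"] = flags
    return out
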