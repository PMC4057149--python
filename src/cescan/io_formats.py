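"""Readers and writers for every external representation the pipeline touches.

All genomic and transcript-local intervals are 0-based, half-open (BED
convention) internally; 1-based coordinates appear only in human-readable
messages. Sequence comparison downstream is alphabet-agnostic over T/U, so
transcripts may be supplied in DNA or RNA space; miRNA sequences are
normalised to RNA (T -> U) on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

BIOTYPES = frozenset({"miRNA", "lncRNA", "protein_coding"})
VALID_STRANDS = frozenset({"+", "-", "."})
_VALID_CHARS = frozenset("ACGUTN")

#: canonical column order of the site table written by the target finder
SITE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "biotype",
    "mirna_id",
    "site_class",
    "t_start",
    "t_end",
    "window_start",
    "window_end",
    "alignment_score",
    "conserved",
    "ago_supported",
]

#: canonical column order of the ceRNA pair table
PAIR_COLUMNS = [
    "lnc_id",
    "mrna_id",
    "n_shared_miRNAs",
    "shared_miRNA_list",
    "shared_MREs",
    "total_MREs_lnc",
    "ceRNA_score",
    "p_value",
    "q_value",
]

_FLAG_TO_STR = {True: "1", False: "0", None: "NA"}
_STR_TO_FLAG = {"1": True, "0": False, "NA": None}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with a biotype label."""

    id: str
    sequence: str
    biotype: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        if self.biotype not in BIOTYPES:
            raise FormatError(
                f"record {self.id!r}: biotype {self.biotype!r} not in {sorted(BIOTYPES)}"
            )
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced transcript with optional genomic exon structure.

    Exons are stored in genomically ascending order regardless of strand;
    strand orientation is resolved at coordinate-projection time.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: transcript without exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise FormatError(
                    f"{self.transcript_id}: exon on {ex.chrom}, transcript on {self.chrom}"
                )
            if ex.start < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: exons overlap or are unsorted at "
                    f"{ex.chrom}:{ex.start}"
                )
            prev_end = ex.end

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, biotype: str) -> list[SequenceRecord]:
    """Load a FASTA file as a list of :class:`SequenceRecord`.

    Sequences are uppercased. For ``biotype="miRNA"`` the alphabet is
    normalised to RNA (T -> U); transcript sequences are left in their
    native alphabet (the comparison layer treats T and U as equivalent).
    Duplicate ids raise :class:`FormatError`.
    """
    if biotype not in BIOTYPES:
        raise FormatError(f"unknown biotype {biotype!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if biotype == "miRNA":
            seq = seq.replace("T", "U")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r} (entry {n})")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(id=rec.id, sequence=seq, biotype=biotype))
        except FormatError as err:
            raise FormatError(f"{path}: entry {n}: {err}") from err
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; strand from column 6 when present, else ".".

    Parsed by hand (rather than through a table reader) so that malformed
    lines can be reported with their line number, which the contract
    requires.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from err
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, label))
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes x tissues abundance TSV into a float DataFrame.

    First column holds row ids, header row holds tissue names. Missing
    cells (empty or NA) become NaN — "unknown", never zero. Negative
    abundances and ragged rows are format errors.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression table")
    width = len(lines[0].split("\t"))
    for lineno, ln in enumerate(lines[1:], start=2):
        if len(ln.split("\t")) != width:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(ln.split(chr(9)))} != {width} fields)")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", "NaN", "nan", ""], keep_default_na=False
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dups}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate tissue names")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as err:
        raise FormatError(f"{path}: non-numeric abundance value: {err}") from err
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative abundance value")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Transcript models (GTF/GFF exon features)
# ---------------------------------------------------------------------------

def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Group GTF/GFF exon features into :class:`TranscriptModel` objects.

    Exons must carry ``transcript_id`` and ``gene_id`` attributes. Exons of
    one transcript may not overlap. Exon order is stored genomically
    ascending on both strands.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks transcript_id")
        if not gids:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id")
        tid = tids[0]
        entry = grouped.setdefault(
            tid,
            {
                "gene_id": gids[0],
                "chrom": feat.seqid,
                "strand": feat.strand if feat.strand in VALID_STRANDS else ".",
                "exons": [],
                "biotype": _biotype_attr(feat),
            },
        )
        # gffutils coordinates are 1-based inclusive (GFF); convert to half-open
        entry["exons"].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, entry["strand"])
        )
    models = []
    for tid, entry in grouped.items():
        exons = tuple(sorted(entry["exons"], key=lambda e: e.start))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
                biotype=entry["biotype"],
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def _biotype_attr(feat) -> str | None:
    for key in ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type"):
        vals = feat.attributes.get(key)
        if vals:
            return vals[0] if vals[0] in BIOTYPES else None
    return None


# ---------------------------------------------------------------------------
# Site and pair tables
# ---------------------------------------------------------------------------

def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table with deterministic column order; flags as 1/0/NA."""
    df = sites.reindex(columns=SITE_COLUMNS).copy()
    for col in ("conserved", "ago_supported"):
        df[col] = [_FLAG_TO_STR[_normalise_flag(v)] for v in df[col]]
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "gene_id": str, "mirna_id": str, "biotype": str},
        keep_default_na=False,
    )
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: site table missing columns {missing}")
    for col in ("t_start", "t_end", "window_start", "window_end"):
        df[col] = df[col].astype(int)
    df["alignment_score"] = df["alignment_score"].astype(float)
    for col in ("conserved", "ago_supported"):
        try:
            df[col] = [_STR_TO_FLAG[str(v)] for v in df[col]]
        except KeyError as err:
            raise FormatError(f"{path}: bad flag value {err} in column {col!r}") from err
    return df[SITE_COLUMNS]


def _normalise_flag(v) -> bool | None:
    if v is None or v is pd.NA or (isinstance(v, float) and pd.isna(v)):
        return None
    return bool(v)


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    df = pairs.reindex(columns=PAIR_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"lnc_id": str, "mrna_id": str, "shared_miRNA_list": str},
        na_values=["NA"], keep_default_na=False,
    )
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: pair table missing columns {missing}")
    return df[PAIR_COLUMNS]


# ---------------------------------------------------------------------------
# Transcript-local interval TSV (conserved / AGO annotation without a GTF)
# ---------------------------------------------------------------------------

def read_transcript_intervals_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3-column TSV of transcript-local intervals (id, start, end)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":  # optional header
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from err
            if not 0 <= start < end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append((fields[0], start, end))
    return out


def write_transcript_intervals_tsv(
    intervals: Sequence[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\n")
        for tid, start, end in intervals:
            fh.write(f"{tid}\t{start}\t{end}\n")
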