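"""Discovery of miRNA response elements (MREs) on transcripts.

The finder works in two stages, the way miRanda-style scanners do:

1. a fast seed scan locates every transcript locus whose sequence is the
   reverse complement of the miRNA seed (positions 2-7, 5'->3'), classifies
   it into the canonical TargetScan site classes (8mer > 7mer-m8 > 7mer-A1
   > 6mer, most specific class wins at a locus), and — in mismatch-tolerant
   mode — also admits loci pairing miRNA positions 2-8 (or 2-7) with exactly
   one mismatch, provided the target perfectly complements the miRNA 3'
   block (positions 13-18) inside the alignment window;
2. a windowed, Smith-Waterman-style complementarity alignment of the miRNA
   against a 25-base target window around each seed hit produces an
   alignment score (Watson-Crick match, G:U wobble outside the seed, affine
   gap penalties) and the per-column pairing states.

Coordinates are transcript-local, 0-based, half-open. Positions quoted for
miRNAs use the field's 1-based convention (position 1 is the miRNA 5' end).
Comparisons treat T and U as the same base; N never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SITE_COLUMNS, SequenceRecord

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "mismatch-compensatory")

#: specificity order used to collapse overlapping classes at one locus
CLASS_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "mismatch-compensatory": 0}

WINDOW_LEN = 25  # target window used for complementarity alignment

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def canonical_rna(seq: str) -> str:
    """Uppercase and map T -> U so DNA- and RNA-space inputs compare equal."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (input may be DNA or RNA)."""
    s = canonical_rna(seq)
    try:
        return "".join(_RNA_COMPLEMENT[b] for b in reversed(s))
    except KeyError as err:
        raise ValueError(f"cannot complement base {err}") from err


def is_watson_crick(a: str, b: str) -> bool:
    return (canonical_rna(a), canonical_rna(b)) in _WC_PAIRS


def is_wobble(a: str, b: str) -> bool:
    return (canonical_rna(a), canonical_rna(b)) in _WOBBLE_PAIRS


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its derived seed subsequences.

    ``seed6`` is positions 2-7, ``seed7`` positions 2-8 and
    ``three_prime_block`` positions 13-18 (all 1-based, 5'->3'). Length must
    be >= 18 so that position 18 exists.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_rna(self.sequence))
        if len(self.sequence) < 18:
            raise ValueError(
                f"miRNA {self.id!r}: length {len(self.sequence)} < 18; "
                "positions up to 18 are required"
            )
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ValueError(f"miRNA {self.id!r}: illegal characters {sorted(bad)}")

    @property
    def seed6(self) -> str:
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        return self.sequence[1:8]

    @property
    def three_prime_block(self) -> str:
        return self.sequence[12:18]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters of the windowed complementarity alignment.

    miRanda-like magnitudes: Watson-Crick +5, G:U wobble +2 (3' region
    only), mismatch -3, affine gaps -8/-2. ``min_report_score`` filters
    reported sites; the default 0 keeps every seed-matched site, since
    perfect-seed sites are accepted by class, not by score.
    """

    match_score: float = 5.0
    wobble_score: float = 2.0
    mismatch_penalty: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    min_report_score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.match_score > self.wobble_score > 0 > self.mismatch_penalty):
            raise ValueError("require match_score > wobble_score > 0 > mismatch_penalty")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class SeedMatch:
    """One seed-complementary locus on a transcript."""

    mirna_id: str
    transcript_id: str
    t_start: int
    t_end: int
    site_class: str
    n_seed_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.t_end - self.t_start not in (6, 7, 8):
            raise ValueError("seed-paired region must span 6-8 bases")
        if (self.n_seed_mismatches == 1) != (self.site_class == "mismatch-compensatory"):
            raise ValueError("n_seed_mismatches=1 iff class is mismatch-compensatory")


@dataclass(frozen=True)
class TargetSite:
    """A predicted MRE: seed match plus alignment window and annotation flags."""

    mirna_id: str
    transcript_id: str
    t_start: int
    t_end: int
    site_class: str
    n_seed_mismatches: int
    window_start: int
    window_end: int
    alignment_score: float
    conserved: bool | None = None
    ago_supported: bool | None = None


@dataclass(frozen=True)
class AlignmentResult:
    """Score and per-column pairing states of one windowed alignment.

    ``paired`` holds (mirna_pos, target_pos, state) triples with 1-based
    miRNA positions, 0-based transcript positions, and state one of
    "WC" / "wobble" / "mismatch".
    """

    score: float
    paired: tuple[tuple[int, int, str], ...]

    def watson_crick_positions(self) -> set[int]:
        return {p for p, _, state in self.paired if state == "WC"}


# ---------------------------------------------------------------------------
# Seed patterns and scanning
# ---------------------------------------------------------------------------

def seed_target_patterns(mirna: MiRNA) -> dict[str, str]:
    """Target-side (5'->3') patterns of the four perfect-seed site classes.

    6mer and 7mer-m8 are the reverse complements of miRNA positions 2-7 and
    2-8; 7mer-A1 and 8mer append the adenine anchor opposite miRNA position
    1 (an A on the target regardless of the miRNA's first base).
    """
    if len(mirna) < 8:  # unreachable through MiRNA, kept for raw callers
        raise ValueError("miRNA must be at least 8 nt to define seed patterns")
    rc6 = reverse_complement(mirna.seed6)
    rc7 = reverse_complement(mirna.seed7)
    return {
        "6mer": rc6,
        "7mer-m8": rc7,
        "7mer-A1": rc6 + "A",
        "8mer": rc7 + "A",
    }


def _window_bounds(t_len: int, core_start: int) -> tuple[int, int]:
    """Alignment window around a seed core starting at ``core_start``.

    The window covers the seed-paired region plus the base opposite miRNA
    position 1 (downstream) and extends upstream on the target — where the
    miRNA 3' end pairs in the antiparallel duplex — up to 25 bases total,
    truncating at transcript ends.
    """
    window_end = min(t_len, core_start + 7)
    window_start = max(0, window_end - WINDOW_LEN)
    return window_start, window_end


def _has_compensatory_block(t: str, core_start: int, site_start: int, mirna: MiRNA) -> bool:
    """True if the window upstream of the seed perfectly complements miRNA 13-18."""
    block = reverse_complement(mirna.three_prime_block)
    window_start, _ = _window_bounds(len(t), core_start)
    return block in t[window_start:site_start]


def scan_seed_matches(
    transcript: SequenceRecord,
    mirna: MiRNA,
    allow_mismatch: bool = False,
) -> list[SeedMatch]:
    """Locate every seed-complementary locus of ``mirna`` on ``transcript``.

    Each 6mer-core position is classified once, into the most specific
    perfect class it supports (8mer > 7mer-m8 > 7mer-A1 > 6mer). With
    ``allow_mismatch``, loci whose core pairs miRNA 2-7 (plus the position-8
    base when it pairs) with exactly one mismatch are reported as class
    ``mismatch-compensatory`` — but only when the target also perfectly
    complements miRNA positions 13-18 within the alignment window upstream
    of the site.
    """
    t = canonical_rna(transcript.sequence)
    if len(t) < 6:
        return []
    pats = seed_target_patterns(mirna)
    p6 = pats["6mer"]
    m8_char = pats["7mer-m8"][0]  # target base pairing miRNA position 8
    out: list[SeedMatch] = []
    for p in range(len(t) - 5):
        core = t[p : p + 6]
        d = sum(1 for a, b in zip(core, p6) if a != b or a == "N")
        if d == 0:
            has_m8 = p >= 1 and t[p - 1] == m8_char and m8_char != "N"
            has_a1 = p + 6 < len(t) and t[p + 6] == "A"
            if has_m8 and has_a1:
                cls, start, end = "8mer", p - 1, p + 7
            elif has_m8:
                cls, start, end = "7mer-m8", p - 1, p + 6
            elif has_a1:
                cls, start, end = "7mer-A1", p, p + 7
            else:
                cls, start, end = "6mer", p, p + 6
            out.append(SeedMatch(mirna.id, transcript.id, start, end, cls))
        elif d == 1 and allow_mismatch:
            has_m8 = p >= 1 and t[p - 1] == m8_char and m8_char != "N"
            start = p - 1 if has_m8 else p
            if _has_compensatory_block(t, p, start, mirna):
                out.append(
                    SeedMatch(
                        mirna.id, transcript.id, start, p + 6,
                        "mismatch-compensatory", n_seed_mismatches=1,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Windowed complementarity alignment
# ---------------------------------------------------------------------------

def _pair_state(mi_base: str, t_base: str, in_seed: bool) -> str:
    if (mi_base, t_base) in _WC_PAIRS:
        return "WC"
    if not in_seed and (mi_base, t_base) in _WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


def _local_align(
    q: str, s: str, params: AlignmentParams
) -> tuple[float, list[tuple[int, int, str]]]:
    """Smith-Waterman local alignment with affine gaps (Gotoh).

    ``q`` and ``s`` are compared by complementarity: Watson-Crick pairs score
    ``match_score``, G:U wobbles ``wobble_score``, anything else
    ``mismatch_penalty``. Returns the best local score (>= 0) and the aligned
    (q_index, s_index, state) columns of the best path.
    """
    n, m = len(q), len(s)
    if n == 0 or m == 0:
        return 0.0, []
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q (consumes s)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s (consumes q)
    # traceback pointers: for each state at (i, j), the (state, i, j) it came from
    ptr_h: dict[tuple[int, int], tuple[str, int, int] | None] = {}
    ptr_e: dict[tuple[int, int], tuple[str, int, int]] = {}
    ptr_f: dict[tuple[int, int], tuple[str, int, int]] = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            open_e = H[i][j - 1] + params.gap_open
            ext_e = E[i][j - 1] + params.gap_extend
            if ext_e > open_e:
                E[i][j], ptr_e[(i, j)] = ext_e, ("E", i, j - 1)
            else:
                E[i][j], ptr_e[(i, j)] = open_e, ("H", i, j - 1)
            open_f = H[i - 1][j] + params.gap_open
            ext_f = F[i - 1][j] + params.gap_extend
            if ext_f > open_f:
                F[i][j], ptr_f[(i, j)] = ext_f, ("F", i - 1, j)
            else:
                F[i][j], ptr_f[(i, j)] = open_f, ("H", i - 1, j)
            if (qi, s[j - 1]) in _WC_PAIRS:
                sub = params.match_score
            elif (qi, s[j - 1]) in _WOBBLE_PAIRS:
                sub = params.wobble_score
            else:
                sub = params.mismatch_penalty
            diag = H[i - 1][j - 1] + sub
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h == 0.0:
                ptr_h[(i, j)] = None
            elif h == diag:
                ptr_h[(i, j)] = ("H", i - 1, j - 1)
            elif h == E[i][j]:
                ptr_h[(i, j)] = ("E", i, j)
            else:
                ptr_h[(i, j)] = ("F", i, j)
            if h > best:
                best, best_pos = h, (i, j)
    cols: list[tuple[int, int, str]] = []
    if best_pos is not None:
        state, i, j = "H", *best_pos
        while i > 0 and j > 0:
            if state == "H":
                prev = ptr_h.get((i, j))
                if prev is None:
                    break
                if prev[0] == "H":  # diagonal: an aligned column
                    cols.append((i - 1, j - 1, _pair_state(q[i - 1], s[j - 1], in_seed=False)))
                state, i, j = prev
            elif state == "E":
                state, i, j = ptr_e[(i, j)]
            else:
                state, i, j = ptr_f[(i, j)]
    cols.reverse()
    return best, cols


def align_window(
    transcript: SequenceRecord | str,
    seed_match: SeedMatch,
    mirna: MiRNA,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AlignmentResult:
    """Align the miRNA against the 25-base window around a seed match.

    Seed-paired columns are anchored, not realigned: miRNA positions 1-8 are
    scored against their fixed antiparallel target positions (Watson-Crick
    pairs earn ``match_score``; the single tolerated seed mismatch costs
    ``mismatch_penalty``; an unpaired flanking column contributes nothing).
    The miRNA 3' tail (positions 9 to the end) is then locally aligned to
    the window upstream of the seed, where G:U wobbles are permitted.
    """
    t = canonical_rna(transcript if isinstance(transcript, str) else transcript.sequence)
    # locate the 6mer core: sites with an m8 column start one base before it
    if seed_match.site_class in ("8mer", "7mer-m8"):
        core_start = seed_match.t_start + 1
    elif seed_match.site_class == "mismatch-compensatory":
        core_start = seed_match.t_end - 6
    else:
        core_start = seed_match.t_start
    if not (0 <= seed_match.t_start and seed_match.t_end <= len(t)):
        raise ValueError("seed match lies outside the transcript")
    window_start, window_end = _window_bounds(len(t), core_start)

    score = 0.0
    paired: list[tuple[int, int, str]] = []
    # anchored block: miRNA positions 1..8 pair target core_start+6 .. core_start-1
    for pos in range(1, 9):
        tpos = core_start + 7 - pos  # antiparallel: position 7 sits at core_start
        if not (window_start <= tpos < window_end) or tpos >= len(t):
            continue
        mi_base, t_base = mirna.sequence[pos - 1], t[tpos]
        if (mi_base, t_base) in _WC_PAIRS:
            score += params.match_score
            paired.append((pos, tpos, "WC"))
        elif 2 <= pos <= 7 and seed_match.n_seed_mismatches:
            # the tolerated seed mismatch is penalised, not ignored
            score += params.mismatch_penalty
            paired.append((pos, tpos, "mismatch"))
        # flanking columns (pos 1 / pos 8) that do not pair are simply unpaired

    # 3' tail: miRNA 9..L against the window upstream of the anchored block
    tail_end = core_start - 1 if core_start - 1 >= window_start else core_start
    region = t[window_start:tail_end]
    tail = mirna.sequence[8:][::-1]  # reversed: colinear with the target 5'->3'
    tail_score, cols = _local_align(tail, region, params)
    score += tail_score
    L = len(mirna)
    for qi, sj, state in cols:
        paired.append((L - qi, window_start + sj, state))
    paired.sort(key=lambda c: c[0])
    return AlignmentResult(score=score, paired=tuple(paired))


# ---------------------------------------------------------------------------
# Site discovery
# ---------------------------------------------------------------------------

def find_target_sites(
    transcript: SequenceRecord,
    mirna: MiRNA,
    params: AlignmentParams = DEFAULT_PARAMS,
    allow_mismatch: bool = False,
) -> list[TargetSite]:
    """Seed scan + windowed alignment, returning annotated-ready target sites.

    Perfect-seed classes are always reported (subject to
    ``params.min_report_score``); mismatch-compensatory sites require the
    perfect 13-18 complement, already enforced by the scan. Conservation and
    AGO flags start as ``None`` ("unknown") until annotation.
    """
    sites: list[TargetSite] = []
    for sm in scan_seed_matches(transcript, mirna, allow_mismatch=allow_mismatch):
        core_start = sm.t_end - 6
        window_start, window_end = _window_bounds(len(transcript.sequence), core_start)
        result = align_window(transcript, sm, mirna, params)
        if result.score < params.min_report_score:
            continue
        sites.append(
            TargetSite(
                mirna_id=sm.mirna_id,
                transcript_id=sm.transcript_id,
                t_start=sm.t_start,
                t_end=sm.t_end,
                site_class=sm.site_class,
                n_seed_mismatches=sm.n_seed_mismatches,
                window_start=window_start,
                window_end=window_end,
                alignment_score=result.score,
            )
        )
    sites.sort(key=lambda s: (s.transcript_id, s.t_start, s.mirna_id))
    return sites


def sites_to_frame(
    sites: Iterable[TargetSite],
    biotypes: Mapping[str, str] | None = None,
    gene_ids: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build the canonical site table (``SITE_COLUMNS``) from TargetSite objects."""
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "gene_id": (gene_ids or {}).get(s.transcript_id, s.transcript_id),
                "biotype": (biotypes or {}).get(s.transcript_id, ""),
                "mirna_id": s.mirna_id,
                "site_class": s.site_class,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "window_start": s.window_start,
                "window_end": s.window_end,
                "alignment_score": s.alignment_score,
                "conserved": s.conserved,
                "ago_supported": s.ago_supported,
            }
        )
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df


def predict_all(
    transcripts: Sequence[SequenceRecord],
    mirnas: Sequence[MiRNA],
    params: AlignmentParams = DEFAULT_PARAMS,
    allow_mismatch: bool | str = "lncRNA",
    gene_ids: Mapping[str, str] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run :func:`find_target_sites` over every transcript x miRNA combination.

    ``allow_mismatch`` may be True, False, or ``"lncRNA"`` (default): apply
    the one-mismatch + 3'-compensation rule only to lncRNA transcripts, the
    scope for which the rule is described.
    """
    all_sites: list[TargetSite] = []
    for n, tx in enumerate(sorted(transcripts, key=lambda r: r.id), start=1):
        mism = allow_mismatch if isinstance(allow_mismatch, bool) else tx.biotype == "lncRNA"
        for mi in sorted(mirnas, key=lambda m: m.id):
            all_sites.extend(find_target_sites(tx, mi, params, allow_mismatch=mism))
        if progress and n % 50 == 0:
            print(f"scanned {n} transcripts, {len(all_sites)} sites so far")
    all_sites.sort(key=lambda s: (s.transcript_id, s.t_start, s.mirna_id))
    biotypes = {tx.id: tx.biotype for tx in transcripts}
    return sites_to_frame(all_sites, biotypes=biotypes, gene_ids=gene_ids)
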