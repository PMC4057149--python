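"""Seed-reproducible synthetic inputs for every pipeline stage.

Two generators are provided:

* :func:`make_transcript_with_planted_sites` builds a single transcript
  whose background provably contains no seed pattern of any panel miRNA
  (per-base rejection against a forbidden 6-mer set, with post-assembly
  verification and bounded retries), then writes the requested sites into
  it, returning the exact expected site list;
* :func:`make_cerna_universe` builds a whole lncRNA/mRNA/miRNA universe
  with per-transcript miRNA target sets drawn from a universe of size M_T
  under an independent-overlap model (optionally boosted for designated
  pairs), planted sequences, annotation intervals, expression matrices and
  the exact expected per-pair statistics (m_p, m_n, m_c, ceRNA score,
  hypergeometric p-value).

All randomness flows from explicit integer seeds; no global RNG state is
touched. Sequences are synthetic: composition is uniform by default and no
attempt is made to mimic real human transcript structure.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    SequenceRecord,
    write_expression_table,
    write_fasta,
    write_transcript_intervals_tsv,
)
from .site_annotation import TranscriptInterval
from .target_finder import MiRNA, reverse_complement, seed_target_patterns

BASES = "ACGU"
PERFECT_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


class FixtureError(RuntimeError):
    """Raised when a fixture specification cannot be satisfied."""


@dataclass(frozen=True)
class PlantSpec:
    """One synthetic transcript with sites planted at fixed positions.

    ``planted`` holds (mirna_id, site_class, t_start) triples; ``t_start``
    is the transcript-local start of the reported site (for 7mer-m8 / 8mer /
    mismatch-compensatory sites this is the position pairing miRNA position
    8, one base before the 6mer core). ``background`` gives A/C/G/U
    sampling probabilities.
    """

    transcript_length: int
    planted: tuple[tuple[str, str, int], ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rng_seed: int = 0
    transcript_id: str = "synthetic-tx"
    biotype: str = "lncRNA"

    def __post_init__(self) -> None:
        if self.transcript_length < 6:
            raise FixtureError("transcript_length must be >= 6")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise FixtureError("background must be a probability vector over ACGU")


@dataclass(frozen=True)
class UniverseSpec:
    """Statistical shape of a synthetic ceRNA universe.

    Defaults describe a small but fully exercised universe: a 30-miRNA
    panel, 6 lncRNAs and 8 mRNAs, each miRNA targeting each transcript
    independently with probability 0.25, and 1-3 MREs per realised
    interaction — enough shared miRNAs per pair to make every statistic
    non-degenerate. Expression covers 22 named tissues, mirroring the
    tissue panel of the public RNA-Seq compendia this emulates, with
    log-normal gene abundances and Bernoulli miRNA detectability.
    """

    n_mirnas: int = 30
    n_lncrnas: int = 6
    n_mrnas: int = 8
    target_prob: float = 0.25
    pair_overlap_boost: float = 0.0
    mres_low: int = 1
    mres_high: int = 3
    n_tissues: int = 22
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.0
    mirna_detect_prob: float = 0.8
    missing_prob: float = 0.05
    with_sequences: bool = True
    with_expression: bool = True
    max_transcript_length: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_lncrnas, self.n_mrnas, self.n_tissues) < 1:
            raise FixtureError("all universe counts must be positive")
        for p in (self.target_prob, self.pair_overlap_boost, self.mirna_detect_prob, self.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise FixtureError("probabilities must lie in [0, 1]")
        if not 1 <= self.mres_low <= self.mres_high:
            raise FixtureError("need 1 <= mres_low <= mres_high")


# ---------------------------------------------------------------------------
# miRNA panel
# ---------------------------------------------------------------------------

def make_mirna_panel(n: int, rng_seed: int) -> list[MiRNA]:
    """``n`` random 22-nt miRNAs with pairwise-distinct 6-mer seeds.

    Seeds are rejection-sampled so that planted sites stay unambiguous:

    * pairwise Hamming distance >= 2 between seed patterns, so a planted
      site of one panel miRNA is never a one-mismatch seed match of
      another;
    * no miRNA's seed pattern occurs at a +-1 shift inside another's
      written site content (the position-8 complement prefix or the
      adenine-anchor suffix), nor anywhere in a 13-18 complement block —
      otherwise writing one site would deterministically create a site of
      a different miRNA.
    """
    if n < 1:
        raise FixtureError("panel size must be >= 1")
    if n > 4 ** 6:
        raise FixtureError(f"cannot draw {n} distinct 6-mer seeds (max {4 ** 6})")
    rng = np.random.default_rng(rng_seed)

    def _contexts(p6: str, m8: str, block_rc: str) -> set[str]:
        # 6-mers that planting this miRNA writes besides p6 itself,
        # including the deterministically mutated mismatch-plant core
        mc = _mutated_core(p6)
        return {m8 + p6[:5], p6[1:] + "A", block_rc, m8 + mc[:5], mc}

    accepted: list[tuple[str, set[str]]] = []  # (p6, plant contexts)
    panel: list[MiRNA] = []
    width = max(3, len(str(n)))
    for i in range(n):
        for _ in range(10000):
            seq = "".join(BASES[b] for b in rng.integers(0, 4, size=22))
            mi = MiRNA(id=f"syn-miR-{i + 1:0{width}d}", sequence=seq)
            pats = seed_target_patterns(mi)
            p6, m8 = pats["6mer"], pats["7mer-m8"][0]
            ctx = _contexts(p6, m8, reverse_complement(mi.three_prime_block))
            ok = p6 not in ctx
            # a mismatch plant writes W = m8 + mutated core next to its own
            # 13-18 block, which legitimises any nearby one-mismatch window
            # of the same seed; shifted windows overlapping W must keep
            # written-distance + redrawable-background >= 2 from p6, else a
            # spurious site of this miRNA is unavoidable
            W = m8 + _mutated_core(p6)
            if sum(a != b for a, b in zip(W[:6], p6)) < 2:
                ok = False  # core shifted one left, no background freedom
            if W[2:] == p6[:5]:
                ok = False  # core shifted one right, one background base
            if W[:5] == p6[1:]:
                ok = False  # core shifted two left, one background base
            for q6, qctx in accepted:
                if not ok:
                    break
                if sum(a != b for a, b in zip(p6, q6)) < 2:
                    ok = False
                elif p6 in qctx or q6 in ctx:
                    ok = False
            if ok:
                accepted.append((p6, ctx))
                panel.append(mi)
                break
        else:
            raise FixtureError("could not draw a sufficiently distinct seed")
    return panel


# ---------------------------------------------------------------------------
# Pattern-free backgrounds
# ---------------------------------------------------------------------------

def _forbidden_kmers(panel: Sequence[MiRNA]) -> frozenset[str]:
    """6-mers a background must avoid for exact site truth.

    Blocks every panel seed pattern, its whole one-mismatch neighbourhood
    (so mismatch-tolerant scans find nothing spurious) and every 13-18
    complement (so no spurious 3' compensation can arise).
    """
    forb: set[str] = set()
    for mi in panel:
        pat = reverse_complement(mi.seed6)
        forb.add(pat)
        for pos, alt in itertools.product(range(6), BASES):
            if alt != pat[pos]:
                forb.add(pat[:pos] + alt + pat[pos + 1:])
        forb.add(reverse_complement(mi.three_prime_block))
    return frozenset(forb)


def _sample_background(
    length: int,
    forbidden: frozenset[str],
    probs: Sequence[float],
    rng: np.random.Generator,
    max_steps_factor: int = 200,
) -> str:
    """Sample a sequence containing none of the forbidden 6-mers.

    Randomised depth-first rejection: each new base is drawn (in
    probability-weighted random order) from the subset whose 6-mer with the
    previous five bases is allowed; a dead end backtracks to the previous
    position and tries its remaining bases. Bounded by
    ``max_steps_factor * length`` placements, after which the spec is
    declared infeasible. Some 5-mers admit no extension at all (every
    pattern's own 5-prefix, since its one-mismatch neighbourhood is
    blocked), so plain restarts cannot work — backtracking is required.
    """
    probs = np.asarray(probs, dtype=float)
    chars: list[str] = []
    stack: list[list[str]] = []

    def _candidates() -> list[str]:
        if len(chars) >= 5:
            prefix = "".join(chars[-5:])
            idx = [i for i in range(4) if prefix + BASES[i] not in forbidden]
        else:
            idx = [0, 1, 2, 3]
        if not idx:
            return []
        w = probs[idx]
        if w.sum() <= 0:
            return []
        order = rng.choice(len(idx), size=len(idx), replace=False, p=w / w.sum())
        return [BASES[idx[k]] for k in order]

    steps = 0
    max_steps = max_steps_factor * length
    stack.append(_candidates())
    while len(chars) < length:
        if steps > max_steps:
            raise FixtureError(
                f"could not sample a pattern-free background of length {length} "
                f"within {max_steps} placements"
            )
        if stack[-1]:
            chars.append(stack[-1].pop())
            stack.append(_candidates())
            steps += 1
        else:
            stack.pop()
            if not chars:
                raise FixtureError("no pattern-free sequence exists for this panel")
            chars.pop()
    return "".join(chars)


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _mutated_core(p6: str) -> str:
    """The deterministic one-mismatch seed core written by mismatch plants."""
    core = list(p6)
    core[2] = next(b for b in BASES if b != core[2])
    return "".join(core)


def _plant_extent(site_class: str, t_start: int) -> tuple[int, int]:
    """Occupied region of a plant, guard bases included."""
    if site_class == "6mer":
        return t_start - 1, t_start + 7
    if site_class in ("7mer-A1", "7mer-m8"):
        return t_start - 1, t_start + 8
    if site_class == "8mer":
        return t_start, t_start + 8
    if site_class == "mismatch-compensatory":
        return t_start - 10, t_start + 7
    raise FixtureError(f"unknown site class {site_class!r}")


def _write_plant(
    seq: list[str], written: list[bool], mirna: MiRNA, site_class: str, s: int
) -> dict:
    """Overwrite ``seq`` in place with one site; return its truth record.

    ``written`` marks the positions carrying plant content, which junction
    repair must never touch. Guard bases adjacent to a plant (kept from
    upgrading the site class) stay unmarked: they are re-drawable
    background.
    """
    pats = seed_target_patterns(mirna)
    m8 = pats["7mer-m8"][0]
    not_m8 = next(b for b in BASES if b != m8)
    not_a = "G"

    def _put(at: int, frag: str) -> None:
        seq[at : at + len(frag)] = frag
        written[at : at + len(frag)] = [True] * len(frag)

    if site_class == "6mer":
        _put(s, pats["6mer"])
        if s >= 1 and seq[s - 1] == m8:
            seq[s - 1] = not_m8
        if s + 6 < len(seq) and seq[s + 6] == "A":
            seq[s + 6] = not_a
        t_start, t_end = s, s + 6
    elif site_class == "7mer-A1":
        _put(s, pats["7mer-A1"])
        if s >= 1 and seq[s - 1] == m8:
            seq[s - 1] = not_m8
        t_start, t_end = s, s + 7
    elif site_class == "7mer-m8":
        _put(s, pats["7mer-m8"])
        if s + 7 < len(seq) and seq[s + 7] == "A":
            seq[s + 7] = not_a
        t_start, t_end = s, s + 7
    elif site_class == "8mer":
        _put(s, pats["8mer"])
        t_start, t_end = s, s + 8
    elif site_class == "mismatch-compensatory":
        # m8 column, then the 6mer core with one deliberate seed mismatch,
        # plus the perfect 13-18 complement upstream inside the window
        _put(s, m8 + _mutated_core(pats["6mer"]))
        _put(s - 10, reverse_complement(mirna.three_prime_block))
        t_start, t_end = s, s + 7
    else:
        raise FixtureError(f"unknown site class {site_class!r}")
    return {
        "mirna_id": mirna.id,
        "site_class": site_class,
        "t_start": t_start,
        "t_end": t_end,
    }


def _expected_sites(seq: str, panel: Sequence[MiRNA]) -> tuple[list[dict], list[dict]]:
    """Generator-internal scan: (perfect sites, mismatch-compensatory sites).

    Used only to verify assembled fixtures; the production finder stays the
    independent route that tests exercise.
    """
    perfect: list[dict] = []
    mismatch: list[dict] = []
    n = len(seq)
    for mi in panel:
        pats = seed_target_patterns(mi)
        p6, m8 = pats["6mer"], pats["7mer-m8"][0]
        block = reverse_complement(mi.three_prime_block)
        for p in range(n - 5):
            core = seq[p : p + 6]
            d = sum(1 for a, b in zip(core, p6) if a != b)
            if d == 0:
                has_m8 = p >= 1 and seq[p - 1] == m8
                has_a1 = p + 6 < n and seq[p + 6] == "A"
                if has_m8 and has_a1:
                    rec = ("8mer", p - 1, p + 7)
                elif has_m8:
                    rec = ("7mer-m8", p - 1, p + 6)
                elif has_a1:
                    rec = ("7mer-A1", p, p + 7)
                else:
                    rec = ("6mer", p, p + 6)
                perfect.append({"mirna_id": mi.id, "site_class": rec[0], "t_start": rec[1], "t_end": rec[2]})
            elif d == 1:
                has_m8 = p >= 1 and seq[p - 1] == m8
                start = p - 1 if has_m8 else p
                wstart = max(0, min(n, p + 7) - 25)
                if block in seq[wstart:start]:
                    mismatch.append(
                        {"mirna_id": mi.id, "site_class": "mismatch-compensatory",
                         "t_start": start, "t_end": p + 6}
                    )
    return perfect, mismatch


def make_transcript_with_planted_sites(
    spec: PlantSpec, panel: Sequence[MiRNA]
) -> tuple[SequenceRecord, list[dict]]:
    """Build one transcript containing exactly the requested sites.

    The returned truth list holds one record per plant with the coordinates
    and class the finder must report. Backgrounds are re-sampled (bounded)
    until the assembled sequence verifies: a full scan finds the planted
    sites and nothing else, for any panel miRNA, in either finder mode.
    """
    panel_by_id = {m.id: m for m in panel}
    spans: list[tuple[int, int]] = []
    for mid, cls, pos in spec.planted:
        if mid not in panel_by_id:
            raise FixtureError(f"planted miRNA {mid!r} not in panel")
        lo, hi = _plant_extent(cls, pos)
        if lo < 0 or hi > spec.transcript_length:
            raise FixtureError(
                f"plant {cls} at {pos} does not fit in length {spec.transcript_length}"
            )
        for plo, phi in spans:
            if lo < phi and plo < hi:
                raise FixtureError(f"overlapping plants near position {pos}")
        spans.append((lo, hi))

    rng = np.random.default_rng(spec.rng_seed)
    forbidden = _forbidden_kmers(panel)
    for _attempt in range(10):
        seq = list(_sample_background(spec.transcript_length, forbidden, spec.background, rng))
        written = [False] * spec.transcript_length
        truth = []
        for mid, cls, pos in spec.planted:
            rec = _write_plant(seq, written, panel_by_id[mid], cls, pos)
            rec["transcript_id"] = spec.transcript_id
            truth.append(rec)
        want = sorted(
            (r["mirna_id"], r["site_class"], r["t_start"], r["t_end"]) for r in truth
        )
        # verify, then locally redraw background around any discrepancy:
        # junction windows straddling plant content and background collide
        # with some panel pattern a few percent of the time, so targeted
        # repair converges where whole-sequence resampling would thrash
        for _repair in range(80):
            assembled = "".join(seq)
            perfect, mismatch = _expected_sites(assembled, panel)
            found = sorted(
                (r["mirna_id"], r["site_class"], r["t_start"], r["t_end"])
                for r in perfect + mismatch
            )
            if found == want:
                truth.sort(key=lambda r: (r["t_start"], r["mirna_id"]))
                record = SequenceRecord(
                    id=spec.transcript_id, sequence=assembled, biotype=spec.biotype
                )
                return record, truth
            bad_spans = [
                (s, e)
                for rec4 in set(found).symmetric_difference(want)
                for s, e in [(rec4[2] - 1, rec4[3] + 1)]
            ]
            touched = False
            for s, e in bad_spans:
                for pos in range(max(0, s), min(spec.transcript_length, e)):
                    if not written[pos]:
                        seq[pos] = BASES[int(rng.integers(4))]
                        touched = True
            if not touched:
                break  # conflict inside plant content: resample from scratch
    raise FixtureError("could not assemble a clean fixture for this plant spec")


# ---------------------------------------------------------------------------
# ceRNA universes
# ---------------------------------------------------------------------------

@dataclass
class CernaUniverse:
    """Bundle of synthetic inputs plus the exact expected pair statistics."""

    spec: UniverseSpec
    mirna_ids: list[str]
    lnc_ids: list[str]
    mrna_ids: list[str]
    expected_pairs: pd.DataFrame
    panel: list[MiRNA] | None = None
    lnc_records: list[SequenceRecord] | None = None
    mrna_records: list[SequenceRecord] | None = None
    truth_sites: pd.DataFrame | None = None
    lnc_sets: dict[str, frozenset[str]] | None = None
    mrna_sets: dict[str, frozenset[str]] | None = None
    lnc_mre_counts: dict[str, dict[str, int]] | None = None
    mrna_mre_counts: dict[str, dict[str, int]] | None = None
    conserved: list[TranscriptInterval] = field(default_factory=list)
    ago: list[TranscriptInterval] = field(default_factory=list)
    gene_expr: pd.DataFrame | None = None
    mirna_expr: pd.DataFrame | None = None


def _plant_universe_transcript(
    tid: str,
    biotype: str,
    counts: Mapping[str, int],
    panel: Sequence[MiRNA],
    rng: np.random.Generator,
    max_length: int | None,
) -> tuple[SequenceRecord, list[dict]]:
    interactions = [(mid, cls) for mid, c in sorted(counts.items())
                    for cls in rng.choice(PERFECT_CLASSES, size=c)]
    order = rng.permutation(len(interactions))
    start, stride = 30, 40
    length = start + stride * len(interactions) + 20
    if max_length is not None and length > max_length:
        raise FixtureError(
            f"{tid}: {len(interactions)} MREs need length {length} > max {max_length}"
        )
    planted = tuple(
        (interactions[k][0], str(interactions[k][1]), start + stride * i)
        for i, k in enumerate(order)
    )
    spec = PlantSpec(
        transcript_length=length,
        planted=planted,
        rng_seed=int(rng.integers(2 ** 31)),
        transcript_id=tid,
        biotype=biotype,
    )
    return make_transcript_with_planted_sites(spec, panel)


def make_cerna_universe(spec: UniverseSpec) -> CernaUniverse:
    """Generate a full universe; see :class:`UniverseSpec` for the model.

    Designated pairs are (lnc_k, mrna_k) for k < min(n_lncrnas, n_mrnas);
    under ``pair_overlap_boost = 0`` the miRNA sets of every transcript are
    independent draws, giving an exact calibration null for the
    hypergeometric test.
    """
    rng = np.random.default_rng(spec.rng_seed)
    width = max(3, len(str(spec.n_mirnas)))
    mirna_ids = [f"syn-miR-{i + 1:0{width}d}" for i in range(spec.n_mirnas)]
    lnc_ids = [f"synthetic-lnc-{i + 1:03d}" for i in range(spec.n_lncrnas)]
    mrna_ids = [f"synthetic-mrna-{i + 1:03d}" for i in range(spec.n_mrnas)]

    A_l = rng.random((spec.n_lncrnas, spec.n_mirnas)) < spec.target_prob
    A_m = rng.random((spec.n_mrnas, spec.n_mirnas)) < spec.target_prob
    n_pairs = min(spec.n_lncrnas, spec.n_mrnas)
    if spec.pair_overlap_boost > 0:
        for k in range(n_pairs):
            boost = rng.random(spec.n_mirnas) < spec.pair_overlap_boost
            A_l[k] |= A_m[k] & boost

    # MRE multiplicities for every realised interaction
    def _draw_counts(A: np.ndarray, ids: list[str]) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for row, tid in zip(A, ids):
            idx = np.flatnonzero(row)
            cs = rng.integers(spec.mres_low, spec.mres_high + 1, size=idx.size)
            out[tid] = {mirna_ids[j]: int(c) for j, c in zip(idx, cs)}
        return out

    lnc_counts = _draw_counts(A_l, lnc_ids)
    mrna_counts = _draw_counts(A_m, mrna_ids)

    # exact expected statistics of the designated pairs
    m_n = A_l.sum(axis=1)
    m_p = A_m.sum(axis=1)
    rows = []
    for k in range(n_pairs):
        shared_mask = A_l[k] & A_m[k]
        m_c = int(shared_mask.sum())
        shared_ids = [mirna_ids[j] for j in np.flatnonzero(shared_mask)]
        total = sum(lnc_counts[lnc_ids[k]].values())
        shared_mre = sum(lnc_counts[lnc_ids[k]].get(m, 0) for m in shared_ids)
        # independent oracle route for the expected p-value (survival function)
        p = float(stats.hypergeom.sf(m_c - 1, spec.n_mirnas, int(m_p[k]), int(m_n[k])))
        rows.append(
            {
                "lnc_id": lnc_ids[k],
                "mrna_id": mrna_ids[k],
                "m_p": int(m_p[k]),
                "m_n": int(m_n[k]),
                "m_c": m_c,
                "shared_MREs": shared_mre,
                "total_MREs_lnc": total,
                "ceRNA_score": shared_mre / total if total else float("nan"),
                "p_value": min(p, 1.0),
            }
        )
    expected = pd.DataFrame(rows)

    uni = CernaUniverse(
        spec=spec,
        mirna_ids=mirna_ids,
        lnc_ids=lnc_ids,
        mrna_ids=mrna_ids,
        expected_pairs=expected,
        lnc_mre_counts=lnc_counts,
        mrna_mre_counts=mrna_counts,
    )
    if spec.n_lncrnas * spec.n_mirnas <= 500_000:
        uni.lnc_sets = {tid: frozenset(cs) for tid, cs in lnc_counts.items()}
        uni.mrna_sets = {tid: frozenset(cs) for tid, cs in mrna_counts.items()}

    if spec.with_sequences:
        panel = make_mirna_panel(spec.n_mirnas, rng_seed=int(rng.integers(2 ** 31)))
        # panel ids follow the same naming scheme by construction
        panel_by_id = {m.id: m for m in panel}
        assert set(panel_by_id) == set(mirna_ids)
        uni.panel = panel
        uni.lnc_records, uni.mrna_records = [], []
        truth_rows: list[dict] = []
        for ids, counts, biotype, store in (
            (lnc_ids, lnc_counts, "lncRNA", uni.lnc_records),
            (mrna_ids, mrna_counts, "protein_coding", uni.mrna_records),
        ):
            for tid in ids:
                rec, truth = _plant_universe_transcript(
                    tid, biotype, counts[tid], panel, rng,
                    spec.max_transcript_length,
                )
                store.append(rec)
                for r in truth:
                    r["biotype"] = biotype
                truth_rows.extend(truth)
        uni.truth_sites = pd.DataFrame(
            truth_rows,
            columns=["transcript_id", "biotype", "mirna_id", "site_class", "t_start", "t_end"],
        ).sort_values(["transcript_id", "t_start", "mirna_id"], ignore_index=True)
        uni.conserved, uni.ago = _annotation_intervals(uni.truth_sites, rng)

    if spec.with_expression:
        tissues = [f"tissue_{i + 1:02d}" for i in range(spec.n_tissues)]
        genes = lnc_ids + mrna_ids
        vals = rng.lognormal(spec.expr_log_mean, spec.expr_log_sd, size=(len(genes), len(tissues)))
        miss = rng.random(vals.shape) < spec.missing_prob
        vals = np.where(miss, np.nan, np.round(vals, 3))
        uni.gene_expr = pd.DataFrame(vals, index=genes, columns=tissues)
        mvals = rng.lognormal(spec.expr_log_mean, spec.expr_log_sd, size=(spec.n_mirnas, len(tissues)))
        detected = rng.random(mvals.shape) < spec.mirna_detect_prob
        uni.mirna_expr = pd.DataFrame(
            np.round(np.where(detected, mvals, 0.0), 3), index=mirna_ids, columns=tissues
        )
    return uni


def _annotation_intervals(
    truth_sites: pd.DataFrame, rng: np.random.Generator
) -> tuple[list[TranscriptInterval], list[TranscriptInterval]]:
    """Conserved blocks and AGO intervals over a random subset of true sites.

    Roughly 40% of sites get a containing conserved block (length >= 8),
    10% an undersized (7-base) block that must not confer conservation, and
    40% an overlapping AGO interval.
    """
    conserved, ago = [], []
    for r in truth_sites.itertuples():
        u = rng.random()
        if u < 0.4:
            conserved.append(
                TranscriptInterval(r.transcript_id, max(0, r.t_start - 2), r.t_end + 3, "cons")
            )
        elif u < 0.5:
            conserved.append(
                TranscriptInterval(r.transcript_id, r.t_start, r.t_start + 7, "cons-short")
            )
        if rng.random() < 0.4:
            ago.append(TranscriptInterval(r.transcript_id, r.t_end - 1, r.t_end + 9, "ago"))
    return conserved, ago


def write_bundle(uni: CernaUniverse, outdir: str | Path) -> dict[str, Path]:
    """Write a universe in the dialects the io layer reads; returns the paths.

    A ``manifest.json`` records the generating spec and the expected pair
    statistics so a bundle is self-describing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name: str, writer, *args) -> None:
        paths[name] = outdir / name
        writer(*args, paths[name])

    if uni.panel is not None:
        mirna_recs = [SequenceRecord(m.id, m.sequence, "miRNA") for m in uni.panel]
        _save("mirnas.fasta", write_fasta, mirna_recs)
    if uni.lnc_records is not None:
        _save("lncrnas.fasta", write_fasta, uni.lnc_records)
        _save("mrnas.fasta", write_fasta, uni.mrna_records)
    if uni.truth_sites is not None:
        paths["truth_sites.tsv"] = outdir / "truth_sites.tsv"
        uni.truth_sites.to_csv(paths["truth_sites.tsv"], sep="\t", index=False)
    if uni.conserved:
        _save("conserved.tsv", write_transcript_intervals_tsv,
              [(iv.transcript_id, iv.start, iv.end) for iv in uni.conserved])
    if uni.ago:
        _save("ago.tsv", write_transcript_intervals_tsv,
              [(iv.transcript_id, iv.start, iv.end) for iv in uni.ago])
    if uni.gene_expr is not None:
        _save("gene_expression.tsv", write_expression_table, uni.gene_expr)
        _save("mirna_expression.tsv", write_expression_table, uni.mirna_expr)
    paths["expected_pairs.tsv"] = outdir / "expected_pairs.tsv"
    uni.expected_pairs.to_csv(paths["expected_pairs.tsv"], sep="\t", index=False)
    manifest = {
        "spec": asdict(uni.spec),
        "n_designated_pairs": int(len(uni.expected_pairs)),
        "n_truth_sites": int(len(uni.truth_sites)) if uni.truth_sites is not None else 0,
    }
    paths["manifest.json"] = outdir / "manifest.json"
    paths["manifest.json"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
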