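"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — direct pattern tests at every
offset, exhaustive enumeration of hypergeometric draws, per-base coordinate
maps — and built on different primitives (Biopython reverse complements,
itertools combinations) than the production code paths they check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb

from Bio.Seq import Seq


def rc_rna(seq: str) -> str:
    return str(Seq(seq.replace("T", "U")).reverse_complement_rna())


def naive_site_scan(tseq: str, mseq: str, allow_mismatch: bool) -> list[tuple]:
    """All-offsets scanner over the four seed classes plus the mismatch rule.

    Returns (site_class, t_start, t_end) tuples, most specific class per
    6mer-core locus; mismatch-compensatory loci require one seed mismatch
    and the perfect reverse complement of miRNA 13-18 inside the 25-base
    alignment window upstream of the site.
    """
    t = tseq.upper().replace("T", "U")
    m = mseq.upper().replace("T", "U")
    p6 = rc_rna(m[1:7])
    p7 = rc_rna(m[1:8])
    pa1 = p6 + "A"
    p8 = p7 + "A"
    block = rc_rna(m[12:18])
    sites = []
    for p in range(len(t) - 5):
        if p >= 1 and t[p - 1 : p + 7] == p8:
            sites.append(("8mer", p - 1, p + 7))
        elif p >= 1 and t[p - 1 : p + 6] == p7:
            sites.append(("7mer-m8", p - 1, p + 6))
        elif t[p : p + 7] == pa1:
            sites.append(("7mer-A1", p, p + 7))
        elif t[p : p + 6] == p6:
            sites.append(("6mer", p, p + 6))
        elif allow_mismatch and sum(a != b for a, b in zip(t[p : p + 6], p6)) == 1:
            start = p - 1 if p >= 1 and t[p - 1] == p7[0] else p
            wstart = max(0, min(len(t), p + 7) - 25)
            if block in t[wstart:start]:
                sites.append(("mismatch-compensatory", start, p + 6))
    sites.sort(key=lambda s: (s[1], s[0]))
    return sites


def enumerate_hypergeom_tail(M_T: int, m_p: int, m_n: int, m_c: int) -> float:
    """P(overlap >= m_c) by brute-force enumeration of every possible draw."""
    universe = range(M_T)
    targeting_mrna = set(range(m_p))
    total = 0
    at_least = 0
    for draw in itertools.combinations(universe, m_n):
        total += 1
        if len(targeting_mrna.intersection(draw)) >= m_c:
            at_least += 1
    return at_least / total


def closed_form_hypergeom_tail(M_T: int, m_p: int, m_n: int, m_c: int) -> float:
    """Same tail via binomial coefficients (exact rational arithmetic)."""
    num = sum(
        comb(m_p, i) * comb(M_T - m_p, m_n - i)
        for i in range(m_c, min(m_p, m_n) + 1)
        if m_n - i <= M_T - m_p
    )
    return num / comb(M_T, m_n)


def per_base_projection(model) -> dict[int, int]:
    """Map genomic position -> transcript position, one base at a time."""
    genomic = []
    for ex in model.exons:
        genomic.extend(range(ex.start, ex.end))
    if model.strand == "-":
        genomic = genomic[::-1]
    return {g: i for i, g in enumerate(genomic)}


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up q-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q
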