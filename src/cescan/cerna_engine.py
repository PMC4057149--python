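"""ceRNA pair construction: MRE aggregation, score, and hypergeometric test.

Given a predicted site table, each transcript's MREs are aggregated into a
per-miRNA count index. For every (lncRNA, mRNA) combination sharing at
least ``min_shared`` miRNAs, two statistics are reported:

* the **ceRNA score** — the fraction of the candidate lncRNA's MREs that
  belong to miRNAs shared with the mRNA (shared MREs / total MREs of the
  candidate lncRNA), a number in (0, 1];
* the **hypergeometric p-value** — the probability, under random draws from
  a miRNA universe of size ``M_T``, of two transcripts targeted by ``m_p``
  and ``m_n`` miRNAs sharing at least the observed ``m_c``:

  ``p = sum_{i=m_c}^{min(m_p, m_n)} C(m_p, i) C(M_T - m_p, m_n - i) / C(M_T, m_n)``

  computed as an inclusive upper tail in log space for numerical stability.

Pairs are sorted by shared-miRNA count descending, then p-value ascending,
then ids — the ordering the ceRNA browsing interface uses. An optional
Benjamini-Hochberg q-value is attached across all reported pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_formats import PAIR_COLUMNS


@dataclass(frozen=True)
class MreIndex:
    """Per-transcript MRE counts, keyed transcript_id -> {mirna_id: count}."""

    counts: Mapping[str, Mapping[str, int]]

    @property
    def transcripts(self) -> list[str]:
        return sorted(self.counts)

    def mirnas(self, transcript_id: str) -> frozenset[str]:
        return frozenset(m for m, c in self.counts.get(transcript_id, {}).items() if c > 0)

    def total(self, transcript_id: str) -> int:
        return sum(self.counts.get(transcript_id, {}).values())

    def all_mirnas(self) -> frozenset[str]:
        out: set[str] = set()
        for per_tx in self.counts.values():
            out.update(m for m, c in per_tx.items() if c > 0)
        return frozenset(out)


@dataclass(frozen=True)
class CeRNAParams:
    """Knobs of pair construction.

    ``M_T`` is the miRNA universe size of the hypergeometric test; ``None``
    means "the distinct miRNAs observed across both indexes" — the universe
    must match the panel actually scanned, since the genome-wide count is
    annotation-version dependent. ``min_shared`` is the minimum number of
    shared miRNAs for a pair to be reported.
    """

    M_T: int | None = None
    min_shared: int = 1
    fdr: bool = True
    mrna_denominated: bool = False

    def __post_init__(self) -> None:
        if self.min_shared < 0:
            raise ValueError("min_shared must be >= 0")
        if self.M_T is not None and self.M_T < 1:
            raise ValueError("M_T must be >= 1")


@dataclass
class CeRNAPair:
    """One lncRNA-mRNA candidate pair with its shared-miRNA statistics."""

    lnc_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    m_p: int  # miRNAs targeting the mRNA
    m_n: int  # miRNAs targeting the lncRNA
    shared_mre_count: int
    total_mre_lnc: int
    cerna_score: float
    p_value: float
    q_value: float | None = None

    @property
    def m_c(self) -> int:
        return len(self.shared_mirnas)


def aggregate_mres(site_table: pd.DataFrame) -> MreIndex:
    """Count distinct collapsed MREs per (transcript, miRNA).

    Exact duplicate site rows (same transcript, miRNA, coordinates and
    class) are counted once, so re-annotated or concatenated tables do not
    inflate MRE totals.
    """
    if site_table.empty:
        return MreIndex(counts={})
    dedup = site_table.drop_duplicates(
        subset=["transcript_id", "mirna_id", "t_start", "t_end", "site_class"]
    )
    grouped = dedup.groupby(["transcript_id", "mirna_id"], sort=True).size()
    counts: dict[str, dict[str, int]] = {}
    for (tid, mid), n in grouped.items():
        counts.setdefault(tid, {})[mid] = int(n)
    return MreIndex(counts=counts)


def cerna_score(shared_mre_count: int, total_mre_count: int) -> float:
    """Shared-MRE ratio of the candidate transcript: shared / total MREs."""
    if total_mre_count <= 0:
        raise ValueError("candidate transcript must carry at least one MRE")
    if not 0 <= shared_mre_count <= total_mre_count:
        raise ValueError("shared MRE count must lie in [0, total]")
    return shared_mre_count / total_mre_count


def hypergeom_pvalue(M_T: int, m_p: int, m_n: int, m_c: int) -> float:
    """Inclusive upper-tail hypergeometric p-value P(X >= m_c).

    X is the overlap between a fixed set of ``m_p`` miRNAs and a random
    draw of ``m_n`` from a universe of ``M_T``. Summed in log space over
    the tail; exact 1.0 for ``m_c = 0``.
    """
    if M_T < 1:
        raise ValueError("M_T must be >= 1")
    if not (0 <= m_p <= M_T and 0 <= m_n <= M_T):
        raise ValueError("m_p and m_n must lie in [0, M_T]")
    if not 0 <= m_c <= min(m_p, m_n):
        raise ValueError("m_c must lie in [0, min(m_p, m_n)]")
    if m_c == 0:
        return 1.0
    lo = max(m_c, m_p + m_n - M_T)
    hi = min(m_p, m_n)
    support = np.arange(lo, hi + 1)
    logs = stats.hypergeom.logpmf(support, M_T, m_p, m_n)
    p = float(np.exp(logsumexp(logs)))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def build_pairs(
    lnc_index: MreIndex,
    mrna_index: MreIndex,
    params: CeRNAParams = CeRNAParams(),
) -> list[CeRNAPair]:
    """Form every qualifying lncRNA-mRNA pair and compute its statistics.

    Pairs need ``m_c >= params.min_shared`` and at least one MRE on the
    candidate transcript. Output sorted by shared-miRNA count descending,
    then p-value ascending, then ids.
    """
    universe = lnc_index.all_mirnas() | mrna_index.all_mirnas()
    M_T = params.M_T if params.M_T is not None else len(universe)
    pairs: list[CeRNAPair] = []
    mrna_sets = {tid: mrna_index.mirnas(tid) for tid in mrna_index.transcripts}
    for lnc_id in lnc_index.transcripts:
        lnc_set = lnc_index.mirnas(lnc_id)
        m_n = len(lnc_set)
        if m_n > M_T:
            raise ValueError(f"M_T={M_T} smaller than observed margin m_n={m_n} ({lnc_id})")
        lnc_counts = lnc_index.counts[lnc_id]
        total_lnc = lnc_index.total(lnc_id)
        for mrna_id, mrna_set in mrna_sets.items():
            m_p = len(mrna_set)
            if m_p > M_T:
                raise ValueError(
                    f"M_T={M_T} smaller than observed margin m_p={m_p} ({mrna_id})"
                )
            shared = lnc_set & mrna_set
            if len(shared) < params.min_shared:
                continue
            if params.mrna_denominated:
                shared_mre = sum(mrna_index.counts[mrna_id].get(m, 0) for m in shared)
                total = mrna_index.total(mrna_id)
            else:
                shared_mre = sum(lnc_counts.get(m, 0) for m in shared)
                total = total_lnc
            if total == 0:
                continue
            pairs.append(
                CeRNAPair(
                    lnc_id=lnc_id,
                    mrna_id=mrna_id,
                    shared_mirnas=frozenset(shared),
                    m_p=m_p,
                    m_n=m_n,
                    shared_mre_count=shared_mre,
                    total_mre_lnc=total,
                    cerna_score=cerna_score(shared_mre, total),
                    p_value=hypergeom_pvalue(M_T, m_p, m_n, len(shared)),
                )
            )
    pairs.sort(key=lambda p: (-p.m_c, p.p_value, p.lnc_id, p.mrna_id))
    if params.fdr:
        pairs = adjust_fdr(pairs)
    return pairs


def adjust_fdr(pairs: Sequence[CeRNAPair]) -> list[CeRNAPair]:
    """Attach Benjamini-Hochberg step-up q-values across all reported pairs."""
    if not pairs:
        return []
    qs = stats.false_discovery_control([p.p_value for p in pairs], method="bh")
    out = []
    for pair, q in zip(pairs, qs):
        pair.q_value = float(q)
        out.append(pair)
    return out


def pairs_to_frame(pairs: Sequence[CeRNAPair]) -> pd.DataFrame:
    """The canonical pair table (``PAIR_COLUMNS``), preserving pair order."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "lnc_id": p.lnc_id,
                "mrna_id": p.mrna_id,
                "n_shared_miRNAs": p.m_c,
                "shared_miRNA_list": ",".join(sorted(p.shared_mirnas)),
                "shared_MREs": p.shared_mre_count,
                "total_MREs_lnc": p.total_mre_lnc,
                "ceRNA_score": p.cerna_score,
                "p_value": p.p_value,
                "q_value": p.q_value if p.q_value is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
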