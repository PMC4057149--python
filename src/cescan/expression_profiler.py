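"""Tissue co-expression reports for ceRNA pairs.

For each tissue shared by the gene-level and miRNA-level expression
matrices, a report states the two competitors' abundances, whether both are
expressed (>= a detectability threshold), whether they are near-equimolar
(within a fold window — the regime in which ceRNA cross-regulation is
strongest), and which shared miRNAs are co-expressed in that tissue.

Missing expression is treated as "unknown", never as zero: every flag is
False when either abundance is unavailable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class ExpressionParams:
    """Detectability and equimolarity thresholds.

    ``expr_threshold`` (default 1.0, FPKM-like units) is a conventional
    detectability cutoff for the competing RNAs; ``mirna_threshold`` plays
    the same role in the units of the miRNA table; ``fold_window`` (default
    2.0) bounds the abundance ratio for the near-equimolar call.
    """

    expr_threshold: float = 1.0
    mirna_threshold: float = 1.0
    fold_window: float = 2.0

    def __post_init__(self) -> None:
        if self.fold_window < 1.0:
            raise ValueError("fold_window must be >= 1")
        if self.expr_threshold < 0 or self.mirna_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class TissueReport:
    tissue: str
    lnc_abundance: float | None
    mrna_abundance: float | None
    both_expressed: bool
    near_equimolar: bool
    coexpressed_shared_mirnas: tuple[str, ...]


def near_equimolar_flag(a: float, b: float, fold_window: float = 2.0) -> bool:
    """True iff both abundances are positive and within ``fold_window``-fold."""
    if a < 0 or b < 0:
        raise ValueError("abundances must be non-negative")
    if a == 0 or b == 0:
        return False
    return max(a, b) / min(a, b) <= fold_window


def coexpressed_shared_mirnas(
    shared_mirnas: Iterable[str],
    mirna_expr: pd.DataFrame,
    tissue: str,
    mirna_threshold: float = 1.0,
) -> list[str]:
    """Shared miRNAs with abundance >= threshold in ``tissue``, sorted.

    miRNAs absent from the matrix are excluded with a warning; an unknown
    tissue is an error naming the available tissues.
    """
    if tissue not in mirna_expr.columns:
        raise KeyError(
            f"tissue {tissue!r} not in miRNA expression matrix; "
            f"available: {sorted(mirna_expr.columns)}"
        )
    out = []
    for mid in sorted(set(shared_mirnas)):
        if mid not in mirna_expr.index:
            warnings.warn(f"miRNA {mid!r} absent from expression matrix", stacklevel=2)
            continue
        val = mirna_expr.at[mid, tissue]
        if pd.notna(val) and val >= mirna_threshold:
            out.append(mid)
    return out


def _lookup(expr: pd.DataFrame, gene: str, tissue: str) -> float | None:
    if gene not in expr.index:
        return None
    val = expr.at[gene, tissue]
    return None if pd.isna(val) else float(val)


def tissue_profile(
    lnc_gene: str,
    mrna_gene: str,
    shared_mirnas: Iterable[str],
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame | None = None,
    params: ExpressionParams = ExpressionParams(),
) -> list[TissueReport]:
    """Per-tissue expression report for one ceRNA pair.

    Tissues are the intersection (by name, in gene-matrix order) of the two
    matrices' columns; with no miRNA matrix the co-expressed miRNA lists
    are empty. A gene absent from the matrix yields all-missing reports
    with a warning rather than an error.
    """
    shared = sorted(set(shared_mirnas))
    for gene in (lnc_gene, mrna_gene):
        if gene not in gene_expr.index:
            warnings.warn(f"gene {gene!r} absent from expression matrix", stacklevel=2)
    tissues = [
        t for t in gene_expr.columns if mirna_expr is None or t in set(mirna_expr.columns)
    ]
    reports = []
    for tissue in tissues:
        a = _lookup(gene_expr, lnc_gene, tissue)
        b = _lookup(gene_expr, mrna_gene, tissue)
        both = (
            a is not None
            and b is not None
            and a >= params.expr_threshold
            and b >= params.expr_threshold
        )
        near = both and near_equimolar_flag(a, b, params.fold_window)
        co: tuple[str, ...] = ()
        if mirna_expr is not None and shared:
            co = tuple(
                coexpressed_shared_mirnas(shared, mirna_expr, tissue, params.mirna_threshold)
            )
        reports.append(
            TissueReport(
                tissue=tissue,
                lnc_abundance=a,
                mrna_abundance=b,
                both_expressed=both,
                near_equimolar=near,
                coexpressed_shared_mirnas=co,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[TissueReport]) -> pd.DataFrame:
    """Report table: tissue, abundances, flags, comma-joined co-expressed miRNAs."""
    rows = []
    for r in reports:
        rows.append(
            {
                "tissue": r.tissue,
                "lnc_fpkm": r.lnc_abundance if r.lnc_abundance is not None else float("nan"),
                "mrna_fpkm": r.mrna_abundance if r.mrna_abundance is not None else float("nan"),
                "both_expressed": int(r.both_expressed),
                "near_equimolar": int(r.near_equimolar),
                "coexpressed_shared_mirnas": ",".join(r.coexpressed_shared_mirnas),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "lnc_fpkm",
            "mrna_fpkm",
            "both_expressed",
            "near_equimolar",
            "coexpressed_shared_mirnas",
        ],
    )


def spearman_coexpression(
    lnc_gene: str, mrna_gene: str, gene_expr: pd.DataFrame
) -> float:
    """Optional extra: Spearman correlation of the pair across tissues.

    Clearly outside the core contracts — the browsing workflow displays
    expression side by side rather than correlating it — but commonly asked
    for. Tissues where either value is missing are dropped; NaN when fewer
    than 3 tissues remain.
    """
    from scipy import stats as _stats

    if lnc_gene not in gene_expr.index or mrna_gene not in gene_expr.index:
        return float("nan")
    sub = gene_expr.loc[[lnc_gene, mrna_gene]].dropna(axis=1)
    if sub.shape[1] < 3:
        return float("nan")
    rho = _stats.spearmanr(sub.iloc[0], sub.iloc[1]).statistic
    return float(rho)
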