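"""miRNA-panel differential expression and genomic-context classification.

Counts are library-size normalized, fold changes (silenced / control) are
computed on normalized means, and significance follows the panel rule:
p < 0.05 (two-sided unpaired t-test across replicates) AND fold change
outside the [0.6, 1.5] dead zone.  Changed miRNAs are then classified by
their genomic context relative to host-gene models — intronic, exonic,
3'UTR-hosted, or intergenic — using same-strand overlap with precedence
3'UTR > exonic > intronic (a 3'UTR is exonic sequence, but 3'UTR-hosted
miRNAs form a distinct regulatory class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicAnnotation, MiRNACountMatrix, ValidationError

FC_DOWN, FC_UP = 0.6, 1.5
ALPHA = 0.05

Category = Literal["intronic", "exonic", "utr3", "intergenic"]
CATEGORIES: tuple[Category, ...] = ("intronic", "exonic", "utr3", "intergenic")


# ---------------------------------------------------------------------------
# normalization and DE
# ---------------------------------------------------------------------------


def normalization_factors(
    matrix: MiRNACountMatrix,
    method: Literal["total_count", "top100_geomean"] = "total_count",
) -> pd.Series:
    """Per-sample scaling factors (divide counts by these).

    ``total_count``: library sum / mean library sum.  ``top100_geomean``:
    geometric mean of the 100 highest-count miRNAs per sample, scaled to its
    cross-sample mean.
    """
    values = matrix.values
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValidationError(f"zero library sum for samples: {bad}")
    if method == "total_count":
        factors = sums / sums.mean()
    elif method == "top100_geomean":
        k = min(100, values.shape[0])
        geo = values.apply(
            lambda col: np.exp(np.mean(np.log1p(np.sort(col)[::-1][:k]))), axis=0
        )
        factors = geo / geo.mean()
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return factors


def normalize_counts(
    matrix: MiRNACountMatrix,
    method: Literal["total_count", "top100_geomean"] = "total_count",
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize counts; returns (normalized values, factors used)."""
    factors = normalization_factors(matrix, method)
    return matrix.values.divide(factors, axis=1), factors


@dataclass
class MiRNADEResult:
    """Per-miRNA fold change, t-test p, and the panel significance flag."""

    table: pd.DataFrame        # mirna_id, mean_control, mean_silenced, fc, p,
    #                            significant, direction
    excluded: list[str]        # zero mean in both conditions
    method: str


def de_test(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    *,
    control: str = "control",
    treatment: str = "silenced",
    log_scale: bool = False,
    method: str = "total_count",
) -> MiRNADEResult:
    """Fold change treatment/control + two-sided unpaired t-test per miRNA.

    A miRNA is significant iff p < 0.05 and fc < 0.6 or fc > 1.5; direction is
    ``down`` below the dead zone, ``up`` above it.  miRNAs with zero mean in
    both conditions are excluded and reported.
    """
    conditions = conditions.loc[normalized.columns]
    a = normalized.loc[:, conditions == control]
    b = normalized.loc[:, conditions == treatment]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates per condition")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    dead = (ma == 0) & (mb == 0)
    excluded = list(normalized.index[dead])
    a, b, ma, mb = a[~dead], b[~dead], ma[~dead], mb[~dead]
    with np.errstate(divide="ignore"):
        fc = mb / ma
    ta, tb = (np.log2(a + 1), np.log2(b + 1)) if log_scale else (a, b)
    t, p = stats.ttest_ind(tb, ta, axis=1)
    sig = (p < ALPHA) & ((fc < FC_DOWN) | (fc > FC_UP))
    direction = np.where(fc < FC_DOWN, "down", np.where(fc > FC_UP, "up", "none"))
    table = pd.DataFrame({
        "mirna_id": a.index,
        "mean_control": ma.to_numpy(),
        "mean_silenced": mb.to_numpy(),
        "fc": fc.to_numpy(),
        "p": p,
        "significant": np.asarray(sig),
        "direction": direction,
    }).reset_index(drop=True)
    return MiRNADEResult(table=table, excluded=excluded,
                         method=("log2 " if log_scale else "") + method)


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class MiRNAContext:
    mirna_id: str
    category: Category
    host_gene_id: str | None

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.host_gene_id is None):
            raise ValidationError("host gene present iff miRNA is intragenic")


def classify_context(
    mirnas: pd.DataFrame,
    models: GenomicAnnotation,
) -> list[MiRNAContext]:
    """Assign each miRNA locus exactly one genomic category.

    Only same-strand, same-chromosome overlap with a host transcript counts.
    Precedence when a miRNA touches several features: 3'UTR > exonic >
    intronic; a miRNA overlapping no same-strand gene span is intergenic.
    Ties between candidate host genes break by largest overlap, then
    lexicographic gene id.
    """
    rank = {"utr3": 0, "exonic": 1, "intronic": 2}
    out = []
    for row in mirnas.itertuples(index=False):
        span = (int(row.start), int(row.end))
        if span[1] <= span[0]:
            raise ValidationError(f"malformed interval for {row.mirna_id!r}")
        candidates = []  # (precedence rank, -overlap, gene_id, category)
        for tx in models.transcripts:
            if tx.chrom != row.chrom or tx.strand != row.strand:
                continue
            gene_ov = _overlap(span, (tx.start, tx.end))
            if gene_ov == 0:
                continue
            # the 3'UTR is exonic sequence: intersect its span with exons
            utr3_exonic = [] if tx.utr3 is None else [
                (max(s, tx.utr3[0]), min(e, tx.utr3[1]))
                for s, e in tx.exons
                if _overlap((s, e), tx.utr3) > 0
            ]
            if any(_overlap(span, piece) > 0 for piece in utr3_exonic):
                cat = "utr3"
            elif any(_overlap(span, e) > 0 for e in tx.exons):
                cat = "exonic"
            else:
                cat = "intronic"
            candidates.append((rank[cat], -gene_ov, tx.gene_id, cat))
        if not candidates:
            out.append(MiRNAContext(str(row.mirna_id), "intergenic", None))
        else:
            candidates.sort()
            _, _, gene_id, cat = candidates[0]
            out.append(MiRNAContext(str(row.mirna_id), cat, gene_id))
    return out


def summarize_contexts(
    de: MiRNADEResult,
    contexts: list[MiRNAContext],
) -> pd.DataFrame:
    """Counts and proportions per category among significant miRNAs, by direction.

    Rows: categories; columns: (count, proportion) x (all, down, up).  An
    empty significant set yields an all-zero table.
    """
    ctx_map = {c.mirna_id: c.category for c in contexts}
    sig = de.table[de.table["significant"]]
    missing = [m for m in sig["mirna_id"] if m not in ctx_map]
    if missing:
        raise ValidationError(f"significant miRNAs without context: {missing[:5]}")
    out = pd.DataFrame(0, index=list(CATEGORIES),
                       columns=["count", "count_down", "count_up"])
    for _, row in sig.iterrows():
        cat = ctx_map[row["mirna_id"]]
        out.loc[cat, "count"] += 1
        if row["direction"] == "down":
            out.loc[cat, "count_down"] += 1
        elif row["direction"] == "up":
            out.loc[cat, "count_up"] += 1
    for col in list(out.columns):
        total = out[col].sum()
        out[col.replace("count", "proportion")] = \
            out[col] / total if total > 0 else 0.0
    return out
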