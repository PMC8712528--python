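"""Probe-level detection of 3'UTR shortening via the SLR statistic.

A gene with tandem poly(A) sites produces short and long 3'UTR isoforms.  On
an expression array, probes 5' of a poly(A) site (proximal) hybridize to all
isoforms, while probes 3' of it (distal) hybridize only to long isoforms.
The short-to-long ratio

    SLR = mean(proximal intensities) / mean(distal intensities)
        = (S + L) / L

therefore rises when tumors shift toward the proximal site.  SLR is computed
per sample, reported on the natural-log scale, and compared between groups
with an unpaired t-test on ln(SLR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    IntensityMatrix,
    PolyASiteTable,
    ProbeAnnotation,
    ValidationError,
)


class PartitionError(ValueError):
    """A probe set cannot be split admissibly at the requested poly(A) site."""


@dataclass
class ProbePartition:
    """A probeset split at a poly(A) site into proximal and distal probes."""

    probeset_id: str
    gene_id: str
    split_site: int
    proximal_probe_ids: list[str]
    distal_probe_ids: list[str]
    dropped_probe_ids: list[str] = field(default_factory=list)
    split_rank: int | None = None

    def __post_init__(self) -> None:
        if set(self.proximal_probe_ids) & set(self.distal_probe_ids):
            raise ValidationError("proximal and distal probe lists overlap")


@dataclass
class SLRResult:
    """Per-sample SLR and ln(SLR) with QC exclusions."""

    partition: ProbePartition
    slr: pd.Series                       # retained samples only
    ln_slr: pd.Series
    excluded_samples: list[str]          # nonpositive distal mean


@dataclass
class SLRGroupComparison:
    gene_id: str
    probeset_id: str
    split_rank: int | None
    group_means: dict[str, float]        # mean ln(SLR) per group
    mean_difference: float               # tumor - normal (second - first group)
    t_statistic: float
    p_value: float
    n_per_group: dict[str, int]


def partition_probes(
    probes: ProbeAnnotation | pd.DataFrame,
    sites: PolyASiteTable,
    gene_id: str,
    split_rank: int = 1,
    *,
    probeset_id: str | None = None,
    min_probes: int = 2,
) -> ProbePartition:
    """Split a probeset's probes at the poly(A) site of the given rank.

    A probe is proximal iff its entire span ends strictly before the site
    position, distal iff it starts at or after it; probes straddling the site
    measure a mixture of isoforms and are dropped.

    Raises :class:`PartitionError` when either side retains fewer than
    ``min_probes`` probes.
    """
    table = probes.table if isinstance(probes, ProbeAnnotation) else probes
    if probeset_id is not None:
        table = table[table["probeset_id"] == probeset_id]
    if table.empty:
        raise PartitionError(f"no probes for probeset {probeset_id!r}")
    probesets = table["probeset_id"].unique()
    if len(probesets) != 1:
        raise ValidationError(f"probes span multiple probesets: {list(probesets)}")
    gene_sites = sites.sites_for(gene_id)
    ranks = gene_sites["rank"].to_numpy()
    if split_rank not in ranks:
        raise PartitionError(
            f"gene {gene_id!r} has no poly(A) site of rank {split_rank}"
        )
    site = int(gene_sites.loc[gene_sites["rank"] == split_rank,
                              "site_position"].iloc[0])
    starts = table["transcript_position"].to_numpy()
    lengths = table.get("probe_length", pd.Series(25, index=table.index)).to_numpy()
    ends = starts + lengths              # half-open span end
    proximal = table.loc[ends <= site, "probe_id"].tolist()
    distal = table.loc[starts >= site, "probe_id"].tolist()
    dropped = table.loc[(starts < site) & (ends > site), "probe_id"].tolist()
    if len(proximal) < min_probes or len(distal) < min_probes:
        raise PartitionError(
            f"{probesets[0]}@rank{split_rank}: {len(proximal)} proximal / "
            f"{len(distal)} distal probes, need >= {min_probes} per side"
        )
    return ProbePartition(
        probeset_id=str(probesets[0]), gene_id=gene_id, split_site=site,
        proximal_probe_ids=proximal, distal_probe_ids=distal,
        dropped_probe_ids=dropped, split_rank=split_rank,
    )


def compute_slr(
    matrix: IntensityMatrix,
    partition: ProbePartition,
    summary: Literal["mean", "median"] = "mean",
) -> SLRResult:
    """Per-sample SLR = summary(proximal) / summary(distal) and its natural log.

    Samples whose distal summary is nonpositive cannot yield a ratio and are
    excluded (flagged, not imputed).
    """
    for pid in partition.proximal_probe_ids + partition.distal_probe_ids:
        if pid not in matrix.values.index:
            raise ValidationError(f"probe {pid!r} missing from intensity matrix")
    agg = np.mean if summary == "mean" else np.median
    prox = matrix.values.loc[partition.proximal_probe_ids].apply(agg, axis=0)
    dist = matrix.values.loc[partition.distal_probe_ids].apply(agg, axis=0)
    ok = dist > 0
    excluded = list(dist.index[~ok])
    slr = prox[ok] / dist[ok]
    return SLRResult(partition=partition, slr=slr, ln_slr=np.log(slr),
                     excluded_samples=excluded)


def compare_slr(
    result: SLRResult,
    groups: pd.Series,
    *,
    group_order: tuple[str, str] | None = None,
    welch: bool = True,
) -> SLRGroupComparison:
    """Two-sided unpaired t-test on ln(SLR) between two sample groups.

    ``mean_difference`` is second group minus first group of ``group_order``
    (defaults to the sorted pair, e.g. normal -> tumor).
    """
    groups = groups.loc[result.ln_slr.index]
    names = sorted(groups.unique()) if group_order is None else list(group_order)
    if len(names) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {names}")
    a = result.ln_slr[groups == names[0]]
    b = result.ln_slr[groups == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"each group needs >= 2 retained samples (got {len(a)}, {len(b)})"
        )
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return SLRGroupComparison(
        gene_id=result.partition.gene_id,
        probeset_id=result.partition.probeset_id,
        split_rank=result.partition.split_rank,
        group_means={names[0]: float(a.mean()), names[1]: float(b.mean())},
        mean_difference=float(b.mean() - a.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_per_group={names[0]: len(a), names[1]: len(b)},
    )


def run_apa_screen(
    matrix: IntensityMatrix,
    annotations: ProbeAnnotation,
    sites: PolyASiteTable,
    *,
    probeset_genes: dict[str, str] | None = None,
    min_probes: int = 2,
    group_order: tuple[str, str] | None = None,
    welch: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every probeset x poly(A)-site split for group SLR shifts.

    ``probeset_genes`` maps probeset id -> gene id; when omitted, the gene id
    is taken to equal the probeset id.  Returns ``(results, rejected)``:
    ``results`` has one row per admissible partition sorted by p-value;
    ``rejected`` lists inadmissible partitions with reasons.
    """
    rows, rejected = [], []
    for probeset_id, sub in annotations.table.groupby("probeset_id"):
        gene_id = (probeset_genes or {}).get(str(probeset_id), str(probeset_id))
        gene_sites = sites.sites_for(gene_id)
        if gene_sites.empty:
            rejected.append((gene_id, probeset_id, None, "no poly(A) sites"))
            continue
        for rank in gene_sites["rank"]:
            try:
                part = partition_probes(sub, sites, gene_id, int(rank),
                                        min_probes=min_probes)
                res = compute_slr(matrix, part)
                cmp_ = compare_slr(res, matrix.sample_groups,
                                   group_order=group_order, welch=welch)
            except (PartitionError, ValidationError) as exc:
                rejected.append((gene_id, probeset_id, int(rank), str(exc)))
                continue
            g1, g2 = sorted(cmp_.group_means) if group_order is None \
                else group_order
            rows.append(dict(
                gene_id=gene_id, probeset_id=probeset_id, split_rank=int(rank),
                **{f"n_{g1}": cmp_.n_per_group[g1], f"n_{g2}": cmp_.n_per_group[g2],
                   f"mean_ln_slr_{g1}": cmp_.group_means[g1],
                   f"mean_ln_slr_{g2}": cmp_.group_means[g2]},
                mean_difference=cmp_.mean_difference,
                t_statistic=cmp_.t_statistic, p_value=cmp_.p_value,
            ))
    results = pd.DataFrame(rows)
    if len(results):
        results = results.sort_values("p_value", kind="stable").reset_index(drop=True)
    rejected_df = pd.DataFrame(
        rejected, columns=["gene_id", "probeset_id", "split_rank", "reason"]
    )
    return results, rejected_df


def adjust_bh(p_values: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values), method="fdr_bh")[1]
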