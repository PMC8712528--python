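"""Isoform-fraction computation and group comparison.

For a gene with isoforms i = 1..k, the fraction of isoform i in a sample is
TPM_i / sum_j TPM_j over that gene's isoforms, so fractions sum to 1 per
sample and are invariant to per-sample rescaling (library size, normalization
constants).  Fractions are compared across sample groups per isoform with
one-way ANOVA followed by Tukey's HSD for all pairwise contrasts, and an
isoform *switch* is called when the reference group's dominant isoform loses
mean fraction to another isoform in a contrast group, with both changes
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IsoformExpressionMatrix, ValidationError

SIGNIFICANCE_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars at the conventional four thresholds."""
    for cut, mark in SIGNIFICANCE_STARS:
        if p < cut:
            return mark
    return "ns"


@dataclass
class IsoformFractionTable:
    """Per-sample isoform fractions for one gene.

    ``fractions`` is isoforms x samples; samples whose gene-total TPM is zero
    have undefined fractions and are masked (NaN), never imputed.
    """

    gene_id: str
    fractions: pd.DataFrame
    sample_groups: pd.Series
    masked_samples: list[str]

    @property
    def defined(self) -> pd.DataFrame:
        return self.fractions.drop(columns=self.masked_samples)


@dataclass
class FractionComparison:
    """Per-isoform one-way ANOVA with Tukey HSD pairwise contrasts."""

    gene_id: str
    anova: pd.DataFrame        # isoform, F, p, stars, degenerate flag
    tukey: pd.DataFrame        # isoform, group_a, group_b, mean_diff, p_adj, stars
    group_means: pd.DataFrame  # isoforms x groups
    dropped_groups: list[str]


def compute_fractions(matrix: IsoformExpressionMatrix,
                      gene: str) -> IsoformFractionTable:
    """Fractions = isoform TPM / per-sample total TPM over the gene's isoforms."""
    iso_ids = matrix.isoforms_of(gene)
    if not iso_ids:
        raise ValidationError(f"gene {gene!r} has no isoforms in the matrix")
    tpm = matrix.values.loc[iso_ids]
    totals = tpm.sum(axis=0)
    masked = list(totals.index[totals == 0])
    fractions = tpm.divide(totals.where(totals > 0), axis=1)
    return IsoformFractionTable(
        gene_id=gene, fractions=fractions,
        sample_groups=matrix.sample_groups, masked_samples=masked,
    )


def compare_fractions(
    table: IsoformFractionTable,
    groups: pd.Series | None = None,
    min_per_group: int = 2,
) -> FractionComparison:
    """One-way ANOVA + Tukey HSD across groups, per isoform.

    Groups with fewer than ``min_per_group`` defined samples are dropped with
    a warning; isoforms with zero within-group variance everywhere are flagged
    degenerate (F undefined) rather than tested.
    """
    import warnings

    fr = table.defined
    groups = (table.sample_groups if groups is None else groups).loc[fr.columns]
    keep, dropped = [], []
    for g, n in groups.value_counts().items():
        (keep if n >= min_per_group else dropped).append(g)
    if dropped:
        warnings.warn(f"dropping groups with < {min_per_group} samples: {dropped}")
    if len(keep) < 2:
        raise ValidationError(f"need >= 2 groups with >= {min_per_group} samples")
    keep = sorted(keep)
    cols = groups.index[groups.isin(keep)]
    fr = fr[cols]
    groups = groups.loc[cols]

    anova_rows, tukey_rows, mean_rows = [], [], []
    for iso in fr.index:
        samples = [fr.loc[iso, groups == g].to_numpy() for g in keep]
        means = {g: float(np.mean(s)) for g, s in zip(keep, samples)}
        mean_rows.append(means)
        within_var = sum(float(np.var(s)) for s in samples)
        if within_var == 0:
            anova_rows.append(dict(isoform=iso, F=np.nan, p=np.nan,
                                   stars="ns", degenerate=True))
            continue
        f, p = stats.f_oneway(*samples)
        anova_rows.append(dict(isoform=iso, F=float(f), p=float(p),
                               stars=stars(float(p)), degenerate=False))
        hsd = stats.tukey_hsd(*samples)
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                p_adj = float(hsd.pvalue[i, j])
                tukey_rows.append(dict(
                    isoform=iso, group_a=keep[i], group_b=keep[j],
                    mean_diff=means[keep[j]] - means[keep[i]],
                    p_adj=p_adj, stars=stars(p_adj),
                ))
    return FractionComparison(
        gene_id=table.gene_id,
        anova=pd.DataFrame(anova_rows),
        tukey=pd.DataFrame(tukey_rows,
                           columns=["isoform", "group_a", "group_b",
                                    "mean_diff", "p_adj", "stars"]),
        group_means=pd.DataFrame(mean_rows, index=fr.index)[keep],
        dropped_groups=dropped,
    )


@dataclass
class SwitchCall:
    gene_id: str
    contrast_group: str
    switched: bool
    loser: str | None = None             # dominant isoform in reference
    gainer: str | None = None
    loser_delta: float = 0.0             # contrast mean - reference mean
    gainer_delta: float = 0.0


def detect_switch(
    comparison: FractionComparison,
    reference_group: str,
    *,
    delta: float = 0.1,
    alpha: float = 0.05,
) -> list[SwitchCall]:
    """Call an isoform switch against each non-reference group.

    A gene is *switched* in a contrast group when the isoform dominant in the
    reference loses >= ``delta`` mean fraction while some other isoform gains
    >= ``delta``, and both isoforms' reference-vs-contrast Tukey contrasts are
    significant at ``alpha``.
    """
    means = comparison.group_means
    if reference_group not in means.columns:
        raise ValidationError(f"unknown reference group {reference_group!r}")
    dominant = means[reference_group].idxmax()
    tk = comparison.tukey

    def _pair_p(iso: str, other: str) -> float:
        m = tk[(tk["isoform"] == iso) &
               (((tk["group_a"] == reference_group) & (tk["group_b"] == other)) |
                ((tk["group_b"] == reference_group) & (tk["group_a"] == other)))]
        return float(m["p_adj"].iloc[0]) if len(m) else np.nan

    calls = []
    for group in means.columns:
        if group == reference_group:
            continue
        loss = means.loc[dominant, group] - means.loc[dominant, reference_group]
        call = SwitchCall(gene_id=comparison.gene_id, contrast_group=group,
                          switched=False)
        if loss <= -delta and _pair_p(dominant, group) < alpha:
            gains = means[group] - means[reference_group]
            gains = gains.drop(index=dominant)
            gainer = gains.idxmax()
            if gains[gainer] >= delta and _pair_p(gainer, group) < alpha:
                call = SwitchCall(
                    gene_id=comparison.gene_id, contrast_group=group,
                    switched=True, loser=dominant, gainer=gainer,
                    loser_delta=float(loss), gainer_delta=float(gains[gainer]),
                )
        calls.append(call)
    return calls
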