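"""Synthetic-data generators for every pipeline input.

Each generator emulates one assay in the study design:

* ``gen_probe_matrix``   — microarray probe intensities for a gene with a
  proximal/distal probe split at a poly(A) site (short vs long 3'UTR isoforms).
* ``gen_isoform_tpm``    — transcript-level TPM with Dirichlet isoform usage.
* ``gen_decay_cts``      — RT-qPCR Ct values from an actinomycin-D time course
  under first-order decay (one PCR cycle per halving).
* ``gen_mirna_counts``   — negative-binomial miRNA panel counts with programmed
  differential expression and matched toy gene models for genomic context.
* ``gen_survival``       — exponential event times with a hazard-ratio contrast
  between high- and low-expression strata, under independent censoring.

All distributions are the simplest standard forms for each data type
(lognormal intensity noise, Dirichlet fractions, Gamma totals, NB counts,
exponential survival); every scenario carries an explicit seed and the output
is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CtTable,
    GenomicAnnotation,
    IntensityMatrix,
    IsoformExpressionMatrix,
    MiRNACountMatrix,
    SurvivalTable,
    TranscriptModel,
    ValidationError,
)

MIRNA_CONTEXTS = ("intronic", "exonic", "utr3", "intergenic")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class SwitchScenario:
    """Tumor-vs-normal 3'UTR shortening contrast on a probe-level array.

    ``short_long_ratio_*`` is the expected abundance ratio of short (proximal
    poly(A) site) to long (distal site) isoforms in each group; measurement
    noise is multiplicative lognormal with coefficient of variation
    ``noise_cv``.
    """

    n_tumor: int = 20
    n_normal: int = 20
    short_long_ratio_normal: float = 1.0
    short_long_ratio_tumor: float = 3.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.short_long_ratio_normal <= 0 or self.short_long_ratio_tumor <= 0:
            raise ValidationError("short/long ratios must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


@dataclass
class FractionScenario:
    """Per-group Dirichlet isoform usage with Gamma-distributed totals."""

    group_names: tuple[str, ...] = ("normal", "tumor")
    dirichlet_alphas: tuple[tuple[float, ...], ...] = (
        (12.0, 4.0, 2.0, 2.0),           # normal: isoform 1 dominant
        (4.0, 12.0, 2.0, 2.0),           # tumor: isoform 2 dominant
    )
    total_tpm_shape: float = 4.0
    total_tpm_scale: float = 25.0        # mean total TPM = shape * scale = 100
    n_per_group: tuple[int, ...] = (50, 50)
    gene_id: str = "GENE1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.dirichlet_alphas) or \
                len(self.group_names) != len(self.n_per_group):
            raise ValidationError("group_names, alphas and n_per_group must align")
        k = len(self.dirichlet_alphas[0])
        for a in self.dirichlet_alphas:
            if len(a) != k:
                raise ValidationError("isoform count must match across groups")
            if any(x <= 0 for x in a):
                raise ValidationError("Dirichlet alphas must be > 0")


@dataclass
class DecayScenario:
    """Actinomycin-D decay time course measured by RT-qPCR.

    Under ideal amplification efficiency 2, a transcript with half-life t1/2
    gains one Ct per t1/2 hours: Ct(t) = Ct(0) + t / t1/2.
    """

    half_lives: dict[str, float] = field(
        default_factory=lambda: {"ISO1": 2.0, "MYC": 0.5, "ISO2": 50.0}
    )
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0)
    ct_noise_sd: float = 0.2
    reference_ct: float = 18.0
    baseline_ct: float = 22.0
    n_replicates: int = 3
    reference_target: str = "RPLP0"
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        if tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("timepoints must be sorted and start at 0")
        if any(h <= 0 for h in self.half_lives.values()):
            raise ValidationError("half-lives must be > 0")
        if self.ct_noise_sd < 0 or self.n_replicates < 1:
            raise ValidationError("invalid noise sd or replicate count")


@dataclass
class MirnaScenario:
    """NanoString-style miRNA panel with programmed DE and genomic contexts."""

    n_mirnas: int = 200
    n_de: int = 10
    fc_range: tuple[float, float] = (0.3, 0.5)
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    context_proportions: tuple[float, float, float, float] = (0.5, 0.2, 0.1, 0.2)
    base_mean_log_mu: float = 6.0        # ln-scale location of baseline counts
    base_mean_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_mirnas:
            raise ValidationError("n_de must be <= n_mirnas")
        if not np.isclose(sum(self.context_proportions), 1.0):
            raise ValidationError("context_proportions must sum to 1")
        if self.nb_dispersion < 0 or self.n_replicates < 2:
            raise ValidationError("invalid dispersion or replicate count")


@dataclass
class SurvivalScenario:
    """Exponential survival with a hazard contrast between expression strata.

    Subjects in the top expression quartile have hazard ``baseline_hazard *
    true_hr``; all others have ``baseline_hazard``.  Censoring times are
    independent exponentials calibrated per stratum so the expected censored
    fraction equals ``censor_rate``.
    """

    n: int = 360
    true_hr: float = 2.7
    baseline_hazard: float = 0.1         # events per unit time
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.true_hr <= 0 or self.baseline_hazard <= 0 or self.n < 8:
            raise ValidationError("invalid hazard parameters or n")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_probe_matrix(scenario: SwitchScenario, partition_spec) -> IntensityMatrix:
    """Simulate probe intensities for one probeset split at a poly(A) site.

    Proximal probes see short + long isoform abundance; distal probes see the
    long isoform only.  Latent long-isoform abundance is fixed at 1000 units,
    short = ratio * long; each probe reading gets independent multiplicative
    lognormal noise with the scenario's CV.  With ``noise_cv=0`` the
    per-sample SLR is exactly ``1 + S/L``.
    """
    if len(partition_spec.proximal_probe_ids) == 0 or \
            len(partition_spec.distal_probe_ids) == 0:
        raise ValidationError("partition must have >= 1 probe on each side")
    rng = np.random.default_rng(scenario.seed)
    long_abund = 1000.0
    groups, ratios, n_samples = ["normal", "tumor"], [
        scenario.short_long_ratio_normal, scenario.short_long_ratio_tumor,
    ], [scenario.n_normal, scenario.n_tumor]
    probe_ids = list(partition_spec.proximal_probe_ids) + \
        list(partition_spec.distal_probe_ids)
    n_prox = len(partition_spec.proximal_probe_ids)
    cols, labels, names = [], [], []
    if scenario.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(scenario.noise_cv ** 2)))
    else:
        sigma = 0.0
    for group, ratio, n in zip(groups, ratios, n_samples):
        for i in range(n):
            short = ratio * long_abund
            expected = np.array(
                [short + long_abund] * n_prox
                + [long_abund] * (len(probe_ids) - n_prox)
            )
            if sigma > 0:
                # mean-one lognormal noise: E[exp(N(-s^2/2, s^2))] = 1
                noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(probe_ids))
            else:
                noise = 1.0
            cols.append(expected * noise)
            labels.append(group)
            names.append(f"{group}_{i + 1}")
    values = pd.DataFrame(np.column_stack(cols), index=probe_ids, columns=names)
    return IntensityMatrix(values=values,
                           sample_groups=pd.Series(labels, index=names))


def gen_apa_panel(
    n_genes: int = 50,
    n_switch: int = 5,
    *,
    n_tumor: int = 20,
    n_normal: int = 20,
    noise_cv: float = 0.2,
    ratio_normal: float = 1.0,
    ratio_tumor_switch: float = 3.0,
    probes_per_side: int = 2,
    seed: int = 0,
):
    """Multi-gene probe panel for screening: a few genes carry a real switch.

    Switch genes move from S/L = ``ratio_normal`` (SLR = 2) in normals to
    ``ratio_tumor_switch`` (SLR = 4) in tumors — an ln(SLR) effect of ln 2 at
    the defaults; the remaining genes keep the normal ratio in both groups.
    Returns ``(IntensityMatrix, ProbeAnnotation, PolyASiteTable, switch_genes)``
    ready for :func:`isoswitch.apa_slr.run_apa_screen`.
    """
    if n_switch > n_genes:
        raise ValidationError("n_switch must be <= n_genes")
    rng = np.random.default_rng(seed)
    switch_idx = set(rng.choice(n_genes, size=n_switch, replace=False).tolist())
    blocks, probe_rows, site_rows, switch_genes = [], [], [], []
    sample_names = None
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:03d}"
        ratio_t = ratio_tumor_switch if gi in switch_idx else ratio_normal
        if gi in switch_idx:
            switch_genes.append(gene)
        prox = [f"{gene}_p{i + 1}" for i in range(probes_per_side)]
        dist = [f"{gene}_d{i + 1}" for i in range(probes_per_side)]
        scen = SwitchScenario(
            n_tumor=n_tumor, n_normal=n_normal,
            short_long_ratio_normal=ratio_normal,
            short_long_ratio_tumor=ratio_t,
            noise_cv=noise_cv, seed=int(rng.integers(2 ** 31)),
        )

        class _Part:
            proximal_probe_ids = prox
            distal_probe_ids = dist

        m = gen_probe_matrix(scen, _Part)
        blocks.append(m.values)
        sample_names = m.sample_groups
        # probes laid at 0/30 (proximal) and 200/230 (distal); site at 100
        for i, pid in enumerate(prox):
            probe_rows.append(dict(probe_id=pid, probeset_id=gene,
                                   transcript_position=30 * i))
        for i, pid in enumerate(dist):
            probe_rows.append(dict(probe_id=pid, probeset_id=gene,
                                   transcript_position=200 + 30 * i))
        site_rows.append(dict(gene_id=gene, site_position=100, rank=1))
    from .io_formats import PolyASiteTable, ProbeAnnotation

    matrix = IntensityMatrix(values=pd.concat(blocks),
                             sample_groups=sample_names)
    return (matrix, ProbeAnnotation(pd.DataFrame(probe_rows)),
            PolyASiteTable(pd.DataFrame(site_rows)), switch_genes)


def gen_isoform_tpm(scenario: FractionScenario) -> IsoformExpressionMatrix:
    """Simulate transcript TPM: fraction ~ Dirichlet(group alphas), total ~ Gamma."""
    rng = np.random.default_rng(scenario.seed)
    k = len(scenario.dirichlet_alphas[0])
    iso_ids = [f"{scenario.gene_id}.iso{i + 1}" for i in range(k)]
    cols, labels, names = [], [], []
    for group, alphas, n in zip(scenario.group_names, scenario.dirichlet_alphas,
                                scenario.n_per_group):
        fracs = rng.dirichlet(alphas, size=n) if k > 1 else np.ones((n, 1))
        totals = rng.gamma(scenario.total_tpm_shape, scenario.total_tpm_scale,
                           size=n)
        for i in range(n):
            cols.append(fracs[i] * totals[i])
            labels.append(group)
            names.append(f"{group}_{i + 1}")
    values = pd.DataFrame(np.column_stack(cols), index=iso_ids, columns=names)
    gene_map = pd.Series(scenario.gene_id, index=iso_ids)
    return IsoformExpressionMatrix(values=values, gene_map=gene_map,
                                   sample_groups=pd.Series(labels, index=names))


def _ct_records(rng, targets: dict[str, float], condition: str,
                timepoints, n_replicates: int, baseline_ct: float,
                reference_ct: float, reference_target: str,
                noise_sd: float) -> list[dict]:
    rows = []
    for t in timepoints:
        for rep in range(1, n_replicates + 1):
            for target, hl in targets.items():
                ct = baseline_ct + t / hl
                if noise_sd > 0:
                    ct += rng.normal(0, noise_sd)
                rows.append(dict(target_id=target, condition=condition,
                                 timepoint=float(t), replicate=rep, ct=ct))
            ref_ct = reference_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(dict(target_id=reference_target, condition=condition,
                             timepoint=float(t), replicate=rep, ct=ref_ct))
    return rows


def gen_decay_cts(scenario: DecayScenario) -> CtTable:
    """Simulate an actinomycin-D RT-qPCR time course as a Ct table."""
    rng = np.random.default_rng(scenario.seed)
    rows = _ct_records(rng, scenario.half_lives, "actD", scenario.timepoints,
                       scenario.n_replicates, scenario.baseline_ct,
                       scenario.reference_ct, scenario.reference_target,
                       scenario.ct_noise_sd)
    return CtTable(pd.DataFrame(rows), reference_target=scenario.reference_target)


def gen_chx_cts(scenario: DecayScenario, timepoint: float,
                decay_suppression: dict[str, float]) -> CtTable:
    """Simulate a paired actD vs actD+CHX experiment at one timepoint.

    ``decay_suppression[target] = s`` multiplies the target's half-life by
    ``s`` under cycloheximide (s > 1 means decay is slowed, as expected for a
    co-translationally degraded transcript).  Both conditions share t = 0 as
    calibrator.
    """
    rng = np.random.default_rng(scenario.seed)
    tps = (0.0, float(timepoint))
    rows = _ct_records(rng, scenario.half_lives, "actD", tps,
                       scenario.n_replicates, scenario.baseline_ct,
                       scenario.reference_ct, scenario.reference_target,
                       scenario.ct_noise_sd)
    chx_hl = {t: hl * decay_suppression.get(t, 1.0)
              for t, hl in scenario.half_lives.items()}
    rows += _ct_records(rng, chx_hl, "actD+CHX", tps,
                        scenario.n_replicates, scenario.baseline_ct,
                        scenario.reference_ct, scenario.reference_target,
                        scenario.ct_noise_sd)
    return CtTable(pd.DataFrame(rows), reference_target=scenario.reference_target)


def _toy_host_gene(gene_id: str, chrom: str, offset: int,
                   strand: str) -> TranscriptModel:
    """Three-exon coding gene: CDS ends mid-exon 3, leaving a 3'UTR tail."""
    g = offset
    exons = [(g, g + 200), (g + 1000, g + 1400), (g + 2000, g + 3000)]
    cds = (g + 100, g + 2300)
    utr3 = (g + 2300, g + 3000)
    if strand == "-":
        # downstream is leftward: 3'UTR occupies the head of exon 1
        cds = (g + 150, g + 2900)
        utr3 = (g, g + 150)
    return TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
        strand=strand, start=g, end=g + 3000, exons=exons, cds=cds, utr3=utr3,
    )


def gen_mirna_counts(
    scenario: MirnaScenario,
) -> tuple[MiRNACountMatrix, GenomicAnnotation, pd.DataFrame]:
    """Simulate panel counts, matched toy gene models, and a truth table.

    Returns ``(counts, annotation, truth)`` where ``truth`` records each
    miRNA's true DE status, true fold change (silenced / control) and assigned
    genomic context.  Each intragenic miRNA gets its own toy host gene laid
    out along one chromosome; intergenic miRNAs sit in the gaps between genes.
    """
    rng = np.random.default_rng(scenario.seed)
    n, n_de = scenario.n_mirnas, scenario.n_de
    mirna_ids = [f"miR-sim-{i + 1}" for i in range(n)]
    base_means = rng.lognormal(scenario.base_mean_log_mu,
                               scenario.base_mean_log_sd, size=n)
    is_de = np.zeros(n, dtype=bool)
    is_de[rng.choice(n, size=n_de, replace=False)] = True
    fcs = np.ones(n)
    fcs[is_de] = rng.uniform(*scenario.fc_range, size=n_de)

    def _draw(mean: np.ndarray, size: int) -> np.ndarray:
        if scenario.nb_dispersion <= 1e-12:
            return rng.poisson(mean[:, None], size=(n, size))
        r = 1.0 / scenario.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(n, size))

    ctrl = _draw(base_means, scenario.n_replicates)
    sil = _draw(base_means * fcs, scenario.n_replicates)
    names = [f"NT_{i + 1}" for i in range(scenario.n_replicates)] + \
        [f"sh_{i + 1}" for i in range(scenario.n_replicates)]
    values = pd.DataFrame(np.hstack([ctrl, sil]), index=mirna_ids, columns=names)
    conditions = pd.Series(
        ["control"] * scenario.n_replicates + ["silenced"] * scenario.n_replicates,
        index=names,
    )
    counts = MiRNACountMatrix(values=values, conditions=conditions)

    contexts = rng.choice(MIRNA_CONTEXTS, size=n, p=scenario.context_proportions)
    transcripts, loci = [], []
    gap, gene_len, chrom = 2000, 3000, "chrSim"
    for i, (mid, ctx) in enumerate(zip(mirna_ids, contexts)):
        offset = i * (gene_len + gap) + gap
        strand = "+" if rng.random() < 0.5 else "-"
        if ctx == "intergenic":
            # place in the gap upstream of this slot; no host gene emitted
            loci.append((mid, chrom, offset - gap + 200, offset - gap + 280,
                         strand))
            continue
        host_id = f"HOST{i + 1}"
        host = _toy_host_gene(host_id, chrom, offset, strand)
        transcripts.append(host)
        g = offset
        if ctx == "intronic":
            span = (g + 400, g + 480)          # intron 1
        elif ctx == "exonic":
            span = (g + 1100, g + 1180)        # exon 2, inside the CDS
        elif strand == "+":                    # utr3, exon 3 tail
            span = (g + 2500, g + 2580)
        else:                                  # utr3 on minus strand: exon 1
            span = (g + 50, g + 130)
        loci.append((mid, chrom, span[0], span[1], strand))
    annotation = GenomicAnnotation(
        transcripts=transcripts,
        mirna_loci=pd.DataFrame(
            loci, columns=["mirna_id", "chrom", "start", "end", "strand"]
        ),
    )
    truth = pd.DataFrame({
        "mirna_id": mirna_ids,
        "is_de": is_de,
        "true_fc": fcs,
        "context": contexts,
    })
    return counts, annotation, truth


def gen_survival(scenario: SurvivalScenario) -> SurvivalTable:
    """Simulate a right-censored cohort with an expression-linked hazard."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    expression = rng.normal(0, 1, size=n)
    cut = np.quantile(expression, 0.75)
    high = expression >= cut
    hazard = np.where(high, scenario.baseline_hazard * scenario.true_hr,
                      scenario.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if scenario.censor_rate > 0:
        c = scenario.censor_rate
        censor_hazard = hazard * c / (1 - c)
        censor_time = rng.exponential(1.0 / censor_hazard)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    table = pd.DataFrame({
        "sample_id": [f"P{i + 1:04d}" for i in range(n)],
        "time": time,
        "event": event,
        "expression": expression,
    })
    return SurvivalTable(table)
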