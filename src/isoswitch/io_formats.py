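"""Typed on-disk artifacts and their readers/writers.

Every downstream stage consumes only the validated containers defined here.
Matrices travel as plain TSV (first column = feature ids, header row = sample
ids) with sample-group labels in a two-column sidecar TSV; gene models arrive
as BED12 or GTF; survival tables and Ct tables are long-format TSV.

Coordinate convention: all intervals are 0-based half-open internally.  GTF
(1-based closed) is converted at the boundary and converted back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An on-disk artifact or in-memory container violates its contract."""


# ---------------------------------------------------------------------------
# matrix containers
# ---------------------------------------------------------------------------


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups}")


def _check_groups(sample_ids, sample_groups: pd.Series) -> pd.Series:
    groups = pd.Series(sample_groups)
    missing = [s for s in sample_ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group labels: {missing}")
    return groups.loc[list(sample_ids)]


@dataclass
class IntensityMatrix:
    """Linear-scale probe intensities, probes x samples, with group labels."""

    values: pd.DataFrame                 # index = probe ids, columns = samples
    sample_groups: pd.Series             # index = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        neg = self.values.lt(0)
        if neg.any().any():
            r, c = np.argwhere(neg.to_numpy())[0]
            raise ValidationError(
                f"negative intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        self.sample_groups = _check_groups(self.values.columns, self.sample_groups)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProbeAnnotation:
    """Maps probes to probesets and transcript coordinates.

    ``table`` columns: probe_id, probeset_id, transcript_position (0-based
    offset of the probe start on the transcript), probe_length, strand.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "probeset_id", "transcript_position")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns: {missing}")
        t = self.table.copy()
        if "probe_length" not in t.columns:
            t["probe_length"] = 25        # Affymetrix-style 25-mer default
        if "strand" not in t.columns:
            t["strand"] = "+"
        if (t["transcript_position"] < 0).any():
            raise ValidationError("negative transcript_position")
        _check_unique(t["probe_id"], "probe")
        self.table = t.reset_index(drop=True)

    def for_probeset(self, probeset_id: str) -> pd.DataFrame:
        return self.table[self.table["probeset_id"] == probeset_id]


@dataclass
class PolyASiteTable:
    """Poly(A) sites per gene in transcript coordinates; rank 1 = most proximal."""

    table: pd.DataFrame                  # columns: gene_id, site_position, rank

    def __post_init__(self) -> None:
        for gene, sub in self.table.groupby("gene_id"):
            sub = sub.sort_values("rank")
            ranks = sub["rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
                raise ValidationError(f"ranks for {gene} not contiguous from 1")
            pos = sub["site_position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"site positions for {gene} not strictly increasing with rank"
                )

    def sites_for(self, gene_id: str) -> pd.DataFrame:
        return self.table[self.table["gene_id"] == gene_id].sort_values("rank")


@dataclass
class IsoformExpressionMatrix:
    """Transcript-level TPM, isoforms x samples, with isoform->gene map."""

    values: pd.DataFrame
    gene_map: pd.Series                  # index = isoform ids, values = gene ids
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "isoform")
        _check_unique(self.values.columns, "sample")
        if self.values.lt(0).any().any():
            neg = self.values.lt(0)
            r, c = np.argwhere(neg.to_numpy())[0]
            raise ValidationError(
                f"negative TPM at isoform {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        unmapped = [i for i in self.values.index if i not in self.gene_map.index]
        if unmapped:
            raise ValidationError(f"isoforms without gene mapping: {unmapped}")
        self.gene_map = pd.Series(self.gene_map).loc[list(self.values.index)]
        self.sample_groups = _check_groups(self.values.columns, self.sample_groups)

    def isoforms_of(self, gene_id: str) -> list[str]:
        return list(self.gene_map.index[self.gene_map == gene_id])


@dataclass
class CtTable:
    """Long-format RT-qPCR Ct records with a designated reference target."""

    records: pd.DataFrame  # target_id, condition, timepoint, replicate, ct
    reference_target: str

    REQUIRED = ("target_id", "condition", "timepoint", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns: {missing}")
        if not np.isfinite(self.records["ct"]).all():
            raise ValidationError("non-finite Ct value")
        ref = self.records[self.records["target_id"] == self.reference_target]
        if ref.empty:
            raise ValidationError(
                f"reference target {self.reference_target!r} absent from table"
            )
        cells = set(map(tuple, self.records[["condition", "timepoint", "replicate"]]
                        .itertuples(index=False)))
        ref_cells = set(map(tuple, ref[["condition", "timepoint", "replicate"]]
                            .itertuples(index=False)))
        gap = cells - ref_cells
        if gap:
            raise ValidationError(
                f"reference {self.reference_target!r} missing at "
                f"(condition, timepoint, replicate) cells: {sorted(gap)[:5]}"
            )
        self.records = self.records.reset_index(drop=True)


@dataclass
class MiRNACountMatrix:
    """Raw miRNA counts, miRNAs x samples, with condition per sample."""

    values: pd.DataFrame
    conditions: pd.Series                # index = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "miRNA")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            bad = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"count for {self.values.index[bad[0]]!r} in sample "
                f"{self.values.columns[bad[1]]!r} is not a nonnegative integer"
            )
        self.conditions = _check_groups(self.values.columns, self.conditions)
        counts = self.conditions.value_counts()
        if (counts < 2).any():
            raise ValidationError(
                f"conditions with < 2 replicates: {list(counts[counts < 2].index)}"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """A stranded transcript: gene span, exon blocks, CDS and 3'UTR spans.

    All intervals 0-based half-open on the genome.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.transcript_id}: zero-length gene span")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: zero-length exon")
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GenomicAnnotation:
    """Gene models plus miRNA loci as stranded 0-based half-open intervals."""

    transcripts: list[TranscriptModel]
    mirna_loci: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["mirna_id", "chrom", "start", "end", "strand"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.mirna_loci):
            if (self.mirna_loci["end"] <= self.mirna_loci["start"]).any():
                raise ValidationError("zero-length miRNA locus")


@dataclass
class SurvivalTable:
    """Right-censored time-to-event records with an expression covariate."""

    table: pd.DataFrame                  # sample_id, time, event, expression

    REQUIRED = ("sample_id", "time", "event", "expression")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"survival table missing columns: {missing}")
        t = self.table
        if (t["time"] < 0).any():
            raise ValidationError("negative survival time")
        if not t["event"].isin([0, 1, True, False]).all():
            raise ValidationError("event indicator must be 0/1")
        if not np.isfinite(t["expression"]).all():
            raise ValidationError("non-finite expression value")
        _check_unique(t["sample_id"], "sample")
        out = t.copy()
        out["event"] = out["event"].astype(int)
        self.table = out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

MatrixKind = Literal["intensity", "isoform_tpm", "mirna_counts"]


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample->group sidecar TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str)
    return pd.Series(df["group"].values, index=df["sample_id"].values)


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_matrix(path: str | Path, kind: MatrixKind, *,
                groups_path: str | Path | None = None,
                gene_map_path: str | Path | None = None):
    """Read a feature x sample TSV into the typed container for ``kind``.

    The first column holds feature ids and the header row sample ids.  For
    ``isoform_tpm`` a two-column isoform->gene map TSV is required.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dups}")
    groups = read_groups(groups_path) if groups_path is not None else pd.Series(
        "unknown", index=df.columns
    )
    if kind == "intensity":
        return IntensityMatrix(values=df.astype(float), sample_groups=groups)
    if kind == "isoform_tpm":
        if gene_map_path is None:
            raise ValidationError("isoform_tpm requires a gene_map_path")
        gm = pd.read_csv(gene_map_path, sep="\t", header=None,
                         names=["isoform_id", "gene_id"], dtype=str)
        gene_map = pd.Series(gm["gene_id"].values, index=gm["isoform_id"].values)
        return IsoformExpressionMatrix(values=df.astype(float),
                                       gene_map=gene_map, sample_groups=groups)
    if kind == "mirna_counts":
        return MiRNACountMatrix(values=df, conditions=groups)
    raise ValidationError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path: str | Path, *,
                 groups_path: str | Path | None = None) -> None:
    """Write a matrix container back to TSV (round-trips through read_matrix)."""
    obj.values.to_csv(path, sep="\t", index_label="id")
    if groups_path is not None:
        labels = obj.conditions if isinstance(obj, MiRNACountMatrix) \
            else obj.sample_groups
        write_groups(labels, groups_path)


def read_survival_table(path: str | Path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t"))


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path, reference_target: str) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference_target=reference_target)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-model readers (BED12 / GTF)
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
]


def _utr3_from_cds(strand: str, exons: list[tuple[int, int]],
                   cds: tuple[int, int] | None) -> tuple[int, int] | None:
    """3'UTR = transcript span downstream of the CDS end, on the coding strand."""
    if cds is None:
        return None
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if strand == "+":
        return (cds[1], tx_end) if cds[1] < tx_end else None
    return (tx_start, cds[0]) if cds[0] > tx_start else None


def _read_bed12(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED12_COLS[: df.shape[1]]
    models = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(row.start + s, row.start + s + z) for s, z in zip(starts, sizes)]
        cds = None
        if row.thick_end > row.thick_start:
            cds = (int(row.thick_start), int(row.thick_end))
        # BED names are "gene_id|transcript_id" when both are needed
        name = str(row.name)
        gene_id, _, tx_id = name.partition("|")
        models.append(TranscriptModel(
            transcript_id=tx_id or name, gene_id=gene_id, chrom=str(row.chrom),
            strand=str(row.strand), start=int(row.start), end=int(row.end),
            exons=exons, cds=cds,
            utr3=_utr3_from_cds(str(row.strand), sorted(exons), cds),
        ))
    return models


def _read_gtf(path: str | Path) -> list[TranscriptModel]:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    models = []
    # pyranges already converts GTF 1-based closed to 0-based half-open
    for tx_id, sub in df[df["Feature"].isin(["exon", "CDS"])].groupby("transcript_id"):
        exons = sorted(
            (int(r.Start), int(r.End))
            for r in sub[sub["Feature"] == "exon"].itertuples()
        )
        cds_rows = sub[sub["Feature"] == "CDS"]
        cds = None
        if len(cds_rows):
            cds = (int(cds_rows["Start"].min()), int(cds_rows["End"].max()))
        strand = str(sub["Strand"].iloc[0])
        gene_id = str(sub["gene_id"].iloc[0])
        chrom = str(sub["Chromosome"].iloc[0])
        gene_rows = df[(df["Feature"] == "gene") & (df["gene_id"] == gene_id)]
        if len(gene_rows):
            start, end = int(gene_rows["Start"].iloc[0]), int(gene_rows["End"].iloc[0])
        else:
            start, end = exons[0][0], exons[-1][1]
        models.append(TranscriptModel(
            transcript_id=str(tx_id), gene_id=gene_id, chrom=chrom,
            strand=strand, start=start, end=end, exons=exons, cds=cds,
            utr3=_utr3_from_cds(strand, exons, cds),
        ))
    return models


def read_gene_models(path: str | Path,
                     mirna_bed: str | Path | None = None) -> GenomicAnnotation:
    """Read gene models (BED12 or GTF by extension) and optional miRNA BED6."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        transcripts = _read_bed12(path)
    elif path.suffix.lower() in (".gtf", ".gff"):
        transcripts = _read_gtf(path)
    else:
        raise ValidationError(f"cannot infer gene-model dialect from {path.name!r}")
    mirnas = None
    if mirna_bed is not None:
        m = pd.read_csv(mirna_bed, sep="\t", header=None, comment="#")
        m = m.iloc[:, :6]
        m.columns = ["chrom", "start", "end", "mirna_id", "score", "strand"]
        mirnas = m[["mirna_id", "chrom", "start", "end", "strand"]]
    if mirnas is None:
        return GenomicAnnotation(transcripts=transcripts)
    return GenomicAnnotation(transcripts=transcripts, mirna_loci=mirnas)


def write_gene_models_bed12(annotation: GenomicAnnotation,
                            path: str | Path) -> None:
    """Write transcripts as BED12; name field is gene_id|transcript_id."""
    rows = []
    for tx in annotation.transcripts:
        exons = sorted(tx.exons)
        thick = tx.cds if tx.cds is not None else (tx.start, tx.start)
        rows.append([
            tx.chrom, tx.start, tx.end, f"{tx.gene_id}|{tx.transcript_id}",
            0, tx.strand, thick[0], thick[1], "0",
            len(exons),
            ",".join(str(e - s) for s, e in exons) + ",",
            ",".join(str(s - tx.start) for s, _ in exons) + ",",
        ])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_mirna_bed(annotation: GenomicAnnotation, path: str | Path) -> None:
    m = annotation.mirna_loci
    pd.DataFrame({
        "chrom": m["chrom"], "start": m["start"], "end": m["end"],
        "name": m["mirna_id"], "score": 0, "strand": m["strand"],
    }).to_csv(path, sep="\t", header=False, index=False)
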