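"""miRNA DE filters, normalization, genomic-context classification."""

import numpy as np
import pandas as pd
import pytest

from isoswitch import mirna_panel as mp
from isoswitch.io_formats import (
    GenomicAnnotation,
    MiRNACountMatrix,
    TranscriptModel,
    ValidationError,
)
from isoswitch.synthetic_data import MirnaScenario, gen_mirna_counts


def _counts(values, conditions):
    df = pd.DataFrame(values)
    df.index = [f"m{i + 1}" for i in range(len(df))]
    return MiRNACountMatrix(values=df,
                            conditions=pd.Series(conditions, index=df.columns))


class TestNormalization:
    def test_identical_samples_unchanged(self):
        m = _counts({"a1": [10, 20], "a2": [10, 20], "b1": [10, 20],
                     "b2": [10, 20]}, ["control"] * 2 + ["silenced"] * 2)
        normalized, factors = mp.normalize_counts(m)
        pd.testing.assert_frame_equal(normalized, m.values.astype(float))
        assert np.allclose(factors, 1.0)

    def test_doubled_library_scaled_back(self):
        m = _counts({"a1": [10, 20], "a2": [20, 40], "b1": [10, 20],
                     "b2": [10, 20]}, ["control"] * 2 + ["silenced"] * 2)
        normalized, _ = mp.normalize_counts(m)
        pd.testing.assert_series_equal(normalized["a1"], normalized["a2"],
                                       check_names=False)

    def test_factors_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 500, size=(30, 4))
        m = _counts({f"s{i}": vals[:, i] for i in range(4)},
                    ["control"] * 2 + ["silenced"] * 2)
        factors = mp.normalization_factors(m)
        sums = vals.sum(axis=0)
        expected = sums / sums.mean()
        assert np.allclose(factors.to_numpy(), expected)

    def test_zero_library_rejected(self):
        m = _counts({"a1": [0, 0], "a2": [1, 2], "b1": [1, 2], "b2": [1, 2]},
                    ["control"] * 2 + ["silenced"] * 2)
        with pytest.raises(ValidationError, match="a1"):
            mp.normalize_counts(m)


class TestDeTest:
    def _de(self, ctrl_rows, sil_rows):
        ctrl = np.asarray(ctrl_rows, float)
        sil = np.asarray(sil_rows, float)
        df = pd.DataFrame(
            np.hstack([ctrl, sil]),
            index=[f"m{i + 1}" for i in range(ctrl.shape[0])],
            columns=["c1", "c2", "c3", "t1", "t2", "t3"],
        )
        cond = pd.Series(["control"] * 3 + ["silenced"] * 3, index=df.columns)
        return mp.de_test(df, cond)

    def test_half_fold_with_small_p_is_significant_down(self):
        res = self._de([[100, 102, 98]], [[50, 51, 49]])
        row = res.table.iloc[0]
        assert row["fc"] == pytest.approx(0.5)
        assert row["p"] < 0.05
        assert row["significant"]
        assert row["direction"] == "down"

    def test_dead_zone_fc_not_significant_despite_tiny_p(self):
        res = self._de([[1000, 1001, 999]], [[800, 801, 799]])
        row = res.table.iloc[0]
        assert row["p"] < 0.001
        assert 0.6 <= row["fc"] <= 1.5
        assert not row["significant"]

    def test_flag_reproducible_from_printed_rule(self):
        rng = np.random.default_rng(8)
        ctrl = rng.poisson(200, size=(50, 3))
        sil = rng.poisson(rng.uniform(50, 400, size=50)[:, None], size=(50, 3))
        res = self._de(ctrl, sil)
        t = res.table
        rule = (t["p"] < 0.05) & ((t["fc"] < 0.6) | (t["fc"] > 1.5))
        assert (t["significant"] == rule).all()

    def test_zero_in_both_conditions_excluded(self):
        res = self._de([[0, 0, 0], [10, 11, 9]], [[0, 0, 0], [10, 10, 12]])
        assert res.excluded == ["m1"]
        assert list(res.table["mirna_id"]) == ["m2"]


def _gene(gene_id, chrom, strand, start, exons, cds=None, utr3=None):
    return TranscriptModel(
        transcript_id=f"{gene_id}.t", gene_id=gene_id, chrom=chrom,
        strand=strand, start=start, end=max(e for _, e in exons),
        exons=exons, cds=cds, utr3=utr3,
    )


class TestContext:
    def test_mirna_inside_host_intron(self):
        # miR-21/VMP1-like configuration: miRNA wholly inside a host intron
        host = _gene("VMP1L", "chr17", "+", 0,
                     [(0, 100), (500, 600), (900, 1000)],
                     cds=(10, 950), utr3=(950, 1000))
        mirnas = pd.DataFrame([("mir21", "chr17", 700, 780, "+")],
                              columns=["mirna_id", "chrom", "start", "end",
                                       "strand"])
        (ctx,) = mp.classify_context(mirnas, GenomicAnnotation([host]))
        assert ctx.category == "intronic"
        assert ctx.host_gene_id == "VMP1L"

    def test_opposite_strand_overlap_is_intergenic(self):
        host = _gene("G", "chr1", "+", 0, [(0, 1000)])
        mirnas = pd.DataFrame([("m", "chr1", 100, 180, "-")],
                              columns=["mirna_id", "chrom", "start", "end",
                                       "strand"])
        (ctx,) = mp.classify_context(mirnas, GenomicAnnotation([host]))
        assert ctx.category == "intergenic"
        assert ctx.host_gene_id is None

    def test_utr3_precedence_over_exonic(self):
        host = _gene("G", "chr1", "+", 0, [(0, 1000)],
                     cds=(0, 600), utr3=(600, 1000))
        mirnas = pd.DataFrame([("m", "chr1", 700, 780, "+")],
                              columns=["mirna_id", "chrom", "start", "end",
                                       "strand"])
        (ctx,) = mp.classify_context(mirnas, GenomicAnnotation([host]))
        assert ctx.category == "utr3"

    def test_every_mirna_gets_exactly_one_category(self):
        _, annot, truth = gen_mirna_counts(MirnaScenario(n_mirnas=60, seed=2))
        contexts = mp.classify_context(annot.mirna_loci, annot)
        assert len(contexts) == len(annot.mirna_loci)
        assert all(c.category in mp.CATEGORIES for c in contexts)

    def test_matches_exhaustive_interval_scan_oracle(self):
        rng = np.random.default_rng(17)
        genes = []
        for i in range(12):
            start = int(rng.integers(0, 5000))
            exon_starts = np.sort(rng.choice(np.arange(0, 900, 10), 3,
                                             replace=False))
            exons = [(start + int(s), start + int(s) + int(rng.integers(10, 80)))
                     for s in exon_starts]
            end = max(e for _, e in exons)
            cds = (exons[0][0], exons[-1][0] + 5)
            strand = "+" if rng.random() < 0.5 else "-"
            utr3 = None
            if strand == "+" and cds[1] < end:
                utr3 = (cds[1], end)
            genes.append(TranscriptModel(
                transcript_id=f"g{i}.t", gene_id=f"g{i}", chrom="chrR",
                strand=strand, start=exons[0][0], end=end, exons=exons,
                cds=cds, utr3=utr3))
        mirnas = pd.DataFrame(
            [(f"m{j}", "chrR", int(p), int(p) + 30,
              "+" if rng.random() < 0.5 else "-")
             for j, p in enumerate(rng.integers(0, 6000, size=80))],
            columns=["mirna_id", "chrom", "start", "end", "strand"])
        got = mp.classify_context(mirnas, GenomicAnnotation(genes))

        def oracle_one(row):
            # scan every base of the miRNA against every annotation feature
            best = None  # (precedence, -overlap, gene_id, category)
            rank = {"utr3": 0, "exonic": 1, "intronic": 2}
            for g in genes:
                if g.strand != row.strand or g.chrom != row.chrom:
                    continue
                bases = set(range(row.start, row.end)) & set(
                    range(g.start, g.end))
                if not bases:
                    continue
                exonic_bases = set()
                for s, e in g.exons:
                    exonic_bases |= set(range(s, e))
                utr3_bases = set()
                if g.utr3 is not None:
                    utr3_bases = set(range(*g.utr3)) & exonic_bases
                if set(range(row.start, row.end)) & utr3_bases:
                    cat = "utr3"
                elif set(range(row.start, row.end)) & exonic_bases:
                    cat = "exonic"
                else:
                    cat = "intronic"
                cand = (rank[cat], -len(bases), g.gene_id, cat)
                best = cand if best is None else min(best, cand)
            if best is None:
                return "intergenic", None
            return best[3], best[2]

        for row, ctx in zip(mirnas.itertuples(index=False), got):
            cat, host = oracle_one(row)
            assert (ctx.category, ctx.host_gene_id) == (cat, host), row


class TestSummaries:
    def test_proportions_among_significant(self):
        table = pd.DataFrame({
            "mirna_id": ["m1", "m2", "m3", "m4", "m5"],
            "mean_control": [1] * 5, "mean_silenced": [1] * 5,
            "fc": [0.4, 0.4, 0.4, 2.0, 1.0],
            "p": [0.01, 0.01, 0.01, 0.01, 0.01],
            "significant": [True, True, True, True, False],
            "direction": ["down", "down", "down", "up", "none"],
        })
        de = mp.MiRNADEResult(table=table, excluded=[], method="total_count")
        contexts = [
            mp.MiRNAContext("m1", "intronic", "h1"),
            mp.MiRNAContext("m2", "intronic", "h2"),
            mp.MiRNAContext("m3", "exonic", "h3"),
            mp.MiRNAContext("m4", "intergenic", None),
            mp.MiRNAContext("m5", "utr3", "h5"),
        ]
        out = mp.summarize_contexts(de, contexts)
        assert out.loc["intronic", "count"] == 2
        assert out.loc["intronic", "proportion"] == pytest.approx(0.5)
        assert out.loc["exonic", "proportion"] == pytest.approx(0.25)
        assert out.loc["intergenic", "count_up"] == 1
        assert out.loc["utr3", "count"] == 0

    def test_empty_significant_set_all_zero(self):
        table = pd.DataFrame({
            "mirna_id": ["m1"], "mean_control": [1.0], "mean_silenced": [1.0],
            "fc": [1.0], "p": [0.9], "significant": [False],
            "direction": ["none"],
        })
        de = mp.MiRNADEResult(table=table, excluded=[], method="total_count")
        out = mp.summarize_contexts(de, [mp.MiRNAContext("m1", "intronic", "h")])
        assert (out[["count", "count_down", "count_up"]] == 0).all().all()
        assert (out[["proportion", "proportion_down", "proportion_up"]]
                == 0).all().all()

    def test_generated_context_proportions_recovered(self):
        scen = MirnaScenario(n_mirnas=300, n_de=0,
                             context_proportions=(0.7, 0.1, 0.1, 0.1), seed=6)
        _, annot, truth = gen_mirna_counts(scen)
        contexts = mp.classify_context(annot.mirna_loci, annot)
        frac = pd.Series([c.category for c in contexts]).value_counts(
            normalize=True)
        # binomial error at n=300: sd ~ 0.026 for the largest class
        assert frac["intronic"] == pytest.approx(0.7, abs=0.08)
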