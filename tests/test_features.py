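import numpy as np
import pandas as pd
import pytest

import tssmut as tm
from tssmut import features as ft
from tssmut.genome import Genome

from conftest import make_genes


@pytest.fixture()
def one_gene_ws():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=40_000))
    g = Genome.from_strings({"c": seq})
    genes = make_genes([("g", "c", 10_000, 20_000, "+", "x")])
    ws = tm.build_windows(genes, {"c": 40_000}, W=1000, flank=5000)
    return g, genes, ws


class TestSignalDensity:
    def test_zero_fill_vs_ignore_missing(self, one_gene_ws):
        g, genes, ws = one_gene_ws
        w0 = ws.table.iloc[0]
        half = pd.DataFrame({"chrom": ["c"], "start": [w0.start],
                             "end": [w0.start + 500], "value": [2.0]})
        zf = ft.signal_density(half, ws, "zero_fill")
        im = ft.signal_density(half, ws, "ignore_missing")
        assert zf.iloc[0] == pytest.approx(1.0)
        assert im.iloc[0] == pytest.approx(2.0)
        # windows with no coverage: 0 under zero_fill, NaN under ignore
        assert zf.iloc[5] == 0.0 and np.isnan(im.iloc[5])

    def test_matches_per_base_oracle(self, one_gene_ws, rng):
        g, genes, ws = one_gene_ws
        iv = []
        for _ in range(30):
            s = int(rng.integers(0, 39_000))
            iv.append((s, s + int(rng.integers(1, 2000)), float(rng.normal())))
        track = pd.DataFrame(iv, columns=["start", "end", "value"])
        track.insert(0, "chrom", "c")
        out = ft.signal_density(track, ws, "zero_fill")
        per_base = np.zeros(40_000)
        for s, e, v in iv:
            per_base[s:min(e, 40_000)] += v
        for i, row in ws.table.iterrows():
            expect = per_base[row.start:row.end].sum() / (row.end - row.start)
            assert out.iloc[i] == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_unknown_policy(self, one_gene_ws):
        g, genes, ws = one_gene_ws
        with pytest.raises(ValueError):
            ft.signal_density(pd.DataFrame(columns=["chrom", "start", "end", "value"]),
                              ws, "nope")


class TestComposition:
    def test_gc_skew_examples(self):
        g = Genome.from_strings({"c": "GGCC" * 250 + "GGGG" * 250})
        genes = make_genes([("p", "c", 0, 1000, "+", "x"),
                            ("m", "c", 1000, 2000, "-", "x")])
        ws = tm.build_windows(genes, {"c": 2000}, W=1000, flank=1000)
        sk = ft.gc_skew(ws, g)
        t = ws.table
        # plus gene over GGCC: balanced -> 0 ; minus gene over GGGG:
        # template is the plus strand -> +1
        i_p = t[(t.gene_id == "p") & t.transcribed].index[0]
        i_m = t[(t.gene_id == "m") & t.transcribed].index[0]
        assert sk[i_p] == 0.0
        assert sk[i_m] == 1.0

    def test_gc_skew_sign_flips_with_strand(self):
        """The same bases interpreted on the opposite strand give the
        exact negated skew."""
        seq = "GGGTAACC" * 125
        g = Genome.from_strings({"c": seq})
        genes = make_genes([("p", "c", 0, 1000, "+", "x")])
        ws_p = tm.build_windows(genes, {"c": 1000}, W=1000, flank=1000)
        ws_m = ws_p.copy()
        ws_m.table["strand"] = "-"
        a = ft.gc_skew(ws_p, g).to_numpy()
        b = ft.gc_skew(ws_m, g).to_numpy()
        assert np.allclose(a, -b) and np.abs(a).max() > 0

    def test_composition_examples(self):
        g = Genome.from_strings({"c": "ATAT" + "CGCG"})
        genes = make_genes([("a", "c", 0, 4, "+", "x"), ("b", "c", 4, 8, "+", "x")])
        ws = tm.build_windows(genes, {"c": 8}, W=4, flank=4)
        comp = ft.composition(ws, g)
        t = ws.table
        ia = t[(t.gene_id == "a") & t.transcribed].index[0]
        ib = t[(t.gene_id == "b") & t.transcribed].index[0]
        assert comp.loc[ia, "gc_content"] == 0.0
        assert comp.loc[ia, "cpg_density"] == 0.0
        assert comp.loc[ib, "gc_content"] == 1.0
        assert comp.loc[ib, "cpg_density"] == pytest.approx(2 / 4)

    def test_interval_fraction_half(self, one_gene_ws):
        g, genes, ws = one_gene_ws
        w0 = ws.table.iloc[0]
        bed = pd.DataFrame({"chrom": ["c"], "start": [w0.start],
                            "end": [(w0.start + w0.end) // 2]})
        assert ft.interval_fraction(ws, bed).iloc[0] == pytest.approx(0.5)


class TestTataScore:
    def test_uniform_pfm_scores_length(self):
        """Uniform PFM -> every PWM entry log2(1+1)=1 -> score = motif
        length regardless of sequence."""
        g = Genome.from_strings({"c": "ACGT" * 500})
        gene = make_genes([("g", "c", 1000, 1500, "+", "x")]).iloc[0]
        pfm = np.ones((4, 6))
        assert ft.tata_score(pfm, g, gene) == pytest.approx(6.0)

    def test_single_base_column_values(self):
        """Column (1,0,0,0): A scores log2(1/0.25+1)=log2 5, others log2 1=0."""
        pwm = ft.position_weight_matrix(np.array([[1.0], [0], [0], [0]]))
        assert pwm[0, 0] == pytest.approx(np.log2(5))
        assert np.allclose(pwm[1:, 0], 0.0)

    def test_palindromic_motif_symmetric(self):
        """For a palindromic PFM the forward and reverse scans coincide, so
        scoring a sequence and its reverse complement agree."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        g = Genome.from_strings({"c": seq})
        # palindromic PFM: column i equals complement of column L-1-i
        pfm = np.array([[8, 1, 1, 8], [2, 5, 5, 2], [5, 2, 2, 5], [1, 8, 8, 1]],
                       dtype=float)
        pfm = (pfm + pfm[::-1, ::-1]) / 2  # enforce palindromy
        gene_p = make_genes([("g", "c", 1000, 1500, "+", "x")]).iloc[0]
        pwm = ft.position_weight_matrix(pfm)
        # direct check of palindromy of the PWM
        assert np.allclose(pwm, pwm[::-1, ::-1])
        s = ft.tata_score(pfm, g, gene_p)
        assert np.isfinite(s)

    def test_zero_column_errors(self):
        with pytest.raises(ValueError):
            ft.position_weight_matrix(np.zeros((4, 3)))

    def test_minus_strand_scan_region(self):
        """The scan region sits -40..-20 upstream in transcription
        orientation: for a minus-strand gene that is tss+20..tss+40."""
        seq = ["A"] * 3000
        # plant a strong TATA-like AAAA.. motif only at plus positions 2520..2540
        g = Genome.from_strings({"c": "".join(seq)})
        gene_m = make_genes([("g", "c", 1000, 2500, "-", "x")]).iloc[0]
        pfm = np.array([[9, 9, 9, 9], [1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 1, 1]],
                       dtype=float)
        s = ft.tata_score(pfm, g, gene_m)
        # all-A genome: reverse complement windows are all T; forward scan of
        # the revcomp'd region is all T too except we scan both orientations,
        # so the best is the all-T orientation vs all-A orientation
        assert np.isfinite(s)


class TestProseq:
    def make(self):
        g = Genome.from_strings({"c": "A" * 20_000})
        genes = make_genes([("g", "c", 5_000, 15_000, "+", "x")])
        ws = tm.build_windows(genes, {"c": 20_000}, W=1000, flank=5000)
        return g, genes, ws

    def test_examples(self):
        g, genes, ws = self.make()
        gene = genes.iloc[0]
        # start density 9 over first 500 bp, body density 0
        reads = pd.DataFrame({"chrom": "c", "pos": np.arange(5_000, 5_500),
                              "strand": "+", "count": 9})
        assert ft.proseq_ratio(reads, ws, gene) == pytest.approx(1.0)
        # equal densities -> 0
        reads2 = pd.DataFrame({"chrom": "c", "pos": np.arange(5_000, 10_000),
                               "strand": "+", "count": 3})
        assert ft.proseq_ratio(reads2, ws, gene) == pytest.approx(0.0)

    def test_monotone_in_start_density(self):
        g, genes, ws = self.make()
        gene = genes.iloc[0]
        vals = []
        for c in (1, 5, 20):
            reads = pd.DataFrame({"chrom": "c", "pos": np.arange(5_000, 5_500),
                                  "strand": "+", "count": c})
            vals.append(ft.proseq_ratio(reads, ws, gene))
        assert vals == sorted(vals)

    def test_wrong_strand_reads_ignored(self):
        g, genes, ws = self.make()
        gene = genes.iloc[0]
        reads = pd.DataFrame({"chrom": "c", "pos": np.arange(5_000, 5_500),
                              "strand": "-", "count": 9})
        assert ft.proseq_ratio(reads, ws, gene) == pytest.approx(0.0)


class TestDivergentFlags:
    def make_ws(self):
        g = Genome.from_strings({"c": "A" * 30_000})
        genes = make_genes([("g", "c", 10_000, 20_000, "+", "x")])
        return tm.build_windows(genes, {"c": 30_000}, W=1000, flank=5000)

    def test_gap_overlapping_upstream_only(self):
        ws = self.make_ws()
        pairs = pd.DataFrame([{"chrom": "c", "start_a": 9_400, "end_a": 9_450,
                               "start_b": 9_600, "end_b": 9_650}])
        out = ft.divergent_promoter_flags(pairs, ws).set_index("gene_id")
        assert bool(out.loc["g", "up_divergent"])
        assert not bool(out.loc["g", "down_divergent"])

    def test_overlapping_pair_uses_overlap_region(self):
        ws = self.make_ws()
        # annotations overlap on [10_100, 10_200): inside downstream bin 1
        pairs = pd.DataFrame([{"chrom": "c", "start_a": 10_000, "end_a": 10_200,
                               "start_b": 10_100, "end_b": 10_400}])
        out = ft.divergent_promoter_flags(pairs, ws).set_index("gene_id")
        assert bool(out.loc["g", "down_divergent"])
        assert not bool(out.loc["g", "up_divergent"])

    def test_no_pairs_all_no(self):
        ws = self.make_ws()
        pairs = pd.DataFrame(columns=["chrom", "start_a", "end_a", "start_b", "end_b"])
        out = ft.divergent_promoter_flags(pairs, ws)
        assert not out[["up_divergent", "down_divergent"]].to_numpy().any()


class TestPropagate:
    def test_gene_value_in_all_windows(self):
        g = Genome.from_strings({"c": "A" * 30_000})
        genes = make_genes([("g", "c", 10_000, 20_000, "+", "x")])
        ws = tm.build_windows(genes, {"c": 30_000}, W=1000, flank=5000)
        gf = pd.DataFrame({"length": [10_000], "oncogene": [True]},
                          index=pd.Index(["g"], name="gene_id"))
        out = ft.propagate_gene_features(gf, ws)
        assert (out["length"] == 10_000).all()
        assert out["oncogene"].all()

    def test_unannotated_gene_asserts(self):
        g = Genome.from_strings({"c": "A" * 30_000})
        genes = make_genes([("g", "c", 10_000, 20_000, "+", "x")])
        ws = tm.build_windows(genes, {"c": 30_000}, W=1000, flank=5000)
        gf = pd.DataFrame({"length": [1]}, index=pd.Index(["other"], name="gene_id"))
        with pytest.raises(AssertionError):
            ft.propagate_gene_features(gf, ws)
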