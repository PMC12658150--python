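import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import tssmut as tm
from tssmut import contexts as cx
from tssmut import selection as sel
from tssmut.genome import BASES, Genome, revcomp_str

from conftest import make_genes


class TestMutationEffect:
    def test_codon_table_examples(self):
        g = Genome.from_strings({"c": "ATGTTTAAATAGAAAA"})
        cds = pd.DataFrame([{"gene_id": "t", "chrom": "c", "start": 0,
                             "end": 12, "strand": "+"}])
        assert sel.mutation_effect("c", 5, "C", cds, g) == "synonymous"     # TTT->TTC
        assert sel.mutation_effect("c", 5, "A", cds, g) == "nonsynonymous"  # TTT->TTA
        assert sel.mutation_effect("c", 13, "G", cds, g) == "noncoding"

    def test_stop_gain_nonsynonymous(self):
        g = Genome.from_strings({"c": "ATGTGGAAA"})
        cds = pd.DataFrame([{"gene_id": "t", "chrom": "c", "start": 0,
                             "end": 9, "strand": "+"}])
        # TGG -> TGA (stop gain)
        assert sel.mutation_effect("c", 5, "A", cds, g) == "nonsynonymous"

    def test_minus_strand_matches_translation_oracle(self, rng):
        """Every site x alternate of a random minus-strand CDS agrees with
        an independent reverse-complement + Biopython translation oracle."""
        n = 30
        coding = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * n))
        genomic = revcomp_str(coding)
        pad = "AAAA"
        g = Genome.from_strings({"c": pad + genomic + pad})
        L = len(coding)
        cds = pd.DataFrame([{"gene_id": "t", "chrom": "c", "start": 4,
                             "end": 4 + L, "strand": "-"}])
        eff = sel.per_site_effects(cds, g)["c"]
        for gpos in range(4, 4 + L):
            for a, alt in enumerate(BASES):
                if g.seqs["c"][gpos] == a:
                    assert eff[gpos, a] == sel.NONCODING
                    continue
                seq2 = list(genomic)
                seq2[gpos - 4] = alt
                new_coding = revcomp_str("".join(seq2))
                aa_old = str(Seq(coding).translate())
                aa_new = str(Seq(new_coding).translate())
                expect = sel.SYN if aa_old == aa_new else sel.NONSYN
                assert eff[gpos, a] == expect

    def test_frame_error_named(self):
        g = Genome.from_strings({"c": "ATGTTTAA"})
        cds = pd.DataFrame([{"gene_id": "badframe", "chrom": "c", "start": 0,
                             "end": 8, "strand": "+"}])
        with pytest.raises(ValueError, match="badframe"):
            sel.per_site_effects(cds, g)

    def test_delta_partition(self, rng):
        """Every CDS site x non-reference alternate is exactly one of
        syn/nonsyn; reference alternates are noncoding-coded."""
        coding = "ATG" + "".join(rng.choice(list("ACGT"), size=60))
        g = Genome.from_strings({"c": coding})
        cds = pd.DataFrame([{"gene_id": "t", "chrom": "c", "start": 0,
                             "end": len(coding), "strand": "+"}])
        eff = sel.per_site_effects(cds, g)["c"]
        ref = g.seqs["c"]
        for l in range(len(coding)):
            for a in range(4):
                if a == ref[l]:
                    assert eff[l, a] == sel.NONCODING
                else:
                    assert eff[l, a] in (sel.SYN, sel.NONSYN)


class TestDnds:
    def test_eq7_arithmetic(self):
        counts = pd.DataFrame({
            "gene_id": ["t"], "anchor": ["TSS"], "side": ["downstream"],
            "bin": [1], "d_z": [4.0], "d_s": [2.0], "h_z": [8.0], "h_s": [2.0]})
        out = sel.dnds_window(counts)
        assert out["r"].iloc[0] == pytest.approx(0.5)

    def test_missing_when_no_synonymous(self):
        counts = pd.DataFrame({
            "gene_id": ["t"], "anchor": ["TSS"], "side": ["downstream"],
            "bin": [1], "d_z": [4.0], "d_s": [0.0], "h_z": [8.0], "h_s": [2.0]})
        out = sel.dnds_window(counts)
        assert out["missing"].iloc[0] and np.isnan(out["r"].iloc[0])

    def test_counts_match_enumeration_oracle(self, rng):
        """selection_counts expectations equal a per-site x alternate loop
        over the CDS (exact, small genome)."""
        cfg = tm.SimulationConfig(n_chroms=1, chrom_length=60_000, n_genes=2,
                                  gene_length_range=(6_000, 6_600),
                                  baseline_rate=5e-3, seed=21)
        genome, genes, cds = tm.simulate_genome(cfg)
        muts, _ = tm.simulate_mutations(genome, genes, cfg, cds)
        ws = tm.build_windows(genes, genome, W=1000, flank=5000)
        ws = tm.resolve_intergenic_overlaps(ws)
        mat = tm.build_matrix(muts, ws, genome, k=5)
        counts = sel.selection_counts(muts, ws, genome, mat, cds)
        eff = sel.per_site_effects(cds, genome)["chr1"]
        m = mat.m
        hz = hs = 0.0
        for row in ws.table.itertuples(index=False):
            v = ws.valid_mask("chr1", row.transcribed)
            ctx = genome.context_codes("chr1", 5, row.strand)
            for l in range(row.start, row.end):
                if not v[l] or ctx[l] < 0:
                    continue
                for a in range(4):
                    j = a if row.strand == "+" else 3 - a
                    if eff[l, a] == sel.NONSYN:
                        hz += m[ctx[l], j]
                    elif eff[l, a] == sel.SYN:
                        hs += m[ctx[l], j]
        assert counts["h_z"].sum() == pytest.approx(hz, rel=1e-9)
        assert counts["h_s"].sum() == pytest.approx(hs, rel=1e-9)
        # observed split agrees with direct effect lookup
        dz = ds = 0
        widx = cx.assign_windows(muts, ws)
        for k_, mrow in enumerate(muts.itertuples(index=False)):
            if widx[k_] < 0:
                continue
            e = eff[mrow.pos, BASES.index(mrow.alt)]
            dz += e == sel.NONSYN
            ds += e == sel.SYN
        assert counts["d_z"].sum() == dz and counts["d_s"].sum() == ds

    def test_resample_default_B_and_zero_syn_windows(self):
        counts = pd.DataFrame({
            "gene_id": ["t", "t"], "anchor": ["TSS", "TSS"],
            "side": ["downstream", "downstream"], "bin": [1, 2],
            "d_z": [5.0, 3.0], "d_s": [5.0, 0.0],
            "h_z": [5.0, 5.0], "h_s": [5.0, 5.0]})
        out = sel.resample_dnds(counts, B=100, seed=0)
        b2 = out[out["bin"] == 2].iloc[0]
        assert b2["missing"] and np.isnan(b2["ci_low"])
        b1 = out[out["bin"] == 1].iloc[0]
        assert np.isfinite(b1["ci_low"]) and b1["ci_low"] <= b1["ci_high"]

    def test_identical_mutations_zero_width_ci(self):
        counts = pd.DataFrame({
            "gene_id": ["t"], "anchor": ["TSS"], "side": ["downstream"],
            "bin": [1], "d_z": [10.0], "d_s": [0.0], "h_z": [5.0], "h_s": [5.0]})
        # all mutations nonsynonymous: every resample identical; r missing
        out = sel.resample_dnds(counts, B=20, seed=0)
        assert out["missing"].iloc[0]


class TestAfRatio:
    def make_density(self, small_world):
        w = small_world
        dt = tm.density_table(w["ws"], w["obs"], w["exp"])
        return dt

    def test_identical_strata_ratio_one(self, small_world):
        dt = self.make_density(small_world)
        out = sel.af_ratio(dt, dt, B=20, seed=0)
        ok = np.isfinite(out["ratio"])
        assert np.allclose(out.loc[ok, "ratio"], 1.0)

    def test_uniform_matrix_rescaling_cancels(self, small_world):
        """Scaling one stratum's matrix (hence its expectations) by a
        constant leaves the ratio unchanged."""
        dt = self.make_density(small_world)
        dt2 = dt.copy()
        dt2["expected"] = dt2["expected"] * 3.0
        a = sel.af_ratio(dt, dt, B=5, seed=0)["ratio"]
        b = sel.af_ratio(dt, dt2, B=5, seed=0)["ratio"]
        ok = np.isfinite(a)
        assert np.allclose(b[ok] / a[ok], 3.0)


class TestBgc:
    def test_class_definitions(self):
        assert sel.bgc_class("A", "T") == "indifferent"
        assert sel.bgc_class("A", "G") == "favoured"
        assert sel.bgc_class("C", "T") == "unfavoured"
        assert sel.bgc_class("G", "C") == "indifferent"

    def test_twelve_types_partition_4_4_4(self):
        from collections import Counter
        c = Counter(sel.bgc_class(r, a) for r in BASES for a in BASES if r != a)
        assert c == {"favoured": 4, "unfavoured": 4, "indifferent": 4}

    def test_class_counts_sum_to_total(self, small_world):
        muts = small_world["muts"]
        cls = sel.bgc_stratify(muts)
        assert cls.value_counts().sum() == len(muts)

    def test_classwise_conservation_and_recombination(self, small_world):
        """Per-class observed/expected sum to the all-mutation values, and
        the expectation-weighted recombination of class mu equals total mu."""
        w = small_world
        cls = sel.bgc_stratify(w["muts"])
        obs_t = np.zeros(len(w["ws"].table))
        exp_t = np.zeros(len(w["ws"].table))
        for c in ("favoured", "unfavoured", "indifferent"):
            sub = w["muts"][cls == c]
            mat = tm.build_matrix(sub, w["ws"], w["genome"], k=5)
            obs_c = tm.observed_counts(w["ws"], sub, w["genome"], 5)
            exp_c = tm.expected_counts(w["ws"], mat, w["genome"])
            assert abs(exp_c.sum() - obs_c.sum()) < 1e-9 * max(obs_c.sum(), 1)
            obs_t += obs_c
            exp_t += exp_c
        assert np.allclose(obs_t, w["obs"])
        assert exp_t.sum() == pytest.approx(w["exp"].sum(), rel=1e-9)
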