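"""SNP-to-gene interval arithmetic and the genic-location enrichment test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2, kstest

from geascan import (
    GeneModel,
    ValidationError,
    assign_snps_to_genes,
    collapse_gene_models,
    genic_enrichment_test,
    read_gene_models,
)


def _meta(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "coded_allele": "A",
        }
    )


class TestGeneModels:
    def test_valid_bed6(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t100\t200\tGENE1\t0\t+\n"
            "chr1\t150\t400\tGENE2\t0\t-\n"
            "chr2\t5\t50\tGENE3\t0\t+\n"
        )
        genes = read_gene_models(p)
        assert [g.gene_id for g in genes] == ["GENE1", "GENE2", "GENE3"]

    def test_dot_strand_rejected(self):
        with pytest.raises(ValidationError, match="strand"):
            GeneModel("X", "chr1", 10, 20, ".")

    def test_start_not_below_end_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel("X", "chr1", 20, 20, "+")

    def test_overlapping_genes_both_retained(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t300\tA\t0\t+\nchr1\t200\t400\tB\t0\t+\n")
        assert len(read_gene_models(p)) == 2

    def test_transcripts_collapse_to_union_span(self):
        rows = [
            GeneModel("G", "chr1", 100, 300, "+"),
            GeneModel("G", "chr1", 250, 700, "+"),
            GeneModel("H", "chr1", 10, 20, "-"),
        ]
        merged = collapse_gene_models(rows)
        assert merged[0] == GeneModel("G", "chr1", 100, 700, "+")
        assert merged[1].gene_id == "H"

    def test_conflicting_transcript_strands_rejected(self):
        rows = [GeneModel("G", "chr1", 1, 5, "+"), GeneModel("G", "chr1", 9, 12, "-")]
        with pytest.raises(ValidationError, match="G"):
            collapse_gene_models(rows)


class TestAssignment:
    GENE_PLUS = GeneModel("G", "chr1", 1000, 2000, "+")
    GENE_MINUS = GeneModel("G", "chr1", 1000, 2000, "-")

    def _assigned(self, pos, gene, upstream):
        m = assign_snps_to_genes(_meta([pos]), [gene], upstream)
        return len(m) == 1

    def test_interior_snp_assigned(self):
        assert self._assigned(1001, self.GENE_PLUS, 0)

    def test_plus_strand_upstream_boundaries(self):
        # 1-based 600 -> 0-based 599 is inside [500, 2000); 499 -> 498 is not
        assert self._assigned(600, self.GENE_PLUS, 500)
        assert not self._assigned(499, self.GENE_PLUS, 500)
        assert self._assigned(501, self.GENE_PLUS, 500)  # exactly at extended start

    def test_minus_strand_upstream_is_rightward(self):
        assert self._assigned(2400, self.GENE_MINUS, 500)
        assert not self._assigned(2400, self.GENE_PLUS, 500)
        assert not self._assigned(2501, self.GENE_MINUS, 500)  # 0-based 2500 = end+500

    def test_half_open_end(self):
        # 0-based 2000 is outside [1000, 2000)
        assert not self._assigned(2001, self.GENE_PLUS, 0)
        assert self._assigned(2000, self.GENE_PLUS, 0)

    def test_negative_extended_start_clamped(self):
        g = GeneModel("G", "chr1", 100, 300, "+")
        assert self._assigned(1, g, 500)  # 0-based 0, window clamps to [0, 300)

    def test_orphan_chromosome_warned_not_dropped(self):
        meta = _meta([1500, 1500], chrom="chrX").assign(chrom=["chr1", "chrX"])
        with pytest.warns(UserWarning, match="chrX"):
            m = assign_snps_to_genes(meta, [self.GENE_PLUS], 0)
        assert m["snp_id"].tolist() == ["s0"]

    def test_snp_maps_to_all_overlapping_genes(self):
        genes = [
            GeneModel("A", "chr1", 1000, 2000, "+"),
            GeneModel("B", "chr1", 1500, 2500, "-"),
        ]
        m = assign_snps_to_genes(_meta([1700]), genes, 0)
        assert sorted(m["gene_id"]) == ["A", "B"]

    @given(
        st.lists(st.integers(1, 3000), min_size=1, max_size=30),
        st.integers(0, 800),
        st.integers(0, 1500),
        st.integers(1, 1000),
        st.sampled_from(["+", "-"]),
    )
    def test_matches_interval_oracle(self, positions, upstream, start, length, strand):
        gene = GeneModel("G", "chr1", start, start + length, strand)
        meta = _meta(sorted(set(positions)))
        m = assign_snps_to_genes(meta, [gene], upstream)
        got = set(m["snp_id"])
        for _, row in meta.iterrows():
            p0 = row["pos"] - 1
            if strand == "+":
                inside = max(start - upstream, 0) <= p0 < start + length
            else:
                inside = start <= p0 < start + length + upstream
            assert (row["snp_id"] in got) == inside

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=40), st.integers(0, 400))
    def test_upstream_extension_is_monotone(self, positions, upstream):
        genes = [
            GeneModel("A", "chr1", 900, 1400, "+"),
            GeneModel("B", "chr1", 2000, 2600, "-"),
        ]
        meta = _meta(sorted(set(positions)))
        small = set(map(tuple, assign_snps_to_genes(meta, genes, upstream)[["snp_id", "gene_id"]].values))
        large = set(map(tuple, assign_snps_to_genes(meta, genes, upstream + 250)[["snp_id", "gene_id"]].values))
        assert small <= large


class TestGenicEnrichment:
    def _results(self, n_sig, n_nonsig, rng=None):
        n = n_sig + n_nonsig
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "tau": 0.1,
                "p_value": 0.5,
                "maf": 0.25,
                "final_sig": [True] * n_sig + [False] * n_nonsig,
            }
        )

    def test_extreme_separation_matches_2x2_formula(self):
        res = self._results(10, 200)
        genic = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(10)], "gene_id": "G", "rule_used": "r"}
        )
        out = genic_enrichment_test(res, genic, k=10, seed=0)
        a, b = out["table"][0]
        c, d = out["table"][1]
        assert (a, b) == (10, 0) and (c + d) == 100 and c == 0
        n = a + b + c + d
        expected_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert out["chi2"] == pytest.approx(expected_chi2, abs=1e-9)
        assert out["p_value"] == pytest.approx(chi2.sf(expected_chi2, 1), abs=1e-12)
        assert out["p_value"] < 1e-3

    def test_identical_fractions_give_null_chi2(self):
        res = self._results(5, 100)
        all_genic = pd.DataFrame(
            {"snp_id": res["snp_id"], "gene_id": "G", "rule_used": "r"}
        )
        out = genic_enrichment_test(res, all_genic, k=10, seed=1)
        assert out["chi2"] == 0.0 and out["p_value"] == 1.0

    def test_insufficient_controls_suggests_smaller_k(self):
        res = self._results(3, 5)
        with pytest.raises(ValidationError, match="smaller k"):
            genic_enrichment_test(res, res[["snp_id"]].assign(gene_id="G", rule_used="r"), k=10)

    def test_no_significant_snps_rejected(self):
        res = self._results(0, 50)
        with pytest.raises(ValidationError):
            genic_enrichment_test(res, pd.DataFrame({"snp_id": [], "gene_id": [], "rule_used": []}))

    def test_null_pvalues_roughly_uniform(self, rng):
        """With genic status independent of significance the test is calibrated."""
        n_sig, n_nonsig = 40, 800
        pvals = []
        for rep in range(200):
            res = self._results(n_sig, n_nonsig)
            genic_ids = rng.choice(res["snp_id"], size=420, replace=False)
            gmap = pd.DataFrame({"snp_id": genic_ids, "gene_id": "G", "rule_used": "r"})
            out = genic_enrichment_test(res, gmap, k=5, seed=int(rng.integers(2**31)))
            pvals.append(out["p_value"])
        rej = np.mean(np.array(pvals) < 0.05)
        assert rej < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)
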