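"""Donor-genotype reconstruction: partitions, filters, specificity, VCF."""

import numpy as np
import pytest
import scipy.sparse as sp

import jointdemux as jd
from jointdemux.refinement import ALT, REF


def _acs(variants, barcodes, ad, dp):
    return jd.AlleleCountSet(
        variants, barcodes,
        sp.csr_matrix(np.asarray(ad)), sp.csr_matrix(np.asarray(dp)),
    )


@pytest.fixture()
def tiny_joint():
    entries = {
        "c1": (jd.singlet("H1"), "confirmed"),
        "c2": (jd.singlet("H1"), "confirmed"),
        "c3": (jd.singlet("H1"), "confirmed"),
        "c4": (jd.singlet("H1"), "rescued"),
        "c5": (jd.singlet("H1"), "conflict"),
        "c6": (jd.singlet("H2"), "confirmed"),
        "c7": (jd.doublet(), "doublet"),
        "c8": (jd.negative(), "negative"),
    }
    return jd.JointAssignment(entries)


class TestPartition:
    def test_by_provenance(self, tiny_joint):
        cons, inc = jd.partition_cells(tiny_joint, "H1")
        assert cons == {"c1", "c2", "c3"}
        assert inc == {"c4", "c5"}

    def test_only_confirmed(self, tiny_joint):
        cons, inc = jd.partition_cells(tiny_joint, "H2")
        assert cons == {"c6"} and inc == set()

    def test_unknown_donor_errors(self, tiny_joint):
        with pytest.raises(ValueError):
            jd.partition_cells(tiny_joint, "H9")

    def test_doublets_and_negatives_excluded(self, tiny_joint):
        cons, inc = jd.partition_cells(tiny_joint, "H1")
        assert "c7" not in cons | inc and "c8" not in cons | inc


class TestAggregate:
    def test_simple_sum(self):
        v = [jd.VariantRecord("chr1", 100, "A", "G")]
        acs = _acs(v, ["c1", "c2"], [[3, 4]], [[3, 4]])
        agg = jd.aggregate_counts(acs, {"c1", "c2"})
        assert agg.loc[0, "sumAD"] == 7 and agg.loc[0, "sumDP"] == 7

    def test_empty_cell_set(self):
        v = [jd.VariantRecord("chr1", 100, "A", "G")]
        acs = _acs(v, ["c1"], [[3]], [[3]])
        assert jd.aggregate_counts(acs, set()).empty

    def test_unknown_barcode_errors(self):
        v = [jd.VariantRecord("chr1", 100, "A", "G")]
        acs = _acs(v, ["c1"], [[3]], [[3]])
        with pytest.raises(ValueError):
            jd.aggregate_counts(acs, {"zz"})

    def test_matches_dense_oracle(self, small_experiment):
        """Sparse column sums agree with a dense brute-force sum."""
        exp = small_experiment
        cells = set(exp.counts.barcodes[::7])
        agg = jd.aggregate_counts(exp.counts, cells)
        cols = [j for j, bc in enumerate(exp.counts.barcodes) if bc in cells]
        dense_ad = exp.counts.AD.toarray()[:, cols].sum(axis=1)
        dense_dp = exp.counts.DP.toarray()[:, cols].sum(axis=1)
        for row in agg.index:
            assert agg.loc[row, "sumAD"] == dense_ad[row]
            assert agg.loc[row, "sumDP"] == dense_dp[row]
        assert set(agg.index) == set(np.flatnonzero(dense_dp > 0))


class TestOverrepresentedAllele:
    @pytest.mark.parametrize(
        "ad, dp, expected",
        [
            (19, 20, ALT),     # alt freq 0.95 > 0.9, depth 20 > 10
            (1, 20, REF),      # ref freq 0.95
            (10, 20, None),    # 0.5 not > 0.9
            (8, 8, None),      # depth 8 <= 10
            (11, 11, ALT),     # depth 11 > 10, freq 1.0
        ],
    )
    def test_rule(self, ad, dp, expected):
        assert jd.overrepresented_allele(ad, dp) == expected

    def test_ad_exceeding_dp_errors(self):
        with pytest.raises(ValueError):
            jd.overrepresented_allele(5, 4)


class TestInformativeVariants:
    def _counts_for_groups(self, cons_ad, cons_dp, inc_ad, inc_dp):
        # 12 consistent + 12 inconsistent cells, one variant, uniform reads
        v = [jd.VariantRecord("chr1", 100, "A", "G")]
        n = 12
        barcodes = [f"k{i}" for i in range(n)] + [f"r{i}" for i in range(n)]
        ad = [[cons_ad / n] * n + [inc_ad / n] * n]
        dp = [[cons_dp / n] * n + [inc_dp / n] * n]
        acs = _acs(v, barcodes, np.array(ad), np.array(dp))
        entries = {f"k{i}": (jd.singlet("H1"), "confirmed") for i in range(n)}
        entries.update({f"r{i}": (jd.singlet("H1"), "rescued") for i in range(n)})
        return acs, jd.JointAssignment(entries)

    def test_concordant_groups_keep_variant(self):
        acs, joint = self._counts_for_groups(24, 24, 24, 24)
        out = jd.informative_variants(acs, joint, "H1")
        assert list(out.values()) == [ALT]

    def test_discordant_groups_drop_variant(self):
        acs, joint = self._counts_for_groups(24, 24, 0, 24)
        assert jd.informative_variants(acs, joint, "H1") == {}

    def test_uncovered_inconsistent_group_keeps_variant(self):
        acs, joint = self._counts_for_groups(24, 24, 0, 0)
        out = jd.informative_variants(acs, joint, "H1")
        assert list(out.values()) == [ALT]
        cfg = jd.RefinementConfig(keep_uncovered_inconsistent=False)
        assert jd.informative_variants(acs, joint, "H1", cfg) == {}

    def test_monotone_in_thresholds(self, small_experiment, small_joint):
        """Raising either threshold never adds variants."""
        exp = small_experiment
        _, joint = small_joint
        donor = sorted({lab.name for lab, p in joint.entries.values()
                        if lab.kind == "singlet" and p == "confirmed"})[0]
        base = set(jd.informative_variants(exp.counts, joint, donor))
        for cfg in (jd.RefinementConfig(depth_threshold=20),
                    jd.RefinementConfig(freq_threshold=0.95)):
            tighter = set(jd.informative_variants(exp.counts, joint, donor, cfg))
            assert tighter <= base


class TestDonorSpecific:
    v1 = jd.VariantRecord("chr1", 100, "A", "G")
    v2 = jd.VariantRecord("chr1", 200, "C", "T")

    def test_unique_call_rules(self):
        calls = {"d1": {self.v1: ALT, self.v2: ALT},
                 "d2": {self.v2: ALT},
                 "d3": {self.v2: REF}}
        out = jd.donor_specific_variants(calls)
        assert out["d1"] == {self.v1: ALT}          # v2 ALT shared with d2
        assert out["d2"] == {}
        assert out["d3"] == {self.v2: REF}          # differing call survives

    def test_exclusive_mode(self):
        calls = {"d1": {self.v1: ALT, self.v2: ALT}, "d2": {self.v2: REF}}
        out = jd.donor_specific_variants(calls, mode="exclusive")
        assert out == {"d1": {self.v1: ALT}, "d2": {}}

    def test_needs_two_donors(self):
        with pytest.raises(ValueError):
            jd.donor_specific_variants({"d1": {}})

    def test_shared_variants_never_survive(self, small_experiment, small_joint):
        exp = small_experiment
        _, joint = small_joint
        genos = jd.reconstruct_genotypes(exp.counts, joint)
        seen = {}
        for d, calls in genos.calls.items():
            for v, a in calls.items():
                seen.setdefault((v, a), []).append(d)
        assert all(len(ds) == 1 for ds in seen.values())


class TestRecheckOracle:
    def test_every_emitted_variant_reverifies(self, small_experiment, small_joint):
        """Emitted calls re-satisfy depth and frequency from raw counts."""
        exp = small_experiment
        _, joint = small_joint
        cfg = jd.RefinementConfig()
        genos = jd.reconstruct_genotypes(exp.counts, joint, cfg)
        row_of = {v.key: i for i, v in enumerate(exp.counts.variants)}
        for d, calls in genos.calls.items():
            cons, _ = jd.partition_cells(joint, d)
            agg = jd.aggregate_counts(exp.counts, cons)
            for v, allele in calls.items():
                ad = int(agg.loc[row_of[v.key], "sumAD"])
                dp = int(agg.loc[row_of[v.key], "sumDP"])
                assert dp > cfg.depth_threshold
                freq = ad / dp if allele == ALT else (dp - ad) / dp
                assert freq > cfg.freq_threshold


class TestDonorVcf:
    def test_disjoint_calls_round_trip(self, tmp_path):
        v = [jd.VariantRecord("chr1", 100, "A", "G"),
             jd.VariantRecord("chr1", 200, "C", "T"),
             jd.VariantRecord("chr2", 50, "G", "A")]
        genos = jd.DonorGenotypeSet(
            donors=["d1", "d2"],
            calls={"d1": {v[0]: ALT, v[2]: REF}, "d2": {v[1]: ALT}},
        )
        path = tmp_path / "donors.vcf"
        jd.write_donor_vcf(genos, path, match={"d1": "H1", "d2": "H2"})
        text = path.read_text()
        assert text.count("./.") == 3  # 2x3 cells minus 3 calls
        back = jd.read_donor_vcf(path)
        assert back.donors == ["H1", "H2"]
        assert {vv.key: a for vv, a in back.calls["H1"].items()} == {
            v[0].key: ALT, v[2].key: REF}
        assert {vv.key: a for vv, a in back.calls["H2"].items()} == {v[1].key: ALT}

    def test_records_sorted_by_position(self, small_experiment, small_joint, tmp_path):
        exp = small_experiment
        _, joint = small_joint
        genos = jd.reconstruct_genotypes(exp.counts, joint)
        path = tmp_path / "donors.vcf"
        jd.write_donor_vcf(genos, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()
                if not l.startswith("#")]
        keys = [(r[0], int(r[1])) for r in rows]
        assert keys == sorted(keys)

    def test_duplicate_sample_names_rejected(self, tmp_path):
        v = jd.VariantRecord("chr1", 100, "A", "G")
        genos = jd.DonorGenotypeSet(donors=["d1", "d2"], calls={"d1": {v: ALT}, "d2": {}})
        with pytest.raises(ValueError):
            jd.write_donor_vcf(genos, tmp_path / "x.vcf", match={"d1": "H1", "d2": "H1"})
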