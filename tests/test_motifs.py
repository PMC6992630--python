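"""Motif enrichment, specificity grouping and viral classification."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from tcrrep import motifs
from tcrrep.simulate import make_naive_reference


class TestTrim:
    def test_trimming_rule(self):
        assert motifs.trim_cdr3("CASSLGQAYEQYF") == "SLGQAYEQ"

    def test_short_sequences_excluded(self):
        assert motifs.trim_cdr3("CASSYF") is None

    def test_trimming_is_lossy(self):
        trimmed = motifs.trim_cdr3("CASSLGQAYEQYF")
        assert len(trimmed) < len("CASSLGQAYEQYF")
        assert not trimmed.startswith("CAS")


class TestEnrichedMotifs:
    def test_planted_motif_absent_from_reference_passes(self):
        rng = np.random.default_rng(1)
        ref = make_naive_reference(2000, rng=rng, forbidden_motifs=["WQRS"])
        analysis = make_naive_reference(80, rng=rng, forbidden_motifs=["WQRS"])
        planted = ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF", "CATSWQRSNQPQF"]
        hits = motifs.enriched_motifs(analysis + planted, ref, seed=3)
        assert "WQRS" in {h.motif for h in hits}
        hit = next(h for h in hits if h.motif == "WQRS")
        assert hit.observed_count == 4
        assert hit.fold_enrichment >= 10
        assert hit.resample_p <= 0.001

    def test_single_occurrence_motifs_never_tested(self):
        rng = np.random.default_rng(2)
        ref = make_naive_reference(1000, rng=rng, forbidden_motifs=["WQRS"])
        analysis = make_naive_reference(50, rng=rng, forbidden_motifs=["WQRS"])
        hits = motifs.enriched_motifs(analysis + ["CASSWQRSTEAFF"], ref, seed=3)
        assert "WQRS" not in {h.motif for h in hits}

    def test_empty_reference_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="reference"):
            motifs.enriched_motifs(["CASSLGQAYEQYF"], [], seed=0)

    def test_null_analysis_from_reference_yields_few_hits(self):
        rng = np.random.default_rng(4)
        ref = make_naive_reference(5000, rng=rng)
        analysis = [ref[i] for i in rng.choice(len(ref), size=200, replace=False)]
        hits = motifs.enriched_motifs(analysis, ref, seed=5)
        # every motif of the analysis set exists in the reference, so only
        # resampling noise can pass both thresholds
        assert len(hits) <= 5


class TestBuildGroups:
    @staticmethod
    def oracle_components(cdr3s, enriched):
        """Independent O(n^2) pairwise relation + transitive closure."""
        trimmed = {c: motifs.trim_cdr3(c) for c in cdr3s}
        nodes = [c for c in cdr3s if trimmed[c] is not None]
        parent = {c: c for c in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(nodes, 2):
            ta, tb = trimmed[a], trimmed[b]
            local = any(m in ta and m in tb for m in enriched)
            hamming = len(ta) == len(tb) and sum(x != y for x, y in zip(ta, tb)) <= 1
            if local or hamming:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        comps = {}
        for c in nodes:
            comps.setdefault(find(c), set()).add(c)
        return {frozenset(v) for v in comps.values() if len(v) >= 2}

    def test_shared_motif_links_members(self):
        hits = [motifs.MotifHit("QRST", 3, 3, 1e-4, 100, 0.001)]
        records = pd.DataFrame(
            {"cdr3_aa": ["CASSQRSTAEQYF", "CAWNMQRSTGYTFF", "CASQRSTPYEQYF"]}
        )
        groups = motifs.build_groups(records, hits)
        assert len(groups) == 1
        assert len(groups[0].member_cdr3s) == 3

    def test_hamming_one_links_without_motif(self):
        records = pd.DataFrame({"cdr3_aa": ["CASSLGQAYEQYF", "CASSLGQAYEGYF"]})
        groups = motifs.build_groups(records, [])
        assert len(groups) == 1

    def test_singletons_discarded(self):
        records = pd.DataFrame({"cdr3_aa": ["CASSLGQAYEQYF", "CAWWWNPGELFFF"]})
        assert motifs.build_groups(records, []) == []

    def test_components_match_pairwise_oracle_with_planted_families(self):
        rng = np.random.default_rng(8)
        background = make_naive_reference(50, rng=rng, forbidden_motifs=["WQRS", "HKYM"])
        fam1 = ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF"]
        fam2 = ["CATHKYMNQPQHF", "CAWHKYMSYGYTF", "CVSHKYMAEKLFF"]
        cdr3s = background + fam1 + fam2
        hits = [
            motifs.MotifHit("WQRS", 3, len(cdr3s), 1e-5, 50, 1e-3),
            motifs.MotifHit("HKYM", 3, len(cdr3s), 1e-5, 50, 1e-3),
        ]
        groups = motifs.build_groups(pd.DataFrame({"cdr3_aa": cdr3s}), hits)
        got = {frozenset(g.member_cdr3s) for g in groups}
        assert got == self.oracle_components(cdr3s, ["WQRS", "HKYM"])
        assert frozenset(fam1) <= set().union(*got)

    def test_input_order_never_changes_components(self):
        rng = np.random.default_rng(9)
        cdr3s = make_naive_reference(40, rng=rng) + ["CASSWQRSTEAFF", "CANSWQRSGELFF"]
        hits = [motifs.MotifHit("WQRS", 2, len(cdr3s), 1e-5, 50, 1e-3)]
        base = {
            frozenset(g.member_cdr3s)
            for g in motifs.build_groups(pd.DataFrame({"cdr3_aa": cdr3s}), hits)
        }
        for _ in range(3):
            rng.shuffle(cdr3s)
            again = {
                frozenset(g.member_cdr3s)
                for g in motifs.build_groups(pd.DataFrame({"cdr3_aa": cdr3s}), hits)
            }
            assert again == base


def _group(cdr3s, v_genes, compartments=None, patients=None):
    n = len(cdr3s)
    members = pd.DataFrame(
        {
            "cdr3_aa": cdr3s,
            "v_gene": v_genes,
            "patient_id": patients or ["P1"] * n,
            "compartment": compartments or ["TUMOR"] * n,
        }
    )
    return motifs.SpecificityGroup("G0001", members, motifs=("WQRS",))


class TestClassifyViral:
    # cohort usage: TRBV9 rare (5%), background gene common
    usage = {"TRBV9": 10, "TRBV28": 95, "TRBV19": 95}
    viral_ref = pd.DataFrame(
        {
            "cdr3_aa": ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF"],
            "v_gene": ["TRBV9"] * 3,
            "epitope": ["CMV-pp65"] * 3,
        }
    )

    def test_three_viral_members_with_v_bias_is_viral(self):
        g = _group(
            ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF", "CATSWQRSNQPQF", "CAWWQRSGYTQYF"],
            ["TRBV9", "TRBV9", "TRBV9", "TRBV9", "TRBV28"],
        )
        motifs.classify_viral(g, self.viral_ref, self.usage)
        assert g.n_viral_members == 3
        assert g.v_gene_fisher_p < 0.05
        assert g.is_viral is True

    def test_two_viral_members_is_not_viral_despite_v_bias(self):
        g = _group(
            ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CATSWQRSNQPQF", "CAWWQRSGYTQYF"],
            ["TRBV9", "TRBV9", "TRBV9", "TRBV9"],
        )
        motifs.classify_viral(g, self.viral_ref, self.usage)
        assert g.n_viral_members == 2
        assert g.is_viral is False

    def test_three_viral_members_without_v_enrichment_is_not_viral(self):
        usage = {"TRBV9": 100, "TRBV28": 100, "TRBV19": 100}
        g = _group(
            ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF"],
            ["TRBV9", "TRBV28", "TRBV19"],
        )
        motifs.classify_viral(g, self.viral_ref, usage)
        assert g.n_viral_members == 3
        # verify the Fisher table truly is unremarkable via the reference test
        p = fisher_exact([[1, 2], [99, 198]], alternative="greater")[1]
        assert g.v_gene_fisher_p >= min(p, 1.0) - 1e-9
        assert g.is_viral is False

    def test_adding_a_viral_member_never_unsets_the_label(self):
        cdr3s = ["CASSWQRSTEAFF", "CANSWQRSGELFF", "CASRWQRSYEQYF", "CATSWQRSNQPQF"]
        vs = ["TRBV9"] * 4
        g = _group(cdr3s, vs)
        motifs.classify_viral(g, self.viral_ref, self.usage)
        assert g.is_viral is True
        ref_plus = pd.concat(
            [self.viral_ref, pd.DataFrame([{"cdr3_aa": "CATSWQRSNQPQF", "v_gene": "TRBV9",
                                            "epitope": "FLU-M1"}])],
            ignore_index=True,
        )
        g2 = _group(cdr3s, vs)
        motifs.classify_viral(g2, ref_plus, self.usage)
        assert g2.n_viral_members == g.n_viral_members + 1
        assert g2.is_viral is True


class TestLocations:
    def _classified(self, cdr3s, comps, is_viral):
        g = _group(cdr3s, ["TRBV9"] * len(cdr3s), compartments=comps)
        g.is_viral = is_viral
        return g

    def test_proportions_normalized_separately_and_fold(self):
        groups = []
        # viral: 1 tumor-only, 1 lung-only, 2 shared
        layout_v = [["TUMOR"], ["ADJACENT_LUNG"], ["TUMOR", "ADJACENT_LUNG"],
                    ["TUMOR", "ADJACENT_LUNG"]]
        # non-viral: 6 tumor-only, 2 lung-only, 2 shared
        layout_n = [["TUMOR"]] * 6 + [["ADJACENT_LUNG"]] * 2 + [["TUMOR", "ADJACENT_LUNG"]] * 2
        k = 0
        for layout, viral in ((layout_v, True), (layout_n, False)):
            for comps in layout:
                cdr3s = [f"CASS{'ACDEFGHIKLMNPQRSTVW'[k % 19]}{i}QRSTEAFF" for i in range(len(comps))]
                k += 1
                groups.append(self._classified(cdr3s, comps, viral))
        lp = motifs.location_proportions(groups, "P1")
        assert lp.viral == pytest.approx(
            {"TUMOR_ONLY": 0.25, "LUNG_ONLY": 0.25, "SHARED": 0.5}
        )
        assert lp.non_viral == pytest.approx(
            {"TUMOR_ONLY": 0.6, "LUNG_ONLY": 0.2, "SHARED": 0.2}
        )
        assert lp.fold_shared == pytest.approx(2.5)

    def test_all_viral_shared(self):
        groups = [
            self._classified(["CASSWQRSTEAFF", "CANSWQRSGELFF"], ["TUMOR", "ADJACENT_LUNG"], True),
            self._classified(["CATSWQRSNQPQF"], ["TUMOR"], False),
        ]
        lp = motifs.location_proportions(groups, "P1")
        assert lp.viral["SHARED"] == 1.0

    def test_equal_category_counts_give_fold_one(self):
        groups = [
            self._classified(["CASSWQRSTEAFF", "CANSWQRSGELFF"], ["TUMOR", "ADJACENT_LUNG"], True),
            self._classified(["CATSWQRSNQPQF"], ["TUMOR"], True),
            self._classified(["CAWSWQRSGYTQF", "CVSSWQRSAEKLF"], ["TUMOR", "ADJACENT_LUNG"], False),
            self._classified(["CASRWQRSYEQYF"], ["TUMOR"], False),
        ]
        lp = motifs.location_proportions(groups, "P1")
        assert lp.fold_shared == pytest.approx(1.0)

    def test_no_viral_groups_leaves_viral_vector_absent(self):
        groups = [self._classified(["CATSWQRSNQPQF"], ["TUMOR"], False)]
        lp = motifs.location_proportions(groups, "P1")
        assert lp.viral is None
        assert lp.fold_shared is None

    def test_unclassified_groups_rejected(self):
        g = _group(["CASSWQRSTEAFF"], ["TRBV9"])
        with pytest.raises(ValueError, match="classified"):
            motifs.location_proportions([g], "P1")
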