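import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlscan.annotate import (
    assign_state,
    assign_states,
    classify_region,
    classify_regions,
    compare_interaction_counts,
    count_interactions,
    count_interactions_table,
    fisher_enrichment,
    membership_flags,
)
from meqtlscan.exceptions import DomainError
from meqtlscan.simulate import gen_annotation


def fisher_two_sided_enumeration(a, b, c, d):
    """Independent oracle: sum of hypergeometric probabilities <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestRegionClassification:
    def test_upstream_of_plus_strand_tss_is_promoter(self, toy_genes):
        # TSS of GA at 10001 (+); 1400 bp upstream, outside all bodies
        assert classify_region("chr1", 10_001 - 1400, toy_genes) == "promoter"

    def test_body_plus_nearby_tss_is_ambiguous(self, toy_genes):
        # inside GB's body and 1000 bp from GB's TSS (60000, - strand)
        assert classify_region("chr1", 59_000, toy_genes) == "ambiguous"

    def test_far_from_genes_is_intergenic(self, toy_genes):
        assert classify_region("chr1", 1_000_000, toy_genes) == "intergenic"

    def test_inside_body_only_is_gene_body(self, toy_genes):
        assert classify_region("chr1", 20_000, toy_genes) == "gene_body"

    def test_promoter_window_boundary(self, toy_genes):
        assert classify_region("chr1", 10_001 - 1500, toy_genes) == "promoter"
        assert classify_region("chr1", 10_001 - 1501, toy_genes) == "intergenic"

    def test_strandless_gene_rejected(self, toy_genes):
        genes = toy_genes.copy()
        genes.loc[0, "strand"] = "."
        with pytest.raises(DomainError, match="GA"):
            classify_region("chr1", 5_000, genes)

    def test_classes_partition_probe_set(self, tiny_config):
        ann = gen_annotation(tiny_config)
        classes = classify_regions(tiny_config.probe_manifest(), ann.genes)
        assert len(classes) == len(tiny_config.probe_specs)
        assert classes.isin(["promoter", "gene_body", "intergenic", "ambiguous"]).all()
        assert classes.to_dict() == ann.true_region_class


class TestStateAssignment:
    seg = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [0, 1000, 5000],
        "end": [1000, 5000, 9000],
        "name": ["enhancer", "quiescent", "tss"],
    })

    def test_containing_interval_category(self):
        assert assign_state("chr1", 500, self.seg) == "enhancer"

    def test_half_open_boundary_convention(self):
        # 1-based position 1000 -> 0-based 999, last base of [0, 1000)
        assert assign_state("chr1", 1000, self.seg) == "enhancer"
        # 1-based 1001 -> 0-based 1000, first base of [1000, 5000)
        assert assign_state("chr1", 1001, self.seg) == "quiescent"

    def test_uncovered_position_flagged(self):
        assert assign_state("chr1", 20_000, self.seg) == "uncovered"
        assert assign_state("chr2", 500, self.seg) == "uncovered"

    def test_unmapped_state_label_rejected(self):
        with pytest.raises(DomainError, match="enhancer"):
            assign_state("chr1", 500, self.seg, state_to_category={"tss": "tss"})

    def test_state_mapping_applied(self):
        mapping = {"enhancer": "enh", "quiescent": "quies", "tss": "tss"}
        assert assign_state("chr1", 500, self.seg, mapping) == "enh"

    def test_invariant_to_interval_order(self):
        shuffled = self.seg.sample(frac=1.0, random_state=3)
        assert assign_state("chr1", 6000, shuffled) == "tss"

    def test_round_trip_with_generator(self, tiny_config):
        ann = gen_annotation(tiny_config)
        table = assign_states(tiny_config.probe_manifest(), ann.states)
        for (probe_id, tissue), truth in ann.true_states.items():
            assert table.loc[probe_id, tissue] == truth


class TestInteractions:
    def _anchors(self, rows):
        return pd.DataFrame(rows, columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"])

    def test_count_left_anchor_overlaps(self):
        pos = 5000  # 0-based 4999
        anchors = self._anchors([
            ("chr1", 4900, 5100, "chr1", 90_000, 91_000, "i1", 1),
            ("chr1", 4000, 5500, "chr1", 80_000, 81_000, "i2", 1),
            ("chr1", 4990, 5010, "chr1", 70_000, 71_000, "i3", 1),
            ("chr1", 9000, 9100, "chr1", 60_000, 61_000, "i4", 1),
        ])
        count, _ = count_interactions("chr1", pos, anchors)
        assert count == 3

    def test_partner_hitting_promoter_sets_flag(self, toy_genes):
        # GA TSS at 10001 (1-based) -> promoter window [8500, 11501) 0-based
        anchors = self._anchors([
            ("chr1", 4900, 5100, "chr1", 9_000, 9_500, "i1", 1),
        ])
        count, flag = count_interactions("chr1", 5000, anchors, toy_genes)
        assert count == 1 and flag is True
        far = self._anchors([("chr1", 4900, 5100, "chr1", 500_000, 500_500, "i1", 1)])
        _, flag2 = count_interactions("chr1", 5000, far, toy_genes)
        assert flag2 is False

    def test_malformed_pair_rejected_with_line(self):
        anchors = self._anchors([("chr1", 5100, 4900, "chr1", 9000, 9500, "i1", 1)])
        with pytest.raises(DomainError, match="line"):
            count_interactions("chr1", 5000, anchors)

    def test_generator_round_trip_counts(self, tiny_config):
        planted = {"cg01": 4, "cg02": 1, "cg03": 0}
        ann = gen_annotation(tiny_config, anchor_probe_counts=planted)
        table = count_interactions_table(
            tiny_config.probe_manifest(), ann.anchors, ann.genes)
        for pid, k in planted.items():
            assert table.loc[pid, "interaction_count"] == k
        for pid, flag in ann.true_promoter_interaction.items():
            assert bool(table.loc[pid, "promoter_interaction"]) == flag

    def test_membership_flags_match_generator(self, tiny_config):
        ann = gen_annotation(tiny_config)
        flags = membership_flags(tiny_config.probe_manifest(), ann.enhancers)
        assert set(flags.index[flags]) == ann.true_enhancer_members


class TestFisherEnrichment:
    def test_complete_separation_table(self):
        # [[5,0],[0,5]]: two-sided p = 2 / C(10,5)
        assoc = {f"a{i}" for i in range(5)}
        bg = {f"b{i}" for i in range(5)}
        res = fisher_enrichment(assoc, assoc | bg, {"cat": assoc})
        assert res["p"].iloc[0] == pytest.approx(2 / math.comb(10, 5), rel=1e-9)
        assert res["odds_ratio"].iloc[0] == np.inf

    def test_proportional_membership_is_null(self):
        assoc = {"a1", "a2", "b1", "b2"}
        tested = assoc | {"c1", "c2", "d1", "d2"}
        members = {"a1", "a2", "c1", "c2"}  # half of each group
        res = fisher_enrichment(assoc, tested, {"cat": members})
        assert res["odds_ratio"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self):
        assoc = {"a1", "a2"}
        tested = assoc | {"b1", "b2"}
        res = fisher_enrichment(assoc, tested, {"cat": set()})
        assert res["p"].iloc[0] == 1.0

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(31)
        from meqtlscan.annotate import _fisher_2x2

        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = _fisher_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(
                fisher_two_sided_enumeration(int(a), int(b), int(c), int(d)), abs=1e-9)

    def test_complement_symmetry(self):
        assoc = {f"a{i}" for i in range(10)}
        tested = assoc | {f"b{i}" for i in range(30)}
        members = {f"a{i}" for i in range(7)} | {f"b{i}" for i in range(12)}
        complement = tested - members
        r1 = fisher_enrichment(assoc, tested, {"cat": members})
        r2 = fisher_enrichment(assoc, tested, {"cat": complement})
        assert r1["p"].iloc[0] == pytest.approx(r2["p"].iloc[0], rel=1e-9)
        assert r1["odds_ratio"].iloc[0] == pytest.approx(
            1.0 / r2["odds_ratio"].iloc[0], rel=1e-9)

    def test_overlapping_background_variant(self):
        assoc = {f"a{i}" for i in range(5)}
        tested = assoc | {f"b{i}" for i in range(20)}
        members = assoc | {f"b{i}" for i in range(4)}
        res = fisher_enrichment(assoc, tested, {"cat": members}, background="overlapping")
        assert res["background_in"].iloc[0] == 9  # counts associated twice

    def test_empty_associated_set_rejected(self):
        with pytest.raises(DomainError):
            fisher_enrichment(set(), {"a"}, {"cat": {"a"}})


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        out = compare_interaction_counts([1, 2, 2, 3], [1, 2, 2, 3])
        assert out["p"] == 1.0

    def test_complete_separation_exact(self):
        out = compare_interaction_counts([1, 2, 3], [10, 11, 12])
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(2 / math.comb(6, 3))

    def test_exact_matches_independent_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(33)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            out = compare_interaction_counts(x, y)
            # oracle via rank sums over all labelings
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mid = n1 * (n1 + n2 + 1) / 2.0  # null mean of group-1 rank sum
            obs = abs(ranks[:n1].sum() - mid)
            hits = total = 0
            for combo in combinations(range(n1 + n2), n1):
                dev = abs(ranks[list(combo)].sum() - mid)
                total += 1
                hits += dev >= obs - 1e-12
            assert out["p"] == pytest.approx(hits / total, abs=1e-12)

    def test_large_sample_null_calibration(self):
        rng = np.random.default_rng(34)
        ps = [
            compare_interaction_counts(
                rng.poisson(3, 40), rng.poisson(3, 60))["p"]
            for _ in range(200)
        ]
        # p-values roughly uniform under the null
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            compare_interaction_counts([], [1, 2])
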