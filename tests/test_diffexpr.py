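"""Abundance arithmetic and the three-predicate DE filter."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roothair import diffexpr
from roothair.diffexpr import DeCriteria
from roothair.model import DiffRecord, DiffTable, GeneModel
from roothair.synthetic_data import SyntheticConfig, gen_compendium, gen_diff_table

pos_rpkm = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestRpkm:
    def test_zero_reads_zero_rpkm(self):
        assert diffexpr.compute_rpkm(0, 1000, 10_000_000) == 0.0

    def test_hand_arithmetic(self):
        # 1e9 * 1000 / (2000 * 1e7) = 50
        assert diffexpr.compute_rpkm(1000, 2000, 10_000_000) == pytest.approx(50.0)

    def test_scale_symmetry(self):
        a = diffexpr.compute_rpkm(500, 1500, 4_000_000)
        b = diffexpr.compute_rpkm(1000, 1500, 8_000_000)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("length,libsize", [(0, 1), (1, 0), (-5, 10)])
    def test_degenerate_denominators_rejected(self, length, libsize):
        with pytest.raises(ValueError):
            diffexpr.compute_rpkm(10, length, libsize)


class TestLog2FoldChange:
    def test_published_rh_enriched_gene(self):
        # proline-rich extensin-like gene: 282.55 RPKM in RH vs 0.145177 in NRH
        assert diffexpr.log2_fold_change(282.55, 0.145177) == pytest.approx(
            -10.9265, abs=1e-3
        )

    def test_silent_in_rh_is_positive_infinity(self):
        assert diffexpr.log2_fold_change(0, 1.08437) == math.inf

    def test_silent_in_nrh_is_negative_infinity(self):
        assert diffexpr.log2_fold_change(5.0, 0) == -math.inf

    def test_equal_abundance_is_zero(self):
        assert diffexpr.log2_fold_change(3.7, 3.7) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            diffexpr.log2_fold_change(0, 0)

    @given(a=pos_rpkm, b=pos_rpkm)
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert diffexpr.log2_fold_change(a, b) == pytest.approx(
            -diffexpr.log2_fold_change(b, a), rel=1e-9, abs=1e-12
        )


def _oracle_pass(rec, crit: DeCriteria) -> bool:
    """Independent literal evaluation of the three published predicates."""
    if crit.require_status_ok and rec.status != "OK":
        return False
    ok_q = rec.q_value < crit.q_max
    if rec.rpkm_rh == 0 or rec.rpkm_nrh == 0:
        fold = math.inf
    else:
        r = rec.rpkm_nrh / rec.rpkm_rh
        fold = max(r, 1.0 / r)
    ok_fold = fold > crit.min_fold
    ok_rpkm = rec.rpkm_rh > crit.min_rpkm_either or rec.rpkm_nrh > crit.min_rpkm_either
    return ok_q and ok_fold and ok_rpkm


def _random_table(n=1000, seed=11):
    rng = random.Random(seed)
    rows = []
    for i in range(n):
        rh = rng.choice([0.0, rng.uniform(0, 5), rng.lognormvariate(1, 1.5)])
        nrh = rng.choice([rng.uniform(0, 5), rng.lognormvariate(1, 1.5)])
        if rh == 0 and nrh == 0:
            nrh = 1.0
        rows.append(
            DiffRecord(
                f"g{i}",
                "",
                rh,
                nrh,
                rng.choice([rng.random(), 0.05, 0.049999]),
                rng.choice(["OK", "OK", "OK", "NOTEST"]),
            )
        )
    return DiffTable(rows)


class TestFilterDe:
    def test_matches_three_predicate_oracle_on_random_records(self):
        table = _random_table()
        parts = diffexpr.filter_de(table)
        passed = parts["up_in_rh"] | parts["up_in_nrh"]
        expected = {r.gene_id for r in table if _oracle_pass(r, DeCriteria())}
        assert passed == expected

    def test_direction_assignment(self):
        rec = DiffRecord("g", "", 10.0, 1.0, 0.01)
        parts = diffexpr.filter_de(DiffTable([rec]))
        assert parts == {"up_in_rh": {"g"}, "up_in_nrh": set()}

    def test_q_boundary_is_strict(self):
        rec = DiffRecord("g", "", 10.0, 1.0, 0.05)
        parts = diffexpr.filter_de(DiffTable([rec]))
        assert parts["up_in_rh"] == set()

    def test_rpkm_rule_excludes_low_abundance(self):
        rec = DiffRecord("g", "", 0.9, 0.4, 0.001)
        parts = diffexpr.filter_de(DiffTable([rec]))
        assert parts["up_in_rh"] == set() and parts["up_in_nrh"] == set()

    def test_partition_disjoint_union_and_order_independence(self):
        table = _random_table(seed=12)
        parts = diffexpr.filter_de(table)
        assert not (parts["up_in_rh"] & parts["up_in_nrh"])
        shuffled = list(table.rows)
        random.Random(0).shuffle(shuffled)
        parts2 = diffexpr.filter_de(DiffTable(shuffled))
        assert parts == parts2

    def test_recovers_planted_truth_exactly(self):
        cfg = SyntheticConfig(seed=5, n_genes=1000, rh_only_count=5)
        table, truth = gen_diff_table(cfg)
        parts = diffexpr.filter_de(table)
        assert parts["up_in_rh"] | parts["up_in_nrh"] == set(truth.de_genes)
        assert parts["up_in_rh"] == {g for g, e in truth.de_genes.items() if e < 0}


class TestRhOnly:
    def test_recovers_planted_rh_only_genes(self):
        cfg = SyntheticConfig(seed=5, n_genes=1000, rh_only_count=5)
        table, truth = gen_diff_table(cfg)
        assert diffexpr.rh_only_genes(table) == truth.rh_only_genes

    def test_tiny_nonzero_nrh_excluded(self):
        table = DiffTable([DiffRecord("g", "", 5.0, 1e-9, 0.01)])
        assert diffexpr.rh_only_genes(table) == set()

    def test_empty_table(self):
        assert diffexpr.rh_only_genes(DiffTable([])) == set()


class TestOverlapStats:
    def test_published_91_percent(self):
        a = {f"x{i}" for i in range(635)}
        b = set(list(a)[:580]) | {f"y{i}" for i in range(100)}
        assert diffexpr.overlap_stats(a, b)["pct_of_a"] == 91

    def test_identical_and_disjoint(self):
        s = {"a", "b"}
        assert diffexpr.overlap_stats(s, s)["pct_of_a"] == 100
        assert diffexpr.overlap_stats(s, {"c"})["pct_of_a"] == 0

    def test_empty_denominator_reported_missing(self):
        assert diffexpr.overlap_stats(set(), {"a"})["pct_of_a"] is None


def _locus(gene, chrom, start, end):
    return GeneModel(gene, gene + ".1", chrom, "+", [(start, end)], [(start, end)])


class TestNovelLoci:
    def test_any_overlap_rule(self):
        ref = [_locus("r1", "chr1", 100, 200)]
        inside = _locus("m1", "chr1", 120, 180)
        one_bp = _locus("m2", "chr1", 200, 250)
        clear = _locus("m3", "chr1", 300, 400)
        other_chrom = _locus("m4", "chr9", 100, 200)
        novel = diffexpr.flag_novel_loci([inside, one_bp, clear, other_chrom], ref)
        assert novel == {"m3", "m4"}

    def test_matches_brute_force_on_random_intervals(self):
        rng = random.Random(42)
        ref = [
            _locus(f"r{i}", rng.choice(["c1", "c2"]), s := rng.randint(1, 5000), s + rng.randint(1, 300))
            for i in range(40)
        ]
        merged = [
            _locus(f"m{i}", rng.choice(["c1", "c2"]), s := rng.randint(1, 5000), s + rng.randint(1, 300))
            for i in range(60)
        ]
        expected = {
            m.gene_id
            for m in merged
            if not any(
                r.chrom == m.chrom and r.span[0] <= m.span[1] and m.span[0] <= r.span[1]
                for r in ref
            )
        }
        assert diffexpr.flag_novel_loci(merged, ref) == expected


class TestExpressionClustering:
    def test_recovers_two_planted_modules(self):
        cfg = SyntheticConfig(
            seed=9, n_genes=40, n_arrays=300, module_specs=((12, 0.95), (8, 0.95))
        )
        matrix, truth = gen_compendium(cfg)
        members = sorted(set().union(*truth.true_modules))
        labels = diffexpr.cluster_expression_patterns(members, matrix, k=2)
        groups = {}
        for g, lbl in labels.items():
            groups.setdefault(lbl, set()).add(g)
        assert sorted(map(sorted, groups.values())) == sorted(
            map(sorted, truth.true_modules)
        )

    def test_k_equal_n_gives_singletons(self):
        cfg = SyntheticConfig(seed=9, n_genes=6, n_arrays=50, module_specs=())
        matrix, _ = gen_compendium(cfg)
        labels = diffexpr.cluster_expression_patterns(matrix.genes, matrix, k=6)
        assert len(set(labels.values())) == 6

    def test_duplicated_rows_co_cluster(self):
        import pandas as pd
        from roothair.model import CompendiumMatrix

        rng = random.Random(1)
        base = [rng.gauss(0, 1) for _ in range(30)]
        other = [rng.gauss(0, 1) for _ in range(30)]
        third = [rng.gauss(0, 1) for _ in range(30)]
        df = pd.DataFrame(
            [base, base, other, third],
            index=["a", "a2", "b", "c"],
            columns=[f"x{i}" for i in range(30)],
        )
        labels = diffexpr.cluster_expression_patterns(
            ["a", "a2", "b", "c"], CompendiumMatrix(df), k=3
        )
        assert labels["a"] == labels["a2"]

    def test_constant_gene_excluded_with_warning(self):
        import pandas as pd
        from roothair.model import CompendiumMatrix

        rng = random.Random(2)
        df = pd.DataFrame(
            [[1.0] * 20, [rng.gauss(0, 1) for _ in range(20)], [rng.gauss(0, 1) for _ in range(20)]],
            index=["flat", "a", "b"],
            columns=[f"x{i}" for i in range(20)],
        )
        with pytest.warns(UserWarning, match="constant"):
            labels = diffexpr.cluster_expression_patterns(
                ["flat", "a", "b"], CompendiumMatrix(df), k=2
            )
        assert "flat" not in labels
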