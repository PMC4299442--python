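"""Family detection tables, enrichment tests, set overlaps, tandem arrays."""

import numpy as np
import pandas as pd
import pytest

from florastage import (
    SimulationConfig,
    ValidationError,
    detect_tandem_arrays,
    family_detection_table,
    family_enrichment,
    set_overlap_test,
    simulate_all,
    stage_specific,
)

from conftest import hypergeom_two_sided_oracle


def _annotation_with_families(sizes: dict[str, int], n_extra: int = 0):
    rows = []
    ids = []
    i = 0
    for fam, size in sizes.items():
        for _ in range(size):
            ids.append(f"g{i}")
            rows.append(fam)
            i += 1
    for _ in range(n_extra):
        ids.append(f"g{i}")
        rows.append("")
        i += 1
    return pd.DataFrame(
        {
            "length_bp": 1000,
            "chromosome": "Chr1",
            "start": np.arange(len(ids)) * 2000 + 1,
            "end": np.arange(len(ids)) * 2000 + 1000,
            "gene_type": "coding",
            "families": rows,
            "tf_family": "",
        },
        index=pd.Index(ids, name="gene_id"),
    )


class TestDetectionTable:
    @pytest.mark.parametrize(
        "total,in_set,expected",
        [(167, 108, 0.65), (26, 26, 1.00), (115, 71, 0.62), (391, 154, 0.39)],
    )
    def test_percent_column(self, total, in_set, expected):
        ann = _annotation_with_families({"Fam": total})
        gene_set = {f"g{i}" for i in range(in_set)}
        table = family_detection_table(gene_set, ann)
        row = table[table["family"] == "Fam"].iloc[0]
        assert row["total"] == total and row["in_set"] == in_set
        assert row["percent"] == pytest.approx(expected)

    def test_absent_family_zero_percent(self):
        ann = _annotation_with_families({"A": 5, "B": 5})
        table = family_detection_table({"g0", "g1"}, ann)
        b = table[table["family"] == "B"].iloc[0]
        assert b["in_set"] == 0 and b["percent"] == 0.0

    def test_total_independent_of_gene_set(self):
        ann = _annotation_with_families({"A": 7, "B": 3})
        t1 = family_detection_table(set(), ann).set_index("family")["total"]
        t2 = family_detection_table({"g0"}, ann).set_index("family")["total"]
        pd.testing.assert_series_equal(t1.sort_index(), t2.sort_index())

    def test_filters_and_sorting(self):
        ann = _annotation_with_families({"A": 10, "B": 100, "C": 4})
        gene_set = {f"g{i}" for i in range(8)}  # 8 of A's 10
        table = family_detection_table(gene_set, ann, min_percent=0.0, min_total=5)
        assert "C" not in set(table["family"])
        assert list(table["family"])[0] == "A"  # highest percent first

    def test_multi_family_gene_counts_in_each(self):
        ann = _annotation_with_families({"A": 2})
        ann.loc["g0", "families"] = "A;B"
        table = family_detection_table({"g0"}, ann).set_index("family")
        assert table.loc["A", "in_set"] == 1
        assert table.loc["B", "in_set"] == 1


class TestFamilyEnrichment:
    def test_proportional_family_not_significant(self):
        ann = _annotation_with_families({"A": 10}, n_extra=10)
        universe = set(ann.index)
        gene_set = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        table = family_enrichment(gene_set, universe, ann)
        assert table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        ann = _annotation_with_families({"A": 5}, n_extra=15)
        universe = set(ann.index)
        gene_set = {f"g{i}" for i in range(10)}  # all 5 members inside
        table = family_enrichment(gene_set, universe, ann).set_index("family")
        oracle = hypergeom_two_sided_oracle(5, 5, 0, 10)
        assert table.loc["A", "p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_random_margins_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            total = int(rng.integers(2, 40))
            extra = int(rng.integers(10, 60))
            ann = _annotation_with_families({"A": total}, n_extra=extra)
            universe = set(ann.index)
            size = int(rng.integers(1, total + extra))
            gene_set = set(rng.choice(sorted(universe), size=size, replace=False))
            in_set = sum(1 for g in ann.index[ann["families"] == "A"] if g in gene_set)
            table = family_enrichment(gene_set, universe, ann).set_index("family")
            oracle = hypergeom_two_sided_oracle(
                in_set, size - in_set, total - in_set,
                total + extra - size - total + in_set,
            )
            assert table.loc["A", "p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_set_outside_universe_rejected(self):
        ann = _annotation_with_families({"A": 4})
        with pytest.raises(ValidationError):
            family_enrichment({"zz"}, set(ann.index), ann)

    def test_planted_family_ranks_first(self):
        """A family planted into one stage tops the enrichment of that
        stage's specific gene set."""
        cfg = SimulationConfig(
            n_genes=800, family_catalog={"DUF1216": 20, "F-box": 60},
            family_specific_bias=1.0, designated_family="DUF1216",
            designated_stage="F12", specific_fraction=0.02, seed=23,
        )
        ann, truth, counts, _ = simulate_all(cfg)
        spec_set = stage_specific(counts, ann, "F12", fold=4.0)
        table = family_enrichment(spec_set, set(ann.index), ann)
        assert table.iloc[0]["family"] == "DUF1216"
        assert table.iloc[0]["p_value"] < 1e-6


class TestSetOverlap:
    def test_disjoint_sets(self):
        overlap, p = set_overlap_test({"a", "b"}, {"c", "d"}, universe_size=1000)
        assert overlap == 0
        assert 0 <= p <= 1

    def test_degenerate_full_universe(self):
        s = {f"g{i}" for i in range(10)}
        overlap, p = set_overlap_test(s, s, universe_size=10)
        assert overlap == 10 and p == pytest.approx(1.0)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValidationError):
            set_overlap_test({"a", "b"}, {"c"}, universe_size=2)

    def test_floral_target_margins_match_oracle(self):
        """The DEG-vs-ChIP-target overlap margins: module P equals the
        enumeration oracle at those margins (no printed-value assertion, the
        universe behind the printed P is unstated)."""
        a, b, universe, overlap = 13628, 4505, 27416, 2506
        set_a = {f"g{i}" for i in range(a)}
        set_b = {f"g{i}" for i in range(a - overlap, a - overlap + b)}
        got_overlap, p = set_overlap_test(set_a, set_b, universe)
        assert got_overlap == overlap
        oracle = hypergeom_two_sided_oracle(
            overlap, a - overlap, b - overlap, universe - a - b + overlap
        )
        assert p == pytest.approx(oracle, rel=1e-6)


class TestTandemArrays:
    def test_adjacent_run_detected(self):
        ann = _annotation_with_families({"X": 3})
        arrays = detect_tandem_arrays(ann, "X")
        assert len(arrays) == 1
        assert arrays[0].members == ["g0", "g1", "g2"]
        assert arrays[0].span == (1, 5000)

    def test_gap_rule_blocks_distant_members(self):
        ann = _annotation_with_families({"X": 2}, n_extra=2)
        # place the two X genes at ranks 1 and 4 (two intervening non-family)
        ann.loc[["g0", "g1", "g2", "g3"], "start"] = [1, 6001, 2001, 4001]
        ann.loc[["g0", "g1", "g2", "g3"], "end"] = [1000, 7000, 3000, 5000]
        assert detect_tandem_arrays(ann, "X", max_intervening=1) == []
        assert len(detect_tandem_arrays(ann, "X", max_intervening=2)) == 1

    def test_matches_scan_oracle_on_random_orders(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            n = 30
            fams = rng.choice(["X", ""], size=n, p=[0.4, 0.6])
            ann = _annotation_with_families({}, n_extra=n)
            ann["families"] = fams
            arrays = detect_tandem_arrays(ann, "X", max_intervening=1)
            # oracle: walk the sorted list, counting gaps
            ordered = ann.sort_values("start")
            runs, run, gap = [], [], 0
            for g, row in ordered.iterrows():
                if row["families"] == "X":
                    if run and gap <= 1:
                        run.append(g)
                    else:
                        if len(run) >= 2:
                            runs.append(run)
                        run = [g]
                    gap = 0
                else:
                    gap += 1
            if len(run) >= 2:
                runs.append(run)
            assert [a.members for a in arrays] == runs

    def test_arrays_disjoint_and_maximal(self, small_sim):
        _, ann, _, _, _ = small_sim
        for fam in ("DUF1216", "F-box", "PPR"):
            arrays = detect_tandem_arrays(ann, fam, max_intervening=1)
            seen: set[str] = set()
            for arr in arrays:
                assert arr.size >= 2
                assert not (seen & set(arr.members))
                seen |= set(arr.members)
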