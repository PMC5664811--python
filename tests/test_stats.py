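import numpy as np
import pytest

from panelclass.models import Cohort
from panelclass.stats import (
    alteration_frequencies,
    associate_groups,
    fisher_two_tailed,
    mann_whitney,
    percentage,
    round_half_away,
)

from .conftest import make_tumor
from .oracles import fisher_two_sided_enum, mann_whitney_exact_enum


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(110, 207, 53.1), (33, 207, 15.9), (29, 207, 14.0), (25, 207, 12.1)],
    )
    def test_frequency_style(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_away_from_zero(self):
        assert round_half_away(0.15, 1) == 0.2
        assert round_half_away(-0.15, 1) == -0.2
        assert round_half_away(57.5, 0) == 58.0


class TestFrequencies:
    def test_counts_each_tumor_once_per_gene_class(self, small_panel):
        # duplicate TP53 variants in one tumor must count once
        t = make_tumor("T1", mutated=["TP53", "TP53"])
        cohort = Cohort(panel=small_panel, tumors=[t, make_tumor("T2")])
        freq = alteration_frequencies(cohort)
        row = freq[(freq.gene == "TP53") & (freq.alteration_class == "mutation")]
        assert row["n_altered"].item() == 1
        assert row["frequency_pct"].item() == 50.0

    def test_never_altered_gene_absent(self, small_cohort):
        freq = alteration_frequencies(small_cohort)
        assert "MYC" not in set(freq.gene)

    def test_matches_per_gene_recount(self, small_panel):
        """Frequencies agree with an independent per-gene recount."""
        rng = np.random.default_rng(12)
        genes = sorted(small_panel.genes)
        tumors = []
        for i in range(40):
            mutated = [g for g in genes if rng.random() < 0.2]
            gained = [g for g in genes if rng.random() < 0.1]
            tumors.append(make_tumor(f"T{i}", mutated=mutated, gained=gained))
        cohort = Cohort(panel=small_panel, tumors=tumors)
        freq = alteration_frequencies(cohort)
        for _, row in freq.iterrows():
            if row.alteration_class == "mutation":
                n = sum(any(v.gene == row.gene for v in t.variants) for t in tumors)
            elif row.alteration_class == "AMP":
                n = sum(any(c.gene == row.gene and c.call == "gain" for c in t.cnvs) for t in tumors)
            else:
                n = sum(any(c.gene == row.gene and c.call == "loss" for c in t.cnvs) for t in tumors)
            assert row.n_altered == n
            assert row.frequency_pct == percentage(n, 40)

    def test_ranked_descending_within_class(self, small_cohort):
        freq = alteration_frequencies(small_cohort)
        for cls, grp in freq.groupby("alteration_class"):
            assert list(grp["rank"]) == list(range(1, len(grp) + 1))
            assert (grp["frequency_pct"].diff().dropna() <= 0).all()


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed([[1, 1], [1, 1]]) == 1.0

    def test_extreme_table_enumeration(self):
        # support x in 0..5; only the two extreme tables are as improbable
        assert fisher_two_tailed([[5, 0], [0, 5]]) == pytest.approx(
            fisher_two_sided_enum([[5, 0], [0, 5]]), rel=1e-7
        )
        assert fisher_two_tailed([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-7)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed([[1, -1], [0, 2]])

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            cells = rng.multinomial(int(rng.integers(1, 31)), [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            assert fisher_two_tailed(table) == pytest.approx(
                fisher_two_sided_enum(table), rel=1e-7
            )


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = [1.0, 3.0, 5.0]
        assert mann_whitney(x, x) == 1.0
        assert mann_whitney([1, 3, 5], [2, 4, 6]) == pytest.approx(
            mann_whitney_exact_enum([1, 3, 5], [2, 4, 6]), rel=1e-9
        )

    def test_complete_separation_minimal_p(self):
        x = [6.0, 7.0, 8.0, 9.0, 10.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mann_whitney(x, y) == pytest.approx(2 / 252, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_branch_matches_rank_split_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            nx, ny = int(rng.integers(2, 7)), int(rng.integers(2, 9))
            pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
            x, y = list(pooled[:nx]), list(pooled[nx:])
            assert mann_whitney(x, y) == pytest.approx(
                mann_whitney_exact_enum(x, y), rel=1e-9
            )

    def test_invariant_to_within_sample_order(self):
        x, y = [3.0, 1.0, 9.0], [2.0, 8.0, 4.0, 6.0]
        assert mann_whitney(x, y) == mann_whitney(sorted(x), sorted(y, reverse=True))


class TestAssociations:
    def test_identical_distribution_p_one(self):
        grouping = {f"T{i}": "a" if i < 10 else "b" for i in range(20)}
        feature = {f"T{i}": "diffuse" if i % 2 else "intestinal" for i in range(20)}
        out = associate_groups(grouping, categorical={"lauren": feature})
        assert (out["p_value"] == 1.0).all()

    def test_planted_enrichment_detected(self):
        """Group 90% diffuse vs background 10% -> significant Fisher p."""
        grouping = {f"T{i}": "g" if i < 20 else "rest" for i in range(120)}
        feature = {}
        for i in range(120):
            if i < 20:
                feature[f"T{i}"] = "diffuse" if i < 18 else "intestinal"
            else:
                feature[f"T{i}"] = "diffuse" if i % 10 == 0 else "intestinal"
        out = associate_groups(grouping, categorical={"lauren": feature})
        row = out[(out.group == "g") & (out.level == "diffuse")]
        assert row["p_value"].item() < 0.05
        assert row["significant"].item()
        assert row["effect_direction"].item() == "enriched"
        # independent oracle on the constructed 2x2 table
        assert row["p_value"].item() == pytest.approx(
            fisher_two_sided_enum([[18, 2], [10, 90]]), rel=1e-7
        )

    def test_shape_groups_by_features(self):
        grouping = {f"T{i}": f"g{i % 3}" for i in range(30)}
        cat = {"lauren": {f"T{i}": "diffuse" if i % 2 else "intestinal" for i in range(30)}}
        cont = {"age": {f"T{i}": 50.0 + i for i in range(30)}}
        out = associate_groups(grouping, categorical=cat, continuous=cont)
        # 3 groups x (2 lauren levels + 1 continuous feature)
        assert len(out) == 3 * 3
        assert {"p_adjusted_bh", "significant"} <= set(out.columns)

    def test_reference_set_restriction(self):
        grouping = {f"H{i}": "hyper" for i in range(5)}
        grouping.update({f"N{i}": "non" for i in range(15)})
        feature = {t: ("diffuse" if t.startswith("H") else "intestinal") for t in grouping}
        reference = [t for t in grouping if t.startswith("N")]
        out = associate_groups(grouping, categorical={"lauren": feature},
                               reference_ids=reference)
        row = out[(out.group == "hyper") & (out.level == "diffuse")]
        assert row["p_value"].item() == pytest.approx(
            fisher_two_sided_enum([[5, 0], [0, 15]]), rel=1e-7
        )
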