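import numpy as np
import pandas as pd
import pytest

from taupattern.errors import AnalysisError, ConfigError
from taupattern.proteome import (
    ProteinHitTable,
    annotation_ratio,
    combine_non_groups,
    filter_hits,
    subtract_controls,
    venn_partition,
)
from taupattern.simulate import ProteomeSimConfig, generate_proteome


def table(group, proteins, peptides=None, scores=None):
    n = len(proteins)
    return ProteinHitTable(
        group,
        pd.DataFrame(
            {
                "protein": proteins,
                "n_unique_peptides": peptides if peptides is not None else [2] * n,
                "ion_score": scores if scores is not None else [50.0] * n,
            }
        ),
    )


class TestFilterHits:
    @pytest.mark.parametrize(
        "peptides, score, kept",
        [(1, 31.0, True), (1, 30.0, False), (0, 99.0, False), (2, 30.01, True)],
    )
    def test_peptide_and_strict_ion_score_thresholds(self, peptides, score, kept):
        t = filter_hits(table("Tg_Veh", ["P1"], [peptides], [score]))
        assert (len(t) == 1) is kept

    def test_idempotent_and_commutes_with_subtraction(self):
        t = table("Tg_Veh", ["A", "B", "C", "D"], [1, 0, 3, 2], [50, 60, 20, 45])
        igg = [table("IgG", ["A"])]
        once = filter_hits(t)
        assert filter_hits(once).proteins == once.proteins
        ab = subtract_controls([filter_hits(t)], igg)[0]
        ba = filter_hits(subtract_controls([t], igg)[0])
        assert ab.proteins == ba.proteins == {"D"}


class TestSubtractControls:
    def test_matching_proteins_removed_everywhere(self):
        tables = [table("Non_Veh", ["A", "B"]), table("Tg_Veh", ["A", "C"])]
        out = subtract_controls(tables, [table("IgG", ["A"])])
        assert [t.proteins for t in out] == [{"B"}, {"C"}]

    def test_empty_igg_is_identity(self):
        tables = [table("Non_Veh", ["A", "B"])]
        out = subtract_controls(tables, [table("IgG", [])])
        assert out[0].proteins == {"A", "B"}

    def test_igg_superset_empties_everything(self):
        tables = [table("Non_Veh", ["A"]), table("Tg_Dox", ["B"])]
        out = subtract_controls(tables, [table("IgG1", ["A", "B"]), table("IgG2", ["C"])])
        assert all(t.proteins == set() for t in out)


class TestCombineNonGroups:
    def test_union_of_non_tables(self):
        tables = [
            table("Non_Veh", ["A"]),
            table("Non_Dox", ["B"]),
            table("Tg_Veh", ["C"]),
            table("Tg_Dox", ["D"]),
        ]
        out = combine_non_groups(tables)
        assert [t.group for t in out] == ["Non", "Tg_Veh", "Tg_Dox"]
        assert out[0].proteins == {"A", "B"}

    def test_identical_tables_union_is_idempotent(self):
        tables = [table("Non_Veh", ["A", "B"]), table("Non_Dox", ["A", "B"])]
        assert combine_non_groups(tables)[0].proteins == {"A", "B"}

    def test_empty_non_dox_returns_non_veh(self):
        tables = [table("Non_Veh", ["A"]), table("Non_Dox", [])]
        assert combine_non_groups(tables)[0].proteins == {"A"}

    def test_missing_non_table_is_error(self):
        with pytest.raises(AnalysisError, match="missing"):
            combine_non_groups([table("Non_Veh", ["A"]), table("Tg_Veh", ["B"])])


def bitmask_oracle(sets):
    """Brute-force region assignment by per-protein membership bitmask."""
    regions = {}
    for protein in set().union(*sets):
        key = "".join("1" if protein in s else "0" for s in sets)
        regions.setdefault(key, set()).add(protein)
    return regions


class TestVennPartition:
    def test_two_set_example(self):
        regions = venn_partition([table("a", ["A", "B"]), table("b", ["B", "C"])])
        assert regions["10"] == {"A"}
        assert regions["01"] == {"C"}
        assert regions["11"] == {"B"}

    def test_identical_sets_fill_full_intersection(self):
        regions = venn_partition([table(g, ["A", "B"]) for g in ("x", "y", "z")])
        assert regions["111"] == {"A", "B"}
        assert all(not v for key, v in regions.items() if key != "111")

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_bitmask_oracle_on_random_sets(self, rng, k):
        universe = [f"P{i}" for i in range(60)]
        sets = [set(rng.choice(universe, size=25, replace=False)) for _ in range(k)]
        tables = [table(f"g{i}", sorted(s)) for i, s in enumerate(sets)]
        regions = venn_partition(tables)
        oracle = bitmask_oracle(sets)
        for key, members in regions.items():
            assert members == oracle.get(key, set())

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_regions_disjoint_and_conservative(self, rng, k):
        universe = [f"P{i}" for i in range(80)]
        sets = [set(rng.choice(universe, size=rng.integers(5, 50), replace=False)) for _ in range(k)]
        tables = [table(f"g{i}", sorted(s)) for i, s in enumerate(sets)]
        regions = venn_partition(tables)
        all_members = [p for members in regions.values() for p in members]
        assert len(all_members) == len(set(all_members))  # disjoint
        assert set(all_members) == set().union(*sets)  # conservative

    def test_wrong_arity_rejected(self):
        with pytest.raises(ConfigError):
            venn_partition([table("a", ["A"])])


class TestGeneratorRecovery:
    def test_group_unique_planted_proteins_recovered_by_venn(self):
        # filter-noise fractions 0 so post-filter presence equals planted presence
        config = ProteomeSimConfig(
            n_proteins=400, signal_presence=0.25,
            low_score_fraction=0.0, zero_peptide_fraction=0.0,
        )
        tables, truth = generate_proteome(config, seed=17)
        samples = [t for t in tables if not t.group.startswith("IgG")]
        iggs = [t for t in tables if t.group.startswith("IgG")]
        cleaned = subtract_controls([filter_hits(t) for t in samples], iggs)
        regions = venn_partition(cleaned)
        igg_proteins = set().union(*(t.proteins for t in iggs))
        for i, t in enumerate(cleaned):
            key = "".join("1" if j == i else "0" for j in range(len(cleaned)))
            # every protein reported unique to this group truly was planted
            # there (and nowhere else), post filters and IgG subtraction
            others = [s.group for j, s in enumerate(samples) if j != i]
            for protein in regions[key]:
                assert truth.loc[protein, t.group]
                assert not truth.loc[protein, others].any()
                assert protein not in igg_proteins


class TestAnnotationRatio:
    def records(self):
        rows = []
        for i in range(4):
            rows.append((f"t{i}", "Non", "translation_ribosome", 0.01))
        rows.append(("t0", "Tg_Veh", "translation_ribosome", 0.05))
        rows.append(("tx", "Tg_Veh", "translation_ribosome", 0.1))  # at threshold: excluded
        rows.append(("ty", "Tg_Dox", "synaptic", 0.02))
        return pd.DataFrame(rows, columns=["term", "group", "category", "adjusted_p"])

    def test_ratio_against_reference_counts(self):
        ratios = annotation_ratio(self.records(), reference_group="Non")
        assert ratios.loc["translation_ribosome", "Tg_Veh"] == pytest.approx(0.25)
        assert ratios.loc["translation_ribosome", "Non"] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        ratios = annotation_ratio(self.records())
        # the adjusted_p == 0.1 term must not count: 1/4, not 2/4
        assert ratios.loc["translation_ribosome", "Tg_Veh"] == pytest.approx(0.25)

    def test_reference_is_identically_one(self):
        ratios = annotation_ratio(self.records())
        observed = ratios["Non"].dropna()
        assert (observed == 1.0).all()

    def test_zero_reference_category_is_undefined(self):
        ratios = annotation_ratio(self.records())
        assert np.isnan(ratios.loc["synaptic", "Non"])
        assert np.isnan(ratios.loc["synaptic", "Tg_Dox"])

    def test_unknown_category_rejected(self):
        records = self.records()
        records.loc[0, "category"] = "mystery"
        with pytest.raises(ConfigError, match="unknown"):
            annotation_ratio(records)

    def test_missing_reference_group_rejected(self):
        with pytest.raises(AnalysisError):
            annotation_ratio(self.records(), reference_group="Absent")
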