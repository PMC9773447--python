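import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dsbfold.disulfides import (
    BondKind,
    Category,
    DisulfideRecord,
    ProteinDisulfideProfile,
    build_profiles,
    classify_bond,
    classify_difficulty,
    confidence_filter,
    count_protein_disulfides,
    folding_demand,
    max_potential_disulfides,
    merge_bond_sources,
    periplasmic_subset,
    read_dsb_sheet,
)
from dsbfold.proteome import QuantitativeProteome


def rec(pid, a, b, kind=BondKind.INTRAMOLECULAR, sources=("s1",)):
    return DisulfideRecord(pid, a, b, kind, frozenset(sources))


class TestMerge:
    def test_identical_records_unify_sources(self, bond_frame):
        frame = bond_frame([("P1", 10, 50)])
        merged = merge_bond_sources({"a": frame, "b": frame, "c": frame})
        assert len(merged) == 1
        assert merged[0].sources == {"a", "b", "c"}

    def test_distinct_pairs_stay_distinct(self, bond_frame):
        merged = merge_bond_sources({"a": bond_frame([("P1", 10, 50), ("P1", 10, 90)])})
        assert len(merged) == 2

    def test_set_algebra_oracle(self, bond_frame):
        # three sources with known overlap structure
        rng = np.random.default_rng(42)
        universe = [(f"P{i}", 10 * j, 10 * j + 5) for i in range(10) for j in range(1, 4)]
        tables = {}
        membership = {}
        for source in ("s1", "s2", "s3"):
            picks = [b for b in universe if rng.random() < 0.6]
            tables[source] = bond_frame(picks)
            membership[source] = set(picks)
        merged = merge_bond_sources(tables)
        union = membership["s1"] | membership["s2"] | membership["s3"]
        assert len(merged) == len(union)
        two_plus = {
            b
            for b in union
            if sum(b in membership[s] for s in membership) >= 2
        }
        assert len(confidence_filter(merged, 2)) == len(two_plus)

    def test_merge_order_independent(self, bond_frame):
        frames = {
            "a": bond_frame([("P1", 10, 50), ("P2", 5, 9)]),
            "b": bond_frame([("P1", 50, 10)]),  # reversed residue order
            "c": bond_frame([("P3", 1, 2)]),
        }
        forward = merge_bond_sources(list(frames.items()))
        for perm in itertools.permutations(frames.items()):
            assert merge_bond_sources(list(perm)) == forward

    def test_malformed_rows_skipped(self, bond_frame, caplog):
        frame = pd.DataFrame(
            {"protein_id": ["P1", "P2"], "cys_a": [10, "junk"], "cys_b": [50, 60]}
        )
        merged = merge_bond_sources({"a": frame})
        assert [r.protein_id for r in merged] == ["P1"]

    def test_self_and_inter_markers(self, bond_frame):
        frame = pd.DataFrame(
            {
                "protein_id": ["P1", "P2"],
                "cys_a": [10, 20],
                "cys_b": ["SELF", "OTHER-PROTEIN"],
            }
        )
        merged = merge_bond_sources({"a": frame})
        kinds = {r.protein_id: r.kind for r in merged}
        assert kinds == {"P1": BondKind.SELF_PAIR, "P2": BondKind.INTERMOLECULAR}


class TestCounting:
    def test_alternative_partners_collapse(self):
        assert count_protein_disulfides([rec("P1", 10, 50), rec("P1", 10, 90)]) == 1.0

    def test_self_pairing_counts_half(self):
        assert count_protein_disulfides([rec("P1", 10, 10, BondKind.SELF_PAIR)]) == 0.5

    def test_disjoint_pairs(self):
        assert count_protein_disulfides([rec("P1", 10, 50), rec("P1", 60, 90)]) == 2.0

    def test_intermolecular_excluded(self):
        assert count_protein_disulfides([rec("P1", 10, None, BondKind.INTERMOLECULAR)]) == 0.0

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            count_protein_disulfides([rec("P1", 10, 50), rec("P2", 10, 50)])

    @pytest.mark.parametrize(
        "sequence,expected",
        [("CCACCC", 2), ("ACDEF", 0), ("CCCC", 2), ("C" * 7, 3)],
    )
    def test_max_potential(self, sequence, expected):
        assert max_potential_disulfides(sequence) == expected

    def test_invalid_sequence(self):
        with pytest.raises(ValueError):
            max_potential_disulfides("CXZ1")


class TestClassification:
    @pytest.mark.parametrize(
        "cysteines,bond,expected",
        [
            ((10, 50), (10, 50), Category.CAT1),
            ((10, 50, 90), (10, 50), Category.CAT2),
            ((10, 50, 90), (10, 90), Category.CAT3),
            ((10, 50, 90, 120), (50, 120), Category.CAT3),
        ],
    )
    def test_bond_categories(self, cysteines, bond, expected):
        assert classify_bond(rec("P1", *bond), cysteines) is expected

    def test_intermolecular_is_cat4(self):
        assert classify_bond(rec("P1", 10, None, BondKind.INTERMOLECULAR), (10,)) is Category.CAT4
        assert classify_bond(rec("P1", 10, 10, BondKind.SELF_PAIR), (10,)) is Category.CAT4

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            classify_bond(rec("P1", 10, 50), (10, 60, 90))

    def test_every_bond_in_exactly_one_category(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            cys = tuple(sorted(rng.choice(np.arange(1, 100), n, replace=False)))
            i, j = sorted(rng.choice(n, 2, replace=False))
            cat = classify_bond(rec("P", int(cys[i]), int(cys[j])), cys)
            assert cat in (Category.CAT1, Category.CAT2, Category.CAT3)
            # partition: the assignment rules are mutually exclusive
            if n == 2:
                assert cat is Category.CAT1
            elif j - i == 1:
                assert cat is Category.CAT2
            else:
                assert cat is Category.CAT3

    def test_protein_takes_hardest_category(self):
        profile = ProteinDisulfideProfile(
            "P1", (10, 50, 90, 120), [rec("P1", 10, 50), rec("P1", 60, 120, sources=("s",))]
        )
        # second bond invalid residue -> use valid ones only
        profile = ProteinDisulfideProfile(
            "P1", (10, 50, 90, 120), [rec("P1", 10, 50), rec("P1", 50, 120)]
        )
        assert classify_difficulty(profile) is Category.CAT3


class TestFiltering:
    def test_periplasmic_filter(self):
        profiles = [
            ProteinDisulfideProfile("P1", (1, 5), [rec("P1", 1, 5)]),
            ProteinDisulfideProfile("P2", (1, 5), [rec("P2", 1, 5)]),
        ]
        table = {"P1": "secreted", "P2": "cytoplasmic"}
        kept = periplasmic_subset(profiles, table)
        assert [p.protein_id for p in kept] == ["P1"]
        assert kept[0].periplasmic

    def test_all_secreted_is_identity(self):
        profiles = [
            ProteinDisulfideProfile(f"P{i}", (1, 5), [rec(f"P{i}", 1, 5)]) for i in range(4)
        ]
        table = {p.protein_id: "secreted outer membrane" for p in profiles}
        assert len(periplasmic_subset(profiles, table)) == 4

    def test_brute_force_filter_oracle(self):
        rng = np.random.default_rng(3)
        labels = ["secreted", "secreted outer membrane", "cytoplasmic", "membrane"]
        profiles, table = [], {}
        for i in range(60):
            pid = f"P{i}"
            profiles.append(ProteinDisulfideProfile(pid, (1, 5), [rec(pid, 1, 5)]))
            table[pid] = labels[rng.integers(0, 4)]
        expected = sum(table[p] in ("secreted", "secreted outer membrane") for p in table)
        assert len(periplasmic_subset(profiles, table)) == expected

    def test_missing_location_policy(self):
        profiles = [ProteinDisulfideProfile("P1", (1, 5), [rec("P1", 1, 5)])]
        assert periplasmic_subset(profiles, {}) == []
        assert len(periplasmic_subset(profiles, {}, missing="keep")) == 1

    def test_confidence_filter_nesting(self):
        records = [
            rec("P1", 1, 5, sources=("a",)),
            rec("P2", 1, 5, sources=("a", "b")),
            rec("P3", 1, 5, sources=("a", "b", "c")),
        ]
        assert confidence_filter(records, 1) == records
        assert len(confidence_filter(records, 2)) == 2
        for k in (1, 2, 3):
            assert set(r.protein_id for r in confidence_filter(records, k + 1)) <= set(
                r.protein_id for r in confidence_filter(records, k)
            )


class TestDemand:
    def _proteome(self, abundances):
        return QuantitativeProteome("cond", pd.Series(abundances), growth_rate=0.5)

    def test_single_protein_demand(self):
        profiles = [ProteinDisulfideProfile("P1", (1, 5), [rec("P1", 1, 5)], "secreted")]
        demand = folding_demand(profiles, self._proteome({"P1": 100.0}))
        assert demand.bonds_per_cell[Category.CAT1] == pytest.approx(100.0)
        assert demand.total_kinetic_bonds == pytest.approx(100.0)

    def test_brute_force_sum_and_linearity(self):
        rng = np.random.default_rng(5)
        profiles, abundances, expected = [], {}, {c: 0.0 for c in Category}
        for i in range(40):
            pid = f"P{i}"
            kind = rng.integers(0, 3)
            if kind == 0:
                cys, bonds = (10, 50), [rec(pid, 10, 50)]
            elif kind == 1:
                cys, bonds = (10, 50, 90), [rec(pid, 10, 50)]
            else:
                cys, bonds = (10, 50, 90), [rec(pid, 10, 90)]
            profile = ProteinDisulfideProfile(pid, cys, bonds)
            profiles.append(profile)
            abundances[pid] = float(rng.integers(1, 1000))
            expected[profile.category] += profile.bond_count * abundances[pid]
        demand = folding_demand(profiles, self._proteome(abundances))
        for cat in Category:
            assert demand.bonds_per_cell[cat] == pytest.approx(expected[cat])
        doubled = folding_demand(
            profiles, self._proteome({k: 2 * v for k, v in abundances.items()})
        )
        for cat in Category:
            assert doubled.bonds_per_cell[cat] == pytest.approx(2 * expected[cat])

    def test_missing_protein_contributes_zero(self):
        profiles = [ProteinDisulfideProfile("P9", (1, 5), [rec("P9", 1, 5)])]
        demand = folding_demand(profiles, self._proteome({"OTHER": 10.0}))
        assert demand.total_kinetic_bonds == 0.0


def test_dsb_sheet_reader(tmp_path):
    frame = pd.DataFrame(
        {
            "protein_id": ["P1", "P1", "P2"],
            "cys_a": [10, 60, 5],
            "cys_b": [50, 90, 25],
            "src_uniprot": [1, 1, 0],
            "src_ms": [1, 0, 1],
        }
    )
    path = tmp_path / "dsb.tsv"
    frame.to_csv(path, sep="\t", index=False)
    records = read_dsb_sheet(path)
    assert len(records) == 3
    by_key = {(r.protein_id, r.cys_a): r for r in records}
    assert by_key[("P1", 10)].sources == {"uniprot", "ms"}
    assert by_key[("P1", 60)].sources == {"uniprot"}
    assert by_key[("P2", 5)].sources == {"ms"}
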