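"""Correlation-based feature reduction and candidate feature groups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radgroup.features.extract import FeatureTable
from radgroup.features.registry import FeatureKey
from radgroup.fixtures import TableSpec, make_feature_table, make_redundant_pair_table
from radgroup.selection import (
    CfrConfig,
    GroupHierarchy,
    candidate_group_definitions,
    correlation_matrix,
    enumerate_candidate_groups,
    hierarchical_cfr,
    standard_cfr,
    subset_features,
)


def table_from_matrix(x: np.ndarray, keys: list[FeatureKey]) -> FeatureTable:
    df = pd.DataFrame(
        x,
        columns=pd.MultiIndex.from_tuples(
            [(k.roi, k.feature_class, k.feature_name) for k in keys],
            names=["roi", "feature_class", "feature_name"],
        ),
    )
    df.index = [f"s{i}" for i in range(len(df))]
    return FeatureTable(df)


def naive_standard_cfr(corr: np.ndarray, keys: list[FeatureKey], cutoff: float):
    """Independent re-statement of the iterative rule: find the most
    correlated remaining pair, drop the member with the higher mean absolute
    correlation to the other remaining features."""
    corr = np.abs(corr.copy())
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(keys)))
    while True:
        best_pair, best_val = None, cutoff
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                i, j = alive[ai], alive[bi]
                v = corr[i, j]
                pair = tuple(sorted((i, j), key=lambda t: str(keys[t])))
                if v > best_val or (
                    best_pair is not None
                    and np.isclose(v, best_val)
                    and (str(keys[pair[0]]), str(keys[pair[1]]))
                    < (str(keys[best_pair[0]]), str(keys[best_pair[1]]))
                ):
                    best_pair, best_val = pair, v
        if best_pair is None:
            return [keys[i] for i in alive]
        i, j = best_pair
        mean_i = np.mean([corr[i, o] for o in alive if o != i])
        mean_j = np.mean([corr[j, o] for o in alive if o != j])
        if np.isclose(mean_i, mean_j):
            drop = max(i, j, key=lambda t: str(keys[t]))
        else:
            drop = i if mean_i > mean_j else j
        alive.remove(drop)


def random_keys(rng: np.random.Generator, p: int) -> list[FeatureKey]:
    classes = ["shape", "firstorder", "texture"]
    keys = []
    for idx in range(p):
        c = classes[rng.integers(3)]
        keys.append(FeatureKey("whole", c, f"{c}_f{idx}"))
    return keys


class TestCorrelationMatrix:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        x = np.column_stack([base, base, rng.normal(size=20)])
        keys = random_keys(rng, 3)
        corr = correlation_matrix(table_from_matrix(x, keys))
        assert corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 4))
        corr = correlation_matrix(table_from_matrix(x, random_keys(rng, 4)))
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_matches_hand_computed_spearman(self):
        x = np.array(
            [
                [1.0, 10.0, 3.0],
                [2.0, 8.0, 1.0],
                [3.0, 9.0, 4.0],
                [4.0, 5.0, 2.0],
                [5.0, 7.0, 5.0],
            ]
        )
        keys = random_keys(np.random.default_rng(2), 3)
        corr = correlation_matrix(table_from_matrix(x, keys))
        # rank correlation computed by hand via Pearson on ranks
        ranks = np.argsort(np.argsort(x, axis=0), axis=0) + 1.0
        expected = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_constant_column_error_names_feature(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 2))
        x[:, 1] = 7.0
        keys = random_keys(rng, 2)
        with pytest.raises(ValueError, match=keys[1].feature_name):
            correlation_matrix(table_from_matrix(x, keys))


class TestStandardCfr:
    def test_identity_when_no_pair_above_cutoff(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 5))
        table = table_from_matrix(x, random_keys(rng, 5))
        kept, audit = standard_cfr(table, CfrConfig(cutoff=0.9))
        assert kept == table.keys()
        assert audit == []

    def test_oracle_equivalence_on_random_instances(self):
        # 100 random correlation structures on <= 8 features
        rng = np.random.default_rng(5)
        for trial in range(100):
            p = int(rng.integers(3, 9))
            n = 30
            latent = rng.normal(size=(n, max(2, p // 2)))
            w = rng.normal(size=(max(2, p // 2), p))
            x = latent @ w + 0.3 * rng.normal(size=(n, p))
            keys = random_keys(rng, p)
            table = table_from_matrix(x, keys)
            cutoff = float(rng.uniform(0.4, 0.95))
            corr = correlation_matrix(table)
            expected = naive_standard_cfr(corr, keys, cutoff)
            got, _ = standard_cfr(table, CfrConfig(cutoff=cutoff))
            assert got == expected, f"trial {trial}"

    def test_cutoff_monotonicity(self):
        table, _, _ = make_redundant_pair_table(n_samples=150, seed=2)
        counts = []
        for cutoff in (0.95, 0.8, 0.6, 0.4):
            kept, _ = standard_cfr(table, CfrConfig(cutoff=cutoff))
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)


class TestHierarchicalCfr:
    def test_redundant_pair_preset_contrast(self):
        table, mv, glnu = make_redundant_pair_table(seed=0)
        kept_std, _ = standard_cfr(table, CfrConfig(cutoff=0.9))
        kept_hier, audit = hierarchical_cfr(table, CfrConfig(cutoff=0.9))
        assert mv not in kept_std and glnu in kept_std
        assert mv in kept_hier and glnu not in kept_hier
        rec = next(a for a in audit if str(mv) in a.pair)
        assert rec.rule == "hierarchy" and rec.discarded == str(glnu)

    def test_same_level_pairs_use_standard_rule(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=300)
        x = np.column_stack(
            [base + 0.1 * rng.normal(size=300) for _ in range(3)]
            + [rng.normal(size=300)]
        )
        keys = [FeatureKey("whole", "texture", f"t{i}") for i in range(4)]
        table = table_from_matrix(x, keys)
        kept, audit = hierarchical_cfr(table, CfrConfig(cutoff=0.9))
        assert all(a.rule == "standard" for a in audit)
        expected = naive_standard_cfr(correlation_matrix(table), keys, 0.9)
        assert kept == expected

    def test_hierarchy_dominance_audit(self):
        # no discard decision ever removes the higher-ranked member
        hierarchy = GroupHierarchy()
        rng = np.random.default_rng(7)
        for trial in range(30):
            spec = TableSpec(
                n_samples=50, n_shape=3, n_firstorder=3, n_texture=4,
                rho_within=0.8, rho_between=0.6, seed=int(rng.integers(1 << 30)),
                effect=0.0,
            )
            table, _ = make_feature_table(spec)
            kept, audit = hierarchical_cfr(table, CfrConfig(cutoff=0.7))
            key_by_str = {str(k): k for k in table.keys()}
            for rec in audit:
                a, b = (key_by_str[s] for s in rec.pair)
                la, lb = hierarchy.level_of(a), hierarchy.level_of(b)
                if la != lb:
                    lower = a if la > lb else b
                    assert rec.discarded == str(lower)

    def test_mesh_volume_always_survives(self):
        for seed in range(10):
            spec = TableSpec(
                n_samples=40, n_shape=3, n_firstorder=3, n_texture=4,
                rho_within=0.9, rho_between=0.7, seed=seed, effect=0.0,
            )
            table, _ = make_feature_table(spec)
            kept, _ = hierarchical_cfr(table, CfrConfig(cutoff=0.5))
            assert any(k.is_mesh_volume for k in kept)

    def test_unmapped_feature_errors(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 2))
        keys = random_keys(rng, 2)
        table = table_from_matrix(x, keys)
        with pytest.raises(KeyError):
            hierarchical_cfr(table, hierarchy=GroupHierarchy(("MeshVolume", "shape")))


class TestCandidateGroups:
    def test_default_registry_gives_eight_groups(self):
        spec = TableSpec(seed=0)
        groups = enumerate_candidate_groups(spec.keys())
        assert len(groups) == 8
        assert groups.names == [
            "MeshVolume", "shape", "firstorder", "texture",
            "shape+firstorder", "shape+texture", "firstorder+texture", "all",
        ]

    def test_shape_group_contains_mesh_volume(self):
        spec = TableSpec(seed=0)
        groups = enumerate_candidate_groups(spec.keys())
        assert any(k.is_mesh_volume for k in groups["shape"])
        assert len(groups["MeshVolume"]) == 1
        assert set(groups["MeshVolume"]) <= set(groups["shape"]) <= set(groups["all"])

    def test_generalized_construction_law(self):
        for k in range(1, 6):
            classes = tuple(f"class{i}" for i in range(k))
            defs = candidate_group_definitions(classes)
            assert len(defs) == 2 + k + k * (k - 1) // 2

    def test_union_sizes_add(self):
        spec = TableSpec(seed=0)
        groups = enumerate_candidate_groups(spec.keys())
        assert len(groups["shape+firstorder"]) == len(groups["shape"]) + len(
            groups["firstorder"]
        )

    def test_empty_class_excluded_with_warning(self):
        keys = [FeatureKey("whole", "shape", "MeshVolume"),
                FeatureKey("whole", "shape", "Sphericity")]
        groups = enumerate_candidate_groups(keys)
        assert "texture" not in groups.names
        assert any("texture" in w for w in groups.warnings)

    def test_subset_features(self):
        spec = TableSpec(n_samples=10, seed=0)
        table, _ = make_feature_table(spec)
        groups = enumerate_candidate_groups(table.keys())
        assert subset_features(table, groups, "all").keys() == table.keys()
        assert subset_features(table, groups, "MeshVolume").n_features == 1
        with pytest.raises(KeyError):
            subset_features(table, groups, "nope")
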