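"""Promoter stability, endpoint similarity, and consistency tables."""

import numpy as np
import pytest

from cwqsar.attributes import DescriptorConfig, extract_attributes
from cwqsar.descriptor import CorrelationWeightTable
from cwqsar.optimizer import OptimizerConfig, run_ensemble
from cwqsar.reference import (
    load_consistency_reference,
    load_promoter_blocks,
    load_reference_splits,
)
from cwqsar.similarity import (
    SimilarityMatrix,
    StabilityProfile,
    classify_promoters,
    compare_profiles,
    consistency_table,
    render_report,
    similarity_matrix,
)
from cwqsar.simulate import PlantedModel, generate_molecules, simulate_endpoint


def table(**weights):
    return CorrelationWeightTable(dict(weights))


class TestClassifyPromoters:
    def test_all_positive_is_increase_promoter(self):
        runs = [table(A=0.3), table(A=0.1), table(A=0.8)]
        assert classify_promoters(runs).labels["A"] == 1

    def test_sign_flip_is_unstable(self):
        runs = [table(A=0.3), table(A=-0.1), table(A=0.8)]
        assert classify_promoters(runs).labels["A"] == 0

    def test_all_negative_is_decrease_promoter(self):
        runs = [table(A=-0.3, B=0.1), table(A=-0.1, B=0.2)]
        profile = classify_promoters(runs)
        assert profile.labels["A"] == -1
        assert profile.labels["B"] == 1

    def test_blocked_anywhere_is_unstable(self):
        a = CorrelationWeightTable({"A": 0.5, "B": 0.2})
        b = CorrelationWeightTable({"A": 0.5}, blocked={"B"})
        profile = classify_promoters([a, b])
        assert profile.labels["B"] == 0

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            classify_promoters([table(A=1.0), table(B=1.0)])

    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            classify_promoters([table(A=1.0)])


class TestCompareProfiles:
    def test_symmetry_and_counts(self):
        a = StabilityProfile("e1", {"A": 1, "B": -1, "C": 1, "D": 0}, 3)
        b = StabilityProfile("e2", {"A": 1, "B": 1, "C": 0, "E": -1}, 3)
        assert compare_profiles(a, b) == (1, 1)
        assert compare_profiles(b, a) == compare_profiles(a, b)

    def test_identical_all_stable(self):
        a = StabilityProfile("e1", {"A": 1, "B": -1}, 3)
        assert compare_profiles(a, a) == (2, 0)

    def test_all_zero_vs_anything(self):
        a = StabilityProfile("e1", {"A": 0, "B": 0}, 3)
        b = StabilityProfile("e2", {"A": 1, "B": -1}, 3)
        assert compare_profiles(a, b) == (0, 0)

    def test_conservation_bound(self):
        rng = np.random.default_rng(5)
        keys = [f"K{i}" for i in range(30)]
        for _ in range(20):
            la = {k: int(rng.integers(-1, 2)) for k in keys}
            lb = {k: int(rng.integers(-1, 2)) for k in keys}
            a = StabilityProfile("a", la, 2)
            b = StabilityProfile("b", lb, 2)
            sim, dis = compare_profiles(a, b)
            assert sim + dis <= min(a.stable_count, b.stable_count)


class TestReferenceBlocks:
    """The bundled three-endpoint promoter blocks and their pair counts."""

    EXPECTED = {
        ("mutagenicity", "anticancer"): (10, 8),
        ("mutagenicity", "bbb"): (14, 7),
        ("bbb", "anticancer"): (26, 8),
    }

    def test_pairwise_counts(self):
        blocks = load_promoter_blocks()
        assert set(blocks) == set(self.EXPECTED)
        for pair, (pa, pb) in blocks.items():
            assert compare_profiles(pa, pb) == self.EXPECTED[pair]

    def test_matrix_assembly(self):
        blocks = load_promoter_blocks()
        matrix = SimilarityMatrix.from_profile_pairs(
            ["mutagenicity", "anticancer", "bbb"], blocks
        )
        sim, dis = matrix.to_dataframes()
        assert sim.loc["mutagenicity", "anticancer"] == 10
        assert sim.loc["mutagenicity", "bbb"] == 14
        assert sim.loc["bbb", "anticancer"] == 26
        assert dis.loc["mutagenicity", "anticancer"] == 8
        assert dis.loc["mutagenicity", "bbb"] == 7
        assert dis.loc["bbb", "anticancer"] == 8
        assert np.all(sim.values == sim.values.T)
        assert np.all(np.diag(dis.values) == 0)

    def test_render_report_layout(self):
        blocks = load_promoter_blocks()
        pa, pb = blocks[("mutagenicity", "anticancer")]
        text = render_report(pa, pb)
        lines = [ln for ln in text.splitlines() if not ln.startswith(("#", "attribute"))]
        assert len(lines) == 18  # 10 agreements + 8 conflicts
        for ln in lines:
            assert len(ln.split("\t")[0]) == 12


class TestSimilarityMatrix:
    def test_diagonal_is_stable_count(self):
        a = StabilityProfile("a", {"A": 1, "B": -1, "C": 0}, 3)
        b = StabilityProfile("b", {"A": 1, "B": 1}, 3)
        m = similarity_matrix([a, b])
        assert m.similarity[0, 0] == 2
        assert m.similarity[1, 1] == 2
        assert m.similarity[0, 1] == 1
        assert m.dissimilarity[0, 1] == 1

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix([StabilityProfile("a", {"A": 1}, 2)])


class TestConsistencyTable:
    def test_reference_row_totals_reproduced(self):
        ref, totals = load_consistency_reference()
        assert list(ref.row_totals("mr")) == list(totals["total_mr"])
        assert list(ref.row_totals("fr")) == list(totals["total_fr"])
        i = ref.attributes.index("HALO00000000")
        assert ref.row_totals("mr")[i] == 9
        j = ref.attributes.index("BOND00000000")
        assert ref.row_totals("fr")[j] == 9

    def test_grand_total_is_sum_of_rows(self):
        ref, _ = load_consistency_reference()
        for cohort in ref.cohorts:
            assert ref.grand_total(cohort) == int(ref.row_totals(cohort).sum())

    def test_from_model_grids(self):
        cells = {}
        for cohort, sign in (("m", 1.0), ("f", -1.0)):
            cells[cohort] = {
                (s, r): table(A=sign * 0.5, B=-sign * 0.2)
                for s in ("1", "2") for r in ("1", "2")
            }
        ct = consistency_table(cells, attributes=["A", "B"])
        assert list(ct.row_totals("m")) == [4, 0]
        assert list(ct.row_totals("f")) == [0, 4]

    def test_non_rectangular_design_rejected(self):
        grids = {
            "m": {("1", "1"): table(A=1.0)},
            "f": {("1", "1"): table(A=1.0), ("1", "2"): table(A=1.0)},
        }
        with pytest.raises(ValueError, match="cells"):
            consistency_table(grids)


class TestReferenceSplits:
    def test_validation_sizes(self):
        splits = load_reference_splits()
        sizes = {
            k: sum(1 for v in s.values() if v == "validation")
            for k, s in splits.items()
        }
        assert sizes == {"1": 18, "2": 22, "3": 21}

    def test_each_split_covers_87_compounds(self):
        splits = load_reference_splits()
        universes = [set(s) for s in splits.values()]
        assert all(len(u) == 87 for u in universes)
        assert universes[0] == universes[1] == universes[2]


class TestSyntheticEndToEnd:
    def _profiles(self):
        mols = generate_molecules(120, seed=101)
        from cwqsar.simulate import plant_weights

        planted = plant_weights(mols, seed=102)
        signal = np.array(
            [planted.true_weights.dcw(extract_attributes(s)) for s in mols]
        )
        planted.noise_sd = 0.05 * float(signal.std())
        ds_a = simulate_endpoint(mols, planted, seed=103)
        ds_b = simulate_endpoint(mols, planted, seed=104)
        flipped = PlantedModel(
            CorrelationWeightTable(
                {k: -v for k, v in planted.true_weights.weights.items()}
            ),
            noise_sd=planted.noise_sd,
        )
        ds_c = simulate_endpoint(mols, flipped, seed=105)
        dconf = DescriptorConfig(threshold=1, epochs=30)
        oconf = OptimizerConfig(init_mode="uniform")

        def profile(ds, seeds, eid):
            runs = run_ensemble(ds, dconf, oconf, seeds=seeds)
            return classify_promoters([r.model.cw for r in runs], eid)

        return (
            profile(ds_a, (11, 12, 13), "a"),
            profile(ds_b, (21, 22, 23), "b"),
            profile(ds_c, (31, 32, 33), "c"),
        )

    def test_shared_weights_similar_flipped_weights_dissimilar(self):
        pa, pb, pc = self._profiles()
        sim_same, dis_same = compare_profiles(pa, pb)
        assert sim_same >= 5 * max(dis_same, 1)
        sim_flip, dis_flip = compare_profiles(pa, pc)
        assert dis_flip >= 5 * max(sim_flip, 1)
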