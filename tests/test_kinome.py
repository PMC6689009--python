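"""Kinome pipeline: mapping, clustering, rank activity, dose regression, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sigstrat as ss
from sigstrat.errors import ValidationError
from sigstrat.sigderive import GeneSignature


def toy_readouts():
    return pd.DataFrame(
        {
            "c1": [1.0, 2.0, 3.0, 10.0, 11.0, 5.0],
            "c2": [2.0, 3.0, 1.0, 11.0, 12.0, 5.5],
            "c3": [3.0, 4.0, 2.0, 12.0, 13.0, 4.5],
        },
        index=pd.Index([f"p{i}" for i in range(1, 7)], name="peptide"),
    )


def toy_map():
    return pd.DataFrame(
        {
            "peptide": ["p1", "p2", "p3", "p4", "p5", "p1"],
            "kinase": ["KA", "KA", "KA", "KB", "KB", "KB"],
        }
    )


class TestBuildMatrix:
    def test_many_to_many_and_orphans(self):
        view = ss.build_matrix(toy_readouts(), toy_map())
        assert "p1" in view.kinase_peptides["KA"]
        assert "p1" in view.kinase_peptides["KB"]
        assert view.orphans == ["p6"]
        n_mapped = len(set(toy_map()["peptide"]))
        assert len(view.orphans) == len(toy_readouts()) - n_mapped

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValidationError):
            ss.build_matrix(toy_readouts(), toy_map().iloc[:0])

    def test_generator_map_reproduced_exactly(self):
        cfg = ss.KinomeConfig(n_kinases=12, seed=3)
        matrix, kmap, _ = ss.gen_kinome(cfg)
        view = ss.build_matrix(matrix, kmap)
        assert all(
            len(peps) == cfg.peptides_per_kinase
            for peps in view.kinase_peptides.values()
        )
        assert view.orphans == []


class TestClusterPeptides:
    def test_identical_rows_cluster_together(self):
        readouts = toy_readouts()
        readouts.loc["p2"] = readouts.loc["p1"]
        view = ss.build_matrix(readouts, toy_map())
        clusters = ss.cluster_peptides(view, r_min=1.0)
        ka = clusters.clusters["KA"]
        assert any({"p1", "p2"} <= set(c) for c in ka)

    def test_anticorrelated_rows_split(self):
        view = ss.build_matrix(toy_readouts(), toy_map())
        clusters = ss.cluster_peptides(view, r_min=0.6)
        ka = clusters.clusters["KA"]
        # p3 runs opposite to p1/p2 across conditions
        assert any(set(c) == {"p3"} for c in ka)

    def test_constant_peptide_becomes_singleton(self):
        readouts = toy_readouts()
        readouts.loc["p2"] = 4.2
        view = ss.build_matrix(readouts, toy_map())
        with pytest.warns(UserWarning, match="constant"):
            clusters = ss.cluster_peptides(view)
        assert any(set(c) == {"p2"} for c in clusters.clusters["KA"])

    def test_cluster_sizes_conserve_peptide_count(self):
        matrix, kmap, _ = ss.gen_kinome(ss.KinomeConfig(n_kinases=20, seed=4))
        view = ss.build_matrix(matrix, kmap)
        clusters = ss.cluster_peptides(view)
        for kin, comps in clusters.clusters.items():
            assert sum(len(c) for c in comps) == len(view.kinase_peptides[kin])

    def test_planted_correlation_recovers_single_cluster_per_kinase(self):
        single, total = 0, 0
        for seed in range(3):
            matrix, kmap, _ = ss.gen_kinome(ss.KinomeConfig(seed=60 + seed))
            view = ss.build_matrix(matrix, kmap)
            clusters = ss.cluster_peptides(view)
            single += sum(len(c) == 1 for c in clusters.clusters.values())
            total += len(clusters.clusters)
        assert single / total >= 0.95


class TestKinaseActivity:
    def test_matches_hand_enumeration_on_toy_array(self):
        readouts = toy_readouts()
        view = ss.build_matrix(readouts, toy_map())
        clusters = ss.cluster_peptides(view, r_min=0.6)
        act = ss.kinase_activity(clusters, readouts)
        n = len(readouts)
        for kin, peps in view.kinase_peptides.items():
            for cond in readouts.columns:
                ranks = stats.rankdata(readouts[cond])
                ref = np.mean(
                    [ranks[readouts.index.get_loc(p)] for p in peps]
                ) / n
                assert act.loc[kin, cond] == pytest.approx(ref, abs=1e-12)

    def test_top_ranked_kinase_activity_is_one(self):
        readouts = toy_readouts()
        kmap = pd.DataFrame({"peptide": ["p5", "p1"], "kinase": ["KTOP", "KA"]})
        view = ss.build_matrix(readouts, kmap)
        act = ss.kinase_activity(ss.cluster_peptides(view), readouts)
        # p5 is the highest-intensity peptide in every condition
        assert (act.loc["KTOP"] == 1.0).all()

    def test_uniform_intensities_give_half(self):
        rng = np.random.default_rng(5)
        readouts = pd.DataFrame(
            rng.random((400, 6)), index=[f"p{i}" for i in range(400)]
        )
        kmap = pd.DataFrame(
            {"peptide": readouts.index, "kinase": [f"K{i % 40}" for i in range(400)]}
        )
        view = ss.build_matrix(readouts, kmap)
        act = ss.kinase_activity(ss.cluster_peptides(view), readouts)
        assert act.to_numpy().mean() == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_intensity_transform(self):
        matrix, kmap, _ = ss.gen_kinome(ss.KinomeConfig(n_kinases=15, seed=6))
        view1 = ss.build_matrix(matrix, kmap)
        act1 = ss.kinase_activity(ss.cluster_peptides(view1), matrix)
        warped = np.exp(matrix / 4.0)
        view2 = ss.build_matrix(warped, kmap)
        act2 = ss.kinase_activity(ss.cluster_peptides(view2), warped)
        pd.testing.assert_frame_equal(act1, act2)


class TestDifferentialKinase:
    def _activity(self, seed, slope=0.0):
        cfg = ss.KinomeConfig(effect_slope=slope, seed=seed)
        matrix, kmap, truth = ss.gen_kinome(cfg)
        view = ss.build_matrix(matrix, kmap)
        act = ss.kinase_activity(ss.cluster_peptides(view), matrix)
        return act, matrix.attrs["dose_uM"], truth

    def test_null_calibration_near_ten_percent(self):
        rates = []
        for seed in range(5):
            act, doses, _ = self._activity(70 + seed, slope=0.0)
            diff = ss.differential_kinase(act, doses)
            rates.append(diff["significant"].mean())
        assert np.mean(rates) == pytest.approx(0.10, abs=0.03)

    def test_planted_kinase_detected_with_direction(self):
        act, doses, truth = self._activity(80, slope=1.0)
        diff = ss.differential_kinase(act, doses)
        for kin in truth.planted_up:
            assert diff.loc[kin, "significant"] and diff.loc[kin, "direction"] == "up"
        for kin in truth.planted_down:
            assert diff.loc[kin, "significant"] and diff.loc[kin, "direction"] == "down"

    def test_too_few_doses_rejected(self):
        act = pd.DataFrame([[0.5, 0.6]], index=["K1"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            ss.differential_kinase(act, pd.Series([0.0, 0.0], index=["a", "b"]))


class TestPrioritize:
    def test_empty_input(self):
        empty = pd.DataFrame(columns=["slope", "p", "significant", "direction"])
        assert len(ss.prioritize(empty)) == 0

    def test_planted_up_kinase_ranks_first(self):
        cfg = ss.KinomeConfig(seed=90)
        matrix, kmap, truth = ss.gen_kinome(cfg)
        view = ss.build_matrix(matrix, kmap)
        act = ss.kinase_activity(ss.cluster_peptides(view), matrix)
        diff = ss.differential_kinase(act, matrix.attrs["dose_uM"])
        ranked = ss.prioritize(diff)
        assert ranked.index[0] in truth.planted_up + truth.planted_down

    def test_signature_concordance_annotation(self):
        diff = pd.DataFrame(
            {
                "slope": [0.3, -0.2],
                "p": [0.01, 0.02],
                "significant": [True, True],
                "direction": ["up", "down"],
            },
            index=pd.Index(["KLOW", "KHIGH"], name="kinase"),
        )
        sig = GeneSignature(
            high_template=["KHIGH"],
            low_template=["KLOW"],
            annotations=pd.DataFrame(index=pd.Index(["KHIGH", "KLOW"], name="gene")),
        )
        ranked = ss.prioritize(diff, sig)
        assert ranked["concordant"].all()
        assert ranked["in_signature"].all()
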