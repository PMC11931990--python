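"""Pose efficiency prediction, scoring, selection criteria and robustness."""

import numpy as np
import pandas as pd
import pytest

from agpfret import screening as sc
from agpfret import structure_io as sio
from agpfret import synthetic_data as sd
from agpfret.config import fixture_model_scores, measured_efficiency_set
from agpfret.exceptions import InvalidArgumentError
from agpfret.fret_core import FretParams

from conftest import random_rigid_transform


def single_donor_model(r):
    """Chain-A acceptor at distance r from one donor; everything else remote."""
    far = 5000.0
    rows = [
        ("A", 517, "CYS", "CB", 0.0, 0.0, 0.0),
        ("B", 517, "CYS", "CB", far, far, 0.0),
        ("C", 29, "CYS", "CB", r, 0.0, 0.0),
    ]
    # 13 remaining donor sites, all far away
    positions = [33, 47, 249, 277, 353, 647]
    for k, p in enumerate(positions):
        rows.append(("C", p, "CYS", "CB", -far, far + 10.0 * k, 0.0))
    for k, p in enumerate([29] + positions):
        rows.append(("D", p, "CYS", "CB", far, -far - 10.0 * k, 0.0))
    atoms = pd.DataFrame(
        rows, columns=["chain_id", "residue_number", "residue_name", "atom_name", "x", "y", "z"]
    )
    return sio.StructureModel("toy", atoms)


class TestPredictPositionEfficiency:
    def test_far_field_limit(self, true_complex, scheme):
        model, _ = true_complex
        moved = model.transformed(np.eye(3), np.array([0.0, 50000.0, 0.0]), chains=("A", "B"))
        pred = sc.predict_position_efficiency(moved, scheme)
        assert all(pred[p] < 1e-5 for p in pred.positions())

    def test_single_donor_at_forster_radius(self):
        model = single_donor_model(50.0)
        scheme = sio.default_scheme(acceptor_positions=[517])
        pred = sc.predict_position_efficiency(model, scheme)
        assert pred[517] == pytest.approx(0.5 / 14, rel=1e-6)

    def test_point_mass_donor_weight(self):
        model = single_donor_model(50.0)
        donors = tuple(
            sio.LabelSite("agp2", ch, p, "donor", 1.0 if (ch, p) == ("C", 29) else 0.0)
            for ch in ("C", "D")
            for p in sio.AGP2_LABEL_POSITIONS
        )
        scheme = sio.LabelingScheme(
            donor_sites=donors,
            acceptor_sites=(
                sio.LabelSite("agp1", "A", 517, "acceptor"),
                sio.LabelSite("agp1", "B", 517, "acceptor"),
            ),
        )
        pred = sc.predict_position_efficiency(model, scheme)
        assert pred[517] == pytest.approx(0.5, rel=1e-6)

    def test_invariant_under_rigid_transform(self, true_complex, scheme):
        model, _ = true_complex
        base = sc.predict_position_efficiency(model, scheme)
        rot, trans = random_rigid_transform(np.random.default_rng(9))
        moved = model.transformed(rot, trans)
        pred = sc.predict_position_efficiency(moved, scheme)
        for p in base.positions():
            assert pred[p] == pytest.approx(base[p], abs=1e-9)


class TestScoreModel:
    def test_identical_sets_zero(self):
        e = sc.EfficiencySet({122: 0.1, 554: 0.3})
        assert sc.score_model(e, e) == 0.0

    def test_symmetry(self):
        a = sc.EfficiencySet({122: 0.1, 554: 0.3})
        b = sc.EfficiencySet({122: 0.2, 554: 0.25})
        assert sc.score_model(a, b) == pytest.approx(sc.score_model(b, a))

    def test_single_position(self):
        a = sc.EfficiencySet({122: 0.3})
        b = sc.EfficiencySet({122: 0.1})
        assert sc.score_model(a, b) == pytest.approx(0.04)

    def test_published_row_in_efficiency_space(self):
        predicted = sc.EfficiencySet(
            {122: 0.005, 362: 0.091, 517: 0.305, 535: 0.392, 554: 0.350, 603: 0.337}
        )
        assert sc.score_model(predicted, measured_efficiency_set()) == pytest.approx(
            0.0881, abs=5e-5
        )

    def test_key_mismatch_raises(self):
        with pytest.raises(InvalidArgumentError):
            sc.score_model(sc.EfficiencySet({122: 0.1}), sc.EfficiencySet({554: 0.1}))

    def test_distance_space_mode(self):
        a = sc.EfficiencySet({122: 0.5})
        b = sc.EfficiencySet({122: 0.09})
        expected = (1.0 - (1 / 0.09 - 1) ** (1 / 6)) ** 2
        assert sc.score_model(a, b, space="distance") == pytest.approx(expected)


class TestDomainInvolvement:
    def test_empty_contacts_all_false(self):
        flags = sc.classify_domain_involvement([])
        assert flags == sc.InvolvementFlags()

    def test_single_pair_interval_membership(self):
        from agpfret.interface_contacts import ContactPair

        pair = ContactPair(("HIS", 528, "A"), ("ASP", 346, "C"), 2.0)
        flags = sc.classify_domain_involvement([pair])
        assert flags.agp1_hk and not flags.agp1_pcm
        assert flags.agp2_pcm and not flags.agp2_hk

    def test_pairs_spanning_both_agp2_modules(self):
        from agpfret.interface_contacts import ContactPair

        pairs = [
            ContactPair(("HIS", 528, "A"), ("ASP", 346, "C"), 2.0),
            ContactPair(("HIS", 528, "A"), ("GLU", 600, "C"), 2.5),
        ]
        flags = sc.classify_domain_involvement(pairs)
        assert flags.agp2_pcm and flags.agp2_hk

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sc.DomainRanges(agp1_pcm=(1, 520), agp1_hk=(518, 745))


class TestSelectionCriteria:
    def test_packaged_table_returns_published_finalists(self):
        survivors, audit = sc.apply_selection_criteria(fixture_model_scores())
        assert {s.model_id for s in survivors} == {
            "model.000.09", "model.002.03", "model.002.04", "model.002.05",
        }
        assert len(audit) == 44

    def test_low_554_model_eliminated_by_first_criterion(self):
        audit = sc.apply_selection_criteria(fixture_model_scores())[1]
        row = audit[audit.model_id == "model.000.00"].iloc[0]
        assert row.eliminated_by == "c1_122_vs_554"

    def test_wrong_involvement_eliminated_by_third_criterion(self):
        audit = sc.apply_selection_criteria(fixture_model_scores())[1]
        row = audit[audit.model_id == "model.000.08"].iloc[0]
        assert row.c1_122_vs_554 and row.c2_362_vs_554
        assert row.eliminated_by == "c3_domain_involvement"

    def test_published_training_poses(self):
        # of the three manually built arrangements only the antiparallel one
        # satisfies the two efficiency criteria
        scores = {s.model_id: s for s in fixture_model_scores()}
        for mid, expected in [
            ("manual.parallel", False),
            ("manual.vertical", False),
            ("manual.antiparallel", True),
        ]:
            v = sc.evaluate_criteria(scores[mid].predicted, scores[mid].involvement)
            assert (v["c1_122_vs_554"] and v["c2_362_vs_554"]) is expected

    def test_missing_position_raises(self):
        bad = sc.ModelScore("x", sc.EfficiencySet({122: 0.1}), 0.0)
        with pytest.raises(InvalidArgumentError):
            sc.apply_selection_criteria([bad])


class TestRobustness:
    def test_max_fold_one_is_uniform(self, true_complex, scheme):
        model, _ = true_complex
        samples, stability = sc.robustness_resample(
            model, scheme, n_samples=10, max_fold=1.0, seed=1
        )
        assert np.allclose(samples.to_numpy(), samples.to_numpy()[0], atol=1e-12)
        assert (stability.fraction_preserved == 1.0).all()

    def test_same_seed_reproducible(self, true_complex, scheme):
        model, _ = true_complex
        s1, _ = sc.robustness_resample(model, scheme, n_samples=20, seed=5)
        s2, _ = sc.robustness_resample(model, scheme, n_samples=20, seed=5)
        pd.testing.assert_frame_equal(s1, s2)

    def test_fold_bound_respected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = sc.sample_weights(rng, 14, 40.0)
            assert w.max() / w.min() <= 40.0 + 1e-9
            assert w.sum() == pytest.approx(1.0)

    def test_dominating_pose_ordering_never_reversed(self, true_complex, scheme):
        # every 554-site distance is smaller than the matching 122-site
        # distance in the reference pose, so reweighting cannot flip the order
        model, _ = true_complex
        _, stability = sc.robustness_resample(
            model, scheme, n_samples=300, max_fold=40.0, seed=11
        )
        row = stability[(stability.pos_hi == 554) & (stability.pos_lo == 122)]
        assert row.fraction_preserved.item() == 1.0

    def test_invalid_max_fold_raises(self, true_complex, scheme):
        model, _ = true_complex
        with pytest.raises(InvalidArgumentError):
            sc.robustness_resample(model, scheme, n_samples=5, max_fold=0.5)


def test_pose_recovery_small_ensemble(agp1_dimer, agp2_dimer, scheme):
    """The generating pose scores best against its own noisy measurements."""
    ensemble = sd.make_pose_ensemble(agp2_dimer, agp1_dimer, n_decoys=10, seed=21)
    truth = sd.make_complex_truth(ensemble[0][0], ensemble[0][1])
    measured = sd.simulate_measurements(truth, noise_sd=0.03, seed=22)
    scores = sc.screen_models([m for m, _ in ensemble], scheme, measured)
    assert min(scores, key=lambda s: s.ssd).model_id == "pose_true"
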