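"""Two-step cleaning: cross-prediction screening + neighborhood filtering."""

import numpy as np
import pytest

from mnporigin.chem_io import MICROBIAL_LABELS
from mnporigin.cleaning import (
    CleaningReport,
    apply_cleaning,
    auto_radius,
    cross_prediction_screen,
    neighborhood_filter,
)
from mnporigin.encoder import EmbeddingTable
from mnporigin.synthetic import SyntheticSpec, generate_dataset, inject_label_noise


def oracle_trainer_factory(true_labels):
    """Trainer that predicts each compound's generator truth with certainty."""

    def trainer(train_ds, seed):
        def predict(records):
            out = np.zeros((len(records), 3))
            for i, r in enumerate(records):
                out[i, true_labels[r.id]] = 1.0
            return out

        return predict

    return trainer


@pytest.fixture(scope="module")
def noisy_case():
    ds = generate_dataset(SyntheticSpec(n_per_class={0: 40, 1: 20, 2: 20}, seed=3))
    noisy, planted = inject_label_noise(ds, 0.1, seed=5)
    return ds, noisy, planted


class TestCrossPredictionScreen:
    def test_oracle_recovers_planted_flips_exactly(self, noisy_case):
        ds, noisy, planted = noisy_case
        trainer = oracle_trainer_factory({r.id: r.label for r in ds})
        log, flagged = cross_prediction_screen(noisy, trainer, cycles=5,
                                               subset_fraction=0.5, seed=0)
        assert flagged == planted

    def test_noise_free_data_yields_zero_flags(self, noisy_case):
        ds, _, _ = noisy_case
        trainer = oracle_trainer_factory({r.id: r.label for r in ds})
        _, flagged = cross_prediction_screen(ds, trainer, cycles=5,
                                             subset_fraction=0.5, seed=0)
        assert flagged == set()

    def test_microbial_compounds_never_flagged(self, noisy_case):
        _, noisy, _ = noisy_case

        def always_bacteria(train_ds, seed):
            return lambda records: np.tile([0.0, 1.0, 0.0], (len(records), 1))

        _, flagged = cross_prediction_screen(noisy, always_bacteria, cycles=3,
                                             subset_fraction=0.5, seed=0)
        microbial_ids = {r.id for r in noisy if r.label in MICROBIAL_LABELS}
        assert flagged & microbial_ids == set()
        animalia_ids = {r.id for r in noisy if r.label == 0}
        assert flagged == animalia_ids  # every screened compound conflicts

    def test_strict_coverage_every_animalia_appears_oof(self, noisy_case):
        ds, noisy, _ = noisy_case
        trainer = oracle_trainer_factory({r.id: r.label for r in ds})
        log, _ = cross_prediction_screen(noisy, trainer, cycles=4,
                                         subset_fraction=0.7, seed=1)
        for r in noisy:
            if r.label == 0:
                assert log.appearance_count(r.id) >= 1

    def test_same_seed_reproduces_flags(self, noisy_case):
        ds, noisy, _ = noisy_case
        trainer = oracle_trainer_factory({r.id: r.label for r in ds})
        out1 = cross_prediction_screen(noisy, trainer, cycles=5, seed=3)[1]
        out2 = cross_prediction_screen(noisy, trainer, cycles=5, seed=3)[1]
        assert out1 == out2

    def test_invalid_cycles_rejected(self, noisy_case):
        _, noisy, _ = noisy_case
        trainer = oracle_trainer_factory({})
        with pytest.raises(ValueError, match="cycles"):
            cross_prediction_screen(noisy, trainer, cycles=0)

    def test_infeasible_coverage_reports_minimal_cycles(self, noisy_case):
        _, noisy, _ = noisy_case  # ~44 Animalia after noise
        trainer = oracle_trainer_factory({})
        n0 = sum(1 for r in noisy if r.label == 0)
        holdout = n0 - round(0.95 * n0)
        expected_min = int(np.ceil(n0 / holdout))
        with pytest.raises(ValueError, match=str(expected_min)):
            cross_prediction_screen(noisy, trainer, cycles=2, subset_fraction=0.95)

    def test_subset_fraction_bounds(self, noisy_case):
        _, noisy, _ = noisy_case
        trainer = oracle_trainer_factory({})
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                cross_prediction_screen(noisy, trainer, subset_fraction=bad)


def _random_embedding(n, seed, dim=3, spread=3.0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    labels = {ids[i]: int(rng.integers(0, 3)) for i in range(n)}
    emb = EmbeddingTable("last_ffn", ids, rng.normal(size=(n, dim)) * spread)
    return emb, labels


def _brute_force_removed(emb, labels, radius):
    X = emb.vectors
    removed = set()
    for i, cid in enumerate(emb.ids):
        if labels[cid] != 0:
            continue
        for j, other in enumerate(emb.ids):
            if labels[other] in MICROBIAL_LABELS and np.linalg.norm(X[i] - X[j]) < radius:
                removed.add(cid)
                break
    return removed


class TestNeighborhoodFilter:
    def test_radius_zero_removes_nothing(self):
        emb, labels = _random_embedding(30, seed=0)
        assert neighborhood_filter(emb, labels, radius=0.0) == set()

    def test_no_microbial_points_removes_nothing(self):
        emb, _ = _random_embedding(20, seed=1)
        labels = {cid: 0 for cid in emb.ids}
        assert neighborhood_filter(emb, labels, radius=10.0) == set()

    def test_hand_placed_points_match_enumeration(self):
        # 12 points on a 2-D grid; microbial cluster near the origin
        ids = [f"q{i}" for i in range(12)]
        coords = np.array(
            [[0, 0], [1, 0], [0, 1], [5, 5], [5, 6], [6, 5],
             [0.5, 0.5], [1.2, 0.3], [5.5, 5.5], [9, 9], [2.6, 0], [0, 2.6]]
        , dtype=float)
        labels = dict(zip(ids, [1, 1, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0]))
        emb = EmbeddingTable("last_ffn", ids, coords)
        got = neighborhood_filter(emb, labels, radius=1.5)
        assert got == _brute_force_removed(emb, labels, 1.5)
        assert got == {"q6", "q7"}  # inside the microbial cluster only

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_instances(self, seed):
        emb, labels = _random_embedding(150, seed=seed)
        for radius in (0.5, 1.5, 4.0):
            assert neighborhood_filter(emb, labels, radius) == _brute_force_removed(
                emb, labels, radius
            )

    def test_removed_set_monotone_in_radius(self):
        emb, labels = _random_embedding(120, seed=7)
        prev = set()
        for radius in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            cur = neighborhood_filter(emb, labels, radius)
            assert prev <= cur
            prev = cur

    def test_auto_radius_is_distance_quantile(self):
        emb, _ = _random_embedding(40, seed=2)
        from scipy.spatial.distance import pdist

        assert auto_radius(emb, quantile=0.05) == pytest.approx(
            np.quantile(pdist(emb.vectors), 0.05)
        )


class TestApplyCleaning:
    def test_empty_report_is_identity(self, noisy_case):
        _, noisy, _ = noisy_case
        out = apply_cleaning(noisy, CleaningReport())
        assert out.ids == noisy.ids

    def test_union_arithmetic(self, noisy_case):
        _, noisy, _ = noisy_case
        ani = [r.id for r in noisy if r.label == 0]
        report = CleaningReport(step1_flagged=set(ani[:5]), step2_removed=set(ani[5:8]))
        assert len(apply_cleaning(noisy, report)) == len(noisy) - 8

    def test_overlapping_sets_counted_once(self, noisy_case):
        _, noisy, _ = noisy_case
        ani = [r.id for r in noisy if r.label == 0]
        report = CleaningReport(step1_flagged=set(ani[:4]), step2_removed=set(ani[2:6]))
        assert len(apply_cleaning(noisy, report)) == len(noisy) - 6

    def test_unknown_id_rejected(self, noisy_case):
        _, noisy, _ = noisy_case
        with pytest.raises(KeyError):
            apply_cleaning(noisy, CleaningReport(step1_flagged={"ghost"}))

    def test_microbial_targets_rejected(self, noisy_case):
        _, noisy, _ = noisy_case
        microbial = next(r.id for r in noisy if r.label in MICROBIAL_LABELS)
        with pytest.raises(ValueError, match="microbial"):
            apply_cleaning(noisy, CleaningReport(step1_flagged={microbial}))

    def test_report_json_round_trip(self, tmp_path):
        report = CleaningReport(step1_flagged={"a"}, step2_removed={"b"},
                                cycles=10, subset_fraction=0.5, radius=5.0, seed=1)
        back = CleaningReport.from_json(report.to_json(tmp_path / "r.json"))
        assert back.step1_flagged == {"a"} and back.step2_removed == {"b"}
        assert back.radius == 5.0 and back.cycles == 10
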