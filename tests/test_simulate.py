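"""Synthetic experiment generator: construction invariants, boundary
regimes and ground-truth recovery."""

import math

import numpy as np
import pytest

from sourceguess.coding import (
    code_recall_events,
    encoding_sets,
    filter_pair_duplicates,
)
from sourceguess.guessing import build_frequency_norms
from sourceguess.simulate import (
    ActionSpaceConfig,
    EncodingConfig,
    ExperimentConfig,
    RecallConfig,
    make_action_space,
    simulate_experiment,
    simulate_generation_phase,
    simulate_test_phase,
    write_dataset,
)


class TestMakeActionSpace:
    def test_default_construction_invariants(self):
        space = make_action_space(ActionSpaceConfig(seed=0))
        assert len(space.shapes) == 15
        for shape in space.shapes:
            assert 20 <= len(space.supports[shape]) <= 40
            assert space.popularity[shape].sum() == pytest.approx(1.0)
            assert (space.popularity[shape] > 0).all()

    def test_zipf_zero_is_uniform(self):
        space = make_action_space(ActionSpaceConfig(
            popularity="zipf", popularity_param=0.0, seed=1
        ))
        for shape in space.shapes:
            p = space.popularity[shape]
            assert p == pytest.approx(np.full(len(p), 1 / len(p)))

    def test_zipf_is_skewed(self):
        space = make_action_space(ActionSpaceConfig(seed=1))
        p = space.popularity[space.shapes[0]]
        assert p[0] > 3 * p[-1]

    def test_deterministic_under_seed(self):
        a = make_action_space(ActionSpaceConfig(seed=5))
        b = make_action_space(ActionSpaceConfig(seed=5))
        assert a.shapes == b.shapes
        assert a.supports == b.supports
        for s in a.shapes:
            assert (a.popularity[s] == b.popularity[s]).all()

    def test_dirichlet_popularity(self):
        space = make_action_space(ActionSpaceConfig(
            popularity="dirichlet", popularity_param=0.5, seed=2
        ))
        for s in space.shapes:
            assert space.popularity[s].sum() == pytest.approx(1.0)


class TestSimulateGenerationPhase:
    def test_design_arithmetic_without_duplication(self):
        """15 cues x 3 exemplars -> 45 performed and 45 observed actions
        per member, all distinct within the pair."""
        space = make_action_space(ActionSpaceConfig(seed=3))
        enc = EncodingConfig(p_self_repeat=0.0, p_partner_duplicate=0.0)
        events = simulate_generation_phase(
            space, enc, np.random.default_rng(0), member_ids=("m0", "m1")
        )
        per_member = {"m0": [], "m1": []}
        for e in events:
            per_member[e.participant_id].append(e)
        assert len(per_member["m0"]) == len(per_member["m1"]) == 45
        keys = [(e.participant_id, e.key) for e in events]
        assert len({k for _, k in keys}) == 90  # no within-pair duplicates

    def test_forced_duplication_boundary(self):
        space = make_action_space(ActionSpaceConfig(seed=3))
        enc = EncodingConfig(p_self_repeat=0.0, p_partner_duplicate=1.0)
        events = simulate_generation_phase(space, enc, np.random.default_rng(0))
        _, summary = filter_pair_duplicates(events)
        # copying keeps both members' sets identical, so only the second
        # actor of each round has anything new to duplicate: every partner
        # draw is a duplicate, no focal draw can be (3 of 6 per shape)
        assert summary.pct_partner_duplicates == pytest.approx(50.0)
        # every action was performed by both members, so nothing survives
        retained, _ = filter_pair_duplicates(events)
        assert retained == []

    def test_infeasible_support_rejected(self):
        space = make_action_space(ActionSpaceConfig(
            support_range=(4, 4), seed=0
        ))
        with pytest.raises(ValueError):
            simulate_generation_phase(
                space, EncodingConfig(exemplars_per_shape=3),
                np.random.default_rng(0),
            )

    def test_load_schedule_travels_with_events(self):
        space = make_action_space(ActionSpaceConfig(seed=3))
        schedule = {s: "action_planning" for s in space.shapes[:5]}
        enc = EncodingConfig(load_schedule=schedule)
        events = simulate_generation_phase(space, enc, np.random.default_rng(0))
        for e in events:
            expected = schedule.get(e.shape_id, "none")
            assert e.load_condition == expected


class TestSimulateTestPhase:
    @pytest.fixture
    def pair(self):
        space = make_action_space(ActionSpaceConfig(seed=4))
        enc = EncodingConfig(p_self_repeat=0.0, p_partner_duplicate=0.0)
        events = simulate_generation_phase(
            space, enc, np.random.default_rng(1), member_ids=("m0", "m1")
        )
        return space, events

    def test_perfect_memory_no_errors(self, pair):
        space, events = pair
        rec = RecallConfig(
            p_retrieve_own=1.0, p_retrieve_partner=1.0,
            p_source_confusion=0.0, guess_rate=0.0,
        )
        recall = simulate_test_phase(
            events, "m0", space, rec, "recall_own", "free_report",
            np.random.default_rng(2),
        )
        own, partner = encoding_sets(events, "m0")
        assert {e.key for e in recall} == own

    def test_total_confusion_reports_partner_set(self, pair):
        space, events = pair
        rec = RecallConfig(
            p_retrieve_own=1.0, p_retrieve_partner=1.0,
            p_source_confusion=1.0, guess_rate=0.0,
        )
        recall = simulate_test_phase(
            events, "m0", space, rec, "recall_own", "free_report",
            np.random.default_rng(2),
        )
        own, partner = encoding_sets(events, "m0")
        assert {e.key for e in recall} == partner

    def test_extended_mode_marks_withheld_items(self, pair):
        space, events = pair
        rec = RecallConfig(
            p_retrieve_own=1.0, p_retrieve_partner=1.0,
            p_source_confusion=0.0, guess_rate=0.0,
        )
        recall = simulate_test_phase(
            events, "m0", space, rec, "recall_own", "extended",
            np.random.default_rng(2),
        )
        own, partner = encoding_sets(events, "m0")
        reported = {e.key for e in recall if e.attributed_to_target}
        withheld = {e.key for e in recall if not e.attributed_to_target}
        assert reported == own
        assert withheld == partner

    def test_monitoring_strictness_withholds_confusions(self, pair):
        space, events = pair
        rec = RecallConfig(
            p_retrieve_own=1.0, p_retrieve_partner=1.0,
            p_source_confusion=1.0, guess_rate=0.0, monitoring_strictness=1.0,
        )
        recall = simulate_test_phase(
            events, "m0", space, rec, "recall_own", "extended",
            np.random.default_rng(2),
        )
        # everything retrieved is misattributed, but perfect monitoring
        # catches every wrong-source candidate
        assert all(not e.attributed_to_target for e in recall)

    def test_pure_guessing_error_composition(self):
        """With retrieval off, coded source errors vs. intrusions occur in
        the proportion given by the exact without-replacement guess law
        (enumeration oracle), conditioned on the realized guess counts."""
        from sourceguess.guessing import FrequencyNorms, enumerate_guess_distribution

        space = make_action_space(ActionSpaceConfig(
            n_shapes=3, support_range=(8, 8), seed=4
        ))
        enc = EncodingConfig(
            exemplars_per_shape=2, p_self_repeat=0.0, p_partner_duplicate=0.0
        )
        events = simulate_generation_phase(
            space, enc, np.random.default_rng(1), member_ids=("m0", "m1")
        )
        rec = RecallConfig(
            p_retrieve_own=0.0, p_retrieve_partner=0.0,
            p_source_confusion=0.0, guess_rate=2.0,
            p_guess_outside_inventory=0.0,
        )
        norms = FrequencyNorms({
            s: dict(zip(space.supports[s], space.popularity[s]))
            for s in space.shapes
        })
        own, partner = encoding_sets(events, "m0")
        rng = np.random.default_rng(3)
        n_source = n_intr = 0
        exp_source = exp_novel = 0.0
        enum_cache = {}
        for _ in range(400):
            recall = simulate_test_phase(
                events, "m0", space, rec, "recall_own", "free_report", rng
            )
            counts, _ = code_recall_events(recall, own, partner, "recall_own")
            n_source += counts.n_source_errors
            n_intr += counts.n_intrusions
            for shape in space.shapes:
                k = sum(1 for e in recall if e.shape_id == shape)
                if k == 0:
                    continue
                if (shape, k) not in enum_cache:
                    enum = enumerate_guess_distribution(norms, shape, k)
                    enum_cache[(shape, k)] = enum.expected_counts(own, partner)
                expected = enum_cache[(shape, k)]
                exp_source += expected["matched_partner"]
                exp_novel += expected["novel"]
        frac = n_source / (n_source + n_intr)
        frac_expected = exp_source / (exp_source + exp_novel)
        assert abs(frac - frac_expected) < 0.02
        assert abs(n_source - exp_source) / exp_source < 0.1


def _null_rejection_rate(norms_override, n_experiments, seed0, n_pairs=4,
                         n_reps=150):
    """Replicate small pure-guessing experiments end to end and return the
    one-tailed observed>predicted rejection rate at alpha=.05.

    ``norms_override=None`` estimates frequency norms from each synthetic
    experiment's own generation phase (the standard procedure);
    otherwise the supplied norms (e.g. the generator's true popularity)
    are used for the Monte Carlo baseline.
    """
    import warnings as _warnings

    from sourceguess.guessing import build_frequency_norms, predict_participant
    from sourceguess.stats import paired_t_onetailed

    space_cfg = ActionSpaceConfig(n_shapes=5, support_range=(20, 30), seed=50)
    rng_seed = np.random.default_rng(seed0)
    rejections = n_used = 0
    for _ in range(n_experiments):
        sim_seed = int(rng_seed.integers(2**31))
        cfg = ExperimentConfig(
            space=space_cfg,
            encoding=EncodingConfig(exemplars_per_shape=3),
            recall=RecallConfig(p_source_confusion=0.0, guess_rate=1.0),
            n_pairs=n_pairs, seed=sim_seed,
        )
        ds = simulate_experiment(cfg)
        norms = norms_override or build_frequency_norms(ds.generation)
        pairs, by_pid = {}, {}
        for e in ds.generation:
            pairs.setdefault(e.pair_id, []).append(e)
        for e in ds.recall:
            by_pid.setdefault(e.participant_id, []).append(e)
        pair_of = {e.participant_id: e.pair_id for e in ds.generation}
        observed, predicted = [], []
        for idx, (pid, events) in enumerate(sorted(by_pid.items())):
            filtered, _ = filter_pair_duplicates(pairs[pair_of[pid]])
            own, partner = encoding_sets(filtered, pid)
            task = events[0].task
            counts, labels = code_recall_events(events, own, partner, task)
            shape_counts = {}
            for ev, label in labels:
                if label != "repeat":
                    shape_counts[ev.shape_id] = shape_counts.get(ev.shape_id, 0) + 1
            shape_counts = {
                s: min(k, norms.support_size(s)) for s, k in shape_counts.items()
            }
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                pred = predict_participant(
                    pid, shape_counts, counts.n_intrusions, own, partner,
                    norms, task, n_reps=n_reps, seed=sim_seed + idx,
                )
            if math.isnan(pred.predicted_source_errors):
                continue
            observed.append(counts.n_source_errors)
            predicted.append(pred.predicted_source_errors)
        if len(observed) >= 6:
            n_used += 1
            res = paired_t_onetailed(observed, predicted)
            rejections += res.p_one_tailed < 0.05
    return rejections / n_used, n_used


class TestNullRejectionRate:
    BAND = 3 * math.sqrt(0.05 * 0.95 / 500)

    def test_alpha_holds_with_true_popularity_norms(self):
        """With the guessing baseline fed the generator's true popularity,
        the one-tailed test rejects at ~alpha under pure guessing."""
        space = make_action_space(ActionSpaceConfig(
            n_shapes=5, support_range=(20, 30), seed=50
        ))
        from sourceguess.guessing import FrequencyNorms

        true_norms = FrequencyNorms({
            s: dict(zip(space.supports[s], space.popularity[s]))
            for s in space.shapes
        })
        rate, n_used = _null_rejection_rate(true_norms, 500, seed0=51)
        assert n_used == 500
        assert abs(rate - 0.05) < self.BAND

    def test_self_estimated_norms_are_conservative_not_anticonservative(self):
        """Estimating the norms from the experiment itself includes each
        participant's own six actions per cue, which inflates the
        simulated non-target match probability in small samples.  The
        resulting test errs on the conservative side — it must never
        reject above alpha."""
        rate, n_used = _null_rejection_rate(None, 500, seed0=51)
        assert n_used == 500
        assert rate <= 0.05 + self.BAND


class TestSimulateExperiment:
    def test_dataset_passes_schema_validation(self, tmp_path):
        from sourceguess.coding import load_events

        ds = simulate_experiment(ExperimentConfig(n_pairs=4, seed=6))
        paths = write_dataset(ds, tmp_path)
        gen = load_events(paths["generation"], "generation")
        rec = load_events(paths["recall"], "test")
        assert len(gen) == 4 * 2 * 45
        assert len({e.participant_id for e in rec}) == 8

    def test_same_seed_byte_identical_csvs(self, tmp_path):
        cfg = ExperimentConfig(n_pairs=3, seed=11)
        p1 = write_dataset(simulate_experiment(cfg), tmp_path / "a")
        p2 = write_dataset(simulate_experiment(cfg), tmp_path / "b")
        for key in ("generation", "recall"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_sidecar_records_parameters_and_seed(self, tmp_path):
        import json

        cfg = ExperimentConfig(n_pairs=2, seed=13)
        paths = write_dataset(simulate_experiment(cfg), tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == 13
        assert truth["recall"]["p_source_confusion"] == pytest.approx(0.15)
        assert set(truth["support_sizes"]) == set(
            make_action_space(cfg.space).shapes
        )

    def test_load_penalty_reduces_partner_recall_not_predictions(self):
        """Concurrent load lowers correct recall of observed actions but
        leaves the guessing-based prediction mechanism untouched: the
        dissociation the design depends on."""
        space_cfg = ActionSpaceConfig(seed=21)
        schedule = {
            s: "action_planning"
            for s in make_action_space(space_cfg).shapes
        }

        def partner_recall(penalty, seed):
            cfg = ExperimentConfig(
                space=space_cfg,
                encoding=EncodingConfig(
                    load_schedule=schedule, load_encoding_penalty=penalty
                ),
                recall=RecallConfig(p_source_confusion=0.0, guess_rate=0.0),
                n_pairs=40, seed=seed, task="recall_partner",
            )
            ds = simulate_experiment(cfg)
            pairs = {}
            for e in ds.generation:
                pairs.setdefault(e.pair_id, []).append(e)
            by_pid = {}
            for e in ds.recall:
                by_pid.setdefault(e.participant_id, []).append(e)
            total = 0
            for pid, events in by_pid.items():
                pair_id = events and next(
                    e.pair_id for e in ds.generation if e.participant_id == pid
                )
                filtered, _ = filter_pair_duplicates(pairs[pair_id])
                own, partner = encoding_sets(filtered, pid)
                counts, _ = code_recall_events(events, own, partner, "recall_partner")
                total += counts.n_correct
            return total / len(by_pid)

        assert partner_recall(0.5, 31) < 0.75 * partner_recall(1.0, 31)
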