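import math
from fractions import Fraction

import numpy as np
import pytest

import improvlearn as il
from improvlearn.synth import HIERARCHY_MULTISET, drifted_table


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        specs = [il.random_markov_spec(m, order=1, seed=9) for m in ("a", "b")]
        c1 = il.make_corpus(specs, pieces_per_musician=2, length=100)
        c2 = il.make_corpus(specs, pieces_per_musician=2, length=100)
        for p1, p2 in zip(c1.pieces, c2.pieces):
            assert tuple(p1.notes) == tuple(p2.notes)
        assert c1.truths.keys() == c2.truths.keys()
        for pid in c1.truths:
            assert c1.truths[pid].events == c2.truths[pid].events

    def test_distinct_seeds_differ(self):
        s1 = il.random_markov_spec("a", order=1, seed=1)
        s2 = il.random_markov_spec("a", order=1, seed=2)
        p1, _ = il.sample_piece(s1, 1, 100)
        p2, _ = il.sample_piece(s2, 1, 100)
        assert tuple(p1.notes) != tuple(p2.notes)


class TestDecorations:
    def test_skyline_recovers_truth_line(self):
        spec = il.random_markov_spec("m", order=1, seed=7, chord_prob=0.4, grace_prob=0.15)
        piece, truth = il.sample_piece(spec, 1, 400)
        assert il.extract_melody(piece).events == truth.events

    def test_undecorated_truth_equals_clean_spec(self):
        kwargs = dict(order=1, seed=7)
        decorated = il.random_markov_spec("m", chord_prob=0.4, grace_prob=0.15, **kwargs)
        clean = il.random_markov_spec("m", chord_prob=0.0, grace_prob=0.0, **kwargs)
        _, t_dec = il.sample_piece(decorated, 1, 300)
        _, t_clean = il.sample_piece(clean, 1, 300)
        for seq_type in (
            il.SequenceType.PITCH,
            il.SequenceType.RHYTHM,
            il.SequenceType.RHYTHM_WITH_PITCH,
        ):
            a = [w.pattern for w in il.encode(t_dec, seq_type, 2)]
            b = [w.pattern for w in il.encode(t_clean, seq_type, 2)]
            assert a == b

    def test_transposition_and_tempo_leave_relative_streams_unchanged(self):
        base = dict(order=1, seed=12, chord_prob=0.0, grace_prob=0.0)
        ref = il.random_markov_spec("m", transpositions=(0,), tempo_scales=(1.0,), **base)
        moved = il.random_markov_spec("m", transpositions=(5,), tempo_scales=(1.25,), **base)
        _, t_ref = il.sample_piece(ref, 1, 300)
        _, t_mov = il.sample_piece(moved, 1, 300)
        for seq_type in il.SequenceType:
            for order in (2, 3):
                a = [w.pattern for w in il.encode(t_ref, seq_type, order)]
                b = [w.pattern for w in il.encode(t_mov, seq_type, order)]
                assert a == b
        # documented exception: the order-1 crotchet ratio scales with tempo
        ref_iois = [b - a for (a, _), (b, _) in zip(t_ref.events, t_ref.events[1:])]
        b1 = [w.continuation[1] for w in il.encode_pitch_with_rhythm(t_mov, 1)]
        assert all(bb == round(ioi * 1.25, 3) for ioi, bb in zip(ref_iois, b1))


class TestGroundTruth:
    def test_deterministic_generator_zero_entropy(self):
        spec = il.MusicianSpec(
            musician_id="flat", order=1, pitch_tp={(0,): {0: 1.0}},
            chord_prob=0.0, grace_prob=0.0, seed=1,
        )
        _piece, truth = il.sample_piece(spec, 1, 500)
        table = il.estimate_tp(il.encode_pitch(truth, 2))
        assert il.conditional_entropy(table).entropy == pytest.approx(0.0, abs=1e-12)
        assert il.generator_entropy(spec.pitch_tp) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_generator_entropy_two_bits(self):
        table = {
            ctx: {a: 0.25 for a in (-2, -1, 1, 2)}
            for ctx in [(a,) for a in (-2, -1, 1, 2)]
        }
        assert il.generator_entropy(table) == pytest.approx(2.0, abs=1e-12)
        spec = il.MusicianSpec(
            musician_id="u", order=1, pitch_tp=table,
            chord_prob=0.0, grace_prob=0.0, seed=3,
            transpositions=(0,), tempo_scales=(1.0,),
        )
        _piece, truth = il.sample_piece(spec, 1, 20_000)
        est = il.conditional_entropy(il.estimate_tp(il.encode_pitch(truth, 2)))
        assert est.entropy == pytest.approx(2.0, abs=0.05)

    def test_stationary_distribution_sums_to_one(self):
        spec = il.random_markov_spec("m", order=2, seed=5)
        pi = il.stationary_context_distribution(spec.pitch_tp)
        assert sum(pi.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in pi.values())

    def test_window_token_mapping(self):
        table = {(2,): {-3: 0.5, 1: 0.5}, (-3,): {2: 1.0}, (1,): {2: 1.0}}
        tps = il.true_pitch_window_tps(table)
        assert tps[((0, 2), -1)] == 0.5  # context interval 2, continuation -3
        assert tps[((0, 2), 3)] == 0.5
        assert tps[((0, -3), -1)] == 1.0


class TestDrift:
    def test_drifted_table_linear_and_renormalized(self):
        table = {(0,): {0: 0.5, 1: 0.3, -1: 0.2}}
        spec = il.MusicianSpec(
            musician_id="d", order=1, pitch_tp=table, seed=1,
            drift=il.DriftSpec((0,), 1, 0.1),
        )
        d3 = drifted_table(spec, 3)
        assert d3[(0,)][1] == pytest.approx(0.5)
        assert sum(d3[(0,)].values()) == pytest.approx(1.0, abs=1e-12)
        # other continuations rescaled proportionally: 0.5 : 0.2 ratio kept
        assert d3[(0,)][0] / d3[(0,)][-1] == pytest.approx(2.5)

    def test_drift_clamped_to_unit_interval(self):
        table = {(0,): {0: 0.9, 1: 0.1}}
        spec = il.MusicianSpec(
            musician_id="d", order=1, pitch_tp=table, seed=1,
            drift=il.DriftSpec((0,), 0, 0.2),
        )
        d7 = drifted_table(spec, 7)
        assert d7[(0,)][0] == 1.0
        assert d7[(0,)][1] == 0.0

    def test_pipeline_recovers_injected_drift(self):
        spec = il.drift_spec("drifter", slope=0.06, seed=21, chord_prob=0.0, grace_prob=0.0)
        corpus = il.make_corpus([spec], pieces_per_musician=7, length=2500)
        tables = []
        for piece in corpus.pieces:
            melody = il.extract_melody(piece)
            tables.append(
                il.estimate_tp(il.encode_pitch(melody, 2), piece.piece_id, "drifter")
            )
        rank = il.top_k(il.average_tables(tables), k=5)
        chrono = {r.piece_id: r.chronological_index for r in corpus.chronology}
        response, predictors = il.chronology_predictors(tables, rank, chrono)
        result = il.stepwise_regression(response, predictors)
        drift = spec.drift
        prefix = [0]
        for step in drift.context:
            prefix.append(prefix[-1] + step)
        key = il.serialize_pattern(
            ((tuple(prefix)), prefix[-1] + drift.continuation), il.SequenceType.PITCH
        )
        assert key in result.selected
        b = result.predictors.set_index("name").loc[key, "B"]
        assert np.sign(b) == np.sign(drift.slope)


class TestHierarchySpecs:
    def test_motifs_are_permutations_of_shared_multiset(self):
        specs = il.hierarchy_specs(seed=3)
        seen = set()
        for spec in specs:
            for motif in spec.motifs:
                assert sorted(motif) == sorted(HIERARCHY_MULTISET)
                assert motif not in seen
                seen.add(motif)

    def test_unigram_interval_distribution_shared(self):
        specs = il.hierarchy_specs(seed=3)
        dists = []
        for spec in specs:
            _, truth = il.sample_piece(spec, 1, 4000)
            table = il.estimate_tp(il.encode_pitch(truth, 1))
            dists.append(table.pattern_tps())
        for other in dists[1:]:
            for key in dists[0]:
                assert other.get(key, 0.0) == pytest.approx(dists[0][key], abs=0.03)


class TestValidation:
    def test_length_too_small_rejected(self):
        spec = il.random_markov_spec("m", order=3, seed=1)
        with pytest.raises(ValueError, match="length"):
            il.sample_piece(spec, 1, 4)

    def test_duplicate_musician_ids_rejected(self):
        specs = [il.random_markov_spec("same", order=1, seed=s) for s in (1, 2)]
        with pytest.raises(ValueError, match="distinct"):
            il.make_corpus(specs, 1, 50)

    def test_spec_requires_exactly_one_pitch_model(self):
        with pytest.raises(ValueError, match="exactly one"):
            il.MusicianSpec(musician_id="x", order=1)

    def test_unnormalized_table_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            il.MusicianSpec(
                musician_id="x", order=1, pitch_tp={(0,): {0: 0.5, 1: 0.1}}
            )
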