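"""Synthetic corpus generator: ground truth, determinism, fixture round trips."""

from __future__ import annotations

import numpy as np
import pytest

from voicetp.encoding import CHAIN, windows
from voicetp.exceptions import GeneratorSpecError, PitchRangeError
from voicetp.markov import conditional_entropy, estimate_tp
from voicetp.score_io import BASS, MELODY, VoiceLine, extract_voice, parse_score
from voicetp.synthetic import (GeneratorSpec, analytic_entropy, generate_lines,
                               make_corpus, rebase_pair, sample_generator,
                               sample_interval_indices, temper_rows,
                               write_musicxml_fixture)


class TestGeneratorSpec:
    @pytest.mark.parametrize("fields", [
        {"interval_alphabet": ()},
        {"interval_alphabet": (1, 1, 2)},
        {"uncertainty_correlation": 1.5},
        {"temperature_range": (0.0, 2.0)},
        {"temperature_range": (2.0, 1.0)},
        {"base_concentration": 0.0},
        {"voice_perturbation": 0.9, "unit_noise_fraction": 0.5},
        {"tones_per_voice": 2},
        {"layout": "study2", "n_units": 12},
        {"order": 6},
    ])
    def test_invalid_specs_rejected(self, fields):
        with pytest.raises(GeneratorSpecError):
            GeneratorSpec(**fields).validate()

    def test_study2_layout_names_units_by_tonic_and_mode(self):
        spec = GeneratorSpec(layout="study2", n_units=24, tones_per_voice=32)
        corpus = sample_generator(spec)
        ids = [u.unit_id for u in corpus.units]
        assert len(ids) == 24
        assert "C-major" in ids and "C-minor" in ids
        assert sum(u.mode == "major" for u in corpus.units) == 12


class TestGroundTruth:
    def test_zero_perturbation_fixed_temperature_shares_one_generator(self):
        spec = GeneratorSpec(voice_perturbation=0.0, unit_noise_fraction=0.0,
                             temperature_range=(1.0, 1.0), n_units=3,
                             tones_per_voice=32)
        corpus = sample_generator(spec)
        for unit in corpus.units:
            assert np.allclose(unit.true_tp[MELODY], unit.true_tp[BASS])
            assert np.allclose(unit.true_tp[MELODY], corpus.base)

    def test_temperature_zero_limit_drives_entropy_to_zero(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.full(5, 0.7), size=5)
        h_cold = analytic_entropy(temper_rows(rows, 1e-3), order=1)
        h_unit = analytic_entropy(temper_rows(rows, 1.0), order=1)
        assert h_cold < 0.01 < h_unit
        assert np.allclose(temper_rows(rows, 1.0), rows)

    def test_perfect_copula_rank_correlates_entropies(self):
        spec = GeneratorSpec(uncertainty_correlation=1.0, voice_perturbation=0.0,
                             unit_noise_fraction=0.0, n_units=12, tones_per_voice=32)
        corpus = sample_generator(spec)
        hm = [u.analytic_H[MELODY] for u in corpus.units]
        hb = [u.analytic_H[BASS] for u in corpus.units]
        assert np.array_equal(np.argsort(hm), np.argsort(hb))
        for u in corpus.units:
            assert u.temperature[MELODY] == pytest.approx(u.temperature[BASS])

    def test_analytic_entropy_of_uniform_matrix(self):
        assert analytic_entropy(np.full((4, 4), 0.25), order=1) == pytest.approx(2.0)

    def test_analytic_entropy_of_permutation_matrix(self):
        P = np.eye(4)[[1, 2, 3, 0]]
        assert analytic_entropy(P, order=1) == pytest.approx(0.0)

    def test_analytic_entropy_order0_is_shannon_entropy(self):
        assert analytic_entropy(np.array([0.5, 0.25, 0.25]), order=0) == \
            pytest.approx(1.5)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(GeneratorSpecError):
            analytic_entropy(np.array([[0.5, 0.4], [0.5, 0.5]]), order=1)

    def test_analytic_matches_long_run_simulation(self):
        """Stationary-weighted row entropy equals the empirical conditional
        entropy of a million-step sample from the same chain."""
        rng = np.random.default_rng(1)
        T = rng.dirichlet(np.full(3, 0.8), size=3)
        idx = sample_interval_indices(T, order=1, n=1_000_000,
                                      rng=np.random.default_rng(2))
        pairs = list(zip(((int(i),) for i in idx[:-1]), (int(j) for j in idx[1:])))
        h_emp = conditional_entropy(estimate_tp(pairs, 1))
        assert abs(h_emp - analytic_entropy(T, order=1)) < 0.01

    def test_order2_contexts_span_two_intervals(self):
        spec = GeneratorSpec(order=2, interval_alphabet=(-1, 0, 1), n_units=2,
                             tones_per_voice=500)
        corpus = make_corpus(spec)
        mel = corpus.units[0].pieces[0][0]
        pairs = windows(mel.pitches, 2, CHAIN)
        assert all(len(ctx) == 2 for ctx, _ in pairs)
        h = conditional_entropy(estimate_tp(pairs, 2))
        assert abs(h - corpus.units[0].analytic_H[MELODY]) < 0.25


class TestGenerateLines:
    def test_seed_determinism_end_to_end(self, tmp_path):
        spec = GeneratorSpec(n_units=3, tones_per_voice=40,
                             interval_alphabet=tuple(range(-2, 3)), seed=5)
        a, b = make_corpus(spec), make_corpus(spec)
        for ua, ub in zip(a.units, b.units):
            assert [l.pitches for p in ua.pieces for l in p] == \
                [l.pitches for p in ub.pieces for l in p]
        from voicetp.synthetic import write_corpus_fixture
        m1 = write_corpus_fixture(a, tmp_path / "one")
        m2 = write_corpus_fixture(b, tmp_path / "two")
        assert m1.read_bytes() == m2.read_bytes()
        f1 = sorted((tmp_path / "one" / "scores").iterdir())
        f2 = sorted((tmp_path / "two" / "scores").iterdir())
        assert [f.read_bytes() for f in f1] == [f.read_bytes() for f in f2]

    def test_empirical_tp_approaches_truth_on_long_lines(self):
        # stepwise chain at neutral temperature: every context is visited
        # ~17k times in 50k tones, so 0.01 is a meaningful tolerance
        spec = GeneratorSpec(n_units=1, tones_per_voice=50_000, seed=9,
                             interval_alphabet=(-1, 0, 1),
                             base_concentration=1.0,
                             temperature_range=(1.0, 1.0))
        corpus = make_corpus(spec)
        unit = corpus.units[0]
        mel = unit.pieces[0][0]
        alphabet = list(corpus.alphabet)
        d = estimate_tp(windows(mel.pitches, 1, CHAIN), 1)
        T = unit.true_tp[MELODY]
        max_err = 0.0
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                max_err = max(max_err, abs(d.prob((a,), b) - T[i, j]))
        assert max_err < 0.01

    def test_pieces_split_tone_budget(self):
        spec = GeneratorSpec(n_units=2, tones_per_voice=64, pieces_per_unit=4,
                             interval_alphabet=(-1, 0, 1))
        corpus = make_corpus(spec)
        for unit in corpus.units:
            assert len(unit.pieces) == 4
            assert all(len(l.pitches) == 16 for p in unit.pieces for l in p)


class TestFixtures:
    def test_rebase_preserves_intervals_and_orders_voices(self):
        mel = [60, 48, 75]
        bas = [66, 50, 40]
        mel2, bas2 = rebase_pair(mel, bas)
        assert np.diff(mel2).tolist() == np.diff(mel).tolist()
        assert np.diff(bas2).tolist() == np.diff(bas).tolist()
        assert all(m >= b for m, b in zip(mel2, bas2))
        assert all(0 <= p <= 127 for p in mel2 + bas2)

    def test_rebase_rejects_unfittable_span(self):
        with pytest.raises(PitchRangeError):
            rebase_pair([0, 140], [0, -20])

    def _roundtrip(self, tmp_path, mel, bas, **decoys):
        pair = (VoiceLine("p1", "U1", MELODY, "major", mel),
                VoiceLine("p1", "U1", BASS, "major", bas))
        (path,) = write_musicxml_fixture([pair], tmp_path, **decoys)
        events = parse_score(path)
        return (extract_voice(events, MELODY).pitches,
                extract_voice(events, BASS).pitches)

    def test_plain_round_trip(self, tmp_path):
        mel, bas = self._roundtrip(tmp_path, [72, 74, 76], [60, 62, 64])
        assert (mel, bas) == ([72, 74, 76], [60, 62, 64])

    def test_grace_and_unison_decoys_do_not_change_lines(self, tmp_path):
        mel_in = [72 + (i % 5) for i in range(17)]
        bas_in = [48 + (i % 3) for i in range(17)]
        mel, bas = self._roundtrip(tmp_path, mel_in, bas_in,
                                   grace_decoys=True, unison_decoys=True)
        assert (mel, bas) == (mel_in, bas_in)

    def test_melody_below_bass_rejected(self, tmp_path):
        pair = (VoiceLine("p1", "U1", MELODY, "major", [50, 52]),
                VoiceLine("p1", "U1", BASS, "major", [60, 62]))
        with pytest.raises(PitchRangeError):
            write_musicxml_fixture([pair], tmp_path)

    def test_corpus_fixture_round_trip(self, tiny_corpus, tmp_path):
        """Full circle: generated lines -> files -> parsed lines identical up
        to the octave rebase (intervals exactly equal)."""
        from voicetp.score_io import load_corpus
        from voicetp.synthetic import write_corpus_fixture

        manifest = write_corpus_fixture(tiny_corpus, tmp_path,
                                        grace_decoys=True, unison_decoys=True)
        units = load_corpus(manifest)
        assert len(units) == 4
        parsed = {(l.piece_id, l.voice): l.pitches
                  for pairs in units.values() for pair in pairs for l in pair}
        for unit in tiny_corpus.units:
            for mel, bas in unit.pieces:
                assert np.diff(parsed[(mel.piece_id, MELODY)]).tolist() == \
                    np.diff(mel.pitches).tolist()
                assert np.diff(parsed[(bas.piece_id, BASS)]).tolist() == \
                    np.diff(bas.pitches).tolist()
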