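"""MusicXML parsing and highest/lowest-pitch voice extraction."""

from __future__ import annotations

from fractions import Fraction

import pytest

from voicetp.exceptions import (EmptyPieceError, ManifestError, PitchRangeError,
                                ScoreParseError)
from voicetp.score_io import (BASS, MELODY, ScoreEvent, extract_voice,
                              load_corpus, parse_score, read_manifest)

from conftest import note, rest, write_xml


def _measure(*notes: str, number: int = 1, divisions: int | None = 1) -> str:
    attrs = f"<attributes><divisions>{divisions}</divisions></attributes>" if divisions else ""
    return f'<measure number="{number}">{attrs}{"".join(notes)}</measure>'


def _part(part_id: str, *measures: str) -> str:
    return f'<part id="{part_id}">{"".join(measures)}</part>'


class TestParseScore:
    def test_chord_becomes_one_event(self, tmp_path):
        body = _part("P1", _measure(
            note("C", 4), note("E", 4, chord=True), note("G", 4, chord=True)))
        events = parse_score(write_xml(tmp_path, body))
        assert len(events) == 1
        assert events[0].pitches == frozenset({60, 64, 67})

    def test_grace_note_excluded(self, tmp_path):
        body = _part("P1", _measure(note("A", 5, grace=True), note("G", 5)))
        events = parse_score(write_xml(tmp_path, body))
        assert [set(e.pitches) for e in events] == [{79}]

    def test_simultaneous_duplicate_pitch_counted_once(self, tmp_path):
        body = (_part("P1", _measure(note("C", 4)))
                + _part("P2", _measure(note("C", 4))))
        events = parse_score(write_xml(tmp_path, body))
        assert len(events) == 1
        assert events[0].pitches == frozenset({60})

    def test_tied_continuation_is_not_a_new_onset(self, tmp_path):
        body = _part("P1", _measure(
            note("C", 4, tie="start"), note("C", 4, tie="stop"), note("D", 4)))
        events = parse_score(write_xml(tmp_path, body))
        assert [e.onset for e in events] == [Fraction(0), Fraction(2)]
        # the tied chain sounds through the D onset? no: C ends at beat 2, D starts at 2
        assert [set(e.pitches) for e in events] == [{60}, {62}]

    def test_sustained_note_included_at_later_onsets(self, tmp_path):
        body = (_part("P1", _measure(note("C", 5, duration=4)))
                + _part("P2", _measure(note("C", 3), note("D", 3), note("E", 3), note("F", 3))))
        events = parse_score(write_xml(tmp_path, body))
        assert len(events) == 4
        assert all(72 in e.pitches for e in events)
        assert [min(e.pitches) for e in events] == [48, 50, 52, 53]

    def test_rests_produce_no_events_and_no_segmentation(self, tmp_path):
        body = _part("P1", _measure(note("C", 4), rest(2), note("D", 4)))
        events = parse_score(write_xml(tmp_path, body))
        assert [e.onset for e in events] == [Fraction(0), Fraction(3)]

    def test_backup_aligns_second_voice_onsets(self, tmp_path):
        body = _part("P1", _measure(
            note("G", 4), note("A", 4),
            "<backup><duration>2</duration></backup>",
            note("C", 3), note("D", 3)))
        events = parse_score(write_xml(tmp_path, body))
        assert [e.onset for e in events] == [Fraction(0), Fraction(1)]
        assert [set(e.pitches) for e in events] == [{67, 48}, {69, 50}]

    def test_divisions_scale_onsets_to_quarter_notes(self, tmp_path):
        body = _part("P1", _measure(note("C", 4, duration=2), note("D", 4, duration=2),
                                    divisions=2))
        events = parse_score(write_xml(tmp_path, body))
        assert [e.onset for e in events] == [Fraction(0), Fraction(1)]

    def test_partwise_and_timewise_agree(self, tmp_path):
        pw = (_part("P1", _measure(note("E", 5), note("F", 5)))
              + _part("P2", _measure(note("C", 3), note("D", 3))))
        tw = ('<measure number="1">'
              '<part id="P1"><attributes><divisions>1</divisions></attributes>'
              + note("E", 5) + note("F", 5) + "</part>"
              '<part id="P2"><attributes><divisions>1</divisions></attributes>'
              + note("C", 3) + note("D", 3) + "</part>"
              "</measure>")
        ev_pw = parse_score(write_xml(tmp_path, pw, "pw.musicxml"))
        ev_tw = parse_score(write_xml(tmp_path, tw, "tw.musicxml", timewise=True))
        assert ev_pw == ev_tw

    def test_part_order_does_not_matter(self, tmp_path):
        a = (_part("P1", _measure(note("E", 5))) + _part("P2", _measure(note("C", 3))))
        b = (_part("P2", _measure(note("C", 3))) + _part("P1", _measure(note("E", 5))))
        assert parse_score(write_xml(tmp_path, a, "a.musicxml")) == \
            parse_score(write_xml(tmp_path, b, "b.musicxml"))

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.musicxml"
        path.write_text("<score-partwise><part id='P1'>")
        with pytest.raises(ScoreParseError):
            parse_score(path)

    def test_unknown_root_raises_parse_error(self, tmp_path):
        path = tmp_path / "odd.musicxml"
        path.write_text("<not-a-score/>")
        with pytest.raises(ScoreParseError):
            parse_score(path)

    def test_alter_maps_accidentals_to_semitones(self, tmp_path):
        body = _part("P1", _measure(note("C", 4, alter=1), note("E", 4, alter=-1)))
        events = parse_score(write_xml(tmp_path, body))
        assert [set(e.pitches) for e in events] == [{61}, {63}]


class TestExtractVoice:
    EVENTS = [
        ScoreEvent(Fraction(0), frozenset({60, 64, 67})),
        ScoreEvent(Fraction(1), frozenset({59, 62, 67})),
        ScoreEvent(Fraction(2), frozenset({60, 64})),
    ]

    def test_melody_takes_per_event_maximum(self):
        assert extract_voice(self.EVENTS, MELODY).pitches == [67, 67, 64]

    def test_bass_takes_per_event_minimum(self):
        assert extract_voice(self.EVENTS, BASS).pitches == [60, 59, 60]

    def test_monophonic_line_gives_identical_voices(self):
        events = [ScoreEvent(Fraction(t), frozenset({p}))
                  for t, p in enumerate([60, 62, 64])]
        assert extract_voice(events, MELODY).pitches == \
            extract_voice(events, BASS).pitches == [60, 62, 64]

    def test_melody_never_below_bass(self, tmp_path):
        body = (_part("P1", _measure(note("C", 5), note("B", 4), note("A", 4)))
                + _part("P2", _measure(note("E", 3), note("F", 3), note("G", 3))))
        events = parse_score(write_xml(tmp_path, body))
        mel = extract_voice(events, MELODY).pitches
        bas = extract_voice(events, BASS).pitches
        assert all(m >= b for m, b in zip(mel, bas))

    def test_empty_events_raise_with_piece_id(self):
        with pytest.raises(EmptyPieceError, match="op111"):
            extract_voice([], MELODY, piece_id="op111")


class TestManifestAndCorpus:
    def _write_corpus(self, tmp_path, n_units=2, pieces_per_unit=2, mode="minor"):
        rows = ["path,piece_id,unit_id,mode"]
        for u in range(n_units):
            for k in range(pieces_per_unit):
                body = (_part("P1", _measure(note("E", 5), note("G", 5)))
                        + _part("P2", _measure(note("C", 3), note("D", 3))))
                path = write_xml(tmp_path, body, f"u{u}p{k}.musicxml")
                rows.append(f"{path.name},u{u}p{k},No{u + 1},{mode}")
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("\n".join(rows) + "\n")
        return manifest

    def test_grouping_preserves_manifest_order_and_counts(self, tmp_path):
        manifest = self._write_corpus(tmp_path)
        units = load_corpus(manifest)
        assert list(units) == ["No1", "No2"]
        assert all(len(pairs) == 2 for pairs in units.values())
        mel, bas = units["No1"][0]
        assert (mel.voice, bas.voice) == (MELODY, BASS)

    def test_mode_label_propagates_to_all_lines(self, tmp_path):
        manifest = self._write_corpus(tmp_path, mode="minor")
        units = load_corpus(manifest)
        assert all(line.mode == "minor"
                   for pairs in units.values() for pair in pairs for line in pair)

    def test_missing_file_is_a_hard_error(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("path,piece_id,unit_id,mode\nnope.musicxml,x,No1,major\n")
        with pytest.raises(ManifestError, match="nope"):
            read_manifest(manifest)

    def test_invalid_mode_rejected(self, tmp_path):
        body = _part("P1", _measure(note("C", 4)))
        score = write_xml(tmp_path, body)
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(f"path,piece_id,unit_id,mode\n{score.name},x,No1,dorian\n")
        with pytest.raises(ManifestError, match="dorian"):
            read_manifest(manifest)

    def test_parse_failure_skip_or_abort(self, tmp_path):
        good = write_xml(tmp_path, _part("P1", _measure(note("C", 4))), "good.musicxml")
        bad = tmp_path / "bad.musicxml"
        bad.write_text("<score-partwise><part id='P1'>")
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("path,piece_id,unit_id,mode\n"
                            f"{good.name},g,No1,major\n{bad.name},b,No1,major\n")
        with pytest.raises(ScoreParseError):
            load_corpus(manifest, on_parse_error="abort")
        units = load_corpus(manifest, on_parse_error="skip")
        assert len(units["No1"]) == 1

    def test_keyboard_range_enforced(self, tmp_path):
        body = _part("P1", _measure(note("C", 8)))  # MIDI 108
        score = write_xml(tmp_path, body)
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(f"path,piece_id,unit_id,mode\n{score.name},x,No1,major\n")
        with pytest.raises(PitchRangeError):
            load_corpus(manifest, keyboard_range=(21, 96))
        assert load_corpus(manifest, keyboard_range=(21, 108))
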