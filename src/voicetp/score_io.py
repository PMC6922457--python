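"""Read MusicXML scores and extract melody (highest-pitch) and bass
(lowest-pitch) event sequences.

The melody and bass line of a polyphonic score are operationalized as the
highest and lowest pitches *playable at a given point in time*.  "A point in
time" is every onset at which at least one non-grace note begins; the
sounding set at that onset includes notes sustained from earlier onsets.
Grace notes are excluded, simultaneous duplicate pitches are counted once,
and a tied continuation is one playable note, not a new onset.  Rests
generate no events and do not segment a piece: each file yields one event
sequence.

Both the partwise and timewise MusicXML dialects are accepted, as are
compressed ``.mxl`` archives.  Mode (major/minor) labels are never inferred
from key signatures — a key signature does not identify mode — they come
from the corpus manifest, a CSV with header ``path,piece_id,unit_id,mode``.
"""

from __future__ import annotations

import csv
import io
import logging
import zipfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from lxml import etree

from .exceptions import EmptyPieceError, ManifestError, PitchRangeError, ScoreParseError

log = logging.getLogger(__name__)

MELODY = "melody"
BASS = "bass"
VOICES = (MELODY, BASS)
MODES = ("major", "minor", "unknown")

_STEP_SEMITONES = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


@dataclass(frozen=True)
class ScoreEvent:
    """All distinct pitches sounding at one onset (quarter-note units)."""

    onset: Fraction
    pitches: frozenset[int]


@dataclass
class VoiceLine:
    """Ordered pitch sequence for one piece and one voice role."""

    piece_id: str
    unit_id: str
    voice: str
    mode: str
    pitches: list[int]


@dataclass(frozen=True)
class ManifestRow:
    path: Path
    piece_id: str
    unit_id: str
    mode: str


@dataclass
class _Note:
    start: Fraction
    end: Fraction
    pitch: int


@dataclass
class _ParseStats:
    events: int = 0
    grace_dropped: int = 0
    duplicates_collapsed: int = 0
    unpitched_skipped: int = 0


def _midi_pitch(note_el: etree._Element, path: str) -> int:
    pitch = note_el.find("pitch")
    step = pitch.findtext("step")
    octave = pitch.findtext("octave")
    if step is None or octave is None or step not in _STEP_SEMITONES:
        raise ScoreParseError(f"{path}: <pitch> missing or invalid <step>/<octave>")
    alter = pitch.findtext("alter")
    return (int(octave) + 1) * 12 + _STEP_SEMITONES[step] + (int(round(float(alter))) if alter else 0)


def _load_root(path: Path) -> etree._Element:
    try:
        if path.suffix.lower() == ".mxl":
            with zipfile.ZipFile(path) as zf:
                names = [n for n in zf.namelist()
                         if not n.startswith("META-INF") and n.lower().endswith((".xml", ".musicxml"))]
                if not names:
                    raise ScoreParseError(f"{path}: no score XML inside .mxl archive")
                data = zf.read(names[0])
            return etree.parse(io.BytesIO(data)).getroot()
        return etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ScoreParseError(f"{path}: malformed XML ({exc})") from exc
    except (OSError, zipfile.BadZipFile) as exc:
        raise ScoreParseError(f"{path}: cannot read score ({exc})") from exc


def _parts_in_document_order(root: etree._Element, path: str) -> dict[str, list[etree._Element]]:
    """Map part id -> list of its <measure> elements, for either dialect."""
    tag = etree.QName(root).localname if isinstance(root.tag, str) else None
    parts: dict[str, list[etree._Element]] = {}
    if tag == "score-partwise":
        for part in root.iterchildren("part"):
            parts.setdefault(part.get("id", f"P{len(parts) + 1}"), []).extend(
                part.iterchildren("measure"))
    elif tag == "score-timewise":
        for measure in root.iterchildren("measure"):
            for part in measure.iterchildren("part"):
                parts.setdefault(part.get("id", f"P{len(parts) + 1}"), []).append(part)
    else:
        raise ScoreParseError(
            f"{path}: root element <{root.tag}> is neither score-partwise nor score-timewise")
    if not parts:
        raise ScoreParseError(f"{path}: score contains no parts")
    return parts


def _parse_part(
    part_id: str,
    measures: list[etree._Element],
    path: str,
    stats: _ParseStats,
) -> list[_Note]:
    notes: list[_Note] = []
    open_ties: dict[int, _Note] = {}
    divisions = 1
    measure_start = Fraction(0)

    for measure in measures:
        pos = Fraction(0)
        max_pos = Fraction(0)
        last_onset: Fraction | None = None
        for el in measure.iterchildren():
            tag = el.tag if isinstance(el.tag, str) else None
            if tag == "attributes":
                div = el.findtext("divisions")
                if div is not None:
                    divisions = int(div)
                    if divisions <= 0:
                        raise ScoreParseError(f"{path}: non-positive <divisions>")
            elif tag in ("backup", "forward"):
                dur_text = el.findtext("duration")
                dur = Fraction(int(dur_text), divisions) if dur_text else Fraction(0)
                pos = pos - dur if tag == "backup" else pos + dur
                if pos < 0:
                    pos = Fraction(0)
                max_pos = max(max_pos, pos)
            elif tag == "note":
                is_grace = el.find("grace") is not None
                is_chord = el.find("chord") is not None
                is_rest = el.find("rest") is not None
                dur_text = el.findtext("duration")
                dur = Fraction(int(dur_text), divisions) if dur_text else Fraction(0)
                if is_grace:
                    if not is_rest and el.find("pitch") is not None:
                        stats.grace_dropped += 1
                    continue  # grace notes have no duration and no event
                onset = (last_onset if (is_chord and last_onset is not None)
                         else measure_start + pos)
                if not is_chord:
                    last_onset = onset
                    pos += dur
                    max_pos = max(max_pos, pos)
                if is_rest:
                    continue
                if el.find("pitch") is None:
                    stats.unpitched_skipped += 1
                    log.warning("%s: skipping unpitched note in part %s", path, part_id)
                    continue
                midi = _midi_pitch(el, path)
                ties = {t.get("type") for t in el.findall("tie")}
                if "stop" in ties and midi in open_ties:
                    prev = open_ties[midi]
                    prev.end = max(prev.end, onset + dur)
                    if "start" not in ties:
                        del open_ties[midi]
                    continue  # tied continuation: not a new onset
                note = _Note(start=onset, end=onset + dur, pitch=midi)
                notes.append(note)
                if "start" in ties:
                    open_ties[midi] = note
        measure_start += max_pos
    return notes


def parse_score(path: str | Path) -> list[ScoreEvent]:
    """Parse one MusicXML file into a time-ordered list of pitch events.

    One :class:`ScoreEvent` per distinct onset at which at least one
    non-grace note starts; its pitch set holds every non-grace pitch sounding
    at that onset (sustained notes included, tied chains merged, duplicates
    collapsed).
    """
    path = Path(path)
    root = _load_root(path)
    parts = _parts_in_document_order(root, str(path))
    stats = _ParseStats()

    notes: list[_Note] = []
    for part_id, measures in parts.items():
        notes.extend(_parse_part(part_id, measures, str(path), stats))

    onsets = sorted({n.start for n in notes})
    events: list[ScoreEvent] = []
    for t in onsets:
        sounding = [n.pitch for n in notes if n.start <= t and (t < n.end or n.start == t)]
        pitches = frozenset(sounding)
        if not pitches:
            continue
        stats.duplicates_collapsed += len(sounding) - len(pitches)
        events.append(ScoreEvent(onset=t, pitches=pitches))
    stats.events = len(events)
    log.info(
        "%s: %d events, %d grace notes dropped, %d duplicate pitches collapsed, %d unpitched skipped",
        path, stats.events, stats.grace_dropped, stats.duplicates_collapsed,
        stats.unpitched_skipped,
    )
    return events


def extract_voice(
    events: list[ScoreEvent],
    which: str,
    piece_id: str = "",
    unit_id: str = "",
    mode: str = "unknown",
) -> VoiceLine:
    """Reduce events to the highest- (melody) or lowest- (bass) pitch line.

    Consecutive equal pitches are retained — they encode interval 0.
    """
    if which not in VOICES:
        raise ValueError(f"voice must be one of {VOICES}, got {which!r}")
    if not events:
        raise EmptyPieceError(f"piece {piece_id!r} produced no pitch events")
    pick = max if which == MELODY else min
    return VoiceLine(
        piece_id=piece_id,
        unit_id=unit_id,
        voice=which,
        mode=mode,
        pitches=[pick(e.pitches) for e in events],
    )


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """Read and validate a corpus manifest CSV (``path,piece_id,unit_id,mode``).

    Relative score paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"path", "piece_id", "unit_id", "mode"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"{path}: manifest header must contain {sorted(required)}, "
                f"got {reader.fieldnames}")
        for i, row in enumerate(reader, start=2):
            unit = (row["unit_id"] or "").strip()
            mode = (row["mode"] or "unknown").strip().lower()
            if not unit:
                raise ManifestError(f"{path}:{i}: empty unit_id")
            if mode not in MODES:
                raise ManifestError(f"{path}:{i}: mode {mode!r} not in {MODES}")
            score = Path(row["path"])
            if not score.is_absolute():
                score = path.parent / score
            if not score.exists():
                raise ManifestError(f"{path}:{i}: score file missing: {score}")
            rows.append(ManifestRow(path=score, piece_id=row["piece_id"].strip() or score.stem,
                                    unit_id=unit, mode=mode))
    if not rows:
        raise ManifestError(f"{path}: manifest has no rows")
    return rows


def load_corpus(
    manifest: str | Path | list[ManifestRow],
    on_parse_error: str = "abort",
    keyboard_range: tuple[int, int] = (0, 127),
) -> dict[str, list[tuple[VoiceLine, VoiceLine]]]:
    """Load every score in a manifest into (melody, bass) line pairs per unit.

    Grouping preserves manifest order.  ``on_parse_error`` is ``"abort"``
    (default) or ``"skip"``; a *missing* file is always a hard error (raised
    by :func:`read_manifest`).  Pitches outside ``keyboard_range`` raise
    :class:`PitchRangeError`.
    """
    if on_parse_error not in ("abort", "skip"):
        raise ValueError("on_parse_error must be 'abort' or 'skip'")
    rows = manifest if isinstance(manifest, list) else read_manifest(manifest)
    lo, hi = keyboard_range
    units: dict[str, list[tuple[VoiceLine, VoiceLine]]] = {}
    for row in rows:
        try:
            events = parse_score(row.path)
            melody = extract_voice(events, MELODY, row.piece_id, row.unit_id, row.mode)
            bass = extract_voice(events, BASS, row.piece_id, row.unit_id, row.mode)
        except (ScoreParseError, EmptyPieceError) as exc:
            if on_parse_error == "skip":
                log.warning("skipping %s: %s", row.path, exc)
                continue
            raise
        for line in (melody, bass):
            bad = [p for p in line.pitches if not lo <= p <= hi]
            if bad:
                raise PitchRangeError(
                    f"{row.piece_id}: {len(bad)} pitches outside configured range "
                    f"[{lo}, {hi}] (e.g. {bad[0]})")
        units.setdefault(row.unit_id, []).append((melody, bass))
    return units
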