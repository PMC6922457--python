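"""Shared fixtures: handcrafted MusicXML snippets and small synthetic corpora."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest
from hypothesis import settings

from voicetp.synthetic import GeneratorSpec, make_corpus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def write_xml(tmp_path: Path, body: str, name: str = "score.musicxml",
              timewise: bool = False) -> Path:
    """Wrap measure/part markup in a score skeleton and write it to disk."""
    tag = "score-timewise" if timewise else "score-partwise"
    doc = textwrap.dedent(f"""\
        <?xml version="1.0" encoding="UTF-8"?>
        <{tag} version="3.1">
          <part-list>
            <score-part id="P1"><part-name>One</part-name></score-part>
            <score-part id="P2"><part-name>Two</part-name></score-part>
          </part-list>
        {body}
        </{tag}>
        """)
    path = tmp_path / name
    path.write_text(doc)
    return path


def note(step: str, octave: int, duration: int = 1, alter: int | None = None,
         chord: bool = False, grace: bool = False, tie: str | None = None) -> str:
    parts = ["<note>"]
    if grace:
        parts.append("<grace/>")
    if chord:
        parts.append("<chord/>")
    alter_el = f"<alter>{alter}</alter>" if alter is not None else ""
    parts.append(f"<pitch><step>{step}</step>{alter_el}<octave>{octave}</octave></pitch>")
    if not grace:
        parts.append(f"<duration>{duration}</duration>")
    if tie in ("start", "stop"):
        parts.append(f'<tie type="{tie}"/>')
    elif tie == "both":
        parts.append('<tie type="stop"/><tie type="start"/>')
    parts.append("</note>")
    return "".join(parts)


def rest(duration: int = 1) -> str:
    return f"<note><rest/><duration>{duration}</duration></note>"


@pytest.fixture(scope="session")
def tiny_corpus():
    """4-unit, 2-pieces-per-unit corpus with short lines, safe to write as files."""
    spec = GeneratorSpec(order=1, interval_alphabet=tuple(range(-3, 4)),
                         n_units=4, tones_per_voice=64, pieces_per_unit=2,
                         temperature_range=(0.8, 1.2), uncertainty_correlation=0.5,
                         seed=11)
    return make_corpus(spec)


@pytest.fixture(scope="session")
def study2_corpus():
    """24-unit corpus shaped like a prelude/fugue-per-key collection."""
    spec = GeneratorSpec(order=1, n_units=24, layout="study2",
                         tones_per_voice=800, pieces_per_unit=1,
                         uncertainty_correlation=0.6, seed=7)
    return make_corpus(spec)
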