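"""Synthetic two-voice corpora with known Markov ground truth.

The generator emulates the structure the corpus analysis assumes: every
(unit, voice) sequence is driven by an order-n Markov chain over a common
interval alphabet, where each chain is

* a corpus-wide **base** transition matrix (rows drawn from a Dirichlet),
  shared by all units and both voices — the "general" structure;
* perturbed by a **voice-level** Dirichlet noise matrix (one per voice,
  shared across units) — systematic melody/bass differences — and a smaller
  **unit-level** noise matrix — per-piece idiosyncrasy;
* finally sharpened or flattened row-wise by a per-unit **temperature**
  (``row ∝ mixed_row ** (1/tau)``), the knob that moves conditional entropy
  monotonically while preserving support.  The melody and bass temperatures
  of a unit are coupled through a Gaussian copula on log-temperature with
  correlation ``uncertainty_correlation``, giving a controllable cross-voice
  entropy correlation.

Each unit therefore has a true transition matrix and a closed-form
conditional entropy (stationary-weighted row entropy), against which the
empirical pipeline estimates can be checked.  Pitch lines are cumulative sums
of sampled intervals; absolute register is immaterial to the (transposition
invariant) analysis, so long in-memory lines are not range-clipped.  MusicXML
fixture writing *does* enforce MIDI range and melody >= bass, octave-shifting
lines (interval-preserving) where needed.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from lxml import etree

from .exceptions import GeneratorSpecError, PitchRangeError
from .score_io import BASS, MELODY, VoiceLine

log = logging.getLogger(__name__)

_TONICS = ("C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B")

STUDY1, STUDY2 = "study1", "study2"


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of a synthetic corpus; all randomness flows from ``seed``.

    Defaults describe the reference condition used throughout the test
    suite: order-1 interval chains on the alphabet -6..+6 semitones, a spiky
    shared base (Dirichlet concentration 0.5), voice perturbation 0.15 with a
    fifth of that as unit-level noise, temperatures log-normal with central
    95% range 0.4-2.5 and cross-voice copula correlation 0.8, 32 units of
    5000 tones per voice.
    """

    order: int = 1
    interval_alphabet: tuple[int, ...] = tuple(range(-6, 7))
    base_concentration: float = 0.5
    voice_perturbation: float = 0.15
    unit_noise_fraction: float = 0.2
    uncertainty_correlation: float = 0.8
    temperature_range: tuple[float, float] = (0.4, 2.5)
    n_units: int = 32
    tones_per_voice: int = 5000
    pieces_per_unit: int = 1
    layout: str = STUDY1
    seed: int = 0

    def validate(self) -> None:
        if not self.interval_alphabet:
            raise GeneratorSpecError("interval_alphabet must be nonempty")
        if len(set(self.interval_alphabet)) != len(self.interval_alphabet):
            raise GeneratorSpecError("interval_alphabet has duplicates")
        if not 0 <= self.order <= 5:
            raise GeneratorSpecError("order must be in 0..5")
        if self.base_concentration <= 0:
            raise GeneratorSpecError("base_concentration must be positive")
        if not -1.0 <= self.uncertainty_correlation <= 1.0:
            raise GeneratorSpecError("uncertainty_correlation must be in [-1, 1]")
        lo, hi = self.temperature_range
        if lo <= 0 or hi < lo:
            raise GeneratorSpecError("temperature_range must be a positive interval")
        eps = self.voice_perturbation * (1.0 + self.unit_noise_fraction)
        if self.voice_perturbation < 0 or self.unit_noise_fraction < 0 or eps >= 1.0:
            raise GeneratorSpecError("perturbation weights must be nonnegative and sum below 1")
        if self.tones_per_voice <= self.order + 1:
            raise GeneratorSpecError("tones_per_voice must exceed order + 1")
        if self.n_units < 1 or self.pieces_per_unit < 1:
            raise GeneratorSpecError("n_units and pieces_per_unit must be >= 1")
        if self.layout not in (STUDY1, STUDY2):
            raise GeneratorSpecError(f"layout must be '{STUDY1}' or '{STUDY2}'")
        if self.layout == STUDY2 and self.n_units != 24:
            raise GeneratorSpecError("study2 layout requires n_units = 24 (12 tonics x 2 modes)")
        n_states = len(self.interval_alphabet) ** max(self.order, 1)
        if n_states > 20000:
            raise GeneratorSpecError(
                f"{n_states} context states; reduce order or alphabet size")


def _unit_labels(spec: GeneratorSpec) -> list[tuple[str, str]]:
    if spec.layout == STUDY2:
        return [(f"{t}-{m}", m) for t in _TONICS for m in ("major", "minor")]
    half = spec.n_units // 2
    return [(f"No{i + 1:02d}", "major" if i < half else "minor")
            for i in range(spec.n_units)]


def temper_rows(matrix: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise exponent tilting ``row ∝ row ** (1/tau)``, renormalized.

    ``tau -> 0`` approaches a deterministic (one-hot) chain; ``tau > 1``
    flattens rows toward uniform.
    """
    if tau <= 0:
        raise GeneratorSpecError("temperature must be positive")
    logm = np.log(np.clip(matrix, 1e-300, None)) / tau
    logm -= logm.max(axis=-1, keepdims=True)
    out = np.exp(logm)
    return out / out.sum(axis=-1, keepdims=True)


@dataclass
class SyntheticUnit:
    unit_id: str
    mode: str
    temperature: dict[str, float]
    true_tp: dict[str, np.ndarray]
    analytic_H: dict[str, float]
    pieces: list[tuple[VoiceLine, VoiceLine]] = field(default_factory=list)


@dataclass
class SyntheticCorpus:
    spec: GeneratorSpec
    alphabet: tuple[int, ...]
    base: np.ndarray
    units: list[SyntheticUnit]


def sample_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> SyntheticCorpus:
    """Draw the base/voice/unit transition matrices and temperatures.

    Returns a corpus whose units carry true matrices and analytic entropies
    but no sampled lines yet (see :func:`generate_lines`).
    """
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    K = len(spec.interval_alphabet)
    S = K ** max(spec.order, 1) if spec.order >= 1 else 1
    shape = (S, K) if spec.order >= 1 else (K,)

    def draw(conc: float) -> np.ndarray:
        return rng.dirichlet(np.full(K, conc), size=shape[:-1] or None).reshape(shape)

    base = draw(spec.base_concentration)
    voice_noise = {v: draw(spec.base_concentration) for v in (MELODY, BASS)}

    eps_v = spec.voice_perturbation
    eps_u = spec.voice_perturbation * spec.unit_noise_fraction
    lo, hi = np.log(spec.temperature_range)
    mu, sigma = (lo + hi) / 2.0, (hi - lo) / 4.0
    rho = spec.uncertainty_correlation

    units: list[SyntheticUnit] = []
    for unit_id, mode in _unit_labels(spec):
        z_m = rng.standard_normal()
        z_b = rho * z_m + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
        taus = {MELODY: float(np.exp(mu + sigma * z_m)),
                BASS: float(np.exp(mu + sigma * z_b))}
        true_tp: dict[str, np.ndarray] = {}
        analytic: dict[str, float] = {}
        for voice in (MELODY, BASS):
            mixed = ((1.0 - eps_v - eps_u) * base
                     + eps_v * voice_noise[voice]
                     + eps_u * draw(spec.base_concentration))
            mat = temper_rows(mixed, taus[voice])
            true_tp[voice] = mat
            analytic[voice] = analytic_entropy(mat, spec.order)
        units.append(SyntheticUnit(unit_id=unit_id, mode=mode, temperature=taus,
                                   true_tp=true_tp, analytic_H=analytic))
    return SyntheticCorpus(spec=spec, alphabet=tuple(spec.interval_alphabet),
                           base=base, units=units)


def stationary_distribution(P: np.ndarray) -> tuple[np.ndarray, bool]:
    """Stationary distribution of a row-stochastic matrix.

    Returns ``(pi, exact)``; when no clean unit-eigenvector exists (reducible
    or periodic chain), falls back to uniform weights with ``exact=False``.
    """
    S = P.shape[0]
    eigvals, eigvecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    if abs(eigvals[idx] - 1.0) < 1e-9:
        v = np.real(eigvecs[:, idx])
        if abs(v.sum()) > 1e-12:
            v = v / v.sum()
            if np.all(v > -1e-10):
                v = np.clip(v, 0.0, None)
                return v / v.sum(), True
    # power-iteration fallback
    pi = np.full(S, 1.0 / S)
    for _ in range(10000):
        nxt = pi @ P
        if np.max(np.abs(nxt - pi)) < 1e-13:
            return nxt / nxt.sum(), True
        pi = nxt
    log.warning("stationary distribution did not converge; using uniform context weights")
    return np.full(S, 1.0 / S), False


def analytic_entropy(tp: np.ndarray, order: int) -> float:
    """Closed-form conditional entropy (bits) of a true transition model.

    Context weights are the stationary distribution of the context chain
    (uniform, with a warning, if the chain has no clean stationary vector).
    For order 0 the model is an i.i.d. interval distribution and this is its
    plain Shannon entropy.
    """
    tp = np.asarray(tp, dtype=float)
    if order == 0:
        p = tp.reshape(-1)
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise GeneratorSpecError("order-0 distribution does not sum to 1")
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    S, K = tp.shape
    if not np.allclose(tp.sum(axis=1), 1.0, atol=1e-8):
        raise GeneratorSpecError("transition matrix rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(tp > 0, np.log2(np.where(tp > 0, tp, 1.0)), 0.0)
    row_h = -(tp * logs).sum(axis=1)
    if S == K and order == 1:
        pi, _ = stationary_distribution(tp)
    else:
        # context chain: state (d1..dn) -> (d2..dn, j) with prob tp[state, j]
        mod = S // K
        P = np.zeros((S, S))
        for s in range(S):
            nxt_base = (s % mod) * K
            for j in range(K):
                P[s, nxt_base + j] += tp[s, j]
        pi, _ = stationary_distribution(P)
    return float(pi @ row_h)


def sample_interval_indices(
    tp: np.ndarray, order: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` interval indices from a true chain (uniform random start)."""
    K = tp.shape[-1]
    if order == 0:
        return rng.choice(K, size=n, p=np.asarray(tp).reshape(-1))
    S = tp.shape[0]
    cum = np.cumsum(tp, axis=1)
    cum[:, -1] = 1.0
    rows = cum.tolist()
    mod = S // K
    s = int(rng.integers(S))
    us = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    for t in range(n):
        j = bisect_right(rows[s], us[t])
        if j >= K:
            j = K - 1
        out[t] = j
        s = (s % mod) * K + j
    return out


def generate_lines(
    corpus: SyntheticCorpus, rng: np.random.Generator | None = None
) -> SyntheticCorpus:
    """Sample pitch lines for every unit of a sampled generator, in place.

    The unit's tone budget is split evenly over ``pieces_per_unit`` pieces,
    all driven by the same true matrices (so per-unit pooling across pieces
    re-estimates the unit model).  Melody lines start at pitch 72, bass at 48.
    """
    spec = corpus.spec
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    alphabet = np.asarray(corpus.alphabet)
    tones_per_piece = spec.tones_per_voice // spec.pieces_per_unit
    if tones_per_piece <= spec.order + 1:
        raise GeneratorSpecError("tones per piece must exceed order + 1; fewer pieces needed")
    starts = {MELODY: 72, BASS: 48}
    for unit in corpus.units:
        unit.pieces = []
        for k in range(spec.pieces_per_unit):
            piece_id = f"{unit.unit_id}_p{k + 1}"
            lines = {}
            for voice in (MELODY, BASS):
                idx = sample_interval_indices(
                    unit.true_tp[voice], spec.order, tones_per_piece - 1, rng)
                pitches = starts[voice] + np.concatenate(
                    ([0], np.cumsum(alphabet[idx])))
                lines[voice] = VoiceLine(
                    piece_id=piece_id, unit_id=unit.unit_id, voice=voice,
                    mode=unit.mode, pitches=[int(p) for p in pitches])
            unit.pieces.append((lines[MELODY], lines[BASS]))
    return corpus


def make_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Sample generators and lines in one deterministic, seed-driven call."""
    rng = np.random.default_rng(spec.seed)
    corpus = sample_generator(spec, rng)
    return generate_lines(corpus, rng)


# ---------------------------------------------------------------------------
# MusicXML fixture writing
# ---------------------------------------------------------------------------

_SEMITONE_SPELLING = {
    0: ("C", 0), 1: ("C", 1), 2: ("D", 0), 3: ("E", -1), 4: ("E", 0), 5: ("F", 0),
    6: ("F", 1), 7: ("G", 0), 8: ("A", -1), 9: ("A", 0), 10: ("B", -1), 11: ("B", 0),
}


def rebase_pair(melody: list[int], bass: list[int]) -> tuple[list[int], list[int]]:
    """Octave-shift a line pair so melody >= bass pointwise within MIDI 0..127.

    Whole-octave shifts preserve every interval, hence all downstream
    statistics.  Raises :class:`PitchRangeError` when the combined span cannot
    fit the MIDI range (use shorter lines or a narrower interval alphabet).
    """
    if len(melody) != len(bass):
        raise ValueError("melody and bass lines must have equal length")

    def octave_bounds(line: list[int], label: str) -> tuple[int, int]:
        if max(line) - min(line) > 127:
            raise PitchRangeError(
                f"{label} line spans {max(line) - min(line)} semitones; does not "
                "fit MIDI range — use shorter lines or a narrower alphabet")
        # smallest/largest whole-octave shift keeping the line in MIDI 0..127
        lo = -(min(line) // 12)              # ceil(-min/12)
        hi = (127 - max(line)) // 12         # floor((127-max)/12)
        return lo, hi

    s_lo, s_hi = octave_bounds(melody, "melody")
    t_lo, t_hi = octave_bounds(bass, "bass")
    worst_gap = max(b - m for m, b in zip(melody, bass))
    need = -(-worst_gap // 12)  # s - t >= need octaves (negative gap gives slack)
    s = min(max(0, s_lo), s_hi)
    t = min(max(0, t_lo), t_hi)
    if s - t < need:
        s = min(s_hi, t + need)
    if s - t < need:
        t = max(t_lo, s - need)
    if s - t < need:
        raise PitchRangeError(
            "voices cannot be octave-separated within MIDI range "
            f"(worst melody-bass gap {worst_gap} semitones) — use shorter "
            "lines or a wider start separation")
    return [m + 12 * s for m in melody], [b + 12 * t for b in bass]


def _pitch_element(note: etree._Element, midi: int) -> None:
    step, alter = _SEMITONE_SPELLING[midi % 12]
    pitch = etree.SubElement(note, "pitch")
    etree.SubElement(pitch, "step").text = step
    if alter:
        etree.SubElement(pitch, "alter").text = str(alter)
    etree.SubElement(pitch, "octave").text = str(midi // 12 - 1)


def _part_measures(part: etree._Element, pitches: list[int],
                   grace_decoys: bool, unison_decoys: bool) -> None:
    for m_start in range(0, len(pitches), 4):
        measure = etree.SubElement(part, "measure", number=str(m_start // 4 + 1))
        if m_start == 0:
            attrs = etree.SubElement(measure, "attributes")
            etree.SubElement(attrs, "divisions").text = "1"
            time = etree.SubElement(attrs, "time")
            etree.SubElement(time, "beats").text = "4"
            etree.SubElement(time, "beat-type").text = "4"
        for i in range(m_start, min(m_start + 4, len(pitches))):
            midi = pitches[i]
            if grace_decoys and i % 5 == 2:
                grace = etree.SubElement(measure, "note")
                etree.SubElement(grace, "grace")
                _pitch_element(grace, min(midi + 2, 127))
                etree.SubElement(grace, "type").text = "eighth"
            note = etree.SubElement(measure, "note")
            _pitch_element(note, midi)
            etree.SubElement(note, "duration").text = "1"
            etree.SubElement(note, "type").text = "quarter"
            if unison_decoys and i % 7 == 3:
                dup = etree.SubElement(measure, "note")
                etree.SubElement(dup, "chord")
                _pitch_element(dup, midi)
                etree.SubElement(dup, "duration").text = "1"
                etree.SubElement(dup, "type").text = "quarter"
        pad = m_start + 4 - len(pitches)
        if pad > 0:
            rest = etree.SubElement(measure, "note")
            etree.SubElement(rest, "rest")
            etree.SubElement(rest, "duration").text = str(pad)


def write_musicxml_fixture(
    pairs: list[tuple[VoiceLine, VoiceLine]],
    out_dir: str | Path,
    grace_decoys: bool = False,
    unison_decoys: bool = False,
) -> list[Path]:
    """Write one minimal two-part MusicXML file per (melody, bass) pair.

    One quarter note per event; optional grace-note and doubled-unison
    decorations exercise the parser's filters without changing the event
    stream.  Requires melody >= bass pointwise and MIDI-range pitches (see
    :func:`rebase_pair`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for melody, bass in pairs:
        if len(melody.pitches) != len(bass.pitches):
            raise ValueError(f"{melody.piece_id}: melody and bass lengths differ")
        for m, b in zip(melody.pitches, bass.pitches):
            if m < b:
                raise PitchRangeError(
                    f"{melody.piece_id}: melody below bass at some onset; rebase first")
            if not (0 <= b and m <= 127):
                raise PitchRangeError(
                    f"{melody.piece_id}: pitches outside MIDI 0..127; rebase or "
                    "use shorter lines / a wider range")
        root = etree.Element("score-partwise", version="3.1")
        part_list = etree.SubElement(root, "part-list")
        for pid, name in (("P1", "Melody"), ("P2", "Bass")):
            sp = etree.SubElement(part_list, "score-part", id=pid)
            etree.SubElement(sp, "part-name").text = name
        _part_measures(etree.SubElement(root, "part", id="P1"), melody.pitches,
                       grace_decoys, unison_decoys=False)
        _part_measures(etree.SubElement(root, "part", id="P2"), bass.pitches,
                       grace_decoys=False, unison_decoys=unison_decoys)
        path = out_dir / f"{melody.piece_id}.musicxml"
        etree.ElementTree(root).write(str(path), xml_declaration=True,
                                      encoding="UTF-8", pretty_print=True)
        paths.append(path)
    return paths


def write_corpus_fixture(
    corpus: SyntheticCorpus,
    out_dir: str | Path,
    grace_decoys: bool = False,
    unison_decoys: bool = False,
) -> Path:
    """Write a corpus as MusicXML files + manifest CSV + ground-truth CSVs.

    Lines are octave-rebased to satisfy the fixture constraints (interval
    statistics unchanged).  Returns the manifest path.
    """
    import csv as _csv

    out_dir = Path(out_dir)
    scores = out_dir / "scores"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    rows = []
    for unit in corpus.units:
        for melody, bass in unit.pieces:
            mel_p, bas_p = rebase_pair(melody.pitches, bass.pitches)
            mel = replace_line(melody, mel_p)
            bas = replace_line(bass, bas_p)
            (path,) = write_musicxml_fixture([(mel, bas)], scores,
                                             grace_decoys, unison_decoys)
            rows.append({"path": path.relative_to(out_dir).as_posix(),
                         "piece_id": melody.piece_id,
                         "unit_id": unit.unit_id, "mode": unit.mode})
    with open(manifest_path, "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=["path", "piece_id", "unit_id", "mode"])
        writer.writeheader()
        writer.writerows(rows)

    with open(out_dir / "analytic_entropy.csv", "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=["unit_id", "voice", "mode", "order", "H_bits"])
        writer.writeheader()
        for unit in corpus.units:
            for voice, h in unit.analytic_H.items():
                writer.writerow({"unit_id": unit.unit_id, "voice": voice,
                                 "mode": unit.mode, "order": corpus.spec.order,
                                 "H_bits": f"{h:.6f}"})

    alphabet = corpus.alphabet
    K = len(alphabet)
    with open(out_dir / "true_tp.csv", "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=["unit_id", "voice", "context", "target", "prob"])
        writer.writeheader()
        for unit in corpus.units:
            for voice, tp in unit.true_tp.items():
                mat = np.atleast_2d(tp)
                for s in range(mat.shape[0]):
                    ctx = _context_intervals(s, corpus.spec.order, alphabet) \
                        if corpus.spec.order >= 1 else ()
                    for j in range(K):
                        writer.writerow({
                            "unit_id": unit.unit_id, "voice": voice,
                            "context": f"({','.join(str(c) for c in ctx)})",
                            "target": alphabet[j], "prob": f"{mat[s, j]:.6f}"})
    return manifest_path


def replace_line(line: VoiceLine, pitches: list[int]) -> VoiceLine:
    return VoiceLine(piece_id=line.piece_id, unit_id=line.unit_id,
                     voice=line.voice, mode=line.mode, pitches=list(pitches))


def _context_intervals(state: int, order: int, alphabet: tuple[int, ...]) -> tuple[int, ...]:
    K = len(alphabet)
    digits = []
    for _ in range(order):
        digits.append(state % K)
        state //= K
    return tuple(alphabet[d] for d in reversed(digits))
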