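"""Per-unit entropy tables and correlation analyses.

Two designs are supported, mirroring the corpus structures the pipeline
targets:

* melody vs bass: for each model order, Pearson correlation between the
  melody entropies and the bass entropies across aggregation units, either
  pooled over all units or split by tonal mode;
* major vs minor: the entropies of major-key units correlated against their
  tonic-paired minor-key units (C major with C minor, and so on), separately
  per voice and order.

p-values use the exact two-sided t-transformation ``t = r sqrt((n-2)/(1-r^2))``
with ``n - 2`` degrees of freedom.  Correlation strength is banded on |r|:
strong for 0.7 <= |r| <= 1.0, moderate for 0.4 <= |r| < 0.7, weak for
0.2 <= |r| < 0.4, none below.  No multiple-testing correction is applied
across orders.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedCorrelationError, VoiceTPError
from .markov import EntropyRecord
from .score_io import BASS, MELODY

log = logging.getLogger(__name__)

STRONG, MODERATE, WEAK, NONE = "strong", "moderate", "weak", "none"


@dataclass
class CorrelationResult:
    """Pearson r with its two-sided p-value and strength band."""

    label: str
    n: int
    r: float
    p: float
    strength: str
    computable: bool = True

    def significant(self, alpha: float = 0.05) -> bool:
        return self.computable and self.p < alpha


def strength_label(r: float) -> str:
    a = abs(r)
    if a >= 0.7:
        return STRONG
    if a >= 0.4:
        return MODERATE
    if a >= 0.2:
        return WEAK
    return NONE


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r via the t-transformation (df = n - 2)."""
    if n < 3:
        raise UndefinedCorrelationError(f"p-value needs n >= 3, got n = {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(sps.t.sf(t, df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float], label: str = "") -> CorrelationResult:
    """Sample Pearson correlation with exact-t p-value and strength band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"{label or 'correlation'}: needs n >= 3, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError(f"{label or 'correlation'}: non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"{label or 'correlation'}: zero variance in input")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        # variance underflow: ptp > 0 but squared deviations vanish
        raise UndefinedCorrelationError(
            f"{label or 'correlation'}: variance too small to normalize")
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(label=label, n=n, r=r, p=p_from_r(r, n),
                             strength=strength_label(r))


def _not_computable(label: str, n: int) -> CorrelationResult:
    return CorrelationResult(label=label, n=n, r=float("nan"), p=float("nan"),
                             strength=NONE, computable=False)


def entropy_table(records: Iterable[EntropyRecord]) -> pd.DataFrame:
    """Pivot entropy records into a (unit) x (voice, order) table of H in bits.

    Duplicate (unit, voice, order) combinations are an error; combinations
    missing from the records become NaN cells (flagged with a warning, then
    handled pairwise-complete downstream, never silently dropped).
    """
    records = list(records)
    if not records:
        raise VoiceTPError("no entropy records")
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.unit_id, rec.voice, rec.order)
        if key in seen:
            raise VoiceTPError(f"duplicate entropy record for {key}")
        seen.add(key)
    df = pd.DataFrame([{"unit_id": r.unit_id, "voice": r.voice, "order": r.order,
                        "H": r.H} for r in records])
    unit_order = list(dict.fromkeys(df["unit_id"]))
    table = df.pivot(index="unit_id", columns=["voice", "order"], values="H")
    table = table.reindex(unit_order)
    missing = int(table.isna().sum().sum())
    if missing:
        log.warning("entropy table has %d missing (unit, voice, order) cells", missing)
    return table


def unit_modes(records: Iterable[EntropyRecord]) -> dict[str, str]:
    return {r.unit_id: r.mode for r in records}


def melody_bass_correlations(
    table: pd.DataFrame,
    modes: Mapping[str, str] | None = None,
    split_by_mode: bool = False,
    orders: Sequence[int] | None = None,
) -> list[CorrelationResult]:
    """Correlate melody H against bass H across units, per order.

    With ``split_by_mode`` one result per (order, mode); otherwise one pooled
    result per order.  Units missing either voice at an order are removed
    pairwise; fewer than 3 complete pairs yields a not-computable result.
    """
    if orders is None:
        orders = sorted({o for (_, o) in table.columns})
    groups: list[tuple[str, list[str]]]
    if split_by_mode:
        if modes is None:
            raise ValueError("split_by_mode requires unit mode labels")
        groups = [(m, [u for u in table.index if modes.get(u) == m])
                  for m in ("major", "minor")]
    else:
        groups = [("all", list(table.index))]

    out: list[CorrelationResult] = []
    for order in orders:
        for mode_label, units in groups:
            label = f"order{order}_melody_vs_bass_{mode_label}"
            try:
                mel = table.loc[units, (MELODY, order)]
                bas = table.loc[units, (BASS, order)]
            except KeyError:
                out.append(_not_computable(label, 0))
                continue
            ok = mel.notna() & bas.notna()
            if ok.sum() < 3:
                out.append(_not_computable(label, int(ok.sum())))
                continue
            out.append(pearson(mel[ok], bas[ok], label=label))
    return out


_MODE_TOKEN = re.compile(r"major|minor", re.IGNORECASE)


def default_mode_pairing(units: Sequence[str], modes: Mapping[str, str]) -> dict[str, str]:
    """Pair each major unit with the minor unit sharing its tonic.

    The tonic key is the unit id with mode words and separators stripped
    (``"C-major"`` and ``"C-minor"`` share tonic ``"c"``).  Unpaired units
    are an error listing them.
    """
    def tonic(u: str) -> str:
        return re.sub(r"[\s_\-:]+", "", _MODE_TOKEN.sub("", u)).lower()

    majors = {tonic(u): u for u in units if modes.get(u) == "major"}
    minors = {tonic(u): u for u in units if modes.get(u) == "minor"}
    unpaired = sorted(set(majors) ^ set(minors))
    if unpaired:
        raise VoiceTPError(f"units without a major/minor tonic partner: {unpaired}")
    if not majors:
        raise VoiceTPError("no major/minor unit pairs found")
    return {majors[t]: minors[t] for t in sorted(majors)}


def mode_paired_correlation(
    table: pd.DataFrame,
    modes: Mapping[str, str],
    pairing: Mapping[str, str] | None = None,
    orders: Sequence[int] | None = None,
    pooled_voices: bool = False,
) -> list[CorrelationResult]:
    """Correlate major-unit entropies against their tonic-paired minor units.

    One result per (voice, order) by default; ``pooled_voices`` concatenates
    the two voices into a single correlation per order.
    """
    if pairing is None:
        pairing = default_mode_pairing(list(table.index), modes)
    if orders is None:
        orders = sorted({o for (_, o) in table.columns})
    voices = [("pooled", (MELODY, BASS))] if pooled_voices else \
        [(MELODY, (MELODY,)), (BASS, (BASS,))]

    out: list[CorrelationResult] = []
    for order in orders:
        for voice_label, voice_set in voices:
            label = f"order{order}_major_vs_minor_{voice_label}"
            xs: list[float] = []
            ys: list[float] = []
            for major_unit, minor_unit in pairing.items():
                for v in voice_set:
                    try:
                        a = table.loc[major_unit, (v, order)]
                        b = table.loc[minor_unit, (v, order)]
                    except KeyError:
                        continue
                    if pd.notna(a) and pd.notna(b):
                        xs.append(float(a))
                        ys.append(float(b))
            if len(xs) < 3:
                out.append(_not_computable(label, len(xs)))
                continue
            out.append(pearson(xs, ys, label=label))
    return out


def correlations_frame(results: Iterable[CorrelationResult], alpha: float = 0.05) -> pd.DataFrame:
    """Long-format export table for a batch of correlation results."""
    rows = []
    for res in results:
        parts = res.label.split("_")
        rows.append({
            "analysis": "_".join(parts[1:-1]) if len(parts) > 2 else res.label,
            "order": int(parts[0][5:]) if parts[0].startswith("order") else -1,
            "voice_or_pair": parts[-1],
            "n": res.n,
            "r": res.r,
            "p": res.p,
            "strength": res.strength,
            "significant_at_0.05": bool(res.significant(alpha)),
        })
    return pd.DataFrame(rows)
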