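"""Order-n Markov (n-gram) transitional-probability models of interval patterns.

The model of a sequence at order ``n`` is the conditional distribution
``P(target | context)`` over the context/target pairs produced by
:func:`voicetp.encoding.windows`.  Estimation is plug-in maximum likelihood
with no smoothing or bias correction: probabilities are raw count ratios, so
the entropy of the fitted model is exactly the empirical conditional entropy
of the sequence.

Quantities derived from a fitted :class:`TPDistribution`:

* information content of one transition, ``I = log2(1 / P(target|context))``
  in bits (surprisal); reported only for observed transitions, never for
  zero-probability patterns;
* conditional entropy
  ``H = -sum_a P(a) sum_b P(b|a) log2 P(b|a)`` in bits, the uncertainty of
  the transitional-probability distribution, with context weights
  ``P(a)`` equal to each context's share of all transitions.

Distributions from several movements are pooled into one per-unit
distribution by weighted averaging; the default weights are each movement's
transition count, which makes the pooled object the genuine empirical
distribution of the concatenated unit.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .encoding import ContextTarget, pattern_text
from .exceptions import (
    OrderMismatchError,
    UndefinedEntropyError,
    UndefinedInformationError,
)

Context = tuple[int, ...]

BY_TRANSITIONS = "by_transitions"
EXPLICIT = "explicit"


@dataclass
class TPDistribution:
    """Counts and conditional probabilities of one order-n model.

    ``counts[context][target]`` holds (possibly fractional, after pooling)
    occurrence weights.  Conditional probabilities and context probabilities
    are derived views; they always satisfy

    * ``sum_b probs[a][b] == 1`` for every observed context ``a``;
    * ``sum_a context_probs[a] == 1`` and
      ``context_probs[a] == sum_b counts[a][b] / n_transitions``.
    """

    order: int
    counts: dict[Context, dict[int, float]] = field(default_factory=dict)
    n_transitions: float = 0.0

    def context_counts(self) -> dict[Context, float]:
        return {a: sum(row.values()) for a, row in self.counts.items()}

    def context_probs(self) -> dict[Context, float]:
        if self.n_transitions <= 0:
            return {}
        n = self.n_transitions
        return {a: sum(row.values()) / n for a, row in self.counts.items()}

    def probs(self) -> dict[Context, dict[int, float]]:
        out: dict[Context, dict[int, float]] = {}
        for a, row in self.counts.items():
            s = sum(row.values())
            if s > 0:
                out[a] = {b: c / s for b, c in row.items()}
        return out

    def prob(self, context: Context, target: int) -> float:
        row = self.counts.get(context)
        if not row:
            return 0.0
        s = sum(row.values())
        return row.get(target, 0.0) / s if s > 0 else 0.0

    def items(self) -> Iterable[tuple[Context, int, float]]:
        """Yield (context, target, conditional probability) for observed pairs."""
        for a, row in self.counts.items():
            s = sum(row.values())
            for b, c in row.items():
                if c > 0:
                    yield a, b, c / s


def estimate_tp(pairs: Iterable[ContextTarget], order: int) -> TPDistribution:
    """Tally context/target pairs into an order-``n`` TP distribution.

    Empty input yields a distribution with ``n_transitions == 0``.  Pairs of
    inconsistent context length (mixed orders) raise
    :class:`OrderMismatchError`.
    """
    counts: dict[Context, dict[int, float]] = defaultdict(Counter)  # type: ignore[arg-type]
    n = 0
    ctx_len: int | None = None
    for ctx, tgt in pairs:
        if ctx_len is None:
            ctx_len = len(ctx)
        elif len(ctx) != ctx_len:
            raise OrderMismatchError(
                f"mixed context lengths in input: {ctx_len} and {len(ctx)}"
            )
        counts[ctx][tgt] += 1
        n += 1
    return TPDistribution(order=order, counts={a: dict(r) for a, r in counts.items()},
                          n_transitions=float(n))


def information_content(p: float) -> float:
    """Surprisal ``log2(1/p)`` in bits of one observed transition.

    Defined only on (0, 1]; unobserved (zero-probability) transitions have no
    information content in this analysis and raise
    :class:`UndefinedInformationError`.
    """
    if p <= 0.0 or p > 1.0:
        raise UndefinedInformationError(
            f"information content undefined for probability {p!r}; needs 0 < p <= 1"
        )
    return math.log2(1.0 / p)


def conditional_entropy(d: TPDistribution, label: str = "") -> float:
    """Conditional entropy of a TP distribution in bits.

    ``H = -sum_a P(a) sum_b P(b|a) log2 P(b|a)`` with ``0 * log 0 = 0``.
    """
    if d.n_transitions < 1:
        raise UndefinedEntropyError(
            f"conditional entropy undefined for empty distribution{' ' + label if label else ''}"
        )
    n = d.n_transitions
    h = 0.0
    for row in d.counts.values():
        s = sum(row.values())
        if s <= 0:
            continue
        pa = s / n
        h_row = 0.0
        for c in row.values():
            if c > 0:
                pb = c / s
                h_row -= pb * math.log2(pb)
        h += pa * h_row
    return max(h, 0.0)


def pool_tp(
    ds: Sequence[TPDistribution],
    weights: Sequence[float] | None = None,
    method: str = BY_TRANSITIONS,
) -> TPDistribution:
    """Pool per-movement distributions into one weighted-average distribution.

    ``by_transitions`` (default) sums raw counts, i.e. averages TPs weighted
    by each movement's context frequency — the pooled object is the empirical
    TP of the concatenated unit.  ``explicit`` rescales each movement to the
    supplied weight first, so ``probs(a, b) = sum_m w_{m,a} probs_m(a, b)``
    with ``w_{m,a}`` proportional to ``weight_m * context share of a in m``.
    """
    if not ds:
        raise ValueError("pool_tp needs at least one distribution")
    order = ds[0].order
    for d in ds:
        if d.order != order:
            raise OrderMismatchError(
                f"cannot pool distributions of orders {order} and {d.order}"
            )
    if method == BY_TRANSITIONS:
        scales = [1.0] * len(ds)
    elif method == EXPLICIT:
        if weights is None or len(weights) != len(ds):
            raise ValueError("explicit pooling requires one weight per distribution")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be positive")
        scales = [
            (w / d.n_transitions if d.n_transitions > 0 else 0.0)
            for w, d in zip(weights, ds)
        ]
    else:
        raise ValueError(f"unknown pooling method {method!r}")

    counts: dict[Context, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    n = 0.0
    for scale, d in zip(scales, ds):
        if scale == 0.0 or d.n_transitions == 0:
            continue
        for a, row in d.counts.items():
            dest = counts[a]
            for b, c in row.items():
                dest[b] += scale * c
        n += scale * d.n_transitions
    return TPDistribution(order=order,
                          counts={a: dict(r) for a, r in counts.items()},
                          n_transitions=n)


@dataclass(frozen=True)
class EntropyRecord:
    """Conditional entropy in bits for one (aggregation unit, voice, order)."""

    unit_id: str
    voice: str
    mode: str
    order: int
    H: float


def tp_long_records(
    d: TPDistribution, unit_id: str, voice: str
) -> list[dict[str, object]]:
    """Flatten a distribution into long-format rows for CSV export.

    Columns mirror the derived-matrix supplementary-table role:
    ``unit_id, voice, order, context, target, count, prob, ic_bits``.
    """
    rows = []
    for a in sorted(d.counts, key=lambda c: pattern_text(c, 0)):
        row = d.counts[a]
        s = sum(row.values())
        for b in sorted(row):
            c = row[b]
            if c <= 0:
                continue
            p = c / s
            rows.append({
                "unit_id": unit_id,
                "voice": voice,
                "order": d.order,
                "context": f"({','.join(str(x) for x in a)})",
                "target": b,
                "count": c,
                "prob": p,
                "ic_bits": information_content(p),
            })
    return rows
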