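"""Transposition-invariant interval encoding of pitch sequences.

Pitch sequences (integer semitone values, middle C = 60) are converted into
interval patterns so that a phrase and any constant transposition of it map to
the same code.  This removes the effect of key and key changes from all
downstream statistics: a semitone up is +1, a semitone down is -1, measured
relative to a reference tone.

Two conventions are supported for building order-``n`` context/target pairs:

``window`` (default)
    Events are tones.  An order-``n`` pattern is an ``(n+1)``-tone window
    re-based on its first pitch: the context is the offsets of tones
    ``2..n`` relative to tone 1, and the target is the offset of tone
    ``n+1`` relative to tone 1.  Order 0 is defined as the marginal
    distribution of elementary intervals (2-tone windows): a single tone has
    no transposition-invariant code, and using absolute pitch would defeat
    the key-invariance the encoding exists for.  A consequence of this
    convention is that orders 0 and 1 produce identical pairs (a one-tone
    context carries no invariant information).

``chain``
    Events are elementary intervals ``d_t = p_{t+1} - p_t``; the order-``n``
    context is the previous ``n`` intervals and the target the next one.
    Orders 0 and 1 differ under this convention.

Enharmonic spelling is ignored throughout: only integer semitone values
matter.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .exceptions import DegenerateWindowError

log = logging.getLogger(__name__)

WINDOW = "window"
CHAIN = "chain"
CONVENTIONS = (WINDOW, CHAIN)

#: Model orders supported by the analysis.
MIN_ORDER, MAX_ORDER = 0, 5

#: A context/target pair: (tuple of signed semitone offsets, signed target).
ContextTarget = tuple[tuple[int, ...], int]


def encode_window(pitches: Sequence[int]) -> tuple[int, ...]:
    """Encode a tone window as offsets relative to its first pitch.

    ``encode_window([60, 64, 67]) == (4, 7)`` and equals the encoding of the
    same window transposed by any constant.

    Raises
    ------
    DegenerateWindowError
        If fewer than two tones are given (a single tone has no
        transposition-invariant encoding).
    """
    if len(pitches) < 2:
        raise DegenerateWindowError(
            f"cannot encode a {len(pitches)}-tone window; need at least 2 tones"
        )
    p0 = pitches[0]
    return tuple(int(p) - int(p0) for p in pitches[1:])


def _check_order(order: int) -> None:
    if not MIN_ORDER <= order <= MAX_ORDER:
        raise ValueError(f"order must be in {MIN_ORDER}..{MAX_ORDER}, got {order}")


def windows(
    pitches: Sequence[int],
    order: int,
    convention: str = WINDOW,
    piece_id: str = "",
) -> list[ContextTarget]:
    """Enumerate order-``n`` context/target pairs along a pitch sequence.

    Returns one pair per admissible position; a sequence too short to hold a
    single pattern yields an empty list and a logged warning (the piece then
    simply contributes nothing at that order).

    Under the ``window`` convention a sequence of ``L`` tones yields
    ``max(0, L - max(order, 1))`` pairs; under ``chain`` it yields
    ``max(0, L - 1 - order)``.
    """
    _check_order(order)
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    L = len(pitches)
    p = [int(x) for x in pitches]

    if convention == WINDOW:
        if order == 0 or order == 1:
            # 2-tone windows: empty context, elementary-interval target.
            if L < 2:
                _warn_short(piece_id, L, order)
                return []
            return [((), p[t] - p[t - 1]) for t in range(1, L)]
        if L < order + 1:
            _warn_short(piece_id, L, order)
            return []
        out: list[ContextTarget] = []
        for t in range(order, L):
            base = p[t - order]
            ctx = tuple(p[t - order + k] - base for k in range(1, order))
            out.append((ctx, p[t] - base))
        return out

    # chain convention
    d = [b - a for a, b in zip(p, p[1:])]
    if order == 0:
        if not d:
            _warn_short(piece_id, L, order)
            return []
        return [((), x) for x in d]
    if len(d) < order + 1:
        _warn_short(piece_id, L, order)
        return []
    return [(tuple(d[t - order:t]), d[t]) for t in range(order, len(d))]


def pattern_text(context: tuple[int, ...], target: int) -> str:
    """Serialize a context/target pair as ``"(4,7)->12"`` (``"()->2"`` for order 0)."""
    return f"({','.join(str(c) for c in context)})->{target}"


def _warn_short(piece_id: str, length: int, order: int) -> None:
    label = f" in {piece_id!r}" if piece_id else ""
    log.warning(
        "sequence of %d tones%s too short for order %d; contributes no patterns",
        length, label, order,
    )
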