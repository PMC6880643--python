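"""Per-generation chromosome sizing.

The generation must cover the current terminal set about twice over
(``L * CH ≈ 2T``), so the head length is recomputed from the terminal-set
size every generation and shrinks as the search space contracts:

    h = max(h_min, round((T/CH - 1) / n))

Rounding is to the nearest integer with halves away from zero: nearest-integer
sizing tracks the double-coverage target more closely than truncation on
either side, and the floor ``h_min`` guarantees genes always carry enough
structure to evolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SizingInput", "tail_length", "head_size", "chromosome_length"]

#: Minimum head length; below this a gene carries too little structure.
DEFAULT_H_MIN = 3


def _round_half_away(x: float) -> int:
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SizingInput:
    """Inputs to the per-generation sizing rule.

    T: current terminal-set size; CH: chromosomes per generation;
    n: maximum function arity; N: genes per chromosome; h_min: head floor.
    """

    T: int
    CH: int
    n: int = 2
    N: int = 2
    h_min: int = DEFAULT_H_MIN

    def __post_init__(self) -> None:
        for name in ("T", "CH", "n", "N", "h_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


def tail_length(h: int, n: int) -> int:
    """Tail length ``t = h*(n-1) + 1`` that guarantees tree closure."""
    if h < 1 or n < 1:
        raise ValueError(f"h and n must be >= 1, got h={h}, n={n}")
    return h * (n - 1) + 1


def head_size(T: int, CH: int, n: int = 2, h_min: int = DEFAULT_H_MIN) -> int:
    """Head length for a generation built over ``T`` terminals with ``CH``
    chromosomes, clamped from below by ``h_min``.

    Derived from the double-coverage rule ``L*CH = 2T`` with ``N = 2`` genes,
    which gives ``h = (T/CH - 1)/n``; the denominator generalizes to the
    configured maximum arity ``n``.
    """
    sizes = SizingInput(T=T, CH=CH, n=n, h_min=h_min)  # validates
    h = _round_half_away((sizes.T / sizes.CH - 1) / sizes.n)
    return max(sizes.h_min, h)


def chromosome_length(h: int, n: int, N: int) -> int:
    """Chromosome length ``L = N * (h + t)``."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return N * (h + tail_length(h, n))
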