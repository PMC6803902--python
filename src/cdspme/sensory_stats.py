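"""Exact binomial statistics for triangle difference tests.

In a triangle test each panelist receives three samples, two alike and one
odd, and must identify the odd one; under the null of no perceptible
difference the success probability is 1/3.  The one-sided p-value for
``m`` correct answers out of ``n`` is the exact upper binomial tail

    p = Σ_{k=m}^{n} C(n,k) (1/3)^k (2/3)^(n−k),

computed in rational arithmetic (the tail is a ratio of integers over 3^n),
so the result is exact to the last bit of the float conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

__all__ = ["TriangleResult", "triangle_test", "triangle_threshold"]

GUESS_PROBABILITY = Fraction(1, 3)


@dataclass(frozen=True)
class TriangleResult:
    n_correct: int
    n_total: int
    p_value: float
    significant: bool
    alpha: float = 0.05
    p_exact: Fraction = Fraction(1)


def _check_counts(n_correct: int, n_total: int) -> None:
    for label, v in (("n_correct", n_correct), ("n_total", n_total)):
        if not isinstance(v, int) or isinstance(v, bool):
            raise ValueError(f"{label} must be an integer, got {v!r}")
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    if not 0 <= n_correct <= n_total:
        raise ValueError(f"n_correct must be in [0, {n_total}], got {n_correct}")


def _tail(n_correct: int, n_total: int) -> Fraction:
    # Σ C(n,k) 1^k 2^(n-k) / 3^n over k >= n_correct, as an exact rational.
    numerator = sum(comb(n_total, k) * 2 ** (n_total - k)
                    for k in range(n_correct, n_total + 1))
    return Fraction(numerator, 3 ** n_total)


def triangle_test(n_correct: int, n_total: int, alpha: float = 0.05) -> TriangleResult:
    """Exact one-sided triangle test against the 1/3 guessing probability."""
    _check_counts(n_correct, n_total)
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    p = _tail(n_correct, n_total)
    return TriangleResult(
        n_correct=n_correct, n_total=n_total, p_value=float(p),
        significant=p <= Fraction(str(alpha)), alpha=alpha, p_exact=p,
    )


def triangle_threshold(n_total: int, alpha: float) -> int:
    """Smallest number of correct answers whose tail p-value is <= alpha."""
    if not isinstance(n_total, int) or isinstance(n_total, bool) or n_total < 1:
        raise ValueError(f"n_total must be a positive integer, got {n_total!r}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    bound = Fraction(str(alpha))
    for m in range(n_total + 1):
        if _tail(m, n_total) <= bound:
            return m
    # Even all-correct is not significant (possible only for tiny n / alpha).
    raise ValueError(
        f"no attainable threshold: p({n_total}/{n_total}) = "
        f"{float(_tail(n_total, n_total)):.3g} > alpha = {alpha}")
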