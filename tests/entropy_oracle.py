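"""Brute-force arbitrary-precision reference for specificity scoring.

Independent of the numpy implementation: ratios are exact rationals
(``fractions.Fraction``) and the entropy sum is evaluated with mpmath at 50
decimal digits.  Used to freeze expected values and for oracle-equivalence
checks; deliberately slow and simple.
"""

from fractions import Fraction

import mpmath

mpmath.mp.dps = 50


def oracle_ratios(xs):
    """Exact expression ratios as Fractions; None for an all-zero vector."""
    fx = [x if isinstance(x, Fraction) else Fraction(x) for x in xs]
    total = sum(fx)
    if total == 0:
        return None
    return [x / total for x in fx]


def oracle_score(xs):
    """Specificity score via 50-digit arithmetic; None for an all-zero vector."""
    ratios = oracle_ratios(xs)
    if ratios is None:
        return None
    n = len(ratios)
    entropy = mpmath.mpf(0)
    for p in ratios:
        if p > 0:
            mp_p = mpmath.mpf(p.numerator) / mpmath.mpf(p.denominator)
            entropy -= mp_p * mpmath.log(mp_p, 2)
    score = mpmath.log(n, 2) - entropy
    return float(max(0, min(score, mpmath.log(n, 2))))


def oracle_classify(xs):
    """(is_specific, index of dominant type) by exact rational comparison.

    Dominance is decided on Fractions (top > 2 * second, exact); the score
    threshold uses the high-precision score.
    """
    ratios = oracle_ratios(xs)
    if ratios is None or len(ratios) < 2:
        return False, None
    order = sorted(range(len(ratios)), key=lambda i: (-ratios[i], i))
    top, second = ratios[order[0]], ratios[order[1]]
    score = oracle_score(xs)
    if top > 2 * second and score > 1:
        return True, order[0]
    return False, None
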