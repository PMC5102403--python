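"""Exact tests used throughout the pipeline.

All enrichment and detection statistics reduce to the one-tailed
(upper-tail) Fisher exact test on a 2x2 contingency table, plus the EASE
variant that removes one supporting gene from the overlap before testing.
"""

from __future__ import annotations

from scipy.stats import hypergeom

__all__ = ["fisher_one_tailed", "ease_score", "enrichment_fisher"]


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact probability for the table [[a, b], [c, d]].

    Returns P(X >= a) where X is hypergeometric with the table's fixed
    margins, i.e. the probability of an association at least as strong as
    observed in the a-cell direction. Symmetric under simultaneous
    row/column transposition.

    Parameters
    ----------
    a, b, c, d
        Non-negative integer cell counts; the grand total must be positive.
    """
    cells = (a, b, c, d)
    for x in cells:
        if x < 0 or x != int(x):
            raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n <= 0:
        raise ValueError("contingency table is empty")
    # X ~ Hypergeom(population n, successes a+b in row 1, draws a+c in col 1)
    return float(hypergeom.sf(a - 1, n, a + b, a + c))


def enrichment_fisher(k: int, n: int, K: int, N: int) -> float:
    """One-tailed Fisher p for a k/n gene list hit rate vs a K/N background.

    The background (``K`` of ``N``) is the whole annotation universe
    *including* the list; the list is subtracted from the background row so
    the two rows of the table are disjoint:

        [[k, n - k], [K - k, (N - n) - (K - k)]]
    """
    _check_margins(k, n, K, N)
    return fisher_one_tailed(k, n - k, K - k, N - n - K + k)


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE score: jackknifed one-tailed Fisher enrichment p-value.

    One supporting gene is removed from the list/term overlap before the
    test (``k`` becomes ``k - 1`` with the other cells unchanged), which
    penalises categories supported by very few genes. ``k <= 1`` therefore
    returns 1.0, and ``ease_score >= enrichment_fisher`` always.
    """
    _check_margins(k, n, K, N)
    if k <= 1:
        return 1.0
    return fisher_one_tailed(k - 1, n - k, K - k, N - n - K + k)


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N):
        raise ValueError(f"inconsistent margins: k={k}, n={n}, K={K}, N={N}")
    if N - n - K + k < 0:
        raise ValueError(
            f"background smaller than list + term: k={k}, n={n}, K={K}, N={N}"
        )
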