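"""Independent oracles used by the test suite.

These deliberately re-derive expected values through a different route than
the package (exact rational enumeration, brute-force grid search) so that
agreement is evidence, not tautology.
"""

from fractions import Fraction

import numpy as np

# haplotypes of the coupling-phase F1: all alleles from parent 0 / parent 1
_F1 = ((0, 0), (1, 1))


def _meiosis(diplotype, r: Fraction):
    """Enumerate gametes of one meiosis as {gamete: exact probability}.

    Walks every strand-choice pattern (s1, s2) explicitly: probability
    (1-r)/2 when both loci copy the same strand, r/2 otherwise.
    """
    out = {}
    for s1 in (0, 1):
        for s2 in (0, 1):
            p = (1 - r) / 2 if s1 == s2 else r / 2
            g = (diplotype[s1][0], diplotype[s2][1])
            out[g] = out.get(g, Fraction(0)) + p
    return out


def enum_f3_joint(r: Fraction) -> np.ndarray:
    """Exact F3 two-locus genotype distribution by exhaustive enumeration.

    Sums over all F1 gamete pairs (the F2 diplotypes) and, within each, over
    all pairs of F2-meiosis gametes (the F3 diplotypes), in exact rational
    arithmetic; returns the unphased 3x3 distribution as floats.
    """
    r = Fraction(r)
    joint = [[Fraction(0)] * 3 for _ in range(3)]
    f1_gametes = _meiosis(_F1, r)
    for g1, p1 in f1_gametes.items():
        for g2, p2 in f1_gametes.items():
            f2_gametes = _meiosis((g1, g2), r)
            for h1, q1 in f2_gametes.items():
                for h2, q2 in f2_gametes.items():
                    joint[h1[0] + h2[0]][h1[1] + h2[1]] += p1 * p2 * q1 * q2
    total = sum(sum(row) for row in joint)
    assert total == 1
    return np.array([[float(x) for x in row] for row in joint])


def f2_loglik_grid_argmax(counts: np.ndarray, step: float = 1e-4) -> float:
    """Brute-force grid maximizer of the F2 two-point multinomial likelihood."""
    counts = np.asarray(counts, dtype=float)
    grid = np.arange(0.0, 0.5 + step, step)
    best_r, best_ll = 0.0, -np.inf
    for r in grid:
        p = (1 - r) / 2
        q = r / 2
        probs = np.array(
            [
                [p * p, 2 * p * q, q * q],
                [2 * p * q, 2 * p * p + 2 * q * q, 2 * p * q],
                [q * q, 2 * p * q, p * p],
            ]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(probs), 0.0).sum()
        if ll > best_ll:
            best_ll, best_r = ll, r
    return best_r
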