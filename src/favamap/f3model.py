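"""Two-locus genotype model for F3 populations and the F2-to-F3 recombination correction.

An F3 population is obtained by selfing F2 plants once (single-seed descent).
Mapping software that scores recombination assuming an F2 intercross sees the
extra meioses of the F2 -> F3 generation and therefore over-estimates the
recombination fraction.  This module provides

* the exact unphased two-locus genotype distribution of an F3 individual as a
  function of the true per-meiosis recombination fraction ``r``
  (:func:`f3_joint`, :func:`f3_class_probs`);
* the correspondence ``rF2(r)``: the recombination fraction an F2-model
  maximum-likelihood fit converges to when the data are in fact F3
  (:func:`rf2_from_f3`);
* its numerical inverse, the correction applied to F2-scale estimates
  (:func:`correct_r`);
* Haldane's mapping function and inverse (:func:`haldane_cM`,
  :func:`haldane_inverse`).

Single-locus marginals of the F3 model are (0.375, 0.25, 0.375) for every
``r`` — the Mendelian 37.5:25:37.5 expectation of one selfing generation past
the F2.  Genotypes are coded 0 = homozygote for the common (female) parent
allele, 1 = heterozygote, 2 = homozygote for the other parent.

No crossover interference is assumed anywhere (consistent with Haldane's
function); the F1 is in full coupling phase.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "F3_MARGINAL",
    "f3_joint",
    "f3_class_probs",
    "f2_joint",
    "rf2_from_f3",
    "correct_r",
    "haldane_cM",
    "haldane_inverse",
    "correct_map_positions",
]

#: Single-locus genotype distribution (AA, Aa, aa) in an F3 population.
F3_MARGINAL = np.array([0.375, 0.25, 0.375])

# Two-locus gametes as (allele at locus 1, allele at locus 2), 0 = common parent.
_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]

#: Labels of the seven symmetric unphased two-locus genotype classes, using
#: A/a for the first locus and B/b for the second (capital = common parent).
F3_CLASS_LABELS = ("AaBb", "AaBB", "AABb", "AABB", "aabb", "AAbb", "aaBB")


def _check_r(r: float, upper_open: bool = False) -> float:
    r = float(r)
    if not math.isfinite(r):
        raise ValueError("recombination fraction must be finite")
    hi_ok = r < 0.5 if upper_open else r <= 0.5
    if not (0.0 <= r and hi_ok):
        upper = "0.5)" if upper_open else "0.5]"
        raise ValueError(f"recombination fraction must lie in [0, {upper}, got {r}")
    return r


def _f1_gamete_probs(r: float) -> dict[tuple[int, int], float]:
    # F1 in coupling: parental gametes (0,0)/(1,1) each (1-r)/2, recombinant r/2.
    return {
        (0, 0): (1 - r) / 2,
        (1, 1): (1 - r) / 2,
        (0, 1): r / 2,
        (1, 0): r / 2,
    }


def _meiosis_gamete_probs(
    h1: tuple[int, int], h2: tuple[int, int], r: float
) -> dict[tuple[int, int], float]:
    """Gamete distribution produced by one meiosis of the diplotype (h1, h2).

    The gamete copies locus 1 from a random strand and stays on that strand at
    locus 2 with probability 1-r (no interference).
    """
    out: dict[tuple[int, int], float] = {}
    strands = (h1, h2)
    for s1 in range(2):
        for s2 in range(2):
            p = 0.5 * ((1 - r) if s1 == s2 else r)
            g = (strands[s1][0], strands[s2][1])
            out[g] = out.get(g, 0.0) + p
    return out


def f3_joint(r: float) -> np.ndarray:
    """Exact 3x3 unphased two-locus genotype distribution of an F3 individual.

    Entry ``[i, j]`` is the probability that an F3 plant carries ``i`` copies
    of the non-common-parent allele at the first locus and ``j`` at the second
    (0 = AA, 1 = Aa, 2 = aa).  Computed by propagating the coupling F1 double
    heterozygote through two rounds of meiosis/selfing: the F1 gamete pair
    defines an F2 diplotype, and the F3 is a pair of independent gametes from
    that F2's meiosis.

    Parameters
    ----------
    r : float
        True per-meiosis recombination fraction, in [0, 0.5].
    """
    r = _check_r(r)
    pf1 = _f1_gamete_probs(r)
    joint = np.zeros((3, 3))
    for g1, p1 in pf1.items():
        for g2, p2 in pf1.items():
            pf2 = p1 * p2
            if pf2 == 0.0:
                continue
            gam = _meiosis_gamete_probs(g1, g2, r)
            for h1, q1 in gam.items():
                for h2, q2 in gam.items():
                    joint[h1[0] + h2[0], h1[1] + h2[1]] += pf2 * q1 * q2
    return joint


def f3_class_probs(r: float) -> np.ndarray:
    """The 7 symmetric two-locus genotype-class probabilities at true ``r``.

    Classes in the order of :data:`F3_CLASS_LABELS`:
    ``f_AaBb``, ``f_AaBB`` (= ``f_AABb`` = ``f_Aabb`` = ``f_aaBb``),
    ``f_AABb``, ``f_AABB`` (= ``f_aabb``), ``f_aabb``, ``f_AAbb``
    (= ``f_aaBB``), ``f_aaBB``.  Counting each class once per listed label the
    vector sums to 1 minus the two unlisted single-heterozygote classes; the
    full 3x3 distribution from :func:`f3_joint` always sums to 1.
    """
    j = f3_joint(r)
    return np.array([j[1, 1], j[1, 0], j[0, 1], j[0, 0], j[2, 2], j[0, 2], j[2, 0]])


def f2_joint(r: float) -> np.ndarray:
    """Unphased 3x3 two-locus genotype distribution of an F2 intercross.

    Closed form with parental gamete probability ``p = (1-r)/2`` and
    recombinant ``q = r/2``; the double-heterozygote class pools coupling and
    repulsion phases (``2p^2 + 2q^2``).
    """
    r = _check_r(r)
    p = (1 - r) / 2
    q = r / 2
    return np.array(
        [
            [p * p, 2 * p * q, q * q],
            [2 * p * q, 2 * p * p + 2 * q * q, 2 * p * q],
            [q * q, 2 * p * q, p * p],
        ]
    )


@lru_cache(maxsize=4096)
def _rf2_from_f3_cached(r: float) -> float:
    if r <= 0.0:
        return 0.0
    if r >= 0.5:
        return 0.5
    target = f3_joint(r)

    def neg_expected_loglik(rho: float) -> float:
        probs = f2_joint(rho)
        return -float(np.sum(target * np.log(probs + 1e-300)))

    res = minimize_scalar(
        neg_expected_loglik,
        bounds=(1e-9, 0.5 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(min(max(res.x, 0.0), 0.5))


def rf2_from_f3(r: float) -> float:
    """F2-scale recombination fraction corresponding to true F3 fraction ``r``.

    Defined as the maximizer of the expected F2 nine-class multinomial
    log-likelihood under the F3 class proportions ``f3_joint(r)`` — i.e. the
    value an F2-model ML estimator converges to on large F3 samples.  Strictly
    increasing on [0, 0.5] with fixed points at 0 and 0.5, and ``rF2 >= r``
    (the extra F2 -> F3 meioses add observable recombinants).
    """
    return _rf2_from_f3_cached(round(_check_r(r), 12))


def correct_r(rf2_hat: float, tol: float = 1e-8) -> float:
    """Invert :func:`rf2_from_f3`: true F3-scale ``r`` from an F2-scale estimate.

    Monotone bisection to ``tol``; input is clipped to [0, 0.5].
    """
    if not math.isfinite(rf2_hat):
        raise ValueError("rF2 estimate must be finite")
    x = min(max(float(rf2_hat), 0.0), 0.5)
    if x <= 0.0:
        return 0.0
    if x >= 0.5:
        return 0.5
    lo, hi = 0.0, 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rf2_from_f3(mid) < x:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def haldane_cM(r):
    """Haldane map distance d = -50 ln(1 - 2r) in centiMorgans.

    ``r = 0.5`` (free recombination) maps to infinity and is returned as
    ``inf`` rather than raising, so callers can flag unlinked intervals.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inverse(d):
    """Inverse Haldane function: r = (1 - exp(-d/50)) / 2 for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


def correct_map_positions(positions_cM: np.ndarray) -> np.ndarray:
    """Rescale F2-assumed cM positions of one ordered group to true F3 scale.

    Each adjacent interval is converted back to an F2-scale recombination
    fraction (inverse Haldane), corrected with :func:`correct_r`, and
    re-accumulated through Haldane's function.  Coincident positions stay
    coincident; the first position is preserved as the origin.
    """
    pos = np.asarray(positions_cM, dtype=float)
    if pos.ndim != 1:
        raise ValueError("positions must be a 1-D array")
    if pos.size <= 1:
        return pos.copy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be weakly increasing")
    out = np.empty_like(pos)
    out[0] = pos[0]
    for k in range(1, pos.size):
        gap = pos[k] - pos[k - 1]
        if gap == 0.0:
            out[k] = out[k - 1]
            continue
        r_f2 = haldane_inverse(gap)
        out[k] = out[k - 1] + haldane_cM(correct_r(r_f2))
    return out
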