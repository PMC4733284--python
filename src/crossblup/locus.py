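"""Closed-form quantitative genetics of an F1 cross between two pure lines.

A biallelic locus with alleles B and b has genotypic values ``a`` (BB),
``d`` (Bb) and ``-a`` (bb), measured as deviations from the homozygote
midpoint: ``a`` is the biological additive effect, ``d`` the biological
dominance effect.  Two non-inbred parental populations, each in
Hardy-Weinberg equilibrium, carry allele B at frequencies ``p`` (line 1)
and ``p'`` (line 2).  An F1 individual receives one gamete from each line,
so its genotype distribution is ``pp', pq', qp', qq'`` over
``B1B2, B1b2, b1B2, b1b2`` with ``q = 1-p``, ``q' = 1-p'``.

Because allele frequencies differ between lines, the substitution effect
of a gamete from one line depends on the allele frequencies of the *other*
line.  This module provides the resulting genetic mean, substitution
effects, and the decomposition of the F1 genetic variance into gametic
(general combining ability) variances and a dominance (specific combining
ability) variance, together with the multi-locus versions used to convert
SNP-level variances into population-level genetic variances, and an exact
enumeration oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocusParams",
    "VarianceDecomposition",
    "MultiLocusVariances",
    "genetic_mean",
    "substitution_effects",
    "f1_variance_decomposition",
    "brute_force_oracle",
    "multilocus_f1_variances",
    "pureline_variances",
]


def _check_freq(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return arr


@dataclass(frozen=True)
class LocusParams:
    """Single-locus parameters: allele-B frequencies in the two lines and
    the biological additive/dominance effects (trait units)."""

    p: float
    p_prime: float
    a: float
    d: float

    def __post_init__(self) -> None:
        _check_freq(self.p, "p")
        _check_freq(self.p_prime, "p_prime")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def q_prime(self) -> float:
        return 1.0 - self.p_prime

    @property
    def y(self) -> float:
        """Allele-frequency difference between the lines, p - p'."""
        return self.p - self.p_prime


@dataclass(frozen=True)
class VarianceDecomposition:
    """F1 genetic mean and variance components for one locus.

    ``var_A1``/``var_A2`` are the gametic (GCA) variances contributed by
    lines 1 and 2, ``var_A = (var_A1 + var_A2)/2`` the F1 additive
    variance, ``var_D`` the dominance (SCA) variance and
    ``var_G = var_A + var_D`` the total genetic variance.
    """

    mean_G: float
    alpha1: float
    alpha2: float
    var_A1: float
    var_A2: float
    var_A: float
    var_D: float
    var_G: float


@dataclass(frozen=True)
class MultiLocusVariances:
    """Summed-over-loci F1 variances plus the within-line analogues,
    for random marker effects with variances ``sigma2_a``, ``sigma2_d``."""

    var_A1: float
    var_A2: float
    var_A: float
    var_D: float
    var_A_pure1: float
    var_D_pure1: float
    var_A_pure2: float
    var_D_pure2: float


def genetic_mean(params: LocusParams) -> float:
    """F1 genetic mean E(G) = (pp' - qq')a + (pq' + qp')d."""
    p, q = params.p, params.q
    pp, qp = params.p_prime, params.q_prime
    return (p * pp - q * qp) * params.a + (p * qp + q * pp) * params.d


def substitution_effects(params: LocusParams) -> tuple[float, float]:
    """Substitution (breeding) effects of gametes from each line.

    alpha1 = a + d(q' - p') for line-1 gametes mated to line 2, and
    alpha2 = a + d(q - p) for line-2 gametes mated to line 1: each depends
    on the mate line's allele frequencies.
    """
    a, d = params.a, params.d
    alpha1 = a + d * (params.q_prime - params.p_prime)
    alpha2 = a + d * (params.q - params.p)
    return alpha1, alpha2


def f1_variance_decomposition(params: LocusParams) -> VarianceDecomposition:
    """Decompose the F1 genetic variance at one locus.

    var_A1 = 2pq[a + (q'-p')d]^2,  var_A2 = 2p'q'[a + (q-p)d]^2,
    var_A = var_A1/2 + var_A2/2,   var_D = 4 pq p'q' d^2,
    var_G = var_A + var_D.

    The a*d cross-term of the total genetic variance is entirely embedded
    in the gametic variances; no separate covariance component exists.
    """
    p, q = params.p, params.q
    pp, qp = params.p_prime, params.q_prime
    alpha1, alpha2 = substitution_effects(params)
    var_A1 = 2.0 * p * q * alpha1**2
    var_A2 = 2.0 * pp * qp * alpha2**2
    var_A = 0.5 * var_A1 + 0.5 * var_A2
    var_D = 4.0 * p * q * pp * qp * params.d**2
    return VarianceDecomposition(
        mean_G=genetic_mean(params),
        alpha1=alpha1,
        alpha2=alpha2,
        var_A1=var_A1,
        var_A2=var_A2,
        var_A=var_A,
        var_D=var_D,
        var_G=var_A + var_D,
    )


def brute_force_oracle(params: LocusParams) -> tuple[float, float]:
    """Exact mean and variance of G by enumerating the four F1 genotypes.

    Genotypes B1B2, B1b2, b1B2, b1b2 occur with probabilities
    pp', pq', qp', qq' and have values a, d, d, -a.  Independent of the
    closed-form decomposition; used as its verification oracle.
    """
    p, q = params.p, params.q
    pp, qp = params.p_prime, params.q_prime
    probs = np.array([p * pp, p * qp, q * pp, q * qp])
    values = np.array([params.a, params.d, params.d, -params.a])
    mean = float(probs @ values)
    var = float(probs @ values**2 - mean**2)
    return mean, var


def multilocus_f1_variances(
    p_vec, p_prime_vec, sigma2_a: float, sigma2_d: float
) -> MultiLocusVariances:
    """Multi-locus F1 (and within-line) variances for random SNP effects.

    Assumes linkage equilibrium, uncorrelated marker effects and zero
    covariance between a and d.  With per-SNP variances sigma2_a and
    sigma2_d::

        var_A1 = sum(2 p q) s2a + sum(2 p q (q'-p')^2) s2d
        var_A2 = sum(2 p'q') s2a + sum(2 p'q' (q-p)^2) s2d
        var_D  = sum(4 p q p'q') s2d

    and the within-line analogues replace the mate-line frequencies by the
    line's own (see :func:`pureline_variances`).
    """
    p = _check_freq(p_vec, "p_vec")
    pp = _check_freq(p_prime_vec, "p_prime_vec")
    if p.shape != pp.shape or p.ndim != 1:
        raise ValueError("p_vec and p_prime_vec must be 1-D and of equal length")
    if sigma2_a < 0 or sigma2_d < 0:
        raise ValueError("SNP variances must be non-negative")
    q = 1.0 - p
    qp = 1.0 - pp
    het1 = 2.0 * p * q
    het2 = 2.0 * pp * qp
    var_A1 = float(het1.sum() * sigma2_a + (het1 * (qp - pp) ** 2).sum() * sigma2_d)
    var_A2 = float(het2.sum() * sigma2_a + (het2 * (q - p) ** 2).sum() * sigma2_d)
    var_D = float((4.0 * p * q * pp * qp).sum() * sigma2_d)
    a_pure1, d_pure1 = pureline_variances(p, sigma2_a, sigma2_d)
    a_pure2, d_pure2 = pureline_variances(pp, sigma2_a, sigma2_d)
    return MultiLocusVariances(
        var_A1=var_A1,
        var_A2=var_A2,
        var_A=0.5 * var_A1 + 0.5 * var_A2,
        var_D=var_D,
        var_A_pure1=a_pure1,
        var_D_pure1=d_pure1,
        var_A_pure2=a_pure2,
        var_D_pure2=d_pure2,
    )


def pureline_variances(p_vec, sigma2_a: float, sigma2_d: float) -> tuple[float, float]:
    """Within-line additive and dominance variances for one population.

    var_A = sum(2pq) s2a + sum(2pq (q-p)^2) s2d;  var_D = sum((2pq)^2) s2d.
    """
    p = _check_freq(np.atleast_1d(p_vec), "p_vec")
    if sigma2_a < 0 or sigma2_d < 0:
        raise ValueError("SNP variances must be non-negative")
    q = 1.0 - p
    het = 2.0 * p * q
    var_A = float(het.sum() * sigma2_a + (het * (q - p) ** 2).sum() * sigma2_d)
    var_D = float((het**2).sum() * sigma2_d)
    return var_A, var_D
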