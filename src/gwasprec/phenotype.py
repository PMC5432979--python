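"""Quantitative phenotype simulation from a single causal variant.

Model: ``y = g + e`` with ``g = w * u``, where
``w = (x - 2f) / sqrt(2 f (1 - f))`` is the standardized causal genotype
(``x`` coded 0/1/2, ``f`` the coded-allele frequency), ``u ~ N(0, 1)`` is the
effect per standardized genotype, and ``e ~ N(0, var(g) (1/q2 - 1))`` so the
causal variant explains a fraction ``q2`` of the phenotypic variance.  The
per-allele effect is ``b = u / sqrt(2 f (1 - f))``.  At ``q2 = 0`` the
phenotype is standard normal with no genetic effect (the null model).

Power is governed by the non-centrality parameter of the 1-df association
chi-square, ``NCP = n q2 / (1 - q2)`` (approximately ``2 n f b^2`` for small
``q2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "CausalSpec",
    "PhenotypeVector",
    "simulate_phenotype",
    "skew_transform",
    "inverse_normal_transform",
    "ncp",
    "ncp_approx",
]


@dataclass
class CausalSpec:
    """The sampled causal variant and its effect.

    ``u`` is the effect per standardized genotype, ``b = u / sqrt(2f(1-f))``
    the effect per allele, and ``q2`` the fraction of phenotypic variance
    explained.
    """

    site_index: int
    position: int
    f: float
    u: float
    b: float
    q2: float

    def __post_init__(self) -> None:
        if not 0 <= self.q2 < 1:
            raise ValueError("q2 must be in [0, 1)")


@dataclass
class PhenotypeVector:
    """Trait values with their genetic and residual components."""

    y: np.ndarray
    g: np.ndarray
    e: np.ndarray
    transform_applied: str = "none"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)

    @property
    def n(self) -> int:
        return int(self.y.size)


def simulate_phenotype(
    x: np.ndarray,
    q2: float,
    seed: int | None = None,
    f: float | None = None,
    position: int = 0,
    site_index: int = -1,
    u: float | None = None,
) -> tuple[PhenotypeVector, CausalSpec]:
    """Simulate one phenotype replicate from causal genotypes ``x``.

    Parameters
    ----------
    x : array of 0/1/2 dosages for the causal variant.
    q2 : variance explained by the causal variant; ``q2 = 0`` gives the null
        model ``y ~ N(0, 1)`` with no genetic effect.
    f : coded-allele frequency used to standardize ``x``; the in-sample
        frequency when omitted.
    u : optional fixed effect per standardized genotype; drawn from N(0, 1)
        when omitted (a fresh draw each replicate).
    seed : controls ``u`` and the residuals.

    The residual variance is matched to the *realized* variance of ``g``,
    so the population ratio var(g)/var(y) equals ``q2`` by construction.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    if not 0 <= q2 < 1:
        raise ValueError("q2 must be in [0, 1)")
    if f is None:
        f = float(x.mean() / 2.0)
    if q2 == 0:
        y = rng.standard_normal(n)
        spec = CausalSpec(site_index, position, f, 0.0, 0.0, 0.0)
        return PhenotypeVector(y, np.zeros(n), y.copy()), spec
    het = 2.0 * f * (1.0 - f)
    if het == 0:
        raise ValueError("causal genotype is monomorphic; q2 > 0 is impossible")
    w = (x - 2.0 * f) / np.sqrt(het)
    u_val = float(rng.standard_normal()) if u is None else float(u)
    g = w * u_val
    var_g = float(g.var())
    e = rng.standard_normal(n) * np.sqrt(var_g * (1.0 / q2 - 1.0))
    spec = CausalSpec(site_index, position, f, u_val, u_val / np.sqrt(het), q2)
    return PhenotypeVector(g + e, g, e), spec


def skew_transform(pheno: PhenotypeVector) -> PhenotypeVector:
    """Square the phenotype, producing a strongly right-skewed trait."""
    return PhenotypeVector(pheno.y**2, pheno.g, pheno.e, transform_applied="square")


def inverse_normal_transform(pheno: PhenotypeVector, offset: float = 0.375) -> PhenotypeVector:
    """Rank-based inverse-normal transformation (normal scores).

    ``z_i = Phi^-1((r_i - offset) / (n + 1 - 2 * offset))`` with ``r_i`` the
    (average-tie) rank of ``y_i``.  The default offset is Blom's 0.375;
    ``offset=0.5`` gives the van der Waerden-style variant.  Depends on the
    data only through ranks, so any strictly monotone transform of ``y``
    yields identical output.
    """
    y = np.asarray(pheno.y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(y == y[0]):
        raise ValueError("all phenotype values identical; ranks are degenerate")
    ranks = rankdata(y, method="average")
    z = ndtri((ranks - offset) / (y.size + 1.0 - 2.0 * offset))
    return PhenotypeVector(z, pheno.g, pheno.e, transform_applied="INF")


def ncp(n: int, q2: float) -> float:
    """Non-centrality parameter of the causal-variant chi-square test:
    ``n q2 / (1 - q2)``."""
    if not 0 <= q2 < 1:
        raise ValueError("q2 must be in [0, 1)")
    return n * q2 / (1.0 - q2)


def ncp_approx(n: int, f: float, b: float) -> float:
    """Small-q2 approximation ``NCP ~= 2 n f b^2`` (coded-allele frequency
    ``f``, per-allele effect ``b``)."""
    if not 0 < f < 1:
        raise ValueError("f must be in (0, 1)")
    return 2.0 * n * f * b * b
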