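"""Synthetic phased haplotype populations with a realistic allele-frequency
spectrum and distance-decaying linkage disequilibrium.

The generator is a two-stage founder-mosaic model:

1. ``generate_founders`` draws a panel of founder haplotypes.  Per-site target
   allele frequencies follow a truncated power-law spectrum (density
   proportional to ``p**-sfs_shape`` on ``[1/(2*n_founders), 0.5]``, the
   neutral 1/p spectrum at ``sfs_shape=1``).  Alleles are marginally
   Bernoulli(p) but are coupled along the chromosome through a Gaussian
   copula whose latent field decays exponentially with base-pair distance.
   This gives common variants long shared haplotype backgrounds (hence
   high-LD proxies) while rare variants, which live in the tail of the
   latent field where the Gaussian copula is asymptotically independent,
   have far fewer strong proxies -- the qualitative frequency/LD interplay
   seen in sequence data.

2. ``generate_population`` resamples study/reference haplotypes as Markov
   mosaics over the founder panel (a Li-Stephens-style copying process):
   the copied founder switches between consecutive sites with probability
   ``1 - exp(-switch_rate * gap_bp)``, and each copied allele is flipped
   with a small per-copy mutation probability, seeding novel rare alleles.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "HaplotypePanel",
    "GenotypeMatrix",
    "generate_founders",
    "generate_population",
    "mosaic_paths",
    "founder_weights",
    "haplotypes_to_genotypes",
    "filter_variants",
    "variant_table",
    "classify_maf",
    "sample_sfs",
    "ld_r2",
    "generate_independent_genotypes",
    "COMMON_MAF",
    "RARE_MAF_FLOOR",
]

#: class boundaries: common MAF > 0.01, rare 0.0003 < MAF <= 0.01
COMMON_MAF = 0.01
RARE_MAF_FLOOR = 0.0003


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over one linear chromosome.

    Attributes
    ----------
    positions : ndarray of int64, shape (n_sites,)
        1-based base-pair coordinates, strictly increasing.
    alleles : ndarray of uint8, shape (haplotype_count, n_sites)
        0 = reference allele, 1 = alternate allele.  Consecutive pairs of
        rows (2i, 2i+1) form diploid individual ``i``.
    region_length : int
        Chromosome length in bp; all positions lie in [1, region_length].
    """

    positions: np.ndarray
    alleles: np.ndarray
    region_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype-by-site matrix")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions and alleles disagree on site count")
        if self.positions.size and (
            self.positions[0] < 1 or self.positions[-1] > self.region_length
        ):
            raise ValueError("positions must lie within [1, region_length]")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise ValueError("alleles must be 0/1")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def haplotype_count(self) -> int:
        return int(self.alleles.shape[0])

    @property
    def individual_count(self) -> int:
        if self.haplotype_count % 2:
            raise ValueError("odd haplotype count has no diploid interpretation")
        return self.haplotype_count // 2

    def allele_counts(self) -> np.ndarray:
        """Alternate-allele count per site."""
        return self.alleles.sum(axis=0, dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        return self.allele_counts() / float(self.haplotype_count)

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.positions[idx], self.alleles[:, idx], self.region_length)

    def subset_individuals(self, individuals: np.ndarray) -> "HaplotypePanel":
        individuals = np.asarray(individuals, dtype=np.int64)
        hap_rows = np.empty(2 * individuals.size, dtype=np.int64)
        hap_rows[0::2] = 2 * individuals
        hap_rows[1::2] = 2 * individuals + 1
        return HaplotypePanel(self.positions, self.alleles[hap_rows], self.region_length)


@dataclass
class GenotypeMatrix:
    """Individual-by-site dosages; hard calls in {0,1,2} or imputed in [0,2]."""

    positions: np.ndarray
    dosages: np.ndarray
    is_dosage: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != self.positions.size:
            raise ValueError("dosages must be individuals x sites, matching positions")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


def sample_sfs(
    n: int,
    sfs_shape: float,
    p_min: float,
    p_max: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw allele frequencies from a truncated power-law spectrum.

    Density proportional to ``p ** -sfs_shape`` on ``[p_min, p_max]``;
    ``sfs_shape = 1`` is the neutral 1/p site-frequency spectrum.  Sampling
    is by inverse-CDF, so draws are deterministic given ``rng``.
    """
    if not 0 < p_min < p_max <= 0.5:
        raise ValueError("need 0 < p_min < p_max <= 0.5")
    rng = np.random.default_rng() if rng is None else rng
    u = rng.random(n)
    a = float(sfs_shape)
    if abs(a - 1.0) < 1e-12:
        return p_min * (p_max / p_min) ** u
    lo, hi = p_min ** (1.0 - a), p_max ** (1.0 - a)
    return (lo + u * (hi - lo)) ** (1.0 / (1.0 - a))


def _sample_positions(n_sites: int, region_length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform distinct 1-based positions, sorted.  Rejection loop keeps the
    memory footprint independent of region_length."""
    if n_sites > region_length:
        raise ValueError("cannot place n_sites distinct positions in region_length bp")
    have: np.ndarray = np.empty(0, dtype=np.int64)
    while have.size < n_sites:
        draw = rng.integers(1, region_length + 1, size=2 * (n_sites - have.size) + 16)
        have = np.unique(np.concatenate([have, draw]))
    if have.size > n_sites:
        have = rng.choice(have, size=n_sites, replace=False)
    return np.sort(have)


def _ar1_field(
    n_rows: int, positions: np.ndarray, scale_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal field over rows x sites with exp(-gap/scale) serial
    correlation along positions (unit marginal variance at every site)."""
    n_sites = positions.size
    z = np.empty((n_rows, n_sites))
    z[:, 0] = rng.standard_normal(n_rows)
    if n_sites > 1:
        rho = np.exp(-np.diff(positions) / float(scale_bp))
        innov = rng.standard_normal((n_rows, n_sites - 1))
        sd = np.sqrt(1.0 - rho**2)
        for s in range(1, n_sites):
            z[:, s] = rho[s - 1] * z[:, s - 1] + sd[s - 1] * innov[:, s - 1]
    return z


def generate_founders(
    n_founders: int,
    n_sites: int,
    region_length: int,
    sfs_shape: float = 1.0,
    seed: int | None = None,
    ld_length: float = 30_000.0,
    freq_ld_length: float | None = None,
    young_freq: float = 0.02,
    young_mixing: float = 0.6,
    sfs_floor: float | None = None,
) -> HaplotypePanel:
    """Generate ``2 * n_founders`` founder haplotypes.

    Parameters
    ----------
    n_founders : int
        Diploid founder count; the frequency spectrum is truncated below at
        ``1 / (2 * n_founders)`` (one founder copy).
    n_sites : int
        Number of polymorphic sites to place uniformly in the region.
    region_length : int
        Chromosome length in bp.
    sfs_shape : float
        Power-law exponent of the frequency spectrum (1 = neutral 1/p).
    ld_length : float
        Decay scale (bp) of the latent Gaussian copula coupling alleles
        along each founder haplotype; controls the range over which common
        variants share carriers.
    freq_ld_length : float, optional
        Decay scale of the latent field coupling *target frequencies* of
        neighbouring sites (defaults to ``ld_length``); frequency similarity
        between close sites is what allows near-perfect proxies.
    young_freq : float
        Sites with target frequency at or below this value are treated as
        young mutations: their latent field is partially decoupled from the
        shared ancestry field (see ``young_mixing``), so rare variants sit
        on largely random haplotype backgrounds and have far fewer high-LD
        proxies than common variants -- the age/frequency structure of real
        sequence data.
    young_mixing : float in [0, 1]
        Loading of young sites on the shared ancestry field; 0 makes rare
        variants fully independent (no LD partners at all), 1 disables the
        young rule.  Intermediate values leave rare variants a few
        moderate-LD co-inherited partners.
    sfs_floor : float, optional
        Lower truncation of the frequency spectrum; defaults to one founder
        copy, ``1 / (2 * n_founders)``.  A floor below founder resolution
        leaves the lowest-frequency sites monomorphic in the founders;
        the population-stage mutation process then populates the very-rare
        tail at those positions.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    positions = _sample_positions(n_sites, region_length, rng)
    n_hap = 2 * n_founders
    # target frequencies: power-law marginal through a smooth latent field
    w = _ar1_field(1, positions, freq_ld_length or ld_length, rng)[0]
    p = _sfs_quantile(ndtr(w), sfs_shape, sfs_floor if sfs_floor else 1.0 / n_hap)
    z = _ar1_field(n_hap, positions, ld_length, rng)
    if not 0 <= young_mixing <= 1:
        raise ValueError("young_mixing must be in [0, 1]")
    young = p <= young_freq
    if young.any() and young_mixing < 1:
        fresh = rng.standard_normal((n_hap, int(young.sum())))
        a = young_mixing
        z[:, young] = a * z[:, young] + np.sqrt(1.0 - a * a) * fresh
    alleles = (z < ndtri(p)[None, :]).astype(np.uint8)
    return HaplotypePanel(positions, alleles, region_length)


def _sfs_quantile(u: np.ndarray, sfs_shape: float, p_min: float, p_max: float = 0.5) -> np.ndarray:
    a = float(sfs_shape)
    if abs(a - 1.0) < 1e-12:
        return p_min * (p_max / p_min) ** u
    lo, hi = p_min ** (1.0 - a), p_max ** (1.0 - a)
    return (lo + u * (hi - lo)) ** (1.0 / (1.0 - a))


def founder_weights(n_haplotypes: int, exponent: float = 1.0) -> np.ndarray:
    """Zipf-like founder contribution weights, ``w_k`` proportional to
    ``1 / (k + 1) ** exponent``.

    Real genealogies are skewed: a few ancestral haplotypes contribute many
    descendants (the common backbone any reference panel captures) while
    most contribute few -- their private variants are the population's
    inherited rare variants.  ``exponent = 0`` recovers uniform copying.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    w = 1.0 / np.arange(1.0, n_haplotypes + 1.0) ** exponent
    return w / w.sum()


def mosaic_paths(
    founders: HaplotypePanel,
    n_haplotypes: int,
    switch_rate: float,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Founder-template indices for each resampled haplotype (Markov mosaic).

    The template index switches between consecutive sites with probability
    ``1 - exp(-switch_rate * gap_bp)``; on a switch the new template is
    drawn from ``weights`` (uniform when omitted) over founder haplotypes.
    Returned array has shape ``(n_haplotypes, n_sites)``.
    """
    if founders.n_sites == 0 or founders.haplotype_count == 0:
        raise ValueError("founder panel is empty")
    if switch_rate < 0:
        raise ValueError("switch_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n_f = founders.haplotype_count
    n_sites = founders.n_sites
    if weights is None:
        cum = np.arange(1, n_f + 1) / n_f
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.size != n_f or weights.min() < 0 or weights.sum() <= 0:
            raise ValueError("weights must be non-negative, one per founder haplotype")
        cum = np.cumsum(weights / weights.sum())

    def draw(k: int) -> np.ndarray:
        return np.searchsorted(cum, rng.random(k)).astype(np.int32)

    ps = 1.0 - np.exp(-switch_rate * np.diff(founders.positions).astype(float))
    paths = np.empty((n_haplotypes, n_sites), dtype=np.int32)
    paths[:, 0] = draw(n_haplotypes)
    for s in range(1, n_sites):
        switch = rng.random(n_haplotypes) < ps[s - 1]
        paths[:, s] = paths[:, s - 1]
        k = int(switch.sum())
        if k:
            paths[switch, s] = draw(k)
    return paths


def generate_population(
    founders: HaplotypePanel,
    n_individuals: int,
    switch_rate: float,
    mutation_rate: float,
    seed: int | None = None,
    founder_weight_exponent: float = 1.0,
) -> HaplotypePanel:
    """Resample a diploid population as Li-Stephens-style mosaics of founders.

    Each of the ``2 * n_individuals`` haplotypes copies a founder template
    along the chromosome (see :func:`mosaic_paths`); founder contributions
    are Zipf-skewed (see :func:`founder_weights`) so the realized frequency
    of a founder-private allele spans the common-to-rare range; each copied
    allele is additionally flipped with probability ``mutation_rate``
    (genotype noise plus a trickle of novel alleles).  Deterministic given
    ``seed``.
    """
    if mutation_rate < 0 or mutation_rate >= 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    w = founder_weights(founders.haplotype_count, founder_weight_exponent)
    paths = mosaic_paths(founders, n_hap, switch_rate, seed=rng.integers(2**31), weights=w)
    alleles = founders.alleles[paths, np.arange(founders.n_sites)[None, :]]
    if mutation_rate > 0:
        flips = rng.random(alleles.shape) < mutation_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.uint8)
    return HaplotypePanel(founders.positions.copy(), alleles, founders.region_length)


def haplotypes_to_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Sum consecutive haplotype pairs into 0/1/2 dosages."""
    if panel.haplotype_count % 2:
        raise ValueError("panel has an odd number of haplotypes")
    dosages = panel.alleles[0::2].astype(np.int16) + panel.alleles[1::2]
    return GenotypeMatrix(panel.positions.copy(), dosages, is_dosage=False)


def classify_maf(maf: np.ndarray) -> np.ndarray:
    """Paper-style MAF classes: 'common' (> 0.01), 'rare' (0.0003, 0.01],
    'excluded' at or below the QC floor (or monomorphic)."""
    maf = np.asarray(maf, dtype=float)
    out = np.full(maf.shape, "excluded", dtype=object)
    out[maf > COMMON_MAF] = "common"
    out[(maf > RARE_MAF_FLOOR) & (maf <= COMMON_MAF)] = "rare"
    return out


def variant_table(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-site summary: position, alternate count, coded-allele frequency f,
    MAF and common/rare class."""
    ac = panel.allele_counts()
    f = ac / float(panel.haplotype_count)
    maf = np.minimum(f, 1.0 - f)
    return pd.DataFrame(
        {
            "position": panel.positions,
            "ac": ac,
            "f": f,
            "maf": maf,
            "class": classify_maf(maf),
        }
    )


def filter_variants(
    panel: HaplotypePanel, min_mac: int = 3
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Remove sites with minor-allele count below ``min_mac``.

    The default ``min_mac=3`` excludes singletons and doubletons, the usual
    sequencing-QC floor (MAC < 3 corresponds to MAF < 0.0003 in a sample of
    ~3600 diploid individuals).  ``min_mac=0`` is the identity.  Returns the filtered panel and
    its variant table.
    """
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    ac = panel.allele_counts()
    mac = np.minimum(ac, panel.haplotype_count - ac)
    keep = np.flatnonzero(mac >= min_mac)
    out = panel.subset_sites(keep)
    return out, variant_table(out)


def ld_r2(geno: GenotypeMatrix, site_a: int, site_b: int) -> float:
    """Squared Pearson correlation between two dosage columns."""
    x = geno.dosages[:, site_a].astype(float)
    y = geno.dosages[:, site_b].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("LD r^2 undefined for a monomorphic site")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def generate_independent_genotypes(
    n_individuals: int,
    n_sites: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    region_length: int | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """LD-free control panel: i.i.d. Binomial(2, p) dosages per site.

    Useful as the independence construction for family-wise error-rate
    calibration, where the analytic form 1 - (1 - alpha)^m applies.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_sites)
    dosages = rng.binomial(2, p[None, :], size=(n_individuals, n_sites)).astype(np.int16)
    region_length = region_length or 10 * n_sites
    step = max(region_length // n_sites, 1)
    positions = 1 + step * np.arange(n_sites, dtype=np.int64)
    return GenotypeMatrix(positions, dosages, is_dosage=False)
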