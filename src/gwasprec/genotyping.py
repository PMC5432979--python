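"""Genotyping strategies: array-marker selection, reference panels, and
haplotype-copying imputation.

The strategies compared by the pipeline are full sequence (all panel sites),
array (a MAF-stratified subset of sites mimicking a genome-wide genotyping
array), and array-plus-imputation against a reference panel of configurable
sample size and variant coverage.

Imputation is a Li-Stephens hidden Markov model run on truth-phased target
haplotypes: each target haplotype is a mosaic of the reference haplotypes,
switching to a uniformly random reference haplotype between consecutive
sites with probability ``1 - exp(-rho * gap_bp / K)`` (``K`` reference
haplotypes, the standard population-scaled form) and emitting the copied
allele with mismatch probability ``epsilon`` at typed sites.  Forward-
backward posteriors give allele probabilities at every reference-covered
site; the untyped sites between two typed sites are interpolated exactly,
since the uniform-switch transition kernel composes over distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix, HaplotypePanel

__all__ = [
    "MarkerSet",
    "ReferencePanel",
    "ImputationResult",
    "select_markers",
    "build_reference",
    "ls_impute",
    "imputation_r2",
    "DEFAULT_ARRAY_DENSITY",
    "DEFAULT_MAF_BIN_EDGES",
    "DEFAULT_MAF_WEIGHTS",
]

#: genome-wide density of a ~312k-SNP genotyping array spread over ~3 Gbp
DEFAULT_ARRAY_DENSITY = 312_264 / 3.0e9

#: MAF-stratification of marker selection; weights heavily favour common
#: variants, mimicking genome-wide array content
DEFAULT_MAF_BIN_EDGES = (0.0, 0.01, 0.05, 0.5)
DEFAULT_MAF_WEIGHTS = (0.02, 0.6, 1.0)


@dataclass
class MarkerSet:
    """Indices of panel sites designated as array markers."""

    indices: np.ndarray
    density: float
    maf_weights: tuple = DEFAULT_MAF_WEIGHTS

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))

    @property
    def n_markers(self) -> int:
        return int(self.indices.size)

    def to_frame(self, positions: np.ndarray) -> pd.DataFrame:
        """BED-like table of retained marker positions."""
        pos = positions[self.indices]
        return pd.DataFrame({"chrom": "1", "start": pos - 1, "end": pos})


@dataclass
class ReferencePanel:
    """Held-out haplotypes plus the subset of population sites they cover.

    ``haplotypes`` is restricted to the reference individuals but indexed on
    the full population site list; ``covered`` is a boolean mask over those
    sites.  ``individuals`` records which population individuals were used,
    guaranteeing disjointness from the study sample.
    """

    haplotypes: HaplotypePanel
    covered: np.ndarray
    individuals: np.ndarray

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.covered.size != self.haplotypes.n_sites:
            raise ValueError("covered mask must match the site count")

    @property
    def n_ref(self) -> int:
        return int(self.individuals.size)

    @property
    def covered_indices(self) -> np.ndarray:
        return np.flatnonzero(self.covered)


@dataclass
class ImputationResult:
    """Posterior dosages at reference-covered sites.

    ``info`` is the IMPUTE-style INFO score, the panel-estimable surrogate
    for imputation accuracy; ``true_r2`` is the squared correlation between
    imputed dosage and the true genotype, available in simulation when the
    truth is supplied.  Typed marker sites carry the true hard genotypes
    and info = 1.
    """

    site_indices: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    info: np.ndarray
    typed: np.ndarray
    true_r2: np.ndarray | None = None

    def as_genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.positions, self.dosages, is_dosage=True)


def select_markers(
    vtable: pd.DataFrame,
    density: float,
    region_length: int,
    maf_weights: tuple = DEFAULT_MAF_WEIGHTS,
    bin_edges: tuple = DEFAULT_MAF_BIN_EDGES,
    seed: int | None = None,
) -> MarkerSet:
    """Sample array markers from the variant table.

    The marker count is ``round(density * region_length)`` (the genome-wide
    default density, ~1.04e-4 markers/bp, yields ~2082 markers on a 20 Mbp
    region).  Sites are drawn without replacement with probability
    proportional to the weight of their MAF bin.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if len(maf_weights) != len(bin_edges) - 1:
        raise ValueError("need one weight per MAF bin")
    n_markers = int(round(density * region_length))
    rng = np.random.default_rng(seed)
    maf = vtable["maf"].to_numpy()
    bins = np.digitize(maf, bin_edges[1:-1], right=True)
    w = np.asarray(maf_weights, dtype=float)[bins]
    w[maf <= 0] = 0.0  # monomorphic sites are never array content
    eligible = np.flatnonzero(w > 0)
    if n_markers > eligible.size:
        raise ValueError(
            f"requested {n_markers} markers but only {eligible.size} sites have "
            "non-zero selection weight"
        )
    if n_markers == 0:
        chosen = np.empty(0, dtype=np.int64)
    else:
        probs = w[eligible] / w[eligible].sum()
        chosen = rng.choice(eligible, size=n_markers, replace=False, p=probs)
    return MarkerSet(indices=np.sort(chosen), density=density, maf_weights=tuple(maf_weights))


def build_reference(
    population: HaplotypePanel,
    n_study: int,
    n_ref: int,
    coverage: float = 1.0,
    marker_indices: np.ndarray | None = None,
    site_mask: np.ndarray | None = None,
    seed: int | None = None,
    must_include: np.ndarray | None = None,
) -> ReferencePanel:
    """Hold out ``n_ref`` individuals (disjoint from the first ``n_study``
    study individuals) as an imputation reference.

    Covered sites are the markers plus a random ``coverage`` fraction of the
    non-marker sites, or an explicit boolean ``site_mask`` (marker sites are
    always forced in, since the HMM needs them for conditioning).  An
    explicit mask excluding causal sites reproduces the causal-present
    versus causal-absent reference contrast.

    ``must_include`` forces the listed held-out individuals into the sample,
    so a larger panel can be built as a superset of a smaller one (the
    panel-size experiment at fixed variant coverage).
    """
    if n_ref <= 0:
        raise ValueError("n_ref must be > 0")
    pool = population.individual_count - n_study
    if pool < n_ref:
        raise ValueError(
            f"only {pool} held-out individuals available, {n_ref} requested"
        )
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if must_include is not None:
        base = np.unique(np.asarray(must_include, dtype=np.int64))
        if base.size > n_ref:
            raise ValueError("must_include is larger than n_ref")
        if base.size and (base.min() < n_study):
            raise ValueError("must_include individuals overlap the study sample")
        rest = np.setdiff1d(n_study + np.arange(pool), base)
        extra = rng.choice(rest, size=n_ref - base.size, replace=False)
        individuals = np.concatenate([base, extra])
    else:
        individuals = n_study + rng.choice(pool, size=n_ref, replace=False)
    individuals.sort()
    haps = population.subset_individuals(individuals)
    n_sites = population.n_sites
    markers = np.zeros(n_sites, dtype=bool)
    if marker_indices is not None:
        markers[np.asarray(marker_indices, dtype=np.int64)] = True
    if site_mask is not None:
        covered = np.asarray(site_mask, dtype=bool).copy()
        if covered.size != n_sites:
            raise ValueError("site_mask must cover every population site")
        covered |= markers
    else:
        covered = markers.copy()
        non_marker = np.flatnonzero(~markers)
        n_extra = int(round(coverage * non_marker.size))
        if n_extra:
            covered[rng.choice(non_marker, size=n_extra, replace=False)] = True
    return ReferencePanel(haplotypes=haps, covered=covered, individuals=individuals)


def _uniform_switch(v: np.ndarray, ps: float) -> np.ndarray:
    """Propagate a normalized state distribution through the uniform-switch
    kernel (1-ps) I + ps/K."""
    return (1.0 - ps) * v + ps * v.mean(axis=-1, keepdims=True)


def ls_impute(
    target: HaplotypePanel,
    reference: ReferencePanel,
    rho: float = 1e-3,
    epsilon: float = 1e-3,
    truth: GenotypeMatrix | None = None,
    chunk: int = 64,
) -> ImputationResult:
    """Impute study haplotypes to all reference-covered sites.

    Parameters
    ----------
    target : study haplotypes restricted to the typed (marker) sites; must
        be truth-phased.  Every typed position must be covered by the
        reference.
    reference : held-out reference panel.
    rho : population-scaled switch parameter; switch probability over a gap
        of ``d`` bp is ``1 - exp(-rho * d / K)`` with ``K`` reference
        haplotypes.
    epsilon : allele-mismatch (emission error) probability, must be in
        (0, 0.5) -- a zero value would zero out the likelihood whenever no
        reference path matches the target exactly.
    truth : optional true study genotypes on the full site list; fills
        ``true_r2``.
    chunk : target haplotypes processed per block (memory/speed trade-off).

    Returns posterior mean dosages, INFO scores (estimated-information
    surrogate ``1 - mean posterior dosage variance / (2 f (1 - f))``,
    clamped to [0, 1]) and, when the truth is given, per-site ``true_r2``.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    cov_idx = reference.covered_indices
    if cov_idx.size == 0:
        raise ValueError("reference covers no sites")
    ref_pos = reference.haplotypes.positions[cov_idx]
    H = reference.haplotypes.alleles[:, cov_idx].astype(np.float64)  # (K, L)
    K, L = H.shape
    if K == 0:
        raise ValueError("reference panel is empty")
    # locate typed sites within the covered list
    t_idx = np.searchsorted(ref_pos, target.positions)
    bad = (t_idx >= L) | (ref_pos[np.minimum(t_idx, L - 1)] != target.positions)
    if bad.any():
        raise ValueError("some typed marker positions are absent from the reference")
    obs = target.alleles.astype(np.float64)  # (n_hap, T)
    n_hap, T = obs.shape
    if n_hap % 2:
        raise ValueError("target panel must contain haplotype pairs")

    hap_post = np.empty((n_hap, L))  # haploid posterior alternate-allele prob
    typed_gap_ps = (
        1.0 - np.exp(-rho * np.diff(ref_pos[t_idx]).astype(float) / K) if T > 1 else np.empty(0)
    )

    # pre-compute untyped segments: indices of covered sites strictly between
    # consecutive typed sites (plus flanks)
    seg_bounds = np.concatenate([[-1], t_idx, [L]])

    for lo in range(0, n_hap, chunk):
        hi = min(lo + chunk, n_hap)
        c = hi - lo
        ob = obs[lo:hi]  # (c, T)
        # emissions at typed sites: (T, c, K)
        alpha = np.empty((T, c, K)) if T else np.empty((0, c, K))
        if T:
            match0 = ob[:, 0, None] == H[None, :, t_idx[0]]
            a = np.where(match0, 1.0 - epsilon, epsilon) / K
            a /= a.sum(axis=1, keepdims=True)
            alpha[0] = a
            for j in range(1, T):
                a = _uniform_switch(alpha[j - 1], typed_gap_ps[j - 1])
                match = ob[:, j, None] == H[None, :, t_idx[j]]
                a = a * np.where(match, 1.0 - epsilon, epsilon)
                a /= a.sum(axis=1, keepdims=True)
                alpha[j] = a
        # backward sweep, filling posteriors segment by segment
        if T == 0:
            hap_post[lo:hi] = H.mean(axis=0)[None, :]
            continue
        # segment after the last typed site
        tail = np.arange(t_idx[-1] + 1, L)
        for s in tail:
            ps = 1.0 - np.exp(-rho * float(ref_pos[s] - ref_pos[t_idx[-1]]) / K)
            post = _uniform_switch(alpha[-1], ps)
            hap_post[lo:hi, s] = post @ H[:, s]
        btilde = None  # emission-weighted backward variable at typed site j+1
        for j in range(T - 1, -1, -1):
            if btilde is None:
                beta_j = np.full((c, K), 1.0 / K)
            else:
                beta_j = _uniform_switch(btilde, typed_gap_ps[j])
                beta_j /= beta_j.sum(axis=1, keepdims=True)
            # posterior at the typed site itself
            g = alpha[j] * beta_j
            g /= g.sum(axis=1, keepdims=True)
            hap_post[lo:hi, t_idx[j]] = g @ H[:, t_idx[j]]
            # untyped sites between typed j-1 (or region start) and typed j
            inner = np.arange(seg_bounds[j] + 1, t_idx[j])
            match = ob[:, j, None] == H[None, :, t_idx[j]]
            bt = beta_j * np.where(match, 1.0 - epsilon, epsilon)
            for s in inner:
                ps_r = 1.0 - np.exp(-rho * float(ref_pos[t_idx[j]] - ref_pos[s]) / K)
                bwd = _uniform_switch(bt, ps_r)
                if j > 0:
                    ps_l = 1.0 - np.exp(-rho * float(ref_pos[s] - ref_pos[t_idx[j - 1]]) / K)
                    fwd = _uniform_switch(alpha[j - 1], ps_l)
                    post = fwd * bwd
                else:
                    post = bwd  # uniform prior on the left flank
                post /= post.sum(axis=1, keepdims=True)
                hap_post[lo:hi, s] = post @ H[:, s]
            btilde = bt

    # diploid dosages and INFO
    pa, pb = hap_post[0::2], hap_post[1::2]
    dosages = pa + pb
    post_var = pa * (1.0 - pa) + pb * (1.0 - pb)
    fhat = dosages.mean(axis=0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - post_var.mean(axis=0) / (2.0 * fhat * (1.0 - fhat))
    info = np.where((fhat <= 0) | (fhat >= 1), 0.0, np.clip(info, 0.0, 1.0))

    typed = np.zeros(L, dtype=bool)
    typed[t_idx] = True
    # typed sites carry the observed hard genotypes exactly
    hard = target.alleles[0::2].astype(np.float64) + target.alleles[1::2]
    dosages[:, t_idx] = hard
    info[t_idx] = 1.0

    true_r2 = None
    if truth is not None:
        true_r2 = imputation_r2(dosages, truth.dosages[:, cov_idx])
    return ImputationResult(
        site_indices=cov_idx,
        positions=ref_pos.copy(),
        dosages=np.clip(dosages, 0.0, 2.0),
        info=info,
        typed=typed,
        true_r2=true_r2,
    )


def imputation_r2(imputed: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Squared correlation between imputed dosage and true genotype, per
    site (NaN where either is constant)."""
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ic = imputed - imputed.mean(axis=0)
    tc = truth - truth.mean(axis=0)
    num = np.einsum("ij,ij->j", ic, tc)
    den = np.sqrt(np.einsum("ij,ij->j", ic, ic) * np.einsum("ij,ij->j", tc, tc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r**2
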