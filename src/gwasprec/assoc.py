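"""Per-variant association scans, top-hit selection and genomic control.

Each polymorphic site is tested by simple linear regression of the phenotype
on its dosage (with intercept).  The 1-df Wald chi-square
``(beta / se)^2`` with a normal-approximation P value is used throughout: at
GWAS sample sizes the difference from the t reference distribution is
negligible and it matches the chi-square framing under which power is a
non-central chi-square tail probability with NCP = n q2 / (1 - q2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .popgen import GenotypeMatrix

__all__ = [
    "AssocResult",
    "HitRecord",
    "scan",
    "scan_many",
    "top_hit",
    "lambda_gc",
    "variance_explained",
    "CHI2_MEDIAN_1DF",
]

#: median of the chi-square distribution with 1 df
CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))

_P_FLOOR = 1e-300  # keep P values in (0, 1] when sf underflows


@dataclass
class AssocResult:
    """Summary statistics for one scan of a phenotype against a panel.

    ``tested`` flags sites with non-zero dosage variance; skipped sites
    carry NaN statistics.  The invariants ``chisq = (beta/se)^2`` and
    ``p = P(chi2_1 > chisq)`` hold at every tested site.
    """

    positions: np.ndarray
    freq: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    chisq: np.ndarray
    p: np.ndarray
    tested: np.ndarray
    n: int
    strategy: str = ""

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def to_frame(self):
        """GWAS summary-statistics table (PLINK/GCTA-style columns)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "CHR": 1,
                "POS": self.positions,
                "FREQ": self.freq,
                "BETA": self.beta,
                "SE": self.se,
                "CHISQ": self.chisq,
                "P": self.p,
                "TESTED": self.tested,
            }
        )


@dataclass
class HitRecord:
    """Per-replicate top associated variant and its relation to the causal.

    ``q2_gwas`` is the variance explained by the hit; in expectation it
    decomposes as ``q2 * R2_imp * r2`` (causal variance explained, squared
    imputation accuracy, LD between hit and causal).
    """

    replicate: int
    strategy: str
    causal_position: int
    causal_maf: float
    hit_position: int
    hit_maf: float
    distance: int
    maf_diff: float
    p_hit: float
    r2_with_causal: float = np.nan
    q2_gwas: float = np.nan
    hit_is_causal: bool = False


def scan(
    y: np.ndarray, geno: GenotypeMatrix, strategy: str = "", hard_calls: bool = False
) -> AssocResult:
    """OLS scan of ``y`` against every dosage column of ``geno``.

    Imputed dosages are tested as-is by default (the standard frequentist
    choice); ``hard_calls=True`` rounds dosages to the nearest genotype
    first, for sensitivity analysis.
    """
    y = np.asarray(getattr(y, "y", y), dtype=float)
    n = y.size
    if n != geno.n_individuals:
        raise ValueError("phenotype length does not match individual count")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    X = np.asarray(geno.dosages, dtype=float)
    if hard_calls:
        X = np.rint(X)
    freq = X.mean(axis=0) / 2.0
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    syy = float(yc @ yc)
    tested = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = yc @ xc
        beta = np.where(tested, sxy / sxx, np.nan)
        sse = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = sse / max(n - 2, 1)
        se = np.sqrt(np.where(tested, sigma2 / sxx, np.nan))
        chisq = np.where(se > 0, (beta / se) ** 2, np.inf)
    chisq = np.where(tested, chisq, np.nan)
    p = np.where(tested, np.maximum(chi2.sf(chisq, 1), _P_FLOOR), np.nan)
    return AssocResult(
        positions=geno.positions.copy(),
        freq=freq,
        beta=beta,
        se=se,
        chisq=chisq,
        p=p,
        tested=tested,
        n=n,
        strategy=strategy,
    )


def scan_many(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistics and P values for many phenotypes at once.

    ``Y`` is replicates-by-individuals, ``X`` individuals-by-sites; returns
    ``(chisq, p)`` of shape replicates-by-sites.  Algebraically identical to
    calling :func:`scan` per row (``chisq = (n-2) R2 / (1 - R2)`` with
    ``R2`` the squared sample correlation) but implemented as one matrix
    product, which is what makes the large replicate grids tractable.
    Zero-variance sites get NaN columns.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if Y.shape[1] != n:
        raise ValueError("Y must be replicates x individuals matching X rows")
    xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx[None, :] * syy[:, None])
        r2 = np.clip(r2, 0.0, 1.0)
        chisq = (n - 2) * r2 / (1.0 - r2)
    chisq[:, sxx <= 0] = np.nan
    p = np.where(np.isnan(chisq), np.nan, np.maximum(chi2.sf(chisq, 1), _P_FLOOR))
    return chisq, p


def top_hit(
    assoc: AssocResult,
    causal_position: int,
    window: float,
    p_threshold: float,
) -> int | None:
    """Index of the top associated variant near the causal position.

    Considers tested sites within ``[causal - window/2, causal + window/2]``
    with ``p < p_threshold`` and returns the site with the smallest P value;
    ties break to the smallest distance from the causal position, then the
    smallest position.  Returns None when no site passes (a no-power
    replicate, not a miss at infinite distance).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    half = window / 2.0
    pos = assoc.positions
    in_win = (pos >= causal_position - half) & (pos <= causal_position + half)
    ok = in_win & assoc.tested & (assoc.p < p_threshold)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    pvals = assoc.p[idx]
    best_p = pvals.min()
    cand = idx[pvals == best_p]
    if cand.size > 1:
        dist = np.abs(pos[cand] - causal_position)
        cand = cand[dist == dist.min()]
    return int(cand.min())


def lambda_gc(assoc: AssocResult | np.ndarray) -> float:
    """Genomic-control inflation factor: median chi-square over the
    chi-square(1) median (0.4549...)."""
    chisq = assoc.chisq[assoc.tested] if isinstance(assoc, AssocResult) else np.asarray(assoc)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no tested sites")
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def variance_explained(y: np.ndarray, x: np.ndarray) -> float:
    """Estimated fraction of phenotypic variance explained by one variant.

    The squared sample correlation carries a well-known upward bias of
    order (1 - rho^2)^2 / n; the Ezekiel-adjusted form
    ``1 - (1 - r^2)(n - 1)/(n - 2)`` removes the leading term, so replicate
    means recover q2.  Clipped below at 0.
    """
    y = np.asarray(getattr(y, "y", y), dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if n < 4 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
    return float(max(adj, 0.0))
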