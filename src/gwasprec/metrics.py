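"""Replicate-level aggregation: family-wise error rate, power, and
mapping-precision summaries.

Mapping precision is the physical distance (or the LD r^2) between the top
associated variant of a scan and the true causal variant; the summaries here
are empirical CDFs of those quantities over replicates, the proportion of
replicates in which the causal variant itself is the top hit (per causal-MAF
bin), and a query operation that intersects distance and LD thresholds.
Replicates with no genome-wide-significant hit contribute to power's
denominator only; precision CDFs condition on detected loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssocResult, HitRecord

__all__ = [
    "PrecisionSummary",
    "CalibrationReport",
    "gwfpr",
    "power",
    "precision_cdf",
    "maf_diff_cdf",
    "ld_cdf",
    "top_is_causal_by_maf",
    "query",
    "summarize_hits",
    "hits_to_frame",
    "default_distance_grid",
    "DEFAULT_MAF_BINS",
    "DEFAULT_THRESHOLD_GRID",
]

#: causal-MAF bin edges for the top-hit-is-causal summary; includes the
#: named very-rare (0.0003, 0.001] and very-common (0.1, 0.5] bins
DEFAULT_MAF_BINS = (0.0003, 0.001, 0.01, 0.05, 0.1, 0.25, 0.5)

#: genome-wide significance thresholds spanning 5e-8 .. 1e-11
DEFAULT_THRESHOLD_GRID = (5e-8, 1e-8, 5e-9, 1e-9, 5e-10, 1e-10, 5e-11, 1e-11)


def default_distance_grid(lo: float = 100.0, hi: float = 1e7) -> np.ndarray:
    """Logarithmic 1-2-5 distance grid in bp (default 100 bp .. 10 Mbp)."""
    grid = []
    decade = 10 ** np.floor(np.log10(lo))
    while decade <= hi:
        for m in (1, 2, 5):
            v = m * decade
            if lo <= v <= hi:
                grid.append(v)
        decade *= 10
    return np.asarray(grid)


@dataclass
class PrecisionSummary:
    """Mapping-precision summary for one strategy and causal-variant class."""

    strategy: str
    variant_class: str
    distance_grid: np.ndarray
    distance_cdf: np.ndarray
    distance_q80: float
    maf_diff_grid: np.ndarray
    maf_diff_cdf: np.ndarray
    r2_grid: np.ndarray
    r2_cdf: np.ndarray
    top_is_causal: dict
    n_attempted: int
    n_powered: int
    hits: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-grid-point table."""
        rows = []
        for kind, grid, cdf in (
            ("distance_bp", self.distance_grid, self.distance_cdf),
            ("maf_diff", self.maf_diff_grid, self.maf_diff_cdf),
            ("ld_r2", self.r2_grid, self.r2_cdf),
        ):
            for g, c in zip(grid, cdf):
                rows.append(
                    {
                        "strategy": self.strategy,
                        "class": self.variant_class,
                        "measure": kind,
                        "grid": g,
                        "cdf": c,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "class": self.variant_class,
            "distance_grid": list(map(float, self.distance_grid)),
            "distance_cdf": list(map(float, self.distance_cdf)),
            "distance_q80": float(self.distance_q80),
            "maf_diff_grid": list(map(float, self.maf_diff_grid)),
            "maf_diff_cdf": list(map(float, self.maf_diff_cdf)),
            "r2_grid": list(map(float, self.r2_grid)),
            "r2_cdf": list(map(float, self.r2_cdf)),
            "top_is_causal": {str(k): (None if v != v else float(v)) for k, v in self.top_is_causal.items()},
            "n_attempted": self.n_attempted,
            "n_powered": self.n_powered,
        }


@dataclass
class CalibrationReport:
    """Genome-wide false-positive rate per threshold per strategy."""

    thresholds: np.ndarray
    gwfpr: dict  # strategy -> array aligned with thresholds
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strat, vals in self.gwfpr.items():
            for t, v in zip(self.thresholds, vals):
                rows.append({"strategy": strat, "threshold": t, "gwfpr": v})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        obj = {
            "thresholds": list(map(float, self.thresholds)),
            "n_replicates": self.n_replicates,
            "gwfpr": {k: list(map(float, v)) for k, v in self.gwfpr.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _min_p(rep) -> float:
    if isinstance(rep, AssocResult):
        p = rep.p[rep.tested]
    else:
        p = np.asarray(rep, dtype=float)
        p = p[np.isfinite(p)]
    return float(p.min()) if p.size else 1.0


def gwfpr(null_scans, threshold: float) -> float:
    """Genome-wide false-positive rate (family-wise error rate): the
    fraction of null replicates containing at least one site with
    ``p < threshold``.  ``null_scans`` may hold AssocResults or per-replicate
    P-value arrays."""
    scans = list(null_scans)
    if not scans:
        raise ValueError("no null replicates supplied")
    hits = sum(_min_p(rep) < threshold for rep in scans)
    return hits / len(scans)


def power(scans, threshold: float) -> float:
    """Fraction of replicates with at least one in-window site below the
    significance threshold."""
    scans = list(scans)
    if not scans:
        raise ValueError("no replicates supplied")
    return sum(_min_p(rep) < threshold for rep in scans) / len(scans)


def _ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(values, np.asarray(grid, dtype=float), side="right") / values.size


def _quantile_on_grid(values: np.ndarray, level: float) -> float:
    """Smallest observed value v with ECDF(v) >= level."""
    values = np.sort(np.asarray(values, dtype=float))
    k = int(np.ceil(level * values.size)) - 1
    return float(values[max(k, 0)])


def precision_cdf(hits, grid=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Distance CDF: fraction of hits whose distance to the causal variant
    is <= each grid value, plus the 80th-percentile distance."""
    hits = list(hits)
    if not hits:
        raise ValueError("no hits supplied")
    grid = default_distance_grid() if grid is None else np.asarray(grid, dtype=float)
    d = np.array([h.distance for h in hits], dtype=float)
    return grid, _ecdf(d, grid), _quantile_on_grid(d, 0.80)


def maf_diff_cdf(hits, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """CDF of |MAF(hit) - MAF(causal)| over hits."""
    hits = list(hits)
    if not hits:
        raise ValueError("no hits supplied")
    grid = np.asarray(
        [0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.05, 0.1, 0.2, 0.5] if grid is None else grid,
        dtype=float,
    )
    vals = np.array([h.maf_diff for h in hits], dtype=float)
    return grid, _ecdf(vals, grid)


def ld_cdf(hits, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """CDF of LD r^2 between hit and causal variant over hits (NaN r^2,
    e.g. causal monomorphic proxies, are excluded)."""
    hits = list(hits)
    if not hits:
        raise ValueError("no hits supplied")
    grid = np.linspace(0, 1, 21) if grid is None else np.asarray(grid, dtype=float)
    vals = np.array([h.r2_with_causal for h in hits], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite r^2 values among hits")
    return grid, _ecdf(vals, grid)


def top_is_causal_by_maf(hits, bins=DEFAULT_MAF_BINS) -> dict:
    """Per causal-MAF bin, the fraction of hits that are the causal variant
    itself.  Meaningful for the full-sequence strategy, where the causal is
    always among the tested sites.  Empty bins map to NaN (undefined), not 0.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("no hits supplied")
    edges = np.asarray(bins, dtype=float)
    maf = np.array([h.causal_maf for h in hits], dtype=float)
    is_causal = np.array([h.hit_is_causal for h in hits], dtype=bool)
    out = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (maf > lo) & (maf <= hi)
        out[(float(lo), float(hi))] = float(is_causal[sel].mean()) if sel.any() else float("nan")
    return out


def query(hits, max_distance: float | None = None, min_r2: float | None = None) -> float:
    """Fraction of hits within ``max_distance`` bp of the causal variant
    and/or in LD r^2 >= ``min_r2`` with it (both criteria intersected when
    supplied)."""
    if max_distance is None and min_r2 is None:
        raise ValueError("supply max_distance and/or min_r2")
    hits = list(hits)
    if not hits:
        raise ValueError("no hits supplied")
    ok = np.ones(len(hits), dtype=bool)
    if max_distance is not None:
        ok &= np.array([h.distance <= max_distance for h in hits])
    if min_r2 is not None:
        ok &= np.array([h.r2_with_causal >= min_r2 for h in hits])
    return float(ok.mean())


def summarize_hits(
    hits,
    strategy: str,
    variant_class: str,
    n_attempted: int,
    distance_grid=None,
) -> PrecisionSummary:
    """Bundle all precision summaries for one strategy x class hit set."""
    hits = list(hits)
    dgrid, dcdf, q80 = precision_cdf(hits, distance_grid)
    mgrid, mcdf = maf_diff_cdf(hits)
    try:
        rgrid, rcdf = ld_cdf(hits)
    except ValueError:
        rgrid, rcdf = np.linspace(0, 1, 21), np.full(21, np.nan)
    return PrecisionSummary(
        strategy=strategy,
        variant_class=variant_class,
        distance_grid=dgrid,
        distance_cdf=dcdf,
        distance_q80=q80,
        maf_diff_grid=mgrid,
        maf_diff_cdf=mcdf,
        r2_grid=rgrid,
        r2_cdf=rcdf,
        top_is_causal=top_is_causal_by_maf(hits),
        n_attempted=n_attempted,
        n_powered=len(hits),
        hits=hits,
    )


def hits_to_frame(hits) -> pd.DataFrame:
    """HitRecords as a tidy table (one row per powered replicate)."""
    return pd.DataFrame(
        [
            {
                "replicate": h.replicate,
                "strategy": h.strategy,
                "causal_position": h.causal_position,
                "causal_maf": h.causal_maf,
                "hit_position": h.hit_position,
                "hit_maf": h.hit_maf,
                "distance": h.distance,
                "maf_diff": h.maf_diff,
                "p_hit": h.p_hit,
                "r2_with_causal": h.r2_with_causal,
                "q2_gwas": h.q2_gwas,
                "hit_is_causal": h.hit_is_causal,
            }
            for h in hits
        ]
    )
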