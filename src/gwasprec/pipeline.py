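"""End-to-end scenario orchestration.

A :class:`ScenarioConfig` describes one experiment: the synthetic
population, the genotyping strategies to compare, the heritability grid and
replicate counts, significance thresholds and the master seed.  The run
functions mirror the study design:

* :func:`run_null_calibration` -- phenotypes with no genetic effect
  (optionally squared, and inverse-normal transformed) scanned against every
  site, summarised as the genome-wide false-positive rate over a threshold
  grid.
* :func:`run_power_curve` -- detection power per strategy, causal-variant
  class and q2 level.
* :func:`run_precision` -- the mapping-precision experiment: per replicate a
  causal variant is sampled, a phenotype simulated, each strategy scanned,
  and the top hit recorded with its distance, MAF difference, LD r^2 with
  the causal variant and variance explained.

Seeding: every random stream is derived from the master seed plus a purpose
tag and replicate index through ``numpy`` SeedSequence spawn keys, so
replicates are individually reproducible and runs are deterministic
end-to-end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .assoc import HitRecord, scan_many, variance_explained
from .genotyping import (
    DEFAULT_ARRAY_DENSITY,
    ImputationResult,
    MarkerSet,
    build_reference,
    ls_impute,
    select_markers,
)
from .phenotype import inverse_normal_transform, simulate_phenotype, skew_transform, PhenotypeVector
from .popgen import (
    GenotypeMatrix,
    HaplotypePanel,
    filter_variants,
    generate_founders,
    generate_population,
    haplotypes_to_genotypes,
)

__all__ = [
    "StrategyConfig",
    "ScenarioConfig",
    "Cohort",
    "StrategyData",
    "build_cohort",
    "run_null_calibration",
    "run_power_curve",
    "run_precision",
    "make_fixtures",
]

logger = logging.getLogger("gwasprec")

# seed-stream tags
_S_FOUNDERS, _S_POP, _S_MARKERS, _S_REF, _S_CAUSAL, _S_PHENO, _S_NULL = range(7)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class StrategyConfig:
    """One genotyping strategy: 'wgs' (all sequence variants), 'array'
    (markers only) or 'imputed' (markers imputed to a held-out reference
    of ``n_ref`` individuals covering markers plus a ``coverage`` fraction
    of the remaining sites)."""

    name: str
    kind: str = "wgs"
    n_ref: int = 0
    coverage: float = 1.0
    #: exclude every potential causal site (the configured causal classes)
    #: from the reference coverage -- the causal-absent-from-reference
    #: contrast; typed marker sites remain covered.
    exclude_causal_pool: bool = False
    #: inherit the realized variant coverage (covered sites that are
    #: polymorphic in the named earlier imputed strategy's reference) and
    #: include that reference's individuals -- the panel-size experiment at
    #: fixed variant coverage.
    coverage_from: str = ""

    def validate(self, path: str) -> None:
        if self.kind not in ("wgs", "array", "imputed"):
            raise ValueError(f"{path}.kind: unknown kind {self.kind!r}")
        if self.kind == "imputed" and self.n_ref < 1:
            raise ValueError(f"{path}.n_ref: imputed strategy needs n_ref >= 1")
        if not 0 < self.coverage <= 1:
            raise ValueError(f"{path}.coverage: must be in (0, 1]")
        if self.coverage_from and self.kind != "imputed":
            raise ValueError(f"{path}.coverage_from: only valid for imputed strategies")


def _default_strategies() -> list:
    return [
        StrategyConfig("wgs", "wgs"),
        StrategyConfig("array", "array"),
        StrategyConfig("imputed_small_ref", "imputed", n_ref=100, coverage=0.6),
        StrategyConfig("imputed_large_ref", "imputed", n_ref=250, coverage=0.9),
    ]


@dataclass
class ScenarioConfig:
    """Full experiment description (JSON-serialisable).

    The default scenario scales the study design down to desk size:
    n = 2000 individuals on a 20 Mbp chromosome with 2000 precision
    replicates at q2 = 2%, a 0..3% q2 power grid in 0.2% steps, and a
    1000-replicate null calibration on the 5e-8..1e-11 threshold grid.
    """

    # population
    n_individuals: int = 2000
    region_length: int = 20_000_000
    n_sites: int = 5000
    n_founders: int = 150
    sfs_shape: float = 1.0
    sfs_floor: float = 0.002
    founder_ld_length: float = 30_000.0
    founder_weight_exponent: float = 1.3
    young_mixing: float = 0.6
    switch_rate: float = 2e-6
    mutation_rate: float = 2e-4
    min_mac: int = 3
    # genotyping
    marker_density: float = DEFAULT_ARRAY_DENSITY
    rho: float = 4e-4
    epsilon: float = 5e-3
    strategies: list = field(default_factory=_default_strategies)
    # experiments
    q2_grid: tuple = tuple(round(0.002 * i, 3) for i in range(16))
    power_replicates: int = 5000
    null_replicates: int = 1000
    precision_replicates: int = 2000
    precision_q2: float = 0.02
    causal_classes: tuple = ("common", "rare")
    p_threshold: float = 5e-8
    thresholds: tuple = metrics.DEFAULT_THRESHOLD_GRID
    window: float = 20_000_000.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.strategies = [
            s if isinstance(s, StrategyConfig) else StrategyConfig(**s) for s in self.strategies
        ]
        self.validate()

    def validate(self) -> None:
        def check(cond, path, msg):
            if not cond:
                raise ValueError(f"config.{path}: {msg}")

        check(self.n_individuals >= 3, "n_individuals", "need at least 3 individuals")
        check(self.n_sites >= 1, "n_sites", "need at least 1 site")
        check(self.n_sites <= self.region_length, "n_sites", "more sites than base pairs")
        check(self.n_founders >= 2, "n_founders", "need at least 2 founders")
        check(self.switch_rate >= 0, "switch_rate", "must be >= 0")
        check(0 <= self.mutation_rate < 1, "mutation_rate", "must be in [0, 1)")
        check(self.min_mac >= 0, "min_mac", "must be >= 0")
        check(self.marker_density >= 0, "marker_density", "must be >= 0")
        check(self.power_replicates >= 1, "power_replicates", "must be >= 1")
        check(self.null_replicates >= 1, "null_replicates", "must be >= 1")
        check(self.precision_replicates >= 1, "precision_replicates", "must be >= 1")
        check(0 <= self.precision_q2 < 1, "precision_q2", "must be in [0, 1)")
        check(all(0 <= q < 1 for q in self.q2_grid), "q2_grid", "q2 values must be in [0, 1)")
        check(0 < self.p_threshold < 1, "p_threshold", "must be in (0, 1)")
        check(all(0 < t < 1 for t in self.thresholds), "thresholds", "must be in (0, 1)")
        check(self.window > 0, "window", "must be > 0")
        names = [s.name for s in self.strategies]
        check(len(names) == len(set(names)), "strategies", "strategy names must be unique")
        for i, s in enumerate(self.strategies):
            s.validate(f"strategies[{i}]")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("q2_grid", "causal_classes", "thresholds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def n_heldout(self) -> int:
        return max((s.n_ref for s in self.strategies if s.kind == "imputed"), default=0)


@dataclass
class StrategyData:
    """Materialised genotypes for one strategy: dosage matrix over the
    strategy's sites, with indices back into the study site list."""

    name: str
    kind: str
    site_indices: np.ndarray
    positions: np.ndarray
    X: np.ndarray
    maf: np.ndarray
    imputation: ImputationResult | None = None

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


@dataclass
class Cohort:
    """Study population plus materialised genotyping strategies."""

    config: ScenarioConfig
    study: HaplotypePanel
    vtable: pd.DataFrame
    geno: GenotypeMatrix  # true study genotypes, all filtered sites
    markers: MarkerSet
    strategies: dict

    @property
    def positions(self) -> np.ndarray:
        return self.study.positions

    def class_sites(self, variant_class: str) -> np.ndarray:
        return np.flatnonzero((self.vtable["class"] == variant_class).to_numpy())


def build_cohort(config: ScenarioConfig, site_masks: dict | None = None) -> Cohort:
    """Generate the population and materialise every configured strategy.

    ``site_masks`` optionally maps a strategy name to an explicit boolean
    reference-coverage mask over the study sites (markers are forced in);
    this enables the causal-present/causal-absent reference contrast.
    """
    cfg = config
    logger.info(
        "building cohort: n=%d (+%d held out), %d sites over %.1f Mbp, seed=%d",
        cfg.n_individuals, cfg.n_heldout, cfg.n_sites, cfg.region_length / 1e6, cfg.seed,
    )
    founders = generate_founders(
        cfg.n_founders,
        cfg.n_sites,
        cfg.region_length,
        sfs_shape=cfg.sfs_shape,
        seed=_rng(cfg.seed, _S_FOUNDERS).integers(2**31),
        ld_length=cfg.founder_ld_length,
        young_mixing=cfg.young_mixing,
        sfs_floor=cfg.sfs_floor,
    )
    population = generate_population(
        founders,
        cfg.n_individuals + cfg.n_heldout,
        cfg.switch_rate,
        cfg.mutation_rate,
        seed=_rng(cfg.seed, _S_POP).integers(2**31),
        founder_weight_exponent=cfg.founder_weight_exponent,
    )
    study_all = population.subset_individuals(np.arange(cfg.n_individuals))
    # QC on the study sample decides the global site list
    ac = study_all.allele_counts()
    mac = np.minimum(ac, study_all.haplotype_count - ac)
    keep = np.flatnonzero(mac >= max(cfg.min_mac, 1))
    population = population.subset_sites(keep)
    study, vtable = filter_variants(population.subset_individuals(np.arange(cfg.n_individuals)), 0)
    geno = haplotypes_to_genotypes(study)
    markers = select_markers(
        vtable,
        cfg.marker_density,
        cfg.region_length,
        seed=_rng(cfg.seed, _S_MARKERS).integers(2**31),
    )
    logger.info("retained %d sites (%d markers)", study.n_sites, markers.n_markers)

    strategies: dict = {}
    refs: dict = {}
    for i, s in enumerate(cfg.strategies):
        if s.kind == "wgs":
            idx = np.arange(study.n_sites)
            X = geno.dosages.astype(np.float64)
            imp = None
        elif s.kind == "array":
            idx = markers.indices
            X = geno.dosages[:, idx].astype(np.float64)
            imp = None
        else:  # imputed
            mask = None if site_masks is None else site_masks.get(s.name)
            must_include = None
            if mask is None and s.coverage_from:
                if s.coverage_from not in refs:
                    raise ValueError(
                        f"strategy {s.name!r}: coverage_from {s.coverage_from!r} "
                        "must name an earlier imputed strategy"
                    )
                prev = refs[s.coverage_from]
                ac = prev.haplotypes.allele_counts()
                poly = (ac > 0) & (ac < prev.haplotypes.haplotype_count)
                mask = prev.covered & poly
                must_include = prev.individuals
            if mask is None and s.exclude_causal_pool:
                mask = np.ones(study.n_sites, dtype=bool)
                for klass in cfg.causal_classes:
                    mask &= (vtable["class"] != klass).to_numpy()
            ref = build_reference(
                population,
                cfg.n_individuals,
                s.n_ref,
                coverage=s.coverage,
                marker_indices=markers.indices,
                site_mask=mask,
                seed=_rng(cfg.seed, _S_REF, i).integers(2**31),
                must_include=must_include,
            )
            refs[s.name] = ref
            target = study.subset_sites(markers.indices)
            imp = ls_impute(
                target, ref, rho=cfg.rho, epsilon=cfg.epsilon, truth=geno
            )
            idx = imp.site_indices
            X = imp.dosages
        maf = np.minimum(X.mean(axis=0) / 2.0, 1.0 - X.mean(axis=0) / 2.0)
        strategies[s.name] = StrategyData(
            name=s.name,
            kind=s.kind,
            site_indices=idx,
            positions=study.positions[idx],
            X=X,
            maf=maf,
            imputation=imp,
        )
        logger.info("strategy %-18s %d sites", s.name, idx.size)
    return Cohort(cfg, study, vtable, geno, markers, strategies)


# ---------------------------------------------------------------------------
# null calibration


def run_null_calibration(
    config: ScenarioConfig,
    cohort: Cohort | None = None,
    phenotype_kinds: tuple = ("normal",),
    batch: int = 200,
) -> metrics.CalibrationReport:
    """Genome-wide false-positive rate on the threshold grid.

    Phenotypes are standard normal with no genetic effect; the kinds
    'square' (y^2, strongly skewed) and 'square+inf' (y^2 followed by
    rank-based inverse-normal transformation) probe the sensitivity of
    rare-variant tests to phenotype skewness.  Report keys are
    ``strategy`` for the normal phenotype and ``strategy:kind`` otherwise.
    """
    if config.null_replicates < 1:
        raise ValueError("config.null_replicates: must be >= 1")
    for kind in phenotype_kinds:
        if kind not in ("normal", "square", "square+inf"):
            raise ValueError(f"unknown phenotype kind {kind!r}")
    cohort = cohort or build_cohort(config)
    n = config.n_individuals
    R = config.null_replicates
    thr = np.asarray(config.thresholds, dtype=float)
    minp: dict = {}
    for lo in range(0, R, batch):
        B = min(batch, R - lo)
        Y = {k: np.empty((B, n)) for k in phenotype_kinds}
        for b in range(B):
            pheno, _ = simulate_phenotype(
                np.zeros(n), 0.0, seed=_rng(config.seed, _S_NULL, lo + b).integers(2**31)
            )
            for kind in phenotype_kinds:
                if kind == "normal":
                    Y[kind][b] = pheno.y
                elif kind == "square":
                    Y[kind][b] = skew_transform(pheno).y
                else:
                    Y[kind][b] = inverse_normal_transform(skew_transform(pheno)).y
        for sname, sdata in cohort.strategies.items():
            for kind in phenotype_kinds:
                _, p = scan_many(Y[kind], sdata.X)
                key = sname if kind == "normal" else f"{sname}:{kind}"
                rows = minp.setdefault(key, [])
                rows.extend(np.nanmin(p, axis=1))
    out = {
        key: np.array([(np.asarray(v) < t).mean() for t in thr]) for key, v in minp.items()
    }
    return metrics.CalibrationReport(thresholds=thr, gwfpr=out, n_replicates=R)


# ---------------------------------------------------------------------------
# power


def run_power_curve(
    config: ScenarioConfig,
    cohort: Cohort | None = None,
    batch: int = 250,
) -> pd.DataFrame:
    """Power (fraction of replicates with any in-window site below the
    significance threshold) per strategy x causal class x q2 level."""
    cohort = cohort or build_cohort(config)
    rows = []
    for klass in config.causal_classes:
        sites = cohort.class_sites(klass)
        if sites.size == 0:
            logger.warning("no %s sites; skipping class", klass)
            continue
        for qi, q2 in enumerate(config.q2_grid):
            hits = {s: 0 for s in cohort.strategies}
            R = config.power_replicates
            for lo in range(0, R, batch):
                B = min(batch, R - lo)
                Y = np.empty((B, config.n_individuals))
                causal = np.empty(B, dtype=np.int64)
                for b in range(B):
                    r = lo + b
                    rng = _rng(config.seed, _S_CAUSAL, qi, r)
                    c = int(sites[rng.integers(sites.size)])
                    causal[b] = c
                    pheno, _ = simulate_phenotype(
                        cohort.geno.dosages[:, c],
                        q2,
                        seed=_rng(config.seed, _S_PHENO, qi, r).integers(2**31),
                    )
                    Y[b] = pheno.y
                for sname, sdata in cohort.strategies.items():
                    _, p = scan_many(Y, sdata.X)
                    for b in range(B):
                        if _any_hit(p[b], sdata.positions, cohort.positions[causal[b]], config):
                            hits[sname] += 1
            for sname in cohort.strategies:
                rows.append(
                    {
                        "strategy": sname,
                        "class": klass,
                        "q2": q2,
                        "power": hits[sname] / config.power_replicates,
                        "n_replicates": config.power_replicates,
                    }
                )
            logger.info("power %s q2=%.3f done", klass, q2)
    return pd.DataFrame(rows)


def _any_hit(p: np.ndarray, positions: np.ndarray, causal_pos: int, config) -> bool:
    half = config.window / 2.0
    sel = (positions >= causal_pos - half) & (positions <= causal_pos + half)
    pw = p[sel]
    pw = pw[np.isfinite(pw)]
    return bool(pw.size and pw.min() < config.p_threshold)


# ---------------------------------------------------------------------------
# mapping precision


_HIT_COLUMNS = [
    "replicate", "strategy", "powered", "causal_position", "causal_maf",
    "hit_position", "hit_maf", "distance", "maf_diff", "p_hit",
    "r2_with_causal", "q2_gwas", "hit_is_causal",
]


def _select_top(p_row, sdata, causal_pos, threshold, window) -> int | None:
    half = window / 2.0
    pos = sdata.positions
    ok = (
        np.isfinite(p_row)
        & (p_row < threshold)
        & (pos >= causal_pos - half)
        & (pos <= causal_pos + half)
    )
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    pv = p_row[idx]
    cand = idx[pv == pv.min()]
    if cand.size > 1:
        dist = np.abs(pos[cand] - causal_pos)
        cand = cand[dist == dist.min()]
    return int(cand.min())


def run_precision(
    config: ScenarioConfig,
    cohort: Cohort | None = None,
    batch: int = 250,
    out_dir: str | None = None,
) -> dict:
    """The mapping-precision experiment.

    Per replicate: sample a causal variant uniformly from the configured
    class, simulate a phenotype at ``precision_q2``, scan every strategy
    within the window around the causal position, and record the top hit.
    Returns ``{(strategy, class): PrecisionSummary}``.

    When ``out_dir`` is given, per-replicate rows are appended to
    ``precision_<class>.tsv`` as they complete (flushed per batch) and an
    interrupted run resumes after the last fully recorded replicate without
    duplicating rows.
    """
    cohort = cohort or build_cohort(config)
    out_dir = out_dir or config.out_dir
    q2 = config.precision_q2
    summaries = {}
    for klass in config.causal_classes:
        sites = cohort.class_sites(klass)
        if sites.size == 0:
            logger.warning("no %s sites; skipping class", klass)
            continue
        path = os.path.join(out_dir, f"precision_{klass}.tsv") if out_dir else None
        done_rows: list = []
        start = 0
        if path and os.path.exists(path):
            prev = pd.read_csv(path, sep="\t")
            n_strat = len(cohort.strategies)
            complete = len(prev) // n_strat
            prev = prev.iloc[: complete * n_strat]
            done_rows = prev.to_dict("records")
            start = complete
            logger.info("resuming %s precision at replicate %d", klass, start)
        fh = None
        if path:
            os.makedirs(out_dir, exist_ok=True)
            # rewrite the complete prefix, drop any partially written tail
            fh = open(path, "w")
            fh.write("\t".join(_HIT_COLUMNS) + "\n")
            for row in done_rows:
                fh.write("\t".join(_fmt(row[c]) for c in _HIT_COLUMNS) + "\n")
            fh.flush()
        rows = list(done_rows)
        R = config.precision_replicates
        class_id = list(config.causal_classes).index(klass)
        for lo in range(start, R, batch):
            B = min(batch, R - lo)
            Y = np.empty((B, config.n_individuals))
            causal = np.empty(B, dtype=np.int64)
            for b in range(B):
                r = lo + b
                rng = _rng(config.seed, _S_CAUSAL, 100 + class_id, r)
                c = int(sites[rng.integers(sites.size)])
                causal[b] = c
                pheno, _ = simulate_phenotype(
                    cohort.geno.dosages[:, c],
                    q2,
                    seed=_rng(config.seed, _S_PHENO, 100 + class_id, r).integers(2**31),
                )
                Y[b] = pheno.y
            batch_rows = [[] for _ in range(B)]
            for sname, sdata in cohort.strategies.items():
                _, p = scan_many(Y, sdata.X)
                for b in range(B):
                    row = _hit_row(
                        lo + b, sname, sdata, cohort, p[b], causal[b], Y[b], config
                    )
                    batch_rows[b].append(row)
            for b in range(B):
                for row in batch_rows[b]:
                    rows.append(row)
                    if fh:
                        fh.write("\t".join(_fmt(row[c]) for c in _HIT_COLUMNS) + "\n")
            if fh:
                fh.flush()
            logger.info("precision %s: %d/%d replicates", klass, min(lo + B, R), R)
        if fh:
            fh.close()
        for sname in cohort.strategies:
            hits = [
                _row_to_hit(row)
                for row in rows
                if row["strategy"] == sname and row["powered"]
            ]
            if hits:
                summaries[(sname, klass)] = metrics.summarize_hits(
                    hits, sname, klass, n_attempted=R
                )
            else:
                logger.warning("no powered replicates for %s/%s", sname, klass)
    return summaries


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    return str(v)


def _hit_row(replicate, sname, sdata, cohort, p_row, causal_idx, y, config) -> dict:
    causal_pos = int(cohort.positions[causal_idx])
    causal_f = float(cohort.vtable["f"].iloc[causal_idx])
    causal_maf = min(causal_f, 1 - causal_f)
    base = {
        "replicate": replicate,
        "strategy": sname,
        "powered": 0,
        "causal_position": causal_pos,
        "causal_maf": causal_maf,
        "hit_position": -1,
        "hit_maf": float("nan"),
        "distance": -1,
        "maf_diff": float("nan"),
        "p_hit": float("nan"),
        "r2_with_causal": float("nan"),
        "q2_gwas": float("nan"),
        "hit_is_causal": 0,
    }
    top = _select_top(p_row, sdata, causal_pos, config.p_threshold, config.window)
    if top is None:
        return base
    hit_site = int(sdata.site_indices[top])
    hit_pos = int(sdata.positions[top])
    # LD with the causal variant always measured on the true genotypes
    xc = cohort.geno.dosages[:, causal_idx].astype(float)
    xh = cohort.geno.dosages[:, hit_site].astype(float)
    r2 = float(np.corrcoef(xc, xh)[0, 1] ** 2) if xh.std() > 0 else float("nan")
    base.update(
        powered=1,
        hit_position=hit_pos,
        hit_maf=float(sdata.maf[top]),
        distance=abs(hit_pos - causal_pos),
        maf_diff=abs(float(sdata.maf[top]) - causal_maf),
        p_hit=float(p_row[top]),
        r2_with_causal=r2,
        q2_gwas=variance_explained(y, sdata.X[:, top]),
        hit_is_causal=int(hit_site == causal_idx),
    )
    return base


def _row_to_hit(row: dict) -> HitRecord:
    return HitRecord(
        replicate=int(row["replicate"]),
        strategy=row["strategy"],
        causal_position=int(row["causal_position"]),
        causal_maf=float(row["causal_maf"]),
        hit_position=int(row["hit_position"]),
        hit_maf=float(row["hit_maf"]),
        distance=int(row["distance"]),
        maf_diff=float(row["maf_diff"]),
        p_hit=float(row["p_hit"]),
        r2_with_causal=float(row["r2_with_causal"]),
        q2_gwas=float(row["q2_gwas"]),
        hit_is_causal=bool(int(row["hit_is_causal"])),
    )


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, out_dir: str) -> dict:
    """Write a tiny deterministic dataset for tests and demos.

    200 individuals, 1 Mbp, ~400 sites: phased VCF of the study panel, the
    variant table, the marker list, one phenotype replicate and its scan
    summary, plus a JSON manifest.  Regenerates bit-identically per seed.
    """
    from . import io as gio
    from .assoc import scan

    cfg = ScenarioConfig(
        n_individuals=200,
        region_length=1_000_000,
        n_sites=400,
        n_founders=100,
        strategies=[StrategyConfig("wgs", "wgs"), StrategyConfig("array", "array")],
        marker_density=1e-4,
        precision_replicates=10,
        null_replicates=10,
        power_replicates=10,
        seed=seed,
    )
    cohort = build_cohort(cfg)
    os.makedirs(out_dir, exist_ok=True)
    gio.write_vcf(cohort.study, os.path.join(out_dir, "study.vcf"))
    cohort.vtable.to_csv(os.path.join(out_dir, "variants.tsv"), sep="\t", index=False, float_format="%.6g")
    cohort.markers.to_frame(cohort.positions).to_csv(
        os.path.join(out_dir, "markers.tsv"), sep="\t", index=False
    )
    common = cohort.class_sites("common")
    causal = int(common[_rng(seed, _S_CAUSAL).integers(common.size)])
    pheno, spec = simulate_phenotype(
        cohort.geno.dosages[:, causal],
        cfg.precision_q2,
        seed=_rng(seed, _S_PHENO).integers(2**31),
        position=int(cohort.positions[causal]),
        site_index=causal,
    )
    gio.write_phenotype_tsv(pheno, os.path.join(out_dir, "phenotype.tsv"))
    res = scan(pheno.y, cohort.geno, strategy="wgs")
    res.to_frame().to_csv(
        os.path.join(out_dir, "assoc_wgs.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    manifest = {
        "seed": seed,
        "n_individuals": cfg.n_individuals,
        "n_sites_retained": cohort.study.n_sites,
        "n_markers": cohort.markers.n_markers,
        "causal_site": causal,
        "causal_position": int(cohort.positions[causal]),
        "causal_q2": cfg.precision_q2,
        "min_p": float(np.nanmin(res.p)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
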