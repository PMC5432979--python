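"""Shared fixtures.

The two session-scoped cohorts are the expensive objects: a study-scale
population (n = 2000 on 20 Mbp) with the full-sequence versus
50%-coverage-imputation contrast, and the reference coverage-versus-size
experiment (full, causal-masked, and doubled-at-fixed-coverage panels).
Several unit and property tests reuse them rather than regenerating
populations of their own.
"""

from __future__ import annotations

import numpy as np
import pytest

from gwasprec.pipeline import (
    ScenarioConfig,
    StrategyConfig,
    build_cohort,
    run_precision,
)


@pytest.fixture(scope="session")
def contrast_cfg() -> ScenarioConfig:
    return ScenarioConfig(
        strategies=[
            StrategyConfig("wgs", "wgs"),
            StrategyConfig("imputed", "imputed", n_ref=100, coverage=0.5),
        ],
        precision_replicates=1500,
        seed=7,
    )


@pytest.fixture(scope="session")
def contrast_cohort(contrast_cfg):
    """Study cohort with the full-sequence vs imputed(50% coverage) panels."""
    return build_cohort(contrast_cfg)


@pytest.fixture(scope="session")
def contrast_precision(contrast_cfg, contrast_cohort):
    """Mapping-precision summaries for the WGS vs imputed contrast."""
    return run_precision(contrast_cfg, cohort=contrast_cohort)


@pytest.fixture(scope="session")
def coverage_cfg() -> ScenarioConfig:
    # per-test threshold 1e-4 reproduces the family-wise regime of
    # genome-wide 5e-8 at full sequencing-study multiplicity (~17.6M tests)
    # on this panel's ~4.3k tests
    return ScenarioConfig(
        strategies=[
            StrategyConfig("imp_base", "imputed", n_ref=100, coverage=1.0),
            StrategyConfig(
                "imp_masked", "imputed", n_ref=100, coverage=1.0, exclude_causal_pool=True
            ),
            StrategyConfig(
                "imp_double", "imputed", n_ref=200, coverage=1.0, coverage_from="imp_base"
            ),
        ],
        precision_replicates=1500,
        causal_classes=("rare",),
        p_threshold=1e-4,
        seed=7,
    )


@pytest.fixture(scope="session")
def coverage_experiment(coverage_cfg):
    """Precision summaries for full / causal-masked / doubled references."""
    cohort = build_cohort(coverage_cfg)
    return run_precision(coverage_cfg, cohort=cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
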