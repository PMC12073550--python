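"""Shared fixtures: simulated trials at several sizes and cached fits."""

from __future__ import annotations

import logging
import time

import pytest

from provsel.pipeline import PipelineConfig, run_pipeline
from provsel.mixed_models import fit_met_model, fit_site_model
from provsel.simulate import (
    TraitParams,
    TrialDesign,
    VarianceParams,
    default_design,
    default_params,
    simulate_met,
)

logging.getLogger("provsel").setLevel(logging.WARNING)


def make_design(
    n_prov: int,
    n_sites: int = 1,
    n_blocks: int = 3,
    n_trees: int = 5,
    trait: str = "Y",
) -> TrialDesign:
    """Fully balanced design with every provenance at every site."""
    sites = tuple(f"S{i + 1}" for i in range(n_sites))
    provs = tuple(f"G{j + 1:04d}" for j in range(n_prov))
    return TrialDesign(
        site_ids=sites,
        provenance_sets={s: provs for s in sites},
        n_blocks=n_blocks,
        n_trees_per_plot=n_trees,
        traits={trait: True},
    )


def one_trait_params(trait: str = "Y", **kwargs) -> VarianceParams:
    return VarianceParams({trait: TraitParams(**kwargs)})


@pytest.fixture(scope="session")
def default_data():
    """The built-in three-site scenario (61 provenances, 3 blocks, 25 trees)."""
    return simulate_met(default_design(), default_params(), seed=1)


@pytest.fixture(scope="session")
def pipeline_run():
    """Full pipeline on the default scenario, with its wall-clock time."""
    cfg = PipelineConfig(scenario="default", seed=1)
    t0 = time.perf_counter()
    result = run_pipeline(cfg)
    elapsed = time.perf_counter() - t0
    return result, elapsed


SITE_TRUTH = {"v_p": 3.36, "v_r": 19.68}  # total-height scale at one site


@pytest.fixture(scope="session")
def site_recovery():
    """Single-site fit on data simulated at ten times the trial's
    provenance count (550 provenances, 3 blocks)."""
    design = make_design(550, n_sites=1, n_blocks=3, n_trees=4)
    params = one_trait_params(grand_mean=30.36, **SITE_TRUTH)
    data = simulate_met(design, params, seed=11)
    fit = fit_site_model(data, "Y")
    return SITE_TRUTH, fit


MET_TRUTH = {"v_p": 3.53, "v_ge": 3.91, "v_r": 5.69}  # diameter scale


@pytest.fixture(scope="session")
def met_recovery():
    """Across-site fit on data simulated at ten times the common-set size
    (380 provenances at 3 sites)."""
    design = make_design(380, n_sites=3, n_blocks=3, n_trees=3)
    params = one_trait_params(grand_mean=33.03, **MET_TRUTH)
    data = simulate_met(design, params, seed=1)
    fit = fit_met_model(data, "Y")
    return MET_TRUTH, fit
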