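"""Shared synthetic-landscape fixtures.

All fixtures are generated programmatically; the desk-scale landscape keeps
the study window (97-112 degE, 22-36 degN) at a coarser 0.25 deg cell so the
whole suite stays fast.
"""

import numpy as np
import pytest

import popsdm as p


@pytest.fixture(scope="session")
def small_spec() -> p.SyntheticSpec:
    return p.SyntheticSpec(nrows=56, ncols=60, cellsize=0.25, seed=11)


@pytest.fixture(scope="session")
def stack(small_spec) -> p.RasterStack:
    return p.generate_climate_stack(small_spec)


@pytest.fixture(scope="session")
def occurrences(stack, small_spec) -> p.OccurrenceSet:
    return p.generate_populations(stack, small_spec)


@pytest.fixture(scope="session")
def full_mask(stack) -> p.RasterGrid:
    t = stack.template
    return t.copy_with(np.ones((t.nrows, t.ncols)))


@pytest.fixture(scope="session")
def background_climate(stack, full_mask):
    bg = p.sample_background(full_mask, n=1000, seed=7)
    return p.extract_values(stack, bg.as_occurrences())


@pytest.fixture(scope="session")
def presence_climate(stack, occurrences):
    return p.extract_values(stack, occurrences)


@pytest.fixture(scope="session")
def scaled_config() -> p.PipelineConfig:
    """Desk-scale pipeline settings: standard thresholds, smaller
    background / tuning grid / replicate counts."""
    return p.PipelineConfig(background_n=800, rm_grid=(0.5, 1.0),
                            fc_combos=("L", "LQ"), eval_splits=3,
                            bootstrap_reps=6, lda_reps=100, n_knots=8, seed=5)


@pytest.fixture(scope="session")
def scenario_stacks(stack) -> dict:
    shift_2050 = {"Bio01": {"offset": 1.5}, "Bio04": {"offset": 0.8},
                  "Bio14": {"factor": 0.9}}
    shift_2070 = {"Bio01": {"offset": 2.8}, "Bio04": {"offset": 1.5},
                  "Bio14": {"factor": 0.8}}
    return {"2050s_RCP8.5": p.generate_future_stack(stack, shift_2050),
            "2070s_RCP8.5": p.generate_future_stack(stack, shift_2070)}


@pytest.fixture(scope="session")
def pipeline_report(occurrences, stack, scenario_stacks, scaled_config):
    return p.run_pipeline(occurrences, stack, scenario_stacks, scaled_config)


def make_grid(values, xll=0.0, yll=0.0, cellsize=1.0) -> p.RasterGrid:
    values = np.asarray(values, dtype=float)
    return p.RasterGrid(values.shape[0], values.shape[1], xll, yll, cellsize, values)


@pytest.fixture
def grid_factory():
    return make_grid
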