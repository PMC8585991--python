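import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortexpls as cx

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# permutation/bootstrap helpers log expected warnings at small resampling
# depths; keep test output quiet
logging.getLogger("cortexpls").setLevel(logging.ERROR)


def standardized_instance(rng, n_regions, n_genes):
    """Random column-standardized X and centered-scale y."""
    X = rng.standard_normal((n_regions, n_genes))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = rng.standard_normal(n_regions)
    return X, y


@pytest.fixture(scope="session")
def planted():
    """Moderate planted-signal dataset shared by the slower statistical tests."""
    cfg = cx.SimulationConfig(n_regions=100, n_genes=400, n_subjects_a=40,
                              n_subjects_b=30, n_causal=15, effect_size=2.0,
                              subject_noise_sd=0.05, seed=7)
    expr = cx.generate_expression(cfg)
    cohort, truth = cx.generate_cohort(expr, cfg)
    dct = cx.compute_delta_ct(cohort, "stable", "converter")
    exprz = cx.standardize_genes(expr)
    exprz, dct = cx.align(exprz, dct)
    return {"config": cfg, "expr": expr, "exprz": exprz, "cohort": cohort,
            "truth": truth, "dct": dct}


@pytest.fixture(scope="session")
def planted_report(tmp_path_factory):
    """Full pipeline run on a small planted-signal simulation."""
    outdir = tmp_path_factory.mktemp("planted_run")
    config = cx.PipelineConfig(
        simulation=cx.SimulationConfig(n_regions=100, n_genes=400,
                                       n_subjects_a=40, n_subjects_b=30,
                                       n_causal=15, effect_size=2.0,
                                       subject_noise_sd=0.05, seed=11),
        max_components=8, folds=5, n_perm=499, n_boot=200,
        seed=11, outdir=str(outdir))
    return cx.run_pipeline(config), config


@pytest.fixture(scope="session")
def null_report(tmp_path_factory):
    """Full pipeline run with no planted signal (effect size zero)."""
    outdir = tmp_path_factory.mktemp("null_run")
    config = cx.PipelineConfig(
        simulation=cx.SimulationConfig(n_regions=100, n_genes=400,
                                       n_subjects_a=40, n_subjects_b=30,
                                       n_causal=15, effect_size=0.0,
                                       subject_noise_sd=0.05, seed=12),
        max_components=8, folds=5, n_perm=499, n_boot=200,
        seed=12, outdir=str(outdir))
    return cx.run_pipeline(config), config
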