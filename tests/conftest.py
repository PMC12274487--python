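"""Shared fixtures: seeded simulation runs reused across test modules.

The heavier study-scale runs (used for parameter recovery and sampling
checks) are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import pytest

from amplifid import AmpliconFidelityModel, SimConfig, default_reference
from amplifid.simulate import simulate_experiment


def noise_free_config(**overrides) -> SimConfig:
    """A configuration with error-free sequencing: Q93 calls, no post-UMI
    errors, no phasing, no contaminants.  Efficiency 1 makes D equal the
    cycle count exactly."""
    base = dict(
        n_input_molecules=400,
        pre_umi_error_rate=0.0,
        n_pcr_cycles=6,
        per_cycle_efficiency=1.0,
        population_cap=26_000,
        n_umi_molecules=600,
        reads_per_family_mean=8.0,
        post_umi_error_rate=0.0,
        quality_mean=93.0,
        quality_sd=0.0,
        adapter_dimer_fraction=0.0,
        phasing_shift_probability=0.0,
        seed=42,
    )
    base.update(overrides)
    return SimConfig(**base)


def study_scale_config(pre_umi_error_rate: float, seed: int) -> SimConfig:
    """The fidelity-assay study conditions at desk scale: 10^4 input copies,
    12 cycles at 90% efficiency, ~2,400 UMI families of mean size 10,
    Q30-centred qualities."""
    return SimConfig(pre_umi_error_rate=pre_umi_error_rate, seed=seed)


def run_full_pipeline(config: SimConfig, out_dir):
    r1, r2, truth = simulate_experiment(config, out_dir)
    model = AmpliconFidelityModel.from_fastq(
        r1, r2, doubling_number=truth.D_true
    )
    return truth, model.fit()


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def zero_sim(tmp_path_factory):
    """Error-free end to end: no polymerase errors, no sequencing noise."""
    out = tmp_path_factory.mktemp("zero_sim")
    cfg = noise_free_config()
    truth, results = run_full_pipeline(cfg, out)
    return cfg, truth, results, out


@pytest.fixture(scope="session")
def planted_sim(tmp_path_factory):
    """Polymerase errors planted at a high rate, sequencing error-free."""
    out = tmp_path_factory.mktemp("planted_sim")
    cfg = noise_free_config(pre_umi_error_rate=0.004, seed=43)
    truth, results = run_full_pipeline(cfg, out)
    return cfg, truth, results, out


@pytest.fixture(scope="session")
def rt_taq_run(tmp_path_factory):
    """Study-scale recovery run with the parental-enzyme error rate planted."""
    out = tmp_path_factory.mktemp("rt_taq_run")
    cfg = study_scale_config(pre_umi_error_rate=0.0007, seed=20_24)
    return run_full_pipeline(cfg, out)


@pytest.fixture(scope="session")
def v2_run(tmp_path_factory):
    """Study-scale recovery run with the engineered-variant rate planted."""
    out = tmp_path_factory.mktemp("v2_run")
    cfg = study_scale_config(pre_umi_error_rate=0.0021, seed=20_25)
    return run_full_pipeline(cfg, out)


@pytest.fixture(scope="session")
def suppression_run(tmp_path_factory):
    """No polymerase errors, realistic Q30 sequencing noise: everything the
    consensus caller reports is a false positive."""
    out = tmp_path_factory.mktemp("suppression")
    cfg = SimConfig(
        pre_umi_error_rate=0.0,
        n_umi_molecules=2_100,
        reads_per_family_mean=8.0,
        adapter_dimer_fraction=0.0,
        phasing_shift_probability=0.0,
        seed=7,
    )
    return run_full_pipeline(cfg, out)
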