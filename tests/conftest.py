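import pytest

import pp13screen as p


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort at study-default effect structure, fixed seed."""
    cfg = p.CohortConfig(n_subjects=800, seed=11)
    subjects, samples = p.generate_cohort(cfg)
    return cfg, subjects, samples


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    cfg, subjects, samples = default_cohort
    moms = p.score_cohort(subjects, samples)
    return cfg, subjects, samples, moms


@pytest.fixture(scope="session")
def null_effect_config():
    """Generator with no blood-group, disease, covariate or noise effects."""
    return p.CohortConfig(
        n_subjects=60,
        group_serum_multipliers={g: (1.0, 1.0, 1.0) for g in p.BLOOD_GROUPS},
        disease_mom_multipliers={o: (1.0, 1.0, 1.0) for o in p.OUTCOMES},
        covariate_effects={},
        log_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def binding_panel():
    return p.generate_binding_panel(p.BindingConfig(), seed=3)
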