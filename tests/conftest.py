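import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from foundorfly import synthetic
from foundorfly.io import QueenMorphRecord
from foundorfly.morphometrics import profile_table
from foundorfly.synthetic import TraitSpec

TRAIT_FIELDS = (
    "head_width",
    "abdomen_mass",
    "thorax_mass",
    "wing_mass",
    "residual_mass",
    "forewing_length",
    "total_wing_area",
    "abdomen_shape_ratio",
)


def zero_sd(spec):
    """Copy of a caste spec with every trait SD set to zero."""
    updates = {
        f: TraitSpec(getattr(spec, f).mean, 0.0) for f in TRAIT_FIELDS
    }
    return dataclasses.replace(spec, **updates)


def uniform_mass_queens(rng, n, lo=3.5, hi=6.5):
    """Minimal queen records with uniformly spread abdomen masses (mg)."""
    masses = rng.uniform(lo, hi, n)
    return [
        QueenMorphRecord(
            queen_id=f"q{i:03d}",
            species="invicta",
            caste="claustral",
            colony_id=f"c{i % 3}",
            abdomen_mass=float(m),
        )
        for i, m in enumerate(masses)
    ]


@pytest.fixture(scope="session")
def ic_cohort():
    """Synthetic claustral S. invicta cohort at the study sample size."""
    return synthetic.generate_morphometry(
        synthetic.caste_spec("invicta", "claustral"), seed=11
    )


@pytest.fixture(scope="session")
def all_caste_profiles():
    """Per-queen flight indices for all four synthetic cohorts."""
    records = []
    for i, (key, spec) in enumerate(sorted(synthetic.default_caste_specs().items())):
        records.extend(synthetic.generate_morphometry(spec, seed=100 + i))
    return profile_table(records)


@pytest.fixture(scope="session")
def degenerate_profiles():
    """Zero-variance cohorts: every queen sits at her caste's mean."""
    records = []
    for key, spec in sorted(synthetic.default_caste_specs().items()):
        records.extend(
            synthetic.generate_morphometry(zero_sd(spec), seed=0)
        )
    return profile_table(records)
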