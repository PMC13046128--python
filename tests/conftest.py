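import numpy as np
import pytest

from cordpolar.pipeline import StudyConfig, run_synthetic_study
from cordpolar.synthdata import (GrayMatterParams, PopulationSpec, RadialLaw,
                                 SectionConfig, VonMisesComponent,
                                 make_section_geometry)


def small_gray() -> GrayMatterParams:
    """Half-scale butterfly for fast unit tests."""
    return GrayMatterParams(
        band_semi_um=(60.0, 48.0),
        ventral_center_um=(62.0, 58.0), ventral_semi_um=(75.0, 62.0),
        ventral_rot_deg=30.0,
        dorsal_center_um=(48.0, -68.0), dorsal_semi_um=(45.0, 75.0),
        dorsal_rot_deg=-18.0,
    )


def small_config(**kwargs) -> SectionConfig:
    defaults = dict(
        image_size=(320, 320), gray=small_gray(), canal_radius_um=8.0,
        populations=(
            PopulationSpec(
                "ventral", ("ChAT",), 12,
                (VonMisesComponent(305.0, 2.0), VonMisesComponent(235.0, 2.0)),
                RadialLaw("uniform", 0.3, 0.8), (14.0, 24.0)),
            PopulationSpec(
                "spread", ("GAD67",), 20,
                (VonMisesComponent(0.0, 0.0),),
                RadialLaw("uniform", 0.2, 0.85), (10.0, 16.0)),
        ),
        enforce_separation=True, poisson_counts=False, seed=0,
    )
    defaults.update(kwargs)
    return SectionConfig(**defaults)


@pytest.fixture(scope="session")
def small_geometry():
    return make_section_geometry(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study_bundle():
    """A tiny but complete synthetic study, shared across pipeline tests."""
    config = StudyConfig(
        genotypes=("+/+", "-/+"), animals_per_genotype=2,
        sections_per_animal=2,
        section=SectionConfig(enforce_separation=True),
        seed=7, n_perm=300,
    )
    return config, run_synthetic_study(config)
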