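import pytest

from ldctqa.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A compact, fast, arch-enabled phantom spec used across the suite."""
    base = dict(
        shape=(64, 64, 80),
        spacing=(1.5, 1.5, 2.0),
        caudal_gap_slices=8,
        cranial_gap_slices=16,
        lung_semiaxis_x_mm=16.0,
        lung_semiaxis_y_mm=26.0,
        lung_offset_x_mm=20.0,
        lumen_radius_mm=8.0,
        arch_radius_mm=18.0,
        descending_y_mm=20.0,
        noise_sigma=20.0,
        seed=42,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic small phantom (volume, truth), shared read-only."""
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def phantom_vol(phantom_pair):
    return phantom_pair[0]


@pytest.fixture(scope="session")
def phantom_truth(phantom_pair):
    return phantom_pair[1]
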