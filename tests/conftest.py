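import pytest

from gsiprofile import (
    FocalSpot,
    PresetFamily,
    ProfileConstraints,
    published_candidate_table,
    published_profile,
)


@pytest.fixture(scope="session")
def candidate_table():
    return published_candidate_table()


@pytest.fixture(scope="session")
def abdomen_constraints():
    """Large-body 80 mm abdomen protocol, pitch capped at 1.375, XLarge allowed."""
    return ProfileConstraints(
        sfov="Large Body", collimation_mm=80.0, pitch_max=1.375, allow_xlarge=True
    )


@pytest.fixture(scope="session")
def liver_profile():
    return published_profile("liver")


@pytest.fixture
def grid_family():
    """Simple family with an explicit 100..500 mA grid, 1 mGy per 100 mA."""
    return PresetFamily(
        name="grid",
        sfov="Large Body",
        focal_spot=FocalSpot.LARGE,
        collimation_mm=80.0,
        rotation_time_s=1.0,
        pitch=1.0,
        ma_grid=(100.0, 200.0, 300.0, 400.0, 500.0),
        dose_coeff=0.01,
    )


def bounds_family(
    lo,
    hi,
    pitch=0.992,
    rot=0.8,
    focal=FocalSpot.LARGE,
    sfov="Large Body",
    coll=80.0,
    name=None,
):
    return PresetFamily(
        name=name or f"f{lo:g}-{hi:g}",
        sfov=sfov,
        focal_spot=focal,
        collimation_mm=coll,
        rotation_time_s=rot,
        pitch=pitch,
        ctdi_min=lo,
        ctdi_max=hi,
    )
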