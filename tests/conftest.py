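import numpy as np
import pytest

from paintprox import (
    AcquisitionConfig,
    GolgiGeometry,
    LocalizationTable,
    TargetLayout,
    build_golgi_model,
)


def make_table(points, channel="A", frames=None, **kwargs) -> LocalizationTable:
    """LocalizationTable from an (n, 2) array-like of nm coordinates."""
    pts = np.asarray(points, float).reshape(-1, 2)
    return LocalizationTable.from_arrays(
        pts[:, 0], pts[:, 1], frame=frames, channel=channel, **kwargs
    )


@pytest.fixture
def flat_two_layer_model():
    """Two parallel flat layers 30 nm apart, dense labeling."""
    geom = GolgiGeometry(
        ribbon_length=10_000.0,
        ribbon_width=100.0,
        curvature=0.0,
        field_of_view=(12_000.0, 2_000.0),
        n_stacks=1,
    )
    layouts = [
        TargetLayout("A", "layer", axial_offset=0.0, site_density=700.0),
        TargetLayout("B", "layer", axial_offset=30.0, site_density=700.0),
    ]
    return build_golgi_model(geom, layouts, seed=0)


@pytest.fixture
def noise_free_acq():
    """Acquisition with every stochastic degradation switched off."""
    return AcquisitionConfig(
        round_order=("A", "B"),
        mean_blinks_per_site=1.0,
        blink_count_law="fixed",
        sigma_loc=0.0,
        linkage_radius=0.0,
        false_rate=0.0,
        erasure_efficiency=1.0,
    )


@pytest.fixture
def small_ring_model():
    """Three small ring ministacks for fast multi-channel runs."""
    geom = GolgiGeometry(
        ribbon_length=3 * 2 * np.pi * 300.0,
        ribbon_width=150.0,
        curvature=1.0 / 300.0,
        field_of_view=(5_000.0, 5_000.0),
        n_stacks=3,
    )
    layouts = [
        TargetLayout("cis", "layer", axial_offset=0.0, site_density=400.0),
        TargetLayout("medial", "layer", axial_offset=60.0, site_density=400.0),
        TargetLayout("trans", "layer", axial_offset=110.0, site_density=400.0),
        TargetLayout(
            "bridge",
            "interface_puncta",
            axial_offset=25.0,
            puncta_count=30,
            puncta_radius=35.0,
            site_density=5000.0,
        ),
    ]
    return build_golgi_model(geom, layouts, seed=1)
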