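import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_results():
    """The four groove x seeding alignment scenarios, solved once per session."""
    from strainavoid.scenarios import run_scenario

    names = ("3d_parallel", "2d_parallel", "2d_perpendicular", "3d_perpendicular")
    return {name: run_scenario(name) for name in names}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_bar_mesh_2d(length=10.0, height=2.0, h=0.5):
    """Single-region 2D bar with clamped/moving end tags."""
    from strainavoid.mesh import coords1d, structured_mesh

    axes = (coords1d([0.0, length], h), coords1d([0.0, height], h))

    def tag(cent, normals):
        t = np.full(len(cent), "free", dtype="<U24")
        t[(np.abs(cent[:, 0]) < 1e-9) & (normals[:, 0] < 0)] = "clamped_end"
        t[(np.abs(cent[:, 0] - length) < 1e-9) & (normals[:, 0] > 0)] = "moving_end"
        return t

    return structured_mesh(axes, lambda c: np.full(len(c), "solid", dtype=object), tag)


def make_bar_mesh_3d(length=4.0, width=1.0, height=1.0, h=0.5):
    from strainavoid.mesh import coords1d, structured_mesh

    axes = (
        coords1d([0.0, length], h),
        coords1d([0.0, width], h),
        coords1d([0.0, height], h),
    )

    def tag(cent, normals):
        t = np.full(len(cent), "free", dtype="<U24")
        t[(np.abs(cent[:, 0]) < 1e-9) & (normals[:, 0] < 0)] = "clamped_end"
        t[(np.abs(cent[:, 0] - length) < 1e-9) & (normals[:, 0] > 0)] = "moving_end"
        return t

    return structured_mesh(axes, lambda c: np.full(len(c), "solid", dtype=object), tag)
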