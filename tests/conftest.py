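"""Shared phantom fixtures.

Heavy objects (solved Laplace fields, endocardial maps) are session-scoped:
each is built once and shared across test modules.
"""

import numpy as np
import pytest

from vtsubstrate.laplace import solve_laplace
from vtsubstrate.phantom import PhantomSpec, ScarPatch, make_label_volume
from vtsubstrate.streamlines import build_endocardial_map


@pytest.fixture(scope="session")
def slab_phantom():
    """10 mm slab with a half-depth scar patch, noiseless."""
    spec = PhantomSpec(
        shape_kind="slab",
        scar_patches=[
            ScarPatch(center=(0.0, 0.0), extent=12.0, transmural_fraction=0.5)
        ],
        noise_sd=0.0,
    )
    return spec, *make_label_volume(spec)


@pytest.fixture(scope="session")
def slab_solved(slab_phantom):
    _, labels, _, _ = slab_phantom
    field = solve_laplace(labels)
    return labels, field


@pytest.fixture(scope="session")
def shell_phantom():
    """Plain spherical shell, R = 20 / 30 mm, noiseless, no scar."""
    spec = PhantomSpec(
        shape_kind="spherical_shell",
        shell_r_endo_mm=20.0,
        shell_r_epi_mm=30.0,
        noise_sd=0.0,
    )
    return spec, *make_label_volume(spec)


@pytest.fixture(scope="session")
def shell_solved(shell_phantom):
    _, labels, _, _ = shell_phantom
    field = solve_laplace(labels)
    return labels, field


@pytest.fixture(scope="session")
def shell_endo_map(shell_solved):
    labels, field = shell_solved
    return build_endocardial_map(labels, field)


@pytest.fixture(scope="session")
def pipeline_result():
    from vtsubstrate.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=1))


def shell_analytic_u(r, r1=20.0, r2=30.0):
    """Harmonic potential between concentric spheres (u=0 inner, 1 outer)."""
    return (1.0 / r1 - 1.0 / np.asarray(r)) / (1.0 / r1 - 1.0 / r2)
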