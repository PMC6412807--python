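import numpy as np
import pytest

from channeltess import (
    annotate_cvmax,
    build_graph,
    make_shell_pore,
    make_two_pore,
    resolve_target,
    select_atoms,
    triangulate,
)


def run_pipeline(model):
    """Tessellate a model and return (atoms, tessellation, facial graph)."""
    atoms = select_atoms(model)
    tess = annotate_cvmax(triangulate(atoms))
    fg = build_graph(tess, resolve_target(atoms))
    return atoms, tess, fg


@pytest.fixture(scope="session")
def shell_bundle():
    """Default shell-pore fixture (aperture 8 A, carbon-sized atoms), analysed."""
    model = make_shell_pore(seed=0)
    atoms, tess, fg = run_pipeline(model)
    return model, atoms, tess, fg


@pytest.fixture(scope="session")
def two_pore_bundle():
    """Default two-pore fixture (apertures 8 / 7.5 A), analysed."""
    model = make_two_pore(seed=0)
    atoms, tess, fg = run_pipeline(model)
    return model, atoms, tess, fg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
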