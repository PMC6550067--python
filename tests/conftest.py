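"""Shared fixtures: phantoms are generated at test time, never stored."""

from __future__ import annotations

import numpy as np
import pytest

from myelometry.grids import GridSpec
from myelometry.phantom import (
    NodeSpec,
    build_fibre_phantom,
    build_node_phantom,
    render_em,
    straight_fibre,
)


@pytest.fixture(scope="session")
def cylinder():
    """Straight d=1.2/D=2.0 fibre, 20 µm long, 0.05 µm isotropic voxels."""
    vox = 0.05
    grid = GridSpec((int(20.4 / vox), 56, 56), (vox, vox, vox))
    spec = straight_fibre(1.2, 2.0, 20.0, grid)
    labels, truth = build_fibre_phantom(spec, grid)
    return {"grid": grid, "spec": spec, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def cylinder_em(cylinder):
    """Noiseless EM render of the session cylinder."""
    return render_em(cylinder["labels"])


@pytest.fixture(scope="session")
def node_phantom():
    """Node phantom: d=1.5/D=3.5, 10 lamellae per side, 0.02 µm voxels."""
    vox = 0.02
    grid = GridSpec((int(4.4 / vox), int(4.0 / vox), int(4.0 / vox)), (vox,) * 3)
    fibre = straight_fibre(1.5, 3.5, 4.0, grid)
    node = NodeSpec(
        gap_length_um=0.8,
        n_lamellae_per_side=10,
        lamellar_period_um=0.08,
        paranode_length_um=0.8,
    )
    labels, truth = build_node_phantom(fibre, node, grid)
    return {
        "grid": grid,
        "fibre": fibre,
        "node": node,
        "labels": labels,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
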