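import numpy as np
import pytest

from dimerlens import MolecularFrame


def make_frame(coords, atom_names=None, elements=None, res_ids=None,
               res_names=None, chains=None, roles=None, radii=None):
    """Compact frame builder for hand-made fixtures."""
    coords = np.asarray(coords, float)
    n = len(coords)
    return MolecularFrame(
        atom_name=np.asarray(atom_names if atom_names is not None else ["CA"] * n),
        element=np.asarray(elements if elements is not None else ["C"] * n),
        res_name=np.asarray(res_names if res_names is not None else ["ALA"] * n),
        res_id=np.asarray(res_ids if res_ids is not None else np.arange(1, n + 1)),
        chain_id=np.asarray(chains if chains is not None else ["A"] * n),
        coords=coords,
        role_tag=np.asarray(roles if roles is not None else ["protein"] * n),
        radius=np.asarray(radii if radii is not None else [1.7] * n, float),
    )


@pytest.fixture
def frame_builder():
    return make_frame


def mc_sasa(coords, radii, probe=1.4, n_points=100_000, seed=0):
    """Independent Monte-Carlo surface-sampling SASA oracle.

    For every atom, uniform points on its probe-expanded sphere are tested
    against all other expanded spheres; the exposed fraction scales the
    sphere's analytic area.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    R = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + R[i] * pts
        exposed = np.ones(n_points, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= ((pts - coords[j]) ** 2).sum(axis=1) > R[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * R[i] ** 2
    return total
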