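import numpy as np
import pytest

from bindfe.core import SnapshotEnsemble, ThermoContext, ToySolute


@pytest.fixture
def ctx() -> ThermoContext:
    return ThermoContext(temperature=300.0)


def make_solute(coords, charges=None, radii=None, masses=None, epsilons=None,
                sigmas=None, elements=None, res_ids=None, chain_ids=None,
                atom_names=None, roles=None, res_names=None) -> ToySolute:
    """Minimal ToySolute builder with sensible defaults for scalar fields."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)

    def arr(v, default):
        if v is None:
            return np.asarray([default] * n) if np.isscalar(default) else default
        return np.asarray(v)

    return ToySolute(
        elements=arr(elements, "C"),
        res_names=arr(res_names, "RES"),
        res_ids=arr(res_ids, np.arange(1, n + 1)),
        chain_ids=arr(chain_ids, "A"),
        atom_names=arr(atom_names, "C"),
        roles=arr(roles, "ligand"),
        coords=coords,
        charges=arr(charges, 0.0).astype(float),
        radii=arr(radii, 1.7).astype(float),
        masses=arr(masses, 12.0).astype(float),
        lj_epsilons=arr(epsilons, 0.1).astype(float),
        lj_sigmas=arr(sigmas, 3.0).astype(float),
    )


@pytest.fixture
def born_ion() -> ToySolute:
    """A unit point charge in a 2 Å sphere: the Born-energy oracle system."""
    return make_solute([[0.0, 0.0, 0.0]], charges=[1.0], radii=[2.0])


@pytest.fixture
def single_particle_ensemble(ctx):
    """5000-frame isotropic Gaussian cloud of one carbon-mass particle."""
    rng = np.random.default_rng(42)
    sigma = 0.3
    frames = rng.normal(0.0, sigma, size=(5000, 1, 3))
    solute = make_solute([[0.0, 0.0, 0.0]], masses=[12.0])
    return SnapshotEnsemble(solute=solute, frames=frames), sigma
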