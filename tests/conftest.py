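import numpy as np
import pytest

from odorkit import structio, synth


@pytest.fixture
def helix20():
    """Ideal 20-residue alpha-helical backbone."""
    return synth.build_helix(synth.HelixSpec(n_res=20))


@pytest.fixture
def helix_ensemble(helix20):
    """Three-model ensemble: helix, rigidly moved copy, noisy copy."""
    from odorkit.superpose import Transform
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    moved = synth.perturb_structure(helix20, rigid=Transform(rot, np.array([3.0, -1.0, 2.0])))
    noisy = synth.perturb_structure(helix20, noise_sd=0.1, seed=7)
    models = []
    for i, m in enumerate((helix20, moved, noisy), start=1):
        models.append(structio.StructureModel(i, [a for a in m.atoms]))
    return structio.Ensemble(models)


@pytest.fixture
def two_atom_pdb():
    return (
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       2.400   2.000   3.000  1.00  0.00           C\n"
    )
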