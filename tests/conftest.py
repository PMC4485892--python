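import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nbdlink import RigidTransform, SyntheticDimerSpec, make_toy_dimer

#: Planted cross-protomer distances mirroring the sandwich-dimer prediction
#: column (seven values straddling the 14 Å cutoff on both sides).
SANDWICH_PLANT = [
    (10, 10, 14.1), (12, 12, 20.1), (20, 20, 9.3), (25, 30, 12.1),
    (35, 35, 50.8), (40, 40, 26.7), (45, 50, 7.0),
]


@pytest.fixture
def toy_dimer():
    """Noise-free two-chain dimer with the sandwich-column planted distances."""
    spec = SyntheticDimerSpec(n_residues=60, planted_pairs=SANDWICH_PLANT, seed=11,
                              structure_id="toy-sandwich")
    return make_toy_dimer(spec)


@pytest.fixture
def plain_dimer():
    """Dimer with no planted pairs: chain B is an exact rigid copy of chain A."""
    tf = RigidTransform(Rotation.from_euler("y", 120, degrees=True).as_matrix(),
                        np.array([25.0, 5.0, -10.0]))
    spec = SyntheticDimerSpec(n_residues=45, protomer_transform=tf, seed=2,
                              structure_id="toy-plain")
    return make_toy_dimer(spec)


def write_observation_tsv(path, observations):
    with open(path, "w") as fh:
        fh.write("mutant_label\tpos_a\tpos_b\ttemperature_C\toutcome\n")
        for o in observations:
            fh.write(
                f"{o.mutant.label}\t{o.mutant.pos_a}\t{o.mutant.pos_b}\t"
                f"{int(o.temperature)}\t{o.outcome}\n"
            )
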