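import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem
from rdkit.Chem import AllChem

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

import d2pharm
from d2pharm.conformers import Conformer
from d2pharm.model import Feature, PharmacophoreModel


@pytest.fixture(scope="session")
def library():
    return d2pharm.build_library()


@pytest.fixture(scope="session")
def records_by_id(library):
    return {r.id: r for r in library}


def embed_smiles(smiles: str, seed: int = 11) -> Conformer:
    """Embed an arbitrary (possibly charged) SMILES into a Conformer."""
    mol = Chem.MolFromSmiles(smiles)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(molh, params)
    AllChem.MMFFOptimizeMolecule(molh, mmffVariant="MMFF94s")
    return Conformer(ligand_id=smiles, mol=molh, conf_id=0, delta_e=0.0, seed_tag="test")


@pytest.fixture(scope="session")
def dopamine_conformer(records_by_id):
    ens = d2pharm.generate_conformers(records_by_id["dopamine"], max_confs=20, seed=7)
    return ens.conformers[0]


@pytest.fixture(scope="session")
def shipped_model():
    from d2pharm.protocol import shipped_model

    return shipped_model()


@pytest.fixture(scope="session")
def shipped_anchors():
    from d2pharm.anchors import load_default_anchor_set

    return load_default_anchor_set()


@pytest.fixture
def toy_model():
    """Small achiral model handy for probe/decoy unit tests."""
    return PharmacophoreModel(
        features=(
            Feature("cat", "cation", (0.0, 0.0, 0.0), 1.0, essential=True),
            Feature(
                "ring",
                "aromatic",
                (4.0, 0.0, 0.0),
                1.0,
                essential=True,
                direction=(0.0, 0.0, 1.0),
                direction_tol=30.0,
            ),
            Feature("hb", "hbond", (7.0, 1.0, 0.5), 1.0, essential=False),
        ),
        frame_tag="toy",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20120207)
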