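import numpy as np
import pytest

from endonet import synthetic


@pytest.fixture(scope="session")
def bundle_model():
    """Two-chain helix bundle, 8 Å apart, fully overlapping in z."""
    return synthetic.gen_structure(
        [30, 30], accessions=["PROTA", "PROTB"], seed=11,
        model_id="bundle-test",
    )


@pytest.fixture(scope="session")
def shifted_bundle():
    """Two-chain bundle with a 45 Å z-shift: a local interface plus
    far-apart regions, so both satisfiable and decoy link pools exist."""
    return synthetic.gen_structure(
        [40, 40], accessions=["PROTA", "PROTB"], seed=11,
        chain_z_shift=45.0, model_id="bundle-shifted",
    )


@pytest.fixture(scope="session")
def small_world():
    return synthetic.make_world(
        seed=3, n_proteins=400, n_datasets=8, n_complexes=12, n_structures=2
    )


def brute_force_distances(model):
    """Longhand all-pairs Cα–Cα scan, independent of the package's
    evaluation path: plain loops and the √Σ formula."""
    out = {}
    for ca_id, chain_a in model.chains.items():
        acc_a, off_a = model.chain_map[ca_id]
        for cb_id, chain_b in model.chains.items():
            acc_b, off_b = model.chain_map[cb_id]
            for i in range(len(chain_a)):
                for j in range(len(chain_b)):
                    dx = chain_a.coords[i] - chain_b.coords[j]
                    d = (dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2) ** 0.5
                    out[(acc_a, off_a + i + 1, acc_b, off_b + j + 1)] = d
    return out
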