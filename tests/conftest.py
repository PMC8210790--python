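import numpy as np
import pandas as pd
import pytest

from admixscape import simdata
from admixscape.genio import GenotypeMatrix, SampleMetadata


def make_gm(genotypes, tags=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a raw array (helper used across test modules)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, l = g.shape
    tags = tags if tags is not None else [f"loc{j}" for j in range(l)]
    loci = pd.DataFrame(
        {"tag": tags, "pos": np.arange(1, l + 1), "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(g, [f"S{i:03d}" for i in range(n)], loci)


def make_md(coords, sex=None, age=None) -> SampleMetadata:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return SampleMetadata(
        pd.DataFrame(
            {
                "id": [f"S{i:03d}" for i in range(n)],
                "x": coords[:, 0],
                "y": coords[:, 1],
                "sex": sex if sex is not None else ["unknown"] * n,
                "age_class": age if age is not None else ["unknown"] * n,
                "status": "",
            }
        )
    )


@pytest.fixture(scope="session")
def two_pool_dataset():
    """Two diverged pools on a small grid with admixture at the contact.

    Session-scoped: several modules exercise their stages on this one
    simulated dataset.
    """
    land = simdata.LandscapeModel(
        grid_nx=10,
        grid_ny=4,
        founder_regions=[
            [(ix, iy) for ix in range(5) for iy in range(4)],
            [(ix, iy) for ix in range(5, 10) for iy in range(4)],
        ],
    )
    params = simdata.SimParams(
        K=2, L=300, theta=0.3, Ne=100, m=0.1, T=40, n_samples=80, seed=1234
    )
    truth = simdata.run_simulation(land, params)
    gm, md, tt = simdata.export_dataset(truth, seed=99)
    return {"land": land, "params": params, "truth": truth,
            "gm": gm, "md": md, "truth_table": tt}
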