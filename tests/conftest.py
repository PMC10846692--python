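import numpy as np
import pandas as pd
import pytest

import foldphase as fp


@pytest.fixture(scope="session")
def cell_population():
    """200 synthetic optoDroplet cells with a planted c_sat of 1000 a.u."""
    params = fp.SyntheticCellParams(n_cells=200, csat_true=1000.0, seed=1)
    pixels, truth = fp.gen_optodroplet_cells(params)
    return params, pixels, truth


@pytest.fixture(scope="session")
def noiseless_variants():
    """12 variants drawn exactly from the c*/p_U law (no noise)."""
    return fp.gen_variant_table(
        fp.SyntheticVariantParams(c_star_true=10.83, dG_shift_true=-12.9,
                                  noise_cv=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def planted_sticker_ensembles():
    """Target ensemble with paired aromatic stickers and its FRC reference."""
    seq = "GSQNDEGSFYGSQNDEGSQNFYGSQNDEGS"
    stickers = frozenset(i for i, a in enumerate(seq) if a in "FY")
    target = fp.gen_ensemble(
        fp.SyntheticEnsembleParams(
            sequence=seq, sticker_positions=stickers,
            attraction_strength=2.5, n_conformations=200, seed=5,
        )
    )
    reference = fp.gen_ensemble(
        fp.SyntheticEnsembleParams(sequence=seq, n_conformations=200, seed=6),
        reference=True,
    )
    return seq, stickers, target, reference


@pytest.fixture(scope="session")
def null_abundance_table():
    """4 groups x 4 replicates, 1000 proteins, no planted effect."""
    rng = np.random.default_rng(0)
    cols = pd.MultiIndex.from_tuples(
        [(g, r) for g in "ABCD" for r in range(1, 5)],
        names=["group", "replicate"],
    )
    return pd.DataFrame(rng.lognormal(0.0, 0.3, (1000, 16)), columns=cols)
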