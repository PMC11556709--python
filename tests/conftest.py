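import numpy as np
import pytest

from rohbench.seqemu import MISSING, VariantTable


def random_variant_table(rng: np.random.Generator, n_ind: int, n_sites: int,
                         L: int = 1_000_000, missing_frac: float = 0.05) -> VariantTable:
    """A random but internally consistent VariantTable for property tests."""
    positions = np.sort(rng.choice(L, size=n_sites, replace=False))
    gt = rng.choice([0, 1, 2], size=(n_ind, n_sites),
                    p=[0.5, 0.2, 0.3]).astype(np.int8)
    gt[rng.random((n_ind, n_sites)) < missing_frac] = MISSING
    # keep every site polymorphic among calls so af stays in (0, 1)
    gt[0] = 1
    dp = np.where(gt == MISSING, 0,
                  rng.poisson(20, size=(n_ind, n_sites)) + 1).astype(np.int32)
    pl = np.zeros((n_ind, n_sites, 3), dtype=np.int32)
    for g, other in ((0, (1, 2)), (1, (0, 2)), (2, (0, 1))):
        mask = gt == g
        for o in other:
            pl[mask, o] = rng.integers(10, 100, size=mask.sum())
    pl[gt == MISSING] = 0
    return VariantTable(positions, gt, dp, pl)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
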