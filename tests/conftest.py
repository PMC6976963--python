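import numpy as np
import pandas as pd
import pytest

from poolcross.conditions import ALL_LABELS
from poolcross.tables import AlleleCountTable


def make_counts(
    alt: dict[str, np.ndarray],
    depth: dict[str, np.ndarray] | None = None,
    n_loci: int | None = None,
    default_depth: int = 100,
    ref: str = "A",
    alt_allele: str = "T",
    effect: str = "unknown",
) -> AlleleCountTable:
    """Count table with given alt counts/depths; unlisted conditions get
    all-ref reads at the default depth."""
    L = n_loci if n_loci is not None else len(next(iter(alt.values())))
    depth = depth or {}
    data: dict[str, object] = {
        "chrom": ["chr1"] * L,
        "pos": np.arange(L) * 1000,
        "ref": [ref] * L,
        "alt": [alt_allele] * L,
        "effect": [effect] * L,
    }
    for lbl in ALL_LABELS:
        a = np.asarray(alt.get(lbl, np.zeros(L, dtype=int)))
        d = np.asarray(depth.get(lbl, np.full(L, default_depth)))
        data[f"{lbl}:alt"] = a
        data[f"{lbl}:ref"] = d - a
    return AlleleCountTable(pd.DataFrame(data))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
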