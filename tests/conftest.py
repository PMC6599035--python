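import numpy as np
import pandas as pd
import pytest

from sinode.containers import IntensityMatrix


def make_matrix(values, groups=("SN", "SN", "SN", "RA", "RA", "RA"), **kw):
    """Small IntensityMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    samples = []
    counts: dict[str, int] = {}
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        samples.append(f"{g}{counts[g]}")
    ids = pd.Index([f"P{i}" for i in range(n)], name="protein")
    df = pd.DataFrame(values, index=ids, columns=samples)
    labels = pd.Series(list(groups), index=samples)
    defaults = dict(
        peptide_counts=pd.Series(5, index=ids),
        reverse_flag=pd.Series(False, index=ids),
        contaminant_flag=pd.Series(False, index=ids),
        isoform_group=pd.Series(ids, index=ids),
    )
    defaults.update(kw)
    return IntensityMatrix(values=df, group_labels=labels, **defaults)


@pytest.fixture
def toy_matrix():
    """6-protein, 3v3 complete matrix with two strong group differences."""
    rng = np.random.default_rng(42)
    vals = rng.normal(25.0, 0.2, size=(6, 6))
    vals[0, :3] += 4.0  # SN-higher
    vals[1, 3:] += 4.0  # RA-higher
    return make_matrix(vals)
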