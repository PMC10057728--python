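import numpy as np
import pandas as pd
import pytest

from solina.io_formats import GenotypeMatrix


def make_geno(red_dosages, blue_dosages, seeds_per_accession=1, marker_ids=None):
    """Build a GenotypeMatrix from per-cluster dosage arrays (samples x markers).

    Samples are grouped into accessions of ``seeds_per_accession`` consecutive
    rows within each cluster.
    """
    red = np.asarray(red_dosages, float)
    blue = np.asarray(blue_dosages, float)
    if red.ndim == 1:
        red = red[:, None]
    if blue.ndim == 1:
        blue = blue[:, None]
    m = red.shape[1]
    marker_ids = marker_ids or [f"M{j + 1:04d}" for j in range(m)]
    sample_ids, clusters, accessions = [], {}, {}
    for label, block in (("red", red), ("blue", blue)):
        for i in range(block.shape[0]):
            sid = f"{label}_s{i + 1}"
            sample_ids.append(sid)
            clusters[sid] = label
            accessions[sid] = f"{label}_a{i // seeds_per_accession + 1}"
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        dosages=np.vstack([red, blue]),
        cluster_labels=pd.Series(clusters),
        accessions=pd.Series(accessions),
    )


@pytest.fixture
def small_geno():
    """48 + 48 samples at 60 markers with moderate differentiation."""
    rng = np.random.default_rng(11)
    p = rng.uniform(0.1, 0.9, 60)
    red = rng.binomial(2, p, (48, 60)).astype(float)
    blue = rng.binomial(2, np.clip(p + 0.15, 0, 1), (48, 60)).astype(float)
    return make_geno(red, blue, seeds_per_accession=4)
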