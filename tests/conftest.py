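import numpy as np
import pytest
from hypothesis import settings

from antisense_pairs.annotations import FeatureSet, GenomicFeature
from antisense_pairs.diffexpr import CountMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_features(rows, label="features"):
    """rows: (id, chrom, start, end, strand[, kind]) tuples."""
    feats = [GenomicFeature(*r) for r in rows]
    return FeatureSet(feats, label=label)


def make_count_matrix(counts, n_control=None, n_treatment=None):
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    if n_control is None:
        n_control = n_samp // 2
    if n_treatment is None:
        n_treatment = n_samp - n_control
    sample_ids = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_treatment)]
    condition = {s: ("control" if s.startswith("c") else "treatment") for s in sample_ids}
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(n_feat)],
        sample_ids=sample_ids,
        counts=counts,
        condition=condition,
    )


@pytest.fixture
def toy_genes():
    return make_features(
        [
            ("geneA", "chrI", 100, 200, "+"),
            ("geneB", "chrI", 1000, 2000, "-"),
            ("geneC", "chrII", 100, 200, "+"),
        ],
        label="genes",
    )
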