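import numpy as np
import pytest

from eelgrass_allometry.models import LeafRecord


def make_leaves(lengths, weights, site="test"):
    return [
        LeafRecord(site=site, shoot_id=f"s{i}", leaf_rank=1,
                   length_mm=float(l), weight_g=(None if w is None else float(w)))
        for i, (l, w) in enumerate(zip(lengths, weights), start=1)
    ]


def power_law_leaves(a, b, lengths, site="test"):
    lengths = np.asarray(lengths, dtype=float)
    return make_leaves(lengths, a * lengths**b, site=site)


@pytest.fixture
def san_quintin_params():
    """Fitted triple for a large estuary population: a, b, c."""
    return 1e-5, 1.410012, 1e-4
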