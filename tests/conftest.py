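import warnings

import pytest

from tfatlas import grn, pagerank, simulate

# sklearn's graphical lasso warns about the dual gap at very small penalties
# on the dense end of the path; the path points there are still usable
warnings.filterwarnings("ignore", message="graphical_lasso")


@pytest.fixture(scope="session")
def atlas():
    """Default 9-state atlas with planted single-state TFs (seed 7)."""
    return simulate.generate_atlas(seed=7)


@pytest.fixture(scope="session")
def networks(atlas):
    return grn.build_all_grns(atlas)


@pytest.fixture(scope="session")
def pr_matrix(atlas, networks):
    return pagerank.compute_atlas_pagerank(atlas, networks)
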