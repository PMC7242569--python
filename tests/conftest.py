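import io as _io

import pytest
import skbio

from snowniche.synthetic import SimulationSpec, generate

FOUR_TIP_NEWICK = "((A:1,B:1):2,(C:1,D:1):2);"


@pytest.fixture
def four_tip_tree() -> skbio.TreeNode:
    """Two cherries (A,B) and (C,D): d(A,B)=2, cross-clade distance 6."""
    return skbio.TreeNode.read(_io.StringIO(FOUR_TIP_NEWICK))


@pytest.fixture(scope="session")
def standard_dataset():
    """One synthetic dataset at the standard study conditions (one stratum)."""
    spec = SimulationSpec(
        seed=7, n_otus=120, n_reps=6, strata=(("hillslope", "D0_5"),)
    )
    return generate(spec)
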