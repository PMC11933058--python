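import pytest

from abtriage.aggregation import fit_aggregation_model
from abtriage.pipelines import reference_structure_panel
from abtriage.synth import bundled_germlines, VH_TEMPLATE, VL_TEMPLATE
from abtriage.fv import FvSequence


@pytest.fixture(scope="session")
def germlines():
    return list(bundled_germlines())


@pytest.fixture(scope="session")
def template_fv():
    """The germline template pair, CDR-annotated."""
    return FvSequence("TEMPLATE", VH_TEMPLATE, VL_TEMPLATE).annotated()


@pytest.fixture(scope="session")
def reference_panel():
    """Unplanted toy-structure reference: (feature vectors, patch thresholds)."""
    return reference_structure_panel(seed=5, n_structures=25)


@pytest.fixture(scope="session")
def patch_thresholds(reference_panel):
    return reference_panel[1]


@pytest.fixture(scope="session")
def fitted_model(reference_panel):
    vectors, _ = reference_panel
    return fit_aggregation_model(vectors, seed=5)
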