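import numpy as np
import pytest

from coexnet.analysis import CoexpressionAnalysis
from coexnet.simulate import generate_dataset

#: Seed of the desk-scale preset run shared by the slower tests.
PRESET_SEED = 3


@pytest.fixture(scope="session")
def preset_data():
    """One preset synthetic dataset (2,000 genes, 5 modules, 18 samples)."""
    return generate_dataset(seed=PRESET_SEED)


@pytest.fixture(scope="session")
def preset_result(preset_data):
    """The full pipeline fitted on the preset dataset."""
    expr, trait, ann, truth = preset_data
    return CoexpressionAnalysis(expr, trait, ann).fit()


@pytest.fixture(scope="session")
def small_data():
    """A small, fast dataset for end-to-end and CLI tests."""
    return generate_dataset(
        n_genes=400,
        module_sizes=(60, 50, 40),
        trait_modules=(1, 3),
        zero_gene_frac=0.10,
        low_mad_frac=0.225,
        seed=7,
    )


def detected_to_true(assignment, truth, gene_ids):
    """Map each detected module color to the majority true module label."""
    tp = truth.module_of_gene.loc[gene_ids].to_numpy()
    mapping = {}
    for lab in range(1, assignment.n_modules + 1):
        mask = assignment.labels == lab
        vals, counts = np.unique(tp[mask], return_counts=True)
        mapping[assignment.label_to_color[lab]] = int(vals[np.argmax(counts)])
    return mapping
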