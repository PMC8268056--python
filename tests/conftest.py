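import numpy as np
import pandas as pd
import pytest

from protfunnel import ExpressionDataset, ProteaseCatalog, SampleMeta


def make_dataset(
    values,
    genes,
    groups,
    dataset_id="DS1",
    platform_id="GPL1",
    subject_labels=None,
    paired=None,
):
    """Build a small ExpressionDataset from a 2-D array and group labels."""
    values = np.asarray(values, dtype=float)
    sample_ids = [f"{dataset_id}_S{i + 1}" for i in range(values.shape[1])]
    matrix = pd.DataFrame(values, index=list(genes), columns=sample_ids)
    samples = tuple(
        SampleMeta(
            sample_id=sid,
            group=groups[i],
            subject_label=(subject_labels[i] if subject_labels else f"SUB{i + 1}"),
            paired_with=(
                sample_ids[paired[i]] if paired and paired[i] is not None else None
            ),
        )
        for i, sid in enumerate(sample_ids)
    )
    return ExpressionDataset(dataset_id, platform_id, matrix, samples)


def make_catalog(**entries):
    return ProteaseCatalog(
        entries={sym.upper(): frozenset(terms) for sym, terms in entries.items()}
    )


@pytest.fixture
def small_catalog():
    return make_catalog(
        ADAM9={"extracellular", "transmembrane"},
        ADAM10={"transmembrane"},
        CTSB={"lysosome", "secreted"},
        CTSL={"lysosome"},
        CAPN1={"cytoplasm"},
    )


@pytest.fixture
def paired_dataset():
    # 3 genes x 4 samples: 2 tumor + 2 paired adjacent normals
    return make_dataset(
        [[6.0, 6.0, 4.0, 4.0], [10.0, 14.0, 12.0, 12.0], [1.0, 3.0, 2.0, 2.0]],
        genes=["ADAM9", "CTSB", "CTSL"],
        groups=["tumor", "tumor", "adjacent_normal", "adjacent_normal"],
        subject_labels=["P1", "P2", "P1", "P2"],
        paired=[2, 3, 0, 1],
    )
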