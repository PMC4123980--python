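import pytest

from barcodekit import build_alignment
from barcodekit.seqio_qc import SequenceRecord
from barcodekit.synthetic import SyntheticConfig, emit_dataset


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two deeply divergent clusters with shallow within-cluster variation."""
    cfg = SyntheticConfig(K=2, n_per=10, L=300, theta=1.5, d_between=0.12, seed=21)
    return emit_dataset(cfg)


@pytest.fixture(scope="session")
def two_cluster_alignment(two_cluster_dataset):
    return build_alignment(two_cluster_dataset.coi5_records)


@pytest.fixture(scope="session")
def dual_marker_dataset():
    cfg = SyntheticConfig(K=4, n_per=8, L=300, L3=360, theta=1.0, theta3=1.0,
                          d_between=0.10, seed=33, dual_marker=True)
    return emit_dataset(cfg)


def make_records(seqs, prefix="s", marker="COI5", metas=None):
    metas = metas or [{} for _ in seqs]
    return [
        SequenceRecord(id=f"{prefix}{i + 1}", seq=s, marker=marker, meta=m)
        for i, (s, m) in enumerate(zip(seqs, metas))
    ]
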