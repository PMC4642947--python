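"""Shared fixtures: small hand-built alignments and the session-scoped
reference synthetic bundle with its fitted network and null libraries."""

from __future__ import annotations

import numpy as np
import pytest

from coevnet import coevo, msa, nullmodel, synthdata
from coevnet.model import CoevolutionNetwork


def make_alignment(rows: list[str], ids: list[str] | None = None) -> msa.Alignment:
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return msa.Alignment.from_records(zip(ids, rows))


@pytest.fixture
def tiny_aln() -> msa.Alignment:
    return make_alignment(["ARND-A", "ARNDCA", "ARNDCR", "GRNDCR"])


@pytest.fixture(scope="session")
def reference_bundle():
    """The canonical synthetic dataset (N=300, L=120, 8 pairs at c=0.9)."""
    return synthdata.reference_bundle(seed=1)


@pytest.fixture(scope="session")
def reference_fit(reference_bundle):
    """Fitted network on the reference bundle (K=10 null library)."""
    aln, truth, spec = reference_bundle
    res = CoevolutionNetwork(aln).fit(n_null=10, seed=1)
    return res, truth


@pytest.fixture(scope="session")
def null_library_20(reference_bundle):
    """K=20 shuffled library with full matrices retained."""
    aln, _truth, _spec = reference_bundle
    return nullmodel.build_library(aln, K=20, seed=2, keep_matrices=True)


@pytest.fixture(scope="session")
def shuffled_matrix(reference_bundle):
    """Coevolution matrix of one column-shuffled copy of the reference
    alignment (covariation destroyed, entropies preserved)."""
    aln, _truth, _spec = reference_bundle
    shuffled = nullmodel.shuffle_columns(aln, seed=77)
    return coevo.coevolution_matrix(shuffled)


class StubNull:
    """Minimal null-library stand-in for unit tests."""

    def __init__(self, E_R=None, entry_mean=0.0, entry_sigma=0.5,
                 window=(0.0, 1e-3), K=10):
        self.E_R = np.asarray(E_R) if E_R is not None else None
        self.entry_mean = entry_mean
        self.entry_sigma = entry_sigma
        self._window = window
        self.K = K

    def window_stats(self, n):
        return self._window


@pytest.fixture
def stub_null_factory():
    return StubNull
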