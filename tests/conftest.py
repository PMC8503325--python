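import numpy as np
import pytest

import frpssm as fp
from frpssm._seqcodes import translate_codes


@pytest.fixture(scope="session")
def ref():
    return fp.builtin_germline()


@pytest.fixture(scope="session")
def sim_matrices(ref):
    """A 10k-sequence simulated repertoire: (nt matrix, aa matrix)."""
    params = fp.SimParams(germline=ref, n_sequences=10_000, seed=11)
    nt = fp.simulate_nt_matrix(params)
    return nt, translate_codes(nt)


@pytest.fixture(scope="session")
def sim_pssm(ref, sim_matrices):
    _, aa = sim_matrices
    return fp.build_pssm(aa, ref, min_sequences=0)


def make_count_table(freqs, totals=10_000, germline="TOY"):
    """CountTable with exactly the given unmasked (position, aa_idx, frequency)
    entries; every other cell is masked. ``freqs`` is a list of lists per
    position of (aa_index, frequency)."""
    P = len(freqs)
    totals = np.full(P, totals, dtype=np.int64)
    counts = np.zeros((P, 20), dtype=np.int64)
    masked = np.ones((P, 20), dtype=bool)
    for i, entries in enumerate(freqs):
        for j, f in entries:
            counts[i, j] = int(round(f * totals[i]))
            masked[i, j] = False
    return fp.CountTable(
        germline=germline,
        positions=np.arange(1, P + 1),
        counts=counts,
        totals=totals,
        masked=masked,
        region_labels=["FR1"] * P,
        n_sequences=int(totals[0]),
    )
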