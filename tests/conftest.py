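import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cscdecoder import cut_cscs, parse_evoprint


def make_csc(text: str, region_id: str = "fix", icr_cutoff: int = 10_000):
    """One CSC from case-coded text (cutoff large enough to keep it whole)."""
    ep = parse_evoprint(text, region_id)
    cscs = cut_cscs(ep, icr_cutoff=icr_cutoff)
    assert len(cscs) == 1, f"fixture text cut into {len(cscs)} CSCs"
    return cscs[0]


def random_case_text(rng: np.random.Generator, n_runs=5,
                     run_len=(3, 40), gap_len=(1, 10),
                     with_n=False) -> str:
    """Random case-coded text: uppercase runs split by lowercase gaps."""
    alphabet = list("ACGTN") if with_n else list("ACGT")
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    parts = []
    for i in range(n_runs):
        if i:
            g = int(rng.integers(*gap_len))
            parts.append("".join(rng.choice(list("acgt"), size=g)))
        L = int(rng.integers(*run_len))
        parts.append("".join(rng.choice(alphabet, size=L, p=p)))
    return "".join(parts)


def scores_close(got, want, tol=1e-9) -> bool:
    """Compare scorecard values, honouring None and the infinite flag."""
    if want is None or got is None:
        return got is want
    if isinstance(want, float):
        if math.isinf(want):
            return isinstance(got, float) and got == want
        return abs(got - want) <= tol
    return got == want


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)
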