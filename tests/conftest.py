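import numpy as np
import pytest

from tsnegrad.io import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gaussian(rng):
    """12 x 4 standardized Gaussian data."""
    X = rng.normal(size=(12, 4))
    return DataMatrix.from_values(X)


@pytest.fixture
def toy_alignment():
    """Hand-built aligned sequences with known encodable variation.

    Reference length 300 (no gaps).  Events, all relative to the reference:
      pos 150 A->C in samples s1, s2          -> kept feature (count 2)
      pos 160 A->G in sample s1 only          -> singleton, dropped
      pos  50 A->T in s1, s2                  -> in 5' flank, dropped
      pos 260 A->T in s3, s4                  -> in 3' flank (> 200), dropped
      pos 180-184 deletion (5 nt) in s1, s2   -> 5 deletion features (count 2)
      pos 120-139 deletion (20 nt) in s3      -> masked (run > 12 nt)
      pos 170 N in s4                         -> missing call at any feature there
      pos 170 A->G in s1, s2, s3              -> kept feature (count 3), s4 masked
    """
    L = 300
    ref = ["A"] * L
    ref[149] = "A"
    seqs = {}
    for sid in ("s1", "s2", "s3", "s4"):
        seqs[sid] = ["A"] * L
    for sid in ("s1", "s2"):
        seqs[sid][149] = "C"
        seqs[sid][49] = "T"
        for p in range(179, 184):
            seqs[sid][p] = "-"
    seqs["s1"][159] = "G"
    for sid in ("s3", "s4"):
        seqs[sid][259] = "T"
    for p in range(119, 139):
        seqs["s3"][p] = "-"
    seqs["s4"][169] = "N"
    for sid in ("s1", "s2", "s3"):
        seqs[sid][169] = "G"
    records = [("ref", "".join(ref))] + [(sid, "".join(seqs[sid])) for sid in ("s1", "s2", "s3", "s4")]
    return records
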