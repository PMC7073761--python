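import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from potevo.seqio import Alignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20201107)


@pytest.fixture
def small_alignment():
    return Alignment(
        records=(
            SequenceRecord(id="alpha", seq="ACGTACGTAC"),
            SequenceRecord(id="beta", seq="ACGTACGTAA"),
        )
    )


@pytest.fixture
def rm_out_file(tmp_path):
    """A minimal RepeatMasker .out fixture: two queries, one with rows
    deliberately out of coordinate order."""
    text = """\
   SW   perc perc perc  query     position in query    matching repeat
score   div. del. ins.  sequence  begin end (left)     strand repeat class/family

  463   1.3  0.6  1.7  geneA   1001  1500  (3000)  +  L1PA2  LINE/L1
  239  29.4  1.2  0.0  geneA    100   400  (3500)  C  L1M5   LINE/L1
 1200   5.0  0.1  0.2  geneB     10   800  (9000)  +  AluY   SINE/Alu
"""
    path = tmp_path / "repeats.out"
    path.write_text(text)
    return path
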