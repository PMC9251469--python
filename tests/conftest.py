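import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mfhcc import signatures as sg
from mfhcc import synthetic_data as sd


@pytest.fixture(scope="session")
def signature_matrix():
    return sg.load_signature_matrix()


@pytest.fixture(scope="session")
def small_genome():
    return sd.synthetic_genome(n_contigs=3, contig_length=20_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TOY_MAF = """Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tVariant_Classification\tTumor_Sample_Barcode
TP53\tchr17\t7578406\tC\tT\tMissense_Mutation\tS1
ARID1A\t1\t27023000\tG\tA\tNonsense_Mutation\tS1
CTNNB1\t3\t41266100\tC\tA\tMissense_Mutation\tS2
"""


@pytest.fixture()
def toy_maf(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(TOY_MAF)
    return p
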