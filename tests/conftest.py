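import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from nerpe import AUCG, DUCG, ConstructSpec, CopyingModel
from nerpe.construct import simulate_library
from nerpe.reads import process_library


@pytest.fixture(scope="session")
def spec():
    return ConstructSpec()


@pytest.fixture(scope="session")
def clean_model():
    """Default study-condition model without sequencing errors."""
    return CopyingModel(system=DUCG, seq_error_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_library(tmp_path_factory, clean_model, spec):
    """10k error-free reads: truth records, FASTQ path, processed reads."""
    d = tmp_path_factory.mktemp("clean_lib")
    fq = d / "reads.fastq"
    truth = d / "truth.tsv"
    truths, _ = simulate_library(clean_model, spec, 10_000, fastq_path=fq, truth_path=truth)
    processed, summary = process_library(fq, spec, DUCG)
    return {"truths": truths, "fastq": fq, "truth_tsv": truth,
            "processed": processed, "summary": summary}


def binomial_se(p: float, n: int) -> float:
    return np.sqrt(max(p * (1.0 - p), 1e-12) / n)
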