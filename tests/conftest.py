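"""Shared fixtures: toy coding sequences and cohort files built in-memory."""
from itertools import product

import numpy as np
import pytest

from cdnscan.opportunity import CODON_TO_AA, PathProbabilities


@pytest.fixture(scope="session")
def uniform_R():
    return PathProbabilities.uniform()


@pytest.fixture(scope="session")
def all_sense_cds():
    """One CDS containing every sense codon once, plus a terminal stop."""
    codons = ["".join(p) for p in product("ACGT", repeat=3)]
    sense = [c for c in codons if CODON_TO_AA[c] != "*"]
    return {"allcodons": "".join(sense) + "TAA"}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def write_cohort_file(path, rows, header=None):
    """Write a MAF-subset TSV from (patient, chrom, pos, ref, alt, gene, csq[, freq]) rows."""
    if header is None:
        header = ["Tumor_Sample_Barcode", "Chromosome", "Start_Position",
                  "Reference_Allele", "Tumor_Seq_Allele2", "Hugo_Symbol",
                  "Variant_Classification"]
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def cohort_writer(tmp_path):
    def _write(rows, name="cohort.tsv", header=None):
        return write_cohort_file(tmp_path / name, rows, header=header)
    return _write
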