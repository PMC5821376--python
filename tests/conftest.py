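"""Shared fixtures: a study-shaped genotype table and helper builders."""

import numpy as np
import pandas as pd
import pytest

from gxeds import GenotypeTable, SNPDef

# One fixed seed for every stochastic check in the suite.
SEED = 20180221

SNP_DEFS = [
    SNPDef("rs3800373", "A", "C"),
    SNPDef("rs9296158", "G", "A"),
    SNPDef("rs1360780", "C", "T"),
    SNPDef("rs9470080", "C", "T"),
    SNPDef("rs4713916", "G", "A"),
]

BLOCK = ("rs3800373", "rs9296158", "rs1360780")

# Diplotypes over the three-SNP block for 86 individuals, chosen so that
# every per-SNP genotype count and the haplotype comparison groups
# (41 reference, 42 risk-carriers, 3 excluded) match the emulated study's
# genotype table exactly.
STUDY_DIPLOTYPES = (
    [("AGC", "AGC")] * 33
    + [("AGC", "CAT")] * 35
    + [("CAT", "CAT")] * 5
    + [("AGC", "AGT")] * 3
    + [("AGC", "AAT")] * 2
    + [("AGC", "CGT")] * 1
    + [("AGC", "CAC")] * 2
    + [("CAT", "CGT")] * 2
    + [("AGT", "AGT"), ("AAC", "CAC"), ("CGC", "CGT")]
)


def dosages_from_diplotypes(diplotypes, snp_defs=None):
    """Risk-allele dosages for the block SNPs from diplotype strings."""
    defs = {s.rsid: s for s in (snp_defs or SNP_DEFS)}
    out = {}
    for j, rsid in enumerate(BLOCK):
        risk = defs[rsid].risk_allele
        out[rsid] = [
            float((h1[j] == risk) + (h2[j] == risk)) for h1, h2 in diplotypes
        ]
    return out


@pytest.fixture(scope="session")
def study_genotypes() -> GenotypeTable:
    data = dosages_from_diplotypes(STUDY_DIPLOTYPES)
    data["rs9470080"] = [0.0] * 35 + [1.0] * 42 + [2.0] * 9
    data["rs4713916"] = [0.0] * 44 + [1.0] * 39 + [2.0] * 3
    ids = pd.Index([f"P{i:03d}" for i in range(86)], name="individual_id")
    return GenotypeTable(pd.DataFrame(data, index=ids), SNP_DEFS)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
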