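import numpy as np
import pandas as pd
import pytest

from paleokin.genotype_io import GenotypeMatrix, SnpPanel
from paleokin.pedigree_sim import Pedigree
from paleokin.synthetic_data import SimConfig, generate_panel


def make_panel(rows):
    """Build a SnpPanel from (chrom, pos, ref, alt, freq) tuples."""
    recs = []
    for i, (chrom, pos, ref, alt, freq) in enumerate(rows):
        recs.append({"snp_id": f"s{i}", "chromosome": str(chrom),
                     "position_bp": pos, "genetic_pos_cM": pos / 1e6,
                     "ref_allele": ref, "alt_allele": alt, "bg_freq": freq})
    return SnpPanel(pd.DataFrame(recs))


@pytest.fixture
def tiny_panel():
    return make_panel([(1, 100, "A", "C", 0.3), (1, 200, "G", "T", 0.5),
                       (2, 150, "T", "G", 0.7)])


@pytest.fixture
def small_panel():
    cfg = SimConfig(seed=17, n_snps_auto=2000, n_snps_x=400)
    return generate_panel(cfg)


@pytest.fixture
def trio():
    """Founder couple, two unrelated founders, and a daughter."""
    ped = Pedigree()
    ped.add("MOM", "F")
    ped.add("DAD", "M")
    ped.add("U1", "F")
    ped.add("U2", "M")
    ped.add("KID", "F", mother="MOM", father="DAD")
    ped.validate()
    return ped


def diploid_gm(ids, calls):
    return GenotypeMatrix(list(ids), np.asarray(calls, dtype=np.int8), "diploid")


def pseudo_gm(ids, calls):
    return GenotypeMatrix(list(ids), np.asarray(calls, dtype=np.int8),
                          "pseudohaploid")
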