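import numpy as np
import pytest

from directmr.harmonize import HarmonizedRecord, HarmonizedSet
from directmr.sumstats import InstrumentSet, SnpAssociation


def make_hset(g1, se_g1, Gamma, se_G, g2=None, se_g2=None) -> HarmonizedSet:
    """Assemble a HarmonizedSet directly from parallel arrays."""
    n = len(g1)
    records = []
    for j in range(n):
        records.append(HarmonizedRecord(
            rsid=f"rs{j + 1}", gamma1=float(g1[j]), se_g1=float(se_g1[j]),
            Gamma=float(Gamma[j]), se_G=float(se_G[j]),
            gamma2=None if g2 is None else float(g2[j]),
            se_g2=None if se_g2 is None else float(se_g2[j])))
    return HarmonizedSet(records=records, n_exposures=1 if g2 is None else 2)


def random_hset(rng: np.random.Generator, L: int, two_exposures: bool = False) -> HarmonizedSet:
    g1 = rng.normal(0.05, 0.03, L)
    se1 = rng.uniform(0.002, 0.01, L)
    seG = rng.uniform(0.005, 0.02, L)
    G = rng.normal(0.0, 0.02, L)
    if not two_exposures:
        return make_hset(g1, se1, G, seG)
    g2 = 0.5 * g1 + rng.normal(0.03, 0.03, L)
    se2 = rng.uniform(0.002, 0.01, L)
    return make_hset(g1, se1, G, seG, g2, se2)


def make_instruments(rng: np.random.Generator, n: int, name: str = "exposure",
                     stratum: str = "overall", n_gwas: float = 100_000.0) -> InstrumentSet:
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    assocs = []
    for j in range(n):
        ea, oa = pairs[int(rng.integers(len(pairs)))]
        beta = float(rng.normal(0.05, 0.02))
        se = float(rng.uniform(0.005, 0.02))
        assocs.append(SnpAssociation(
            rsid=f"rs{j + 1}", effect_allele=ea, other_allele=oa,
            beta=beta, se=se, eaf=float(rng.uniform(0.05, 0.95)),
            pvalue=float(rng.uniform(0.0, 1.0)), n=n_gwas))
    return InstrumentSet(exposure_name=name, stratum=stratum,
                         associations=assocs, n_gwas=n_gwas)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
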