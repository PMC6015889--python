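import numpy as np
import pytest

from qtsmap.datamodel import (
    GeneticArchitecture,
    GenotypeMatrix,
    LocusEffect,
    Marker,
    PairEffect,
    PhenotypeTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_gm():
    """4 lines x 4 markers, handwritten calls covering all codes."""
    lines = ["Z001E0001", "Z001E0002", "Z002E0001", "Z002E0002"]
    family = {l: l[:4] for l in lines}
    calls = [
        ["QQ", "Qq", "qq", "NA"],
        ["qq", "qq", "QQ", "Qq"],
        ["QQ", "QQ", "qq", "qq"],
        ["Qq", "qq", "NA", "QQ"],
    ]
    return GenotypeMatrix.from_strings(
        lines, family, ["S1_100", "S1_200", "S2_100", "S2_300"], calls
    )


@pytest.fixture
def tiny_ph(tiny_gm):
    records = []
    rng = np.random.default_rng(7)
    for line in tiny_gm.lines:
        for env in (1, 2):
            records.append((line, env, "trait", float(rng.normal(10.0, 1.0))))
    return PhenotypeTable.from_records(records)


@pytest.fixture
def toy_arch():
    """2-locus toy with one epistatic pair (hand-checkable values)."""
    return GeneticArchitecture(
        mu=5.0,
        loci=[LocusEffect("S1_100", a=1.0, d=2.0), LocusEffect("S1_200", a=-1.0)],
        pairs=[PairEffect("S1_100", "S1_200", aa=0.5)],
        residual_sd=1.0,
    )


def random_genotypes(rng, n_lines=60, marker_ids=("S1_100", "S1_200", "S2_100")):
    """Unstructured random genotype matrix for regression-style tests."""
    lines = [f"Z001E{i:04d}" for i in range(1, n_lines + 1)]
    family = {l: "Z001" for l in lines}
    calls = rng.choice([0, 1, 2], size=(n_lines, len(marker_ids))).astype(np.int8)
    markers = [Marker(m) for m in marker_ids]
    return GenotypeMatrix(lines, family, markers, calls)


def phenotypes_for(gm, rng, n_env=2, trait="trait", values=None):
    records = []
    k = 0
    for env in range(1, n_env + 1):
        for line in gm.lines:
            v = float(rng.normal()) if values is None else float(values[k])
            records.append((line, env, trait, v))
            k += 1
    return PhenotypeTable.from_records(records)
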