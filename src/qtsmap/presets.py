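"""Reference simulation configurations for validation experiments.

These presets pin down the synthetic-data scenarios used by the
acceptance checks: a width-like trait architecture (large dominance and
dominance-related epistasis shares), a missing-genotype policy
scenario, and small null/calibration designs.  Effect sizes are
artifact choices calibrated so the realized variance decomposition
resembles the published leaf-width profile (h2_Dplus around 55%,
total around 75-80%).
"""

from __future__ import annotations

import numpy as np

from qtsmap.datamodel import (
    EnvLocusEffect,
    GeneticArchitecture,
    LocusEffect,
    PairEffect,
)
from qtsmap.nam_simulator import GeneticMap, SimConfig


def unlinked_map(n_loci: int) -> GeneticMap:
    """One marker per chromosome: loci segregate independently."""
    return GeneticMap([[50.0] for _ in range(n_loci)])


def width_like_simconfig(seed: int = 11, lines_per_family: int = 200) -> SimConfig:
    """NAM-like dataset with a width-like trait architecture.

    10 families x ``lines_per_family`` RILs, 4 environments, 20 mapped
    markers.  Three selfing generations keep enough heterozygotes for
    the dominance terms to be estimable at desk scale, and masking is
    heterozygote-biased (masked calls are truly heterozygous), so the
    missing-as-heterozygote analysis coding is exact and recovery
    isolates estimation error.
    """
    gmap = GeneticMap([[20.0, 60.0, 100.0, 140.0, 180.0] for _ in range(4)])
    mids = [m.id for m in gmap.markers()]
    L = [mids[i] for i in (0, 3, 5, 8, 11, 14)]
    arch = GeneticArchitecture(
        mu=85.0,
        loci=[
            LocusEffect(L[0], a=0.55, d=1.9),
            LocusEffect(L[1], a=-0.45, d=1.7),
            LocusEffect(L[2], a=0.5, d=-1.8),
            LocusEffect(L[3], a=-0.4, d=1.5),
            LocusEffect(L[4], a=0.4, d=0.0),
            LocusEffect(L[5], a=-0.5, d=0.0),
        ],
        pairs=[
            PairEffect(L[0], L[2], aa=0.3, ad=1.5, da=-1.3, dd=8.0),
            PairEffect(L[1], L[3], aa=-0.25, ad=-1.4, da=1.2, dd=7.0),
        ],
        env_loci=[
            EnvLocusEffect(L[0], 1, ae=0.3),
            EnvLocusEffect(L[0], 2, ae=-0.1),
            EnvLocusEffect(L[0], 3, ae=-0.1),
            EnvLocusEffect(L[0], 4, ae=-0.1),
            EnvLocusEffect(L[4], 1, de=0.2),
            EnvLocusEffect(L[4], 2, de=-0.2),
        ],
        residual_sd=1.0,
    )
    return SimConfig(
        n_families=10,
        lines_per_family=lines_per_family,
        genetic_map=gmap,
        selfing_generations=3,
        founder_poly=1.0,
        missing_rate=0.08,
        missing_mode="het_biased",
        het_odds=np.inf,
        environments=4,
        env_sd=0.25,
        architecture=arch,
        trait="width_like",
        seed=seed,
    )


def missing_policy_simconfig(
    with_dominance: bool = False, seed: int = 7, lines_per_family: int = 60
) -> SimConfig:
    """Scenario for the missing-genotype Monte-Carlo validation.

    Additive effects sized at a few percent of phenotypic variance per
    locus; dominance truth is zero unless ``with_dominance`` (used for
    the power arm, where masked calls are truly heterozygous).
    Masking is heterozygote-biased so that, in the homozygous-truth
    arm, missing calls stand in for all heterozygotes.
    """
    gmap = unlinked_map(6)
    mids = [m.id for m in gmap.markers()]
    d = 1.5 if with_dominance else 0.0
    dd = 5.0 if with_dominance else 0.0
    # additive shares kept at a few percent of Var(y) per locus, matching
    # the published per-QTS magnitudes; larger values would let the
    # homozygote-replacement variance inflation leak into dominance F's
    arch = GeneticArchitecture(
        mu=10.0,
        loci=[
            LocusEffect(mids[0], a=0.30, d=d),
            LocusEffect(mids[1], a=-0.28, d=d),
            LocusEffect(mids[2], a=0.26, d=0.0),
            LocusEffect(mids[3], a=-0.24, d=0.0),
        ],
        pairs=[PairEffect(mids[0], mids[2], aa=0.2, dd=dd)],
        residual_sd=1.0,
    )
    return SimConfig(
        n_families=5,
        lines_per_family=lines_per_family,
        genetic_map=gmap,
        selfing_generations=2,  # ~25% heterozygotes before masking
        founder_poly=1.0,
        missing_rate=0.25,
        missing_mode="het_biased",
        het_odds=np.inf,
        environments=2,
        env_sd=0.25,
        architecture=arch,
        trait="trait",
        seed=seed,
    )


def null_simconfig(n_loci: int = 50, lines: int = 150, seed: int = 0) -> SimConfig:
    """Pure-noise dataset over unlinked loci (all genetic effects zero)."""
    return SimConfig(
        n_families=5,
        lines_per_family=lines // 5,
        genetic_map=unlinked_map(n_loci),
        selfing_generations=3,
        founder_poly=1.0,
        missing_rate=0.0,
        environments=2,
        env_sd=0.5,
        architecture=GeneticArchitecture(mu=0.0, residual_sd=1.0),
        trait="null",
        seed=seed,
    )
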