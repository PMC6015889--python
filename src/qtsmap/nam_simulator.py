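"""Synthetic NAM-population generator.

Simulates biparental families crossed to a common reference parent and
selfed for a configurable number of generations (single-seed descent
with Haldane recombination), masks genotypes either completely at
random or preferentially at heterozygotes, and generates phenotypes
under the same full genetic model the mapper fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from qtsmap.datamodel import (
    GeneticArchitecture,
    GenotypeMatrix,
    Marker,
    PhenotypeTable,
    additive_coefficients,
    dominance_coefficients,
)


@dataclass
class GeneticMap:
    """Marker positions in centimorgans, grouped by chromosome."""

    cm_positions: list[list[float]]  # one increasing list per chromosome

    def __post_init__(self):
        if not self.cm_positions or all(len(c) == 0 for c in self.cm_positions):
            raise ValueError("empty genetic map")
        for c, pos in enumerate(self.cm_positions, start=1):
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"non-increasing cM positions on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return sum(len(c) for c in self.cm_positions)

    def markers(self) -> list[Marker]:
        out = []
        for c, pos in enumerate(self.cm_positions, start=1):
            for p in pos:
                # bp position derived from cM at 1 Mb/cM, offset to stay >= 1
                out.append(Marker(f"S{c}_{int(round(p * 1e6)) + 1}"))
        return out

    def recomb_fractions(self) -> list[np.ndarray]:
        """Haldane recombination fraction between adjacent markers."""
        out = []
        for pos in self.cm_positions:
            d = np.diff(np.asarray(pos, dtype=float))
            out.append(0.5 * (1.0 - np.exp(-2.0 * d / 100.0)))
        return out


def default_map(n_chrom: int = 5, markers_per_chrom: int = 10, length_cm: float = 180.0) -> GeneticMap:
    """Evenly spaced markers on equal-length chromosomes."""
    step = length_cm / markers_per_chrom
    return GeneticMap(
        [[step * (k + 0.5) for k in range(markers_per_chrom)] for _ in range(n_chrom)]
    )


@dataclass
class SimConfig:
    """Configuration of a synthetic NAM dataset."""

    n_families: int = 25
    lines_per_family: int = 200
    genetic_map: GeneticMap = field(default_factory=default_map)
    selfing_generations: int = 5
    founder_poly: float = 0.5  # fraction of markers polymorphic per family
    missing_rate: float = 0.23
    missing_mode: str = "MCAR"  # or "het_biased"
    het_odds: float = 10.0  # masking odds for heterozygotes in het_biased mode
    environments: int = 4
    env_sd: float = 1.0
    architecture: GeneticArchitecture = field(default_factory=GeneticArchitecture)
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.founder_poly <= 1.0:
            raise ValueError("founder_poly must be in [0, 1]")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.environments < 1:
            raise ValueError("environments must be >= 1")
        if self.missing_mode not in ("MCAR", "het_biased"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")


def _meiosis(h1: np.ndarray, h2: np.ndarray, chrom_slices, recomb, rng) -> np.ndarray:
    """One gamete per line from parental haplotypes (n_lines x n_markers)."""
    n = h1.shape[0]
    gam = np.empty_like(h1)
    for sl, r in zip(chrom_slices, recomb):
        m = sl.stop - sl.start
        # state[i, k] = which haplotype line i transmits at marker k
        switches = np.empty((n, m), dtype=bool)
        switches[:, 0] = rng.random(n) < 0.5
        if m > 1:
            switches[:, 1:] = rng.random((n, m - 1)) < r
        state = np.bitwise_xor.accumulate(switches, axis=1)
        gam[:, sl] = np.where(state, h1[:, sl], h2[:, sl])
    return gam


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate the NAM genotype matrix (no missingness).

    Per family, the F1 of (reference x founder) is selfed
    ``cfg.selfing_generations`` times by single-seed descent with
    Haldane recombination.  The reference (B73) allele is ``q``; the
    founder allele at polymorphic loci is ``Q``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    gmap = cfg.genetic_map
    markers = gmap.markers()
    n_mark = len(markers)
    recomb = gmap.recomb_fractions()
    chrom_slices = []
    start = 0
    for pos in gmap.cm_positions:
        chrom_slices.append(slice(start, start + len(pos)))
        start += len(pos)

    lines: list[str] = []
    family: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for f in range(1, cfg.n_families + 1):
        fam = f"Z{f:03d}"
        poly = rng.random(n_mark) < cfg.founder_poly
        n = cfg.lines_per_family
        # F1: founder haplotype (Q at polymorphic loci) over reference (all q)
        h1 = np.tile(poly.astype(np.int8), (n, 1))
        h2 = np.zeros((n, n_mark), dtype=np.int8)
        for _ in range(cfg.selfing_generations):
            g1 = _meiosis(h1, h2, chrom_slices, recomb, rng)
            g2 = _meiosis(h1, h2, chrom_slices, recomb, rng)
            h1, h2 = g1, g2
        blocks.append((h1 + h2).astype(np.int8))  # 0=qq, 1=Qq, 2=QQ
        for i in range(1, n + 1):
            lid = f"{fam}E{i:04d}"
            lines.append(lid)
            family[lid] = fam
    calls = np.vstack(blocks)
    return GenotypeMatrix(lines, family, markers, calls)


def mask_genotypes(
    gm: GenotypeMatrix,
    rate: float,
    mode: str = "MCAR",
    seed: int | np.random.Generator = 0,
    het_odds: float = 10.0,
) -> GenotypeMatrix:
    """Return a copy of ``gm`` with a fraction ``rate`` of calls masked.

    MCAR masks uniformly at random; ``het_biased`` masks calls with
    sampling weight ``het_odds`` for heterozygotes and 1 otherwise
    (``het_odds=inf`` masks all heterozygotes first).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = gm.calls.copy()
    n_total = calls.size
    n_mask = int(round(rate * n_total))
    if n_mask == 0:
        return GenotypeMatrix(gm.lines, gm.family, gm.markers, calls)
    flat = calls.ravel()
    if mode == "MCAR":
        idx = rng.choice(n_total, size=n_mask, replace=False)
    elif mode == "het_biased":
        het = flat == 1
        if np.isinf(het_odds):
            het_idx = np.flatnonzero(het)
            rest_idx = np.flatnonzero(~het)
            rng.shuffle(het_idx)
            rng.shuffle(rest_idx)
            idx = np.concatenate([het_idx, rest_idx])[:n_mask]
        else:
            # weighted sampling without replacement via exponential keys
            w = np.where(het, float(het_odds), 1.0)
            keys = rng.exponential(size=n_total) / w
            idx = np.argpartition(keys, n_mask - 1)[:n_mask]
    else:
        raise ValueError(f"unknown missing mode {mode!r}")
    flat[idx] = -1
    return GenotypeMatrix(gm.lines, gm.family, gm.markers, flat.reshape(calls.shape))


def genetic_values(gm: GenotypeMatrix, arch: GeneticArchitecture, n_env: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-line overall genetic value G and per-environment deviations GE.

    Returns ``(G, GE)`` with shapes ``(n_lines,)`` and ``(n_lines, n_env)``.
    Coefficients use the calls as stored (mask before calling this to get
    the analysis-time view; pass the true matrix for truth generation).
    """
    ids = arch.locus_ids()
    if not ids:
        return np.zeros(gm.n_lines), np.zeros((gm.n_lines, n_env))
    unknown = [m for m in ids if m not in gm._marker_index]
    if unknown:
        raise ValueError(f"architecture references unknown markers: {unknown}")
    calls = gm.calls_for(ids)
    xA = additive_coefficients(calls)
    xD = dominance_coefficients(calls)
    col = {m: k for k, m in enumerate(ids)}
    G = np.zeros(gm.n_lines)
    for l in arch.loci:
        G += l.a * xA[:, col[l.marker]] + l.d * xD[:, col[l.marker]]
    for p in arch.pairs:
        ai, di = xA[:, col[p.marker_i]], xD[:, col[p.marker_i]]
        aj, dj = xA[:, col[p.marker_j]], xD[:, col[p.marker_j]]
        G += p.aa * ai * aj + p.ad * ai * dj + p.da * di * aj + p.dd * di * dj
    GE = np.zeros((gm.n_lines, n_env))
    for e in arch.env_loci:
        GE[:, e.env - 1] += e.ae * xA[:, col[e.marker]] + e.de * xD[:, col[e.marker]]
    for e in arch.env_pairs:
        ai, di = xA[:, col[e.marker_i]], xD[:, col[e.marker_i]]
        aj, dj = xA[:, col[e.marker_j]], xD[:, col[e.marker_j]]
        GE[:, e.env - 1] += (
            e.aae * ai * aj + e.ade * ai * dj + e.dae * di * aj + e.dde * di * dj
        )
    return G, GE


def simulate_phenotypes(
    gm: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> PhenotypeTable:
    """Generate phenotypes under the full model from the TRUE calls of ``gm``."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    arch = cfg.architecture
    E = cfg.environments
    G, GE = genetic_values(gm, arch, E)
    env_eff = rng.normal(0.0, cfg.env_sd, size=E)
    records = []
    noise = rng.normal(0.0, arch.residual_sd, size=(gm.n_lines, E))
    for h in range(E):
        vals = arch.mu + env_eff[h] + G + GE[:, h] + noise[:, h]
        for i, line in enumerate(gm.lines):
            records.append((line, h + 1, cfg.trait, vals[i]))
    return PhenotypeTable.from_records(records)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, PhenotypeTable]:
    """Convenience wrapper: (true genotypes, masked genotypes, phenotypes).

    Phenotypes are generated from the true (pre-masking) calls.
    """
    rng = np.random.default_rng(cfg.seed)
    gm_true = simulate_genotypes(cfg, rng)
    ph = simulate_phenotypes(gm_true, cfg, rng)
    gm_obs = mask_genotypes(gm_true, cfg.missing_rate, cfg.missing_mode, rng, cfg.het_odds)
    return gm_true, gm_obs, ph


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a new seed."""
    return replace(cfg, seed=seed)
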