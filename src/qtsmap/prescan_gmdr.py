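"""GMDR-style candidate pre-selection.

Scores observations by environment-centered residuals, partitions them
into multilocus genotype cells, labels cells high/low-risk by the sign
of the training-fold mean score, and ranks loci (1D) and locus pairs
(2D) by cross-validated testing accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from qtsmap.datamodel import GenotypeMatrix, PhenotypeTable


@dataclass
class CandidateSet:
    """Ranked candidate loci and pairs with cross-validated scores."""

    loci: list[tuple[str, float, float]] = field(default_factory=list)
    # (marker_id, testing accuracy, cv consistency), sorted by accuracy desc
    pairs: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    folds: int = 10
    top_k: int = 0
    seed: int = 0

    def locus_ids(self) -> list[str]:
        return [m for m, _, _ in self.loci]

    def pair_ids(self) -> list[tuple[str, str]]:
        return [p for p, _, _ in self.pairs]


def gmdr_residual_score(ph: PhenotypeTable, trait: str) -> np.ndarray:
    """Per-observation score: trait value centered by its environment mean.

    Aligned with the row order of ``ph.for_trait(trait)``; means are
    zero within each environment by construction.
    """
    sub = ph.for_trait(trait)
    if len(sub) < 2:
        raise ValueError("need at least 2 observations to score")
    vals = sub["value"].to_numpy(dtype=float)
    env = sub["environment"].to_numpy()
    out = vals.copy()
    for e in np.unique(env):
        m = env == e
        if m.sum() == 1 and len(np.unique(env)) > 1:
            pass  # single observation centers to zero below, harmless
        out[m] -= vals[m].mean()
    return out


def _fold_assignment(env: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified round-robin fold labels within each environment."""
    fold = np.empty(len(env), dtype=int)
    for e in np.unique(env):
        idx = np.flatnonzero(env == e)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def _cell_accuracy(
    cells: np.ndarray, n_cells: int, scores: np.ndarray, fold: np.ndarray, folds: int
) -> tuple[float, float]:
    """Mean held-out sign-match accuracy and CV consistency for one candidate."""
    pos = scores > 0
    accs = np.empty(folds)
    for k in range(folds):
        test = fold == k
        train = ~test
        sums = np.bincount(cells[train], weights=scores[train], minlength=n_cells)
        counts = np.bincount(cells[train], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        global_high = scores[train].mean() > 0  # ties -> low-risk
        high = np.where(counts > 0, means > 0, global_high)
        accs[k] = (high[cells[test]] == pos[test]).mean()
    return float(accs.mean()), float((accs > 0.5).mean())


def gmdr_scan(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str,
    dim: int = 1,
    folds: int = 10,
    top_k: int = 20,
    seed: int = 0,
    top_m: int = 20,
    exhaustive_pairs: bool = False,
    scores: np.ndarray | None = None,
) -> CandidateSet:
    """Rank loci (dim=1) or locus pairs (dim=2) by GMDR testing accuracy.

    The 2D pair universe is restricted to the top-``top_m`` 1D loci
    unless ``exhaustive_pairs`` is set.  Missing calls fall in the
    heterozygote cell, matching the analysis-time coding.
    """
    if dim not in (1, 2):
        raise ValueError("dim must be 1 or 2")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    sub = ph.for_trait(trait)
    if scores is None:
        scores = gmdr_residual_score(ph, trait)
    env = sub["environment"].to_numpy()
    rng = np.random.default_rng(seed)
    fold = _fold_assignment(env, folds, rng)
    row_idx = np.array([gm.line_index(l) for l in sub["line"]])

    codes = gm.calls[row_idx].astype(np.int64)  # n_obs x n_markers
    codes[codes == -1] = 1  # missing -> heterozygote cell

    result = CandidateSet(folds=folds, top_k=top_k, seed=seed)
    scored_loci: list[tuple[str, float, float]] = []
    for j, mid in enumerate(gm.marker_ids):
        acc, cons = _cell_accuracy(codes[:, j], 3, scores, fold, folds)
        scored_loci.append((mid, acc, cons))
    scored_loci.sort(key=lambda t: (-t[1], gm.marker_index(t[0])))
    if dim == 1:
        result.loci = scored_loci[:top_k]
        return result

    result.loci = scored_loci[:top_m]
    universe = (
        gm.marker_ids if exhaustive_pairs else [m for m, _, _ in scored_loci[:top_m]]
    )
    universe = sorted(universe, key=gm.marker_index)
    scored_pairs: list[tuple[tuple[str, str], float, float]] = []
    for i, j in combinations(universe, 2):
        ci, cj = codes[:, gm.marker_index(i)], codes[:, gm.marker_index(j)]
        acc, cons = _cell_accuracy(3 * ci + cj, 9, scores, fold, folds)
        scored_pairs.append(((i, j), acc, cons))
    scored_pairs.sort(
        key=lambda t: (-t[1], gm.marker_index(t[0][0]), gm.marker_index(t[0][1]))
    )
    result.pairs = scored_pairs[:top_k]
    return result
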