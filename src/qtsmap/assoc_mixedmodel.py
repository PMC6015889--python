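"""Mixed-model hypothesis testing of candidate QTS terms.

F-statistics follow the method-of-fitting-constants reduction: the
numerator is the drop in model sum of squares when the tested term
group is removed from the fullest model, the denominator the fullest
model's residual mean square.  Random environment-interaction blocks
are absorbed as fitted columns for the reduction, with their degrees
of freedom charged to the residual df.  Experiment-wise significance
comes from a within-environment permutation max-F null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import qr

from qtsmap.datamodel import (
    CoefficientDesign,
    GenotypeMatrix,
    PhenotypeTable,
    build_design,
)

_MIN_PERM = 100


def _orth(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space via pivoted QR."""
    if M.size == 0:
        return np.empty((M.shape[0], 0))
    Q, R, _ = qr(np.asarray(M, dtype=float), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        return np.empty((M.shape[0], 0))
    tol = diag[0] * max(M.shape) * np.finfo(float).eps
    rank = int(np.count_nonzero(diag > tol))
    return Q[:, :rank]


class HendersonIII:
    """Precomputed projections for partial F-tests of term groups.

    For each testable group the orthogonal complement of the reduced
    model within the full model span is stored, so F-statistics for
    many (permuted) responses cost one matrix-vector product each.
    """

    def __init__(self, design: CoefficientDesign, include=None):
        M, groups, _base = design.full_matrix(include)
        self.design = design
        self.n = M.shape[0]
        self.group_names = list(groups)
        Q = _orth(M)
        self.rank = Q.shape[1]
        self.df2 = self.n - self.rank
        if self.df2 <= 0:
            raise ValueError(f"no residual degrees of freedom (n={self.n}, rank={self.rank})")
        self.Q_full = Q
        self._extras: dict[str, tuple[np.ndarray | None, int]] = {}
        # all per-term rank work happens in the r-dimensional coordinates
        # of span(M): B = Q'M has the same column-span structure as M
        B = Q.T @ M
        all_cols = np.arange(M.shape[1])
        for name, cols in groups.items():
            keep = np.setdiff1d(all_cols, np.asarray(cols))
            Qr = _orth(B[:, keep])
            df1 = self.rank - Qr.shape[1]
            if df1 == 0:
                self._extras[name] = (None, 0)  # degenerate (collinear/constant) group
                continue
            C = B[:, cols].astype(float)
            C = C - Qr @ (Qr.T @ C)
            Qe = _orth(C)[:, :df1]
            self._extras[name] = (Q @ Qe, df1)

    def df1(self, name: str) -> int:
        return self._extras[name][1]

    def degenerate_terms(self) -> list[str]:
        return [n for n, (_, d) in self._extras.items() if d == 0]

    def f_stats(self, Y: np.ndarray, names=None) -> dict[str, np.ndarray]:
        """F for each term group, for one response or a matrix of them.

        ``Y`` has shape ``(n,)`` or ``(n, k)``; each returned value has
        shape ``(k,)`` (``k=1`` for a vector response).
        """
        Y2 = np.asarray(Y, dtype=float)
        if Y2.ndim == 1:
            Y2 = Y2[:, None]
        qty = self.Q_full.T @ Y2
        yty = (Y2 * Y2).sum(axis=0)
        sse = yty - (qty * qty).sum(axis=0)
        mse = np.maximum(sse, 0.0) / self.df2
        tol = 1e-12 * np.maximum(yty, 1.0)
        out: dict[str, np.ndarray] = {}
        for name in names if names is not None else self.group_names:
            Q_extra, df1 = self._extras[name]
            if df1 == 0:
                out[name] = np.full(Y2.shape[1], np.nan)
                continue
            rdiff = ((Q_extra.T @ Y2) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[name] = np.where(mse > 0, (rdiff / df1) / np.where(mse > 0, mse, 1.0), np.inf)
            out[name] = np.where(rdiff <= tol, 0.0, out[name])
        return out


def henderson3_f(
    design: CoefficientDesign, term: str, include=None
) -> tuple[float, int, int, float]:
    """Partial F-test of one term group: ``(F, df1, df2, p_point)``.

    Raises on a degenerate (rank-zero) tested group.
    """
    tester = HendersonIII(design, include)
    df1 = tester.df1(term)
    if df1 == 0:
        raise ValueError(f"degenerate term {term!r}: no independent columns to test")
    F = float(tester.f_stats(design.y, [term])[term][0])
    p = float(stats.f.sf(F, df1, tester.df2))
    return F, df1, tester.df2, p


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Max-F null distributions, one per numerator-df class."""

    maxima: dict[int, np.ndarray]  # df1 -> descending-sorted max F values
    n_perm: int
    alpha: float

    def p_ew(self, df1: int, F: float) -> float:
        """Experiment-wise p with +1 smoothing."""
        m = self.maxima[df1]
        return (1.0 + float(np.count_nonzero(m >= F))) / (self.n_perm + 1.0)

    def critical_f(self, df1: int, alpha: float | None = None) -> float:
        """Critical value: reject iff F exceeds it (consistent with p_ew <= alpha)."""
        alpha = self.alpha if alpha is None else alpha
        m = self.maxima[df1]
        k = int(np.floor(alpha * (self.n_perm + 1)))
        k = max(1, min(k, self.n_perm))
        return float(m[k - 1])  # k-th largest

    def floor(self) -> float:
        """Smallest achievable p_ew."""
        return 1.0 / (self.n_perm + 1.0)


def permute_within_env(
    y: np.ndarray, env: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Matrix of permuted responses (n x n_perm), shuffling y across
    lines independently within each environment (genotypes fixed)."""
    n = len(y)
    Y = np.empty((n, n_perm))
    for h in np.unique(env):
        idx = np.flatnonzero(env == h)
        block = np.tile(y[idx], (n_perm, 1))
        block = rng.permuted(block, axis=1)
        Y[idx, :] = block.T
    return Y


def permutation_threshold(
    tester: HendersonIII,
    terms: list[str] | None = None,
    n_perm: int = 2000,
    alpha_ew: float = 0.05,
    seed: int | np.random.Generator = 0,
    chunk: int = 256,
) -> PermutationNull:
    """Empirical max-F null over candidate terms.

    Each permutation shuffles the phenotype within environment, records
    the maximum F over all candidate terms of each df1 class, and the
    critical F is the empirical (1 - alpha) quantile of those maxima.
    """
    if n_perm < _MIN_PERM:
        raise ValueError(f"n_perm={n_perm} below the floor of {_MIN_PERM}")
    if not 0.0 < alpha_ew <= 1.0:
        raise ValueError("alpha_ew must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = tester.design
    if terms is None:
        terms = [t for t in tester.group_names if tester.df1(t) > 0]
    by_df: dict[int, list[str]] = {}
    for t in terms:
        d = tester.df1(t)
        if d == 0:
            continue
        by_df.setdefault(d, []).append(t)
    maxima = {d: np.empty(n_perm) for d in by_df}
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        Y = permute_within_env(design.y, design.env, k, rng)
        fs = tester.f_stats(Y, terms)
        for d, names in by_df.items():
            stacked = np.vstack([fs[t] for t in names])
            maxima[d][done : done + k] = stacked.max(axis=0)
        done += k
    return PermutationNull(
        maxima={d: np.sort(m)[::-1] for d, m in maxima.items()},
        n_perm=n_perm,
        alpha=alpha_ew,
    )


def tail_p_estimate(null_maxima: np.ndarray, F: float, tail_frac: float = 0.1) -> float | None:
    """Generalized-Pareto tail extrapolation of an experiment-wise p.

    Fits exceedances over the (1 - tail_frac) empirical quantile; returns
    None when F is inside the empirical range (use the empirical p there).
    """
    m = np.sort(null_maxima)
    u = float(np.quantile(m, 1.0 - tail_frac))
    exc = m[m > u] - u
    if F <= m[-1] or len(exc) < 20:
        return None
    c, loc, scale = stats.genpareto.fit(exc, floc=0.0)
    return float(len(exc) / len(m) * stats.genpareto.sf(F - u, c, loc=0.0, scale=scale))


# ---------------------------------------------------------------------------
# candidate scanning
# ---------------------------------------------------------------------------


@dataclass
class ScanSettings:
    n_perm: int = 2000
    alpha_ew: float = 0.05
    highly_significant_threshold: float = 5.0  # on -log10 p_ew
    prune: bool = True
    tail_estimate: bool = False
    seed: int = 0


@dataclass
class TermTest:
    """Test result for one model term (or E-column interaction block)."""

    name: str
    kind: str
    markers: tuple[str, ...]
    F: float
    df1: int
    df2: int
    p_point: float
    p_ew: float
    neg_log10_p_ew: float
    p_at_floor: bool  # p_ew hit the permutation resolution floor
    p_ew_tail: float | None
    passes_ew: bool
    highly_significant: bool
    selected: bool
    degenerate: bool = False


@dataclass
class ScanResults:
    terms: list[TermTest]
    selected_loci: list[str]
    selected_pairs: list[tuple[str, str]]
    critical_f: dict[int, float]
    settings: ScanSettings = field(default_factory=ScanSettings)

    def selected_terms(self) -> list[TermTest]:
        return [t for t in self.terms if t.selected]

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _term_sort_key(design: CoefficientDesign, gm: GenotypeMatrix, name: str):
    info = design.column_registry[name]
    return tuple(gm.marker_index(m) for m in info.markers)

_KIND_PRIORITY = {"a": 0, "d": 1, "aa": 2, "ad": 2, "da": 2, "dd": 2,
                  "ae": 3, "de": 4, "aae": 5, "ade": 5, "dae": 5, "dde": 5}


def screen_collinear_terms(
    design: CoefficientDesign, gm: GenotypeMatrix, tol: float = 1e-8
) -> tuple[list[str], list[str]]:
    """Greedy rank screening of candidate terms.

    Term groups are visited in priority order (single-locus a, then d,
    then pair terms, then interaction blocks; marker order within a
    priority) and kept only if their columns add rank beyond the terms
    already kept.  Returns ``(kept, dropped)``; dropped terms are
    exactly collinear with higher-priority candidates in this dataset.
    """
    M, groups, base_cols = design.full_matrix()
    order = sorted(
        groups,
        key=lambda t: (
            _KIND_PRIORITY[design.column_registry[t].kind],
            _term_sort_key(design, gm, t),
        ),
    )
    Q = _orth(M[:, base_cols])
    kept, dropped = [], []
    for name in order:
        C = M[:, groups[name]].astype(float)
        R = C - Q @ (Q.T @ C)
        scale = np.linalg.norm(C) or 1.0
        u, s, _ = np.linalg.svd(R, full_matrices=False)
        add = int(np.count_nonzero(s > tol * scale))
        if add == 0:
            dropped.append(name)
            continue
        kept.append(name)
        Q = np.hstack([Q, u[:, :add]])
    return kept, dropped


def scan_candidates(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str,
    loci: list[str],
    pairs: list[tuple[str, str]] = (),
    model: str = "full",
    settings: ScanSettings | None = None,
) -> ScanResults:
    """Test all candidate terms, apply backward pruning, and select QTS.

    Selection keeps terms with ``p_ew <= alpha_ew``; pruning repeatedly
    drops the weakest non-significant term (largest p_ew, ties broken
    by marker order) and refits until every remaining term is
    significant.  Permutation thresholds are computed once on the
    initial candidate design and held fixed through pruning.
    """
    if not loci and not pairs:
        raise ValueError("empty candidate set")
    settings = settings or ScanSettings()
    all_loci = list(dict.fromkeys(list(loci) + [m for p in pairs for m in p]))
    design = build_design(gm, ph, trait, all_loci, pairs, model)
    testable, screened = screen_collinear_terms(design, gm)
    tester = HendersonIII(design, include=testable)
    degenerate = set(screened) | set(tester.degenerate_terms())
    testable = [t for t in testable if t not in degenerate]
    null = permutation_threshold(
        tester, testable, settings.n_perm, settings.alpha_ew, settings.seed
    )

    def evaluate(active: list[str], tst: HendersonIII) -> dict[str, tuple]:
        fs = tst.f_stats(design.y, active)
        out = {}
        for t in active:
            df1 = tst.df1(t)
            F = float(fs[t][0])
            p_pt = float(stats.f.sf(F, df1, tst.df2)) if df1 > 0 else float("nan")
            p_ew = null.p_ew(df1, F) if df1 > 0 else float("nan")
            out[t] = (F, df1, tst.df2, p_pt, p_ew)
        return out

    active = list(testable)
    stats_now = evaluate(active, tester)
    dropped: dict[str, tuple] = {}
    if settings.prune:
        while active:
            nonsig = [t for t in active if stats_now[t][4] > settings.alpha_ew]
            if not nonsig:
                break
            worst = max(
                nonsig,
                key=lambda t: (stats_now[t][4], tuple(-i for i in _term_sort_key(design, gm, t))),
            )
            dropped[worst] = stats_now[worst]
            active.remove(worst)
            if active:
                tester_a = HendersonIII(design, include=active)
                newly_degenerate = set(tester_a.degenerate_terms())
                for t in newly_degenerate & set(active):
                    dropped[t] = stats_now[t]
                    active.remove(t)
                if active:
                    stats_now = evaluate(active, tester_a)

    floor = null.floor()
    results: list[TermTest] = []
    for name in design.term_groups():
        info = design.column_registry[name]
        if name in degenerate:
            results.append(
                TermTest(name, info.kind, info.markers, float("nan"), 0, tester.df2,
                         float("nan"), float("nan"), float("nan"), False, None,
                         False, False, False, degenerate=True)
            )
            continue
        rec = stats_now.get(name, dropped.get(name))
        F, df1, df2, p_pt, p_ew = rec
        at_floor = p_ew <= floor + 1e-15
        tail = None
        if settings.tail_estimate and at_floor:
            tail = tail_p_estimate(null.maxima[df1], F)
        neg = float(-np.log10(p_ew))
        passes = (name in active) and p_ew <= settings.alpha_ew
        highly = passes and neg > settings.highly_significant_threshold
        results.append(
            TermTest(name, info.kind, info.markers, F, df1, df2, p_pt, p_ew, neg,
                     at_floor, tail, passes, highly, selected=name in active)
        )

    sel_loci: dict[str, None] = {}
    sel_pairs: dict[tuple[str, str], None] = {}
    for t in results:
        if t.selected and t.passes_ew:
            if len(t.markers) == 1:
                sel_loci.setdefault(t.markers[0])
            elif len(t.markers) == 2:
                sel_pairs.setdefault(t.markers)
    return ScanResults(
        terms=results,
        selected_loci=sorted(sel_loci, key=gm.marker_index),
        selected_pairs=sorted(sel_pairs, key=lambda p: (gm.marker_index(p[0]), gm.marker_index(p[1]))),
        critical_f={d: null.critical_f(d) for d in null.maxima},
        settings=settings,
    )
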