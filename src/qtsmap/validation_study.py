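"""Monte-Carlo validation harnesses.

Two experiments: (1) the missing-genotype policy check — when masked
calls are truly homozygous but analyzed under the heterozygote coding,
dominance-related terms should stay at the type-I level; (2) the
end-to-end parameter-recovery harness (simulate, optionally prescan
and map, estimate, partition) that aggregates bias, RMSE, credible
interval coverage and selection rates across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qtsmap.assoc_mixedmodel import (
    HendersonIII,
    ScanSettings,
    permutation_threshold,
    scan_candidates,
)
from qtsmap.datamodel import DOMINANCE_KINDS, GenotypeMatrix, build_design
from qtsmap.effect_estimation import (
    HeritabilityPartition,
    gibbs_fit,
    partition_heritability,
)
from qtsmap.nam_simulator import (
    SimConfig,
    mask_genotypes,
    simulate_genotypes,
    simulate_phenotypes,
    with_seed,
)
from qtsmap.prescan_gmdr import gmdr_scan


@dataclass
class RecoveryReport:
    """Aggregated results of a Monte-Carlo experiment."""

    effects: pd.DataFrame  # term, truth, mean estimate, bias, rmse, coverage
    heritability: pd.DataFrame  # component, truth, mean estimate
    dominance_significant_rate: float | None = None
    dominance_rate_se: float | None = None
    additive_significant_rate: float | None = None
    selection_sensitivity: float | None = None
    selection_fdr: float | None = None
    reps: int = 0
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"replicates: {self.reps}"]
        if self.dominance_significant_rate is not None:
            lines.append(
                f"dominance-term experiment-wise significance rate: "
                f"{self.dominance_significant_rate:.3f} "
                f"(MC SE {self.dominance_rate_se:.3f})"
            )
        if self.additive_significant_rate is not None:
            lines.append(
                f"additive-term significance rate: {self.additive_significant_rate:.3f}"
            )
        if self.selection_sensitivity is not None:
            lines.append(f"selection sensitivity: {self.selection_sensitivity:.3f}")
        if self.selection_fdr is not None:
            lines.append(f"selection FDR: {self.selection_fdr:.3f}")
        if len(self.effects):
            lines.append(self.effects.to_string(index=False))
        if len(self.heritability):
            lines.append(self.heritability.to_string(index=False))
        return "\n".join(lines)


def _truth_effects(cfg: SimConfig) -> dict[str, float]:
    """Map fixed-term names to their true values."""
    arch = cfg.architecture
    out: dict[str, float] = {}
    for l in arch.loci:
        out[f"a:{l.marker}"] = l.a
        out[f"d:{l.marker}"] = l.d
    for p in arch.pairs:
        out[f"aa:{p.marker_i}:{p.marker_j}"] = p.aa
        out[f"ad:{p.marker_i}:{p.marker_j}"] = p.ad
        out[f"da:{p.marker_i}:{p.marker_j}"] = p.da
        out[f"dd:{p.marker_i}:{p.marker_j}"] = p.dd
    return out


def _truth_partition(cfg: SimConfig, gm_true: GenotypeMatrix, ph) -> HeritabilityPartition:
    """Realized truth variance decomposition, by plugging the true
    effects into the partition on the true-call design."""
    arch = cfg.architecture
    loci = arch.locus_ids()
    pairs = arch.pair_ids()
    design = build_design(gm_true, ph, cfg.trait, loci, pairs, "full")
    beta = {}
    for name in design.fixed_names:
        beta[name] = _truth_effects(cfg).get(name, 0.0)
    u: dict[str, np.ndarray] = {}
    for name, Z in design.random_blocks.items():
        kind, *markers = name.split(":")
        levels = np.zeros(Z.shape[1])
        if kind in ("ae", "de"):
            for e in arch.env_loci:
                if e.marker == markers[0]:
                    levels[e.env - 1] = getattr(e, kind)
        else:
            for e in arch.env_pairs:
                if (e.marker_i, e.marker_j) == tuple(markers):
                    levels[e.env - 1] = getattr(e, kind)
        u[name] = levels
    return partition_heritability(design, beta=beta, u=u)


def missing_genotype_experiment(
    cfg: SimConfig,
    scenario: str = "truth_homozygous",
    reps: int = 20,
    seed: int = 0,
    n_perm: int = 300,
    alpha_ew: float = 0.05,
) -> RecoveryReport:
    """Monte-Carlo check of the missing-as-heterozygote analysis policy.

    ``truth_homozygous``: masked calls' true values are replaced by a
    random homozygote before phenotype generation, so no true
    heterozygotes exist; the analysis (which codes NA as Qq) should
    then find dominance-related terms significant only at the type-I
    level.  ``truth_heterozygous``: masked calls are truly Qq, so
    dominance-related truth signal is real and should be detected.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if scenario not in ("truth_homozygous", "truth_heterozygous"):
        raise ValueError(f"unknown scenario {scenario!r}")
    arch = cfg.architecture
    loci = arch.locus_ids()
    pairs = arch.pair_ids()
    dom_hits = 0
    add_hits = 0
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        c = with_seed(cfg, int(rng.integers(2**31)))
        rrng = np.random.default_rng(c.seed)
        gm_true = simulate_genotypes(c, rrng)
        gm_obs = mask_genotypes(gm_true, c.missing_rate, c.missing_mode, rrng, c.het_odds)
        masked = gm_obs.calls == -1
        actual = gm_true.calls.copy()
        if scenario == "truth_homozygous":
            homo = rrng.choice(np.array([0, 2], dtype=np.int8), size=int(masked.sum()))
            actual[masked] = homo
            # any residual true heterozygotes outside the mask are also
            # re-drawn as homozygotes: this scenario has no true hets
            resid_het = (actual == 1) & ~masked
            actual[resid_het] = rrng.choice(
                np.array([0, 2], dtype=np.int8), size=int(resid_het.sum())
            )
        else:
            actual[masked] = 1
        gm_actual = GenotypeMatrix(gm_true.lines, gm_true.family, gm_true.markers, actual)
        ph = simulate_phenotypes(gm_actual, c, rrng)

        design = build_design(gm_obs, ph, c.trait, loci, pairs, "full")
        tester = HendersonIII(design)
        terms = [t for t in tester.group_names if tester.df1(t) > 0]
        null = permutation_threshold(tester, terms, n_perm, alpha_ew, rrng)
        fs = tester.f_stats(design.y, terms)
        dom_sig = add_sig = False
        for t in terms:
            kind = design.column_registry[t].kind
            p_ew = null.p_ew(tester.df1(t), float(fs[t][0]))
            if p_ew <= alpha_ew:
                if kind in DOMINANCE_KINDS:
                    dom_sig = True
                elif kind in ("a", "aa", "ae", "aae"):
                    add_sig = True
        dom_hits += dom_sig
        add_hits += add_sig
    rate = dom_hits / reps
    return RecoveryReport(
        effects=pd.DataFrame(),
        heritability=pd.DataFrame(),
        dominance_significant_rate=rate,
        dominance_rate_se=float(np.sqrt(max(rate * (1 - rate), alpha_ew * (1 - alpha_ew)) / reps)),
        additive_significant_rate=add_hits / reps,
        reps=reps,
        notes={"scenario": scenario, "alpha_ew": alpha_ew, "n_perm": n_perm},
    )


def calibration_experiment(
    reps: int = 200,
    n_terms: int = 50,
    n_perm: int = 500,
    alpha_ew: float = 0.05,
    seed: int = 0,
    lines: int = 150,
) -> dict:
    """Experiment-wise type-I error of the permutation threshold.

    Each replicate simulates a pure-noise dataset over ``n_terms``
    unlinked loci, tests every additive term, and rejects when any
    term's experiment-wise p falls at or below ``alpha_ew``.  Returns
    the empirical rejection rate with its Monte-Carlo standard error.
    """
    from qtsmap.presets import null_simconfig

    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(reps):
        cfg = null_simconfig(n_loci=n_terms, lines=lines, seed=int(rng.integers(2**31)))
        rrng = np.random.default_rng(cfg.seed)
        gm = simulate_genotypes(cfg, rrng)
        ph = simulate_phenotypes(gm, cfg, rrng)
        design = build_design(gm, ph, cfg.trait, gm.marker_ids, (), "additive")
        a_terms = [f"a:{m}" for m in gm.marker_ids]
        tester = HendersonIII(design, include=a_terms)
        terms = [t for t in a_terms if tester.df1(t) > 0]
        null = permutation_threshold(tester, terms, n_perm, alpha_ew, rrng)
        fs = tester.f_stats(design.y, terms)
        if any(
            null.p_ew(tester.df1(t), float(fs[t][0])) <= alpha_ew for t in terms
        ):
            rejections += 1
    rate = rejections / reps
    return {
        "rejection_rate": rate,
        "alpha": alpha_ew,
        "mc_se": float(np.sqrt(alpha_ew * (1 - alpha_ew) / reps)),
        "reps": reps,
        "n_terms": n_terms,
        "n_perm": n_perm,
    }


def recovery_experiment(
    cfg: SimConfig,
    reps: int = 20,
    seed: int = 0,
    mode: str = "oracle",
    mcmc: dict | None = None,
    scan_settings: ScanSettings | None = None,
    prescan_top_k: int = 20,
    ci_level: float = 0.95,
) -> RecoveryReport:
    """End-to-end parameter recovery across simulated replicates.

    ``mode='oracle'`` fits the model at the true loci/pairs (isolating
    estimation from selection); ``mode='pipeline'`` runs the full
    prescan -> map -> estimate chain and additionally reports selection
    sensitivity and false-discovery rate at the experiment-wise level.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mcmc = {"n_iter": 3000, "burn_in": 1000, "thin": 2, **(mcmc or {})}
    arch = cfg.architecture
    truth = _truth_effects(cfg)
    truth_loci = set(arch.locus_ids())
    rng = np.random.default_rng(seed)

    est_rows: dict[str, list] = {t: [] for t in truth}
    cover: dict[str, list] = {t: [] for t in truth}
    herit_truth, herit_est = [], []
    full_h2t, additive_h2t = [], []
    sens, fdr = [], []

    for rep in range(reps):
        c = with_seed(cfg, int(rng.integers(2**31)))
        rrng = np.random.default_rng(c.seed)
        gm_true = simulate_genotypes(c, rrng)
        ph = simulate_phenotypes(gm_true, c, rrng)
        gm_obs = mask_genotypes(gm_true, c.missing_rate, c.missing_mode, rrng, c.het_odds)

        if mode == "pipeline":
            cand = gmdr_scan(gm_obs, ph, c.trait, dim=2, top_k=prescan_top_k, seed=c.seed)
            loci = cand.locus_ids()
            pairs = cand.pair_ids()
            scan = scan_candidates(
                gm_obs, ph, c.trait, loci, pairs, "full", scan_settings or ScanSettings(n_perm=300, seed=c.seed)
            )
            found = set(scan.selected_loci)
            hits = len(found & truth_loci)
            sens.append(hits / max(len(truth_loci), 1))
            fdr.append((len(found) - hits) / max(len(found), 1))
            fit_loci = sorted(set(scan.selected_loci) | truth_loci, key=gm_obs.marker_index)
            fit_pairs = sorted(
                set(scan.selected_pairs) | set(arch.pair_ids()),
                key=lambda p: (gm_obs.marker_index(p[0]), gm_obs.marker_index(p[1])),
            )
        else:
            fit_loci = arch.locus_ids()
            fit_pairs = arch.pair_ids()

        design = build_design(gm_obs, ph, c.trait, fit_loci, fit_pairs, "full")
        fit = gibbs_fit(design, seed=rrng, **mcmc)
        bm = fit.beta_mean()
        for term, tv in truth.items():
            if term not in fit.fixed_names:
                continue
            est = float(bm[fit.fixed_names.index(term)])
            lo, hi = fit.credible_interval(term, ci_level)
            est_rows[term].append(est)
            cover[term].append(lo <= tv <= hi)

        part = partition_heritability(design, fit)
        tpart = _truth_partition(c, gm_true, ph)
        herit_est.append(part)
        herit_truth.append(tpart)
        full_h2t.append(part.h2_T)

        ad_design = build_design(gm_obs, ph, c.trait, fit_loci, (), "additive")
        ad_fit = gibbs_fit(ad_design, seed=rrng, **mcmc)
        ad_part = partition_heritability(ad_design, ad_fit)
        additive_h2t.append(ad_part.h2_T)

    eff = []
    for term, tv in truth.items():
        ests = np.array(est_rows[term], dtype=float)
        if len(ests) == 0:
            continue
        eff.append(
            {
                "term": term,
                "truth": tv,
                "estimate": ests.mean(),
                "bias": ests.mean() - tv,
                "rmse": float(np.sqrt(((ests - tv) ** 2).mean())),
                "coverage": float(np.mean(cover[term])),
            }
        )
    herit = []
    for comp in ("h2_A", "h2_D", "h2_AA", "h2_AD", "h2_DA", "h2_DD", "h2_AE", "h2_DE",
                 "h2_AAE", "h2_ADE", "h2_DAE", "h2_DDE"):
        herit.append(
            {
                "component": comp,
                "truth": float(np.mean([getattr(t, comp) for t in herit_truth])),
                "estimate": float(np.mean([getattr(e, comp) for e in herit_est])),
            }
        )
    herit.append(
        {
            "component": "h2_T",
            "truth": float(np.mean([t.h2_T for t in herit_truth])),
            "estimate": float(np.mean([e.h2_T for e in herit_est])),
        }
    )
    herit.append(
        {
            "component": "h2_Dplus",
            "truth": float(np.mean([t.h2_Dplus for t in herit_truth])),
            "estimate": float(np.mean([e.h2_Dplus for e in herit_est])),
        }
    )
    return RecoveryReport(
        effects=pd.DataFrame(eff),
        heritability=pd.DataFrame(herit),
        selection_sensitivity=float(np.mean(sens)) if sens else None,
        selection_fdr=float(np.mean(fdr)) if fdr else None,
        reps=reps,
        notes={
            "mode": mode,
            "full_h2T": full_h2t,
            "additive_h2T": additive_h2t,
            "additive_below_full_rate": float(
                np.mean([a < f for a, f in zip(additive_h2t, full_h2t)])
            ),
        },
    )
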