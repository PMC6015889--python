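"""Total genotypic values and superior genotype-combination search.

Given an estimated genetic architecture, computes the total genotypic
value of any genotype assignment over the QTS loci, identifies the
best observed line, and finds the exact optimal homozygous (superior
line) and unrestricted (superior hybrid) assignments by exhaustive
enumeration within connected components of the epistasis pair graph.
The population mean is reported alongside but never folded into G.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from qtsmap.datamodel import (
    HET,
    MISSING,
    QQ,
    GeneticArchitecture,
    GenotypeMatrix,
    Marker,
    encode_additive,
    encode_dominance,
    qq,
)

#: enumeration order: ties in optima break toward qq (reference allele)
_CODE_ORDER = (qq, QQ, HET)


@dataclass
class GenotypePlan:
    """A genotype assignment over the QTS loci with its total values."""

    assignment: dict[str, str]  # marker id -> QQ/Qq/qq
    G: float
    G_env: list[float]
    provenance: str  # fixed_pattern(...), best_line(...), superior_line, superior_hybrid
    direction: str = "+"
    line: str | None = None
    mu: float = 0.0


def total_genotypic_value(
    assignment: dict[str, str], arch: GeneticArchitecture, env: int | None = None
) -> float:
    """Total genetic effect G of an assignment (G + GE_h when ``env`` given).

    The population mean is excluded.  Missing assignments at an
    architecture locus are an error; a MISSING call evaluates with the
    heterozygote coding.
    """
    absent = [m for m in arch.locus_ids() if m not in assignment]
    if absent:
        raise ValueError(f"assignment missing architecture loci: {absent}")
    xA = {m: encode_additive(assignment[m]) for m in arch.locus_ids()}
    xD = {m: encode_dominance(assignment[m]) for m in arch.locus_ids()}
    g = 0.0
    for l in arch.loci:
        g += l.a * xA[l.marker] + l.d * xD[l.marker]
    for p in arch.pairs:
        g += (
            p.aa * xA[p.marker_i] * xA[p.marker_j]
            + p.ad * xA[p.marker_i] * xD[p.marker_j]
            + p.da * xD[p.marker_i] * xA[p.marker_j]
            + p.dd * xD[p.marker_i] * xD[p.marker_j]
        )
    if env is not None:
        for e in arch.env_loci:
            if e.env == env:
                g += e.ae * xA[e.marker] + e.de * xD[e.marker]
        for e in arch.env_pairs:
            if e.env == env:
                g += (
                    e.aae * xA[e.marker_i] * xA[e.marker_j]
                    + e.ade * xA[e.marker_i] * xD[e.marker_j]
                    + e.dae * xD[e.marker_i] * xA[e.marker_j]
                    + e.dde * xD[e.marker_i] * xD[e.marker_j]
                )
    return g


def _env_totals(assignment, arch, n_env: int) -> list[float]:
    return [total_genotypic_value(assignment, arch, h) for h in range(1, n_env + 1)]


def fixed_pattern_plan(code: str, arch: GeneticArchitecture, n_env: int) -> GenotypePlan:
    """All-QQ, all-qq or all-Qq (F1) assignment over the architecture loci."""
    assignment = {m: code for m in arch.locus_ids()}
    return GenotypePlan(
        assignment=assignment,
        G=total_genotypic_value(assignment, arch),
        G_env=_env_totals(assignment, arch, n_env),
        provenance=f"fixed_pattern({'F1' if code == HET else code})",
        mu=arch.mu,
    )


def line_assignment(gm: GenotypeMatrix, line: str, arch: GeneticArchitecture) -> dict[str, str]:
    """A line's observed genotypes at the architecture loci (NA kept as NA;
    evaluation treats it as heterozygous via the coding)."""
    i = gm.line_index(line)
    out = {}
    for m in arch.locus_ids():
        code = gm.calls[i, gm.marker_index(m)]
        out[m] = {0: qq, 1: HET, 2: QQ, -1: MISSING}[int(code)]
    return out


def best_line(
    gm: GenotypeMatrix,
    arch: GeneticArchitecture,
    direction: str = "+",
    n_env: int | None = None,
    env: int | None = None,
) -> GenotypePlan:
    """The observed line whose genotypes give the extreme total value.

    ``direction='+'`` maximizes, ``'-'`` minimizes; ``env`` selects the
    per-environment criterion G+GE_h (default: overall G).
    """
    if gm.n_lines == 0:
        raise ValueError("no lines")
    if n_env is None:
        n_env = max(arch.n_environments(), 1)
    sign = 1.0 if direction == "+" else -1.0
    best = None
    for line in gm.lines:
        assignment = line_assignment(gm, line, arch)
        val = total_genotypic_value(assignment, arch, env)
        if best is None or sign * val > sign * best[0]:
            best = (val, line, assignment)
    _, line, assignment = best
    return GenotypePlan(
        assignment=assignment,
        G=total_genotypic_value(assignment, arch),
        G_env=_env_totals(assignment, arch, n_env),
        provenance=f"best_line({line})",
        direction=direction,
        line=line,
        mu=arch.mu,
    )


def epistasis_components(arch: GeneticArchitecture) -> list[list[str]]:
    """Connected components of the epistasis pair graph over the loci.

    Loci in no pair are singleton components.  Components and the loci
    within them are ordered by marker (chrom, pos).
    """
    g = nx.Graph()
    g.add_nodes_from(arch.locus_ids())
    for (i, j) in arch.pair_ids():
        g.add_edge(i, j)
    key = lambda m: (Marker(m).chrom, Marker(m).pos)
    comps = [sorted(c, key=key) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: key(c[0]))
    return comps


def superior_plan(
    arch: GeneticArchitecture,
    direction: str = "+",
    allowed: str = "any",
    n_env: int | None = None,
    env: int | None = None,
    component_cap: int = 16,
) -> GenotypePlan:
    """Exact optimal genotype assignment by per-component enumeration.

    ``allowed='homozygous_only'`` searches {QQ, qq} per locus (the
    superior line); ``'any'`` adds Qq (the superior hybrid).  Ties
    break toward qq, then by lexicographic marker order, making plans
    deterministic.  The optimum decomposes over connected components of
    the pair graph because the total value is additive across them.
    """
    if allowed not in ("homozygous_only", "any"):
        raise ValueError(f"allowed must be 'homozygous_only' or 'any', got {allowed!r}")
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    if n_env is None:
        n_env = max(arch.n_environments(), 1)
    codes = _CODE_ORDER[:2] if allowed == "homozygous_only" else _CODE_ORDER
    sign = 1.0 if direction == "+" else -1.0

    assignment: dict[str, str] = {}
    for comp in epistasis_components(arch):
        if len(comp) > component_cap:
            raise ValueError(
                f"epistasis component of size {len(comp)} exceeds the enumeration "
                f"cap ({component_cap}); raise component_cap to search it exactly"
            )
        sub = _restrict(arch, set(comp))
        best_val, best_assign = -np.inf, None
        for combo in product(codes, repeat=len(comp)):
            a = dict(zip(comp, combo))
            v = sign * total_genotypic_value(a, sub, env)
            if v > best_val + 1e-12:  # strict improvement; earlier combos win ties
                best_val, best_assign = v, a
        assignment.update(best_assign)

    return GenotypePlan(
        assignment=assignment,
        G=total_genotypic_value(assignment, arch),
        G_env=_env_totals(assignment, arch, n_env),
        provenance="superior_line" if allowed == "homozygous_only" else "superior_hybrid",
        direction=direction,
        mu=arch.mu,
    )


def _restrict(arch: GeneticArchitecture, loci: set[str]) -> GeneticArchitecture:
    """Architecture restricted to a locus subset (pairs must be inside)."""
    return GeneticArchitecture(
        mu=arch.mu,
        loci=[l for l in arch.loci if l.marker in loci],
        pairs=[p for p in arch.pairs if p.marker_i in loci and p.marker_j in loci],
        env_loci=[e for e in arch.env_loci if e.marker in loci],
        env_pairs=[e for e in arch.env_pairs if e.marker_i in loci and e.marker_j in loci],
        residual_sd=arch.residual_sd,
    )


def plan_gap(plan_a: GenotypePlan, plan_b: GenotypePlan, env: int | None = None) -> float:
    """Difference in total genetic effect, ``plan_a - plan_b``."""
    if env is None:
        return plan_a.G - plan_b.G
    return plan_a.G_env[env - 1] - plan_b.G_env[env - 1]


def plan_differences(plan_a: GenotypePlan, plan_b: GenotypePlan) -> list[str]:
    """Loci whose assigned genotypes differ between two plans."""
    keys = sorted(plan_a.assignment, key=lambda m: (Marker(m).chrom, Marker(m).pos))
    return [m for m in keys if plan_a.assignment[m] != plan_b.assignment.get(m)]


def plan_report(
    gm: GenotypeMatrix,
    arch: GeneticArchitecture,
    direction: str = "+",
    n_env: int | None = None,
    component_cap: int = 16,
) -> tuple[pd.DataFrame, dict[str, GenotypePlan]]:
    """Prediction table: fixed patterns QQ/qq/F1 plus BL, SL, SH rows.

    Columns are the overall G and the per-environment G+GE_h totals;
    the population mean is carried in the plan objects, not the table.
    """
    if n_env is None:
        n_env = max(arch.n_environments(), 1)
    plans = {
        "QQ": fixed_pattern_plan(QQ, arch, n_env),
        "qq": fixed_pattern_plan(qq, arch, n_env),
        "F1": fixed_pattern_plan(HET, arch, n_env),
        f"Best line ({direction})": best_line(gm, arch, direction, n_env),
        f"Superior line ({direction})": superior_plan(
            arch, direction, "homozygous_only", n_env, component_cap=component_cap
        ),
        f"Superior hybrid ({direction})": superior_plan(
            arch, direction, "any", n_env, component_cap=component_cap
        ),
    }
    rows = []
    for entry, plan in plans.items():
        row = {"entry": entry, "G": plan.G}
        for h in range(1, n_env + 1):
            row[f"G+GE{h}"] = plan.G_env[h - 1]
        rows.append(row)
    return pd.DataFrame(rows), plans
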