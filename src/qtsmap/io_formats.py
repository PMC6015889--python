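"""Readers and writers for on-disk artifacts.

Genotype dialects: a simple matrix CSV (rows = lines, columns =
markers, cells in {QQ,Qq,qq,NA} or {2,1,0,NA}) and a HapMap-like tab
format (rs, alleles, chrom, pos, then one column per line with
two-letter allele calls).  Phenotypes are long-format CSV.  All report
tables are TSV with headers and deterministic row order.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from qtsmap.datamodel import (
    HET,
    MISSING,
    QQ,
    STR_TO_INT,
    EnvLocusEffect,
    EnvPairEffect,
    GeneticArchitecture,
    GenotypeMatrix,
    LocusEffect,
    Marker,
    PairEffect,
    PhenotypeTable,
    family_from_line_id,
    qq,
)

_NUMERIC_CALLS = {"2": QQ, "1": HET, "0": qq, "NA": MISSING, "": MISSING}


def _normalize_call(cell: str, row: int, col: str) -> int:
    cell = cell.strip()
    s = _NUMERIC_CALLS.get(cell, cell)
    try:
        return STR_TO_INT[s]
    except KeyError:
        raise ValueError(
            f"unparseable genotype cell {cell!r} at data row {row}, column {col!r}"
        ) from None


def read_genotypes(path: str | Path, dialect: str = "matrix-csv") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``matrix-csv``: header ``line[,family],<marker ids...>``; cells are
    letter or numeric calls.  Family labels come from the optional
    ``family`` column or from a ``Z{family}E{line}`` id prefix.
    ``hapmap-like``: tab-separated ``rs  alleles  chrom  pos`` then one
    column per line; ``alleles`` is ``Q/q`` (non-reference first) and
    calls are two-letter allele strings (``NN`` missing).
    """
    path = Path(path)
    if dialect == "matrix-csv":
        return _read_matrix_csv(path)
    if dialect == "hapmap-like":
        return _read_hapmap_like(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _family_labels(lines: Sequence[str], families: Sequence[str] | None) -> dict[str, str]:
    out = {}
    for i, l in enumerate(lines):
        if families is not None:
            out[l] = families[i]
        else:
            fam = family_from_line_id(l)
            out[l] = fam if fam is not None else "F0"
    return out


def _read_matrix_csv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "line":
            raise ValueError(f"{path}: matrix-csv must start with a 'line' column")
        has_family = len(header) > 1 and header[1] == "family"
        marker_start = 2 if has_family else 1
        marker_ids = header[marker_start:]
        if len(set(marker_ids)) != len(marker_ids):
            dup = sorted({m for m in marker_ids if marker_ids.count(m) > 1})
            raise ValueError(f"{path}: duplicate marker id {dup[0]!r}")
        lines, fams, rows = [], [], []
        for r, rec in enumerate(reader, start=1):
            lines.append(rec[0])
            if has_family:
                fams.append(rec[1])
            rows.append(
                [_normalize_call(c, r, marker_ids[j]) for j, c in enumerate(rec[marker_start:])]
            )
    family = _family_labels(lines, fams if has_family else None)
    markers = [Marker(m) for m in marker_ids]
    return GenotypeMatrix(lines, family, markers, np.array(rows, dtype=np.int8))


def _read_hapmap_like(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:4] != ["rs", "alleles", "chrom", "pos"]:
            raise ValueError(
                f"{path}: hapmap-like header must start with rs/alleles/chrom/pos"
            )
        lines = header[4:]
        marker_ids, cols = [], []
        for r, rec in enumerate(reader, start=1):
            rs, alleles = rec[0], rec[1]
            try:
                q_allele, ref_allele = alleles.split("/")
            except ValueError:
                raise ValueError(f"{path}: bad alleles field {alleles!r} at row {r}") from None
            marker_ids.append(rs)
            col = []
            for j, call in enumerate(rec[4:]):
                call = call.strip()
                if call in ("NN", "N", "", "NA"):
                    col.append(-1)
                    continue
                if len(call) != 2:
                    raise ValueError(
                        f"{path}: unparseable call {call!r} at row {r}, column {lines[j]!r}"
                    )
                n_q = sum(1 for a in call if a == q_allele)
                n_ref = sum(1 for a in call if a == ref_allele)
                if n_q + n_ref != 2:
                    raise ValueError(
                        f"{path}: call {call!r} at row {r}, column {lines[j]!r} "
                        f"uses alleles outside {alleles!r}"
                    )
                col.append(n_q)
            cols.append(col)
    calls = np.array(cols, dtype=np.int8).T  # lines x markers
    family = _family_labels(lines, None)
    return GenotypeMatrix(lines, family, [Marker(m) for m in marker_ids], calls)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write matrix-csv with letter calls (round-trips through read)."""
    strings = gm.call_strings()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["line", "family"] + gm.marker_ids)
        for i, line in enumerate(gm.lines):
            w.writerow([line, gm.family[line]] + list(strings[i]))


def read_phenotypes(
    path: str | Path, gm: GenotypeMatrix | None = None, strict: bool = True
) -> PhenotypeTable:
    """Read long-format phenotype CSV (line, environment, trait, value)."""
    df = pd.read_csv(path)
    expected = set(PhenotypeTable.COLUMNS)
    unknown = set(df.columns) - expected - {"units"}
    if unknown:
        raise ValueError(f"{path}: unknown phenotype columns {sorted(unknown)}")
    try:
        ph = PhenotypeTable(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None
    if gm is not None and strict:
        ph.check_lines(gm)
    return ph


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    ph.df[list(PhenotypeTable.COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# architecture / effects-table serialization
# ---------------------------------------------------------------------------

_ARCH_COLUMNS = ["qts", "qts2", "kind", "environment", "estimate"]


def write_architecture(arch: GeneticArchitecture, path: str | Path) -> None:
    """Serialize an architecture as an effects table (TSV).

    Special rows with kind ``mu`` / ``residual_sd`` carry the scalars.
    """
    rows = [
        {"qts": "", "qts2": "", "kind": "mu", "environment": "", "estimate": arch.mu},
        {"qts": "", "qts2": "", "kind": "residual_sd", "environment": "", "estimate": arch.residual_sd},
    ]
    for l in arch.loci:
        for kind in ("a", "d"):
            rows.append({"qts": l.marker, "qts2": "", "kind": kind, "environment": "",
                         "estimate": getattr(l, kind)})
    for p in arch.pairs:
        for kind in ("aa", "ad", "da", "dd"):
            rows.append({"qts": p.marker_i, "qts2": p.marker_j, "kind": kind,
                         "environment": "", "estimate": getattr(p, kind)})
    for e in arch.env_loci:
        for kind in ("ae", "de"):
            rows.append({"qts": e.marker, "qts2": "", "kind": kind,
                         "environment": e.env, "estimate": getattr(e, kind)})
    for e in arch.env_pairs:
        for kind in ("aae", "ade", "dae", "dde"):
            rows.append({"qts": e.marker_i, "qts2": e.marker_j, "kind": kind,
                         "environment": e.env, "estimate": getattr(e, kind)})
    pd.DataFrame(rows, columns=_ARCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_architecture(path: str | Path) -> GeneticArchitecture:
    df = pd.read_csv(path, sep="\t", dtype={"qts": str, "qts2": str}, keep_default_na=False)
    if list(df.columns) != _ARCH_COLUMNS:
        raise ValueError(f"{path}: expected columns {_ARCH_COLUMNS}, got {list(df.columns)}")
    arch = GeneticArchitecture()
    loci: dict[str, dict] = {}
    pairs: dict[tuple[str, str], dict] = {}
    env_loci: dict[tuple[str, int], dict] = {}
    env_pairs: dict[tuple[str, str, int], dict] = {}
    for _, row in df.iterrows():
        kind, est = row["kind"], float(row["estimate"])
        if kind == "mu":
            arch.mu = est
        elif kind == "residual_sd":
            arch.residual_sd = est
        elif kind in ("a", "d"):
            loci.setdefault(row["qts"], {})[kind] = est
        elif kind in ("aa", "ad", "da", "dd"):
            pairs.setdefault((row["qts"], row["qts2"]), {})[kind] = est
        elif kind in ("ae", "de"):
            env_loci.setdefault((row["qts"], int(row["environment"])), {})[kind] = est
        elif kind in ("aae", "ade", "dae", "dde"):
            env_pairs.setdefault((row["qts"], row["qts2"], int(row["environment"])), {})[kind] = est
        else:
            raise ValueError(f"{path}: unknown effect kind {kind!r}")
    arch.loci = [LocusEffect(m, **kw) for m, kw in loci.items()]
    arch.pairs = [PairEffect(i, j, **kw) for (i, j), kw in pairs.items()]
    arch.env_loci = [EnvLocusEffect(m, h, **kw) for (m, h), kw in env_loci.items()]
    arch.env_pairs = [EnvPairEffect(i, j, h, **kw) for (i, j, h), kw in env_pairs.items()]
    return arch


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_effects_table(estimates: Iterable, path: str | Path) -> None:
    """Effects TSV: one row per estimated term (EffectEstimate objects)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "qts": e.markers[0],
                "qts2": e.markers[1] if len(e.markers) > 1 else "",
                "kind": e.kind,
                "environment": e.env if e.env is not None else "",
                "estimate": e.estimate,
                "se": e.se,
                "neg_log10_p_ew": "" if e.neg_log10_p_ew is None else e.neg_log10_p_ew,
                "pct_variance": e.pct_variance,
            }
        )
    pd.DataFrame(
        rows,
        columns=["qts", "qts2", "kind", "environment", "estimate", "se",
                 "neg_log10_p_ew", "pct_variance"],
    ).to_csv(path, sep="\t", index=False)


def read_effects_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    expected = ["qts", "qts2", "kind", "environment", "estimate", "se",
                "neg_log10_p_ew", "pct_variance"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return df


def write_heritability_table(partitions: dict[str, object], path: str | Path) -> None:
    """One row per trait, the component columns plus the two totals."""
    cols = ["h2_A", "h2_D", "h2_AA", "h2_AD", "h2_DA", "h2_DD",
            "h2_AE", "h2_DE", "h2_AAE", "h2_ADE", "h2_DAE", "h2_DDE"]
    rows = []
    for trait in sorted(partitions):
        p = partitions[trait]
        row = {"trait": trait}
        row.update({c: getattr(p, c) for c in cols})
        row["h2_T"] = p.h2_T
        row["h2_Dplus"] = p.h2_Dplus
        rows.append(row)
    pd.DataFrame(rows, columns=["trait"] + cols + ["h2_T", "h2_Dplus"]).to_csv(
        path, sep="\t", index=False
    )


def write_prediction_table(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_edge_list(arch: GeneticArchitecture, path: str | Path, scan=None) -> None:
    """G-by-G edge list: one row per epistatic pair, strongest kind first.

    ``significance`` is 'general' when only general epistasis is
    present, 'environment-specific' when only G-by-E epistasis is, and
    'both' otherwise.
    """
    env_pairs = {(e.marker_i, e.marker_j) for e in arch.env_pairs
                 if any(abs(getattr(e, k)) > 0 for k in ("aae", "ade", "dae", "dde"))}
    rows = []
    for p in arch.pairs:
        effects = {k: getattr(p, k) for k in ("aa", "ad", "da", "dd")}
        kind = max(effects, key=lambda k: abs(effects[k]))
        has_general = any(abs(v) > 0 for v in effects.values())
        has_env = (p.marker_i, p.marker_j) in env_pairs
        if has_general and has_env:
            sig = "both"
        elif has_env:
            sig = "environment-specific"
        else:
            sig = "general"
        rows.append(
            {"qts_i": p.marker_i, "qts_j": p.marker_j, "kind": kind,
             "estimate": effects[kind], "significance": sig}
        )
    pd.DataFrame(rows, columns=["qts_i", "qts_j", "kind", "estimate", "significance"]).to_csv(
        path, sep="\t", index=False
    )


def write_scan_table(scan, path: str | Path) -> None:
    """ScanResults TSV, one row per tested term."""
    rows = []
    for t in scan.terms:
        rows.append(
            {
                "term": t.name,
                "kind": t.kind,
                "qts": t.markers[0] if t.markers else "",
                "qts2": t.markers[1] if len(t.markers) > 1 else "",
                "F": t.F,
                "df1": t.df1,
                "df2": t.df2,
                "p_point": t.p_point,
                "p_ew": t.p_ew,
                "neg_log10_p_ew": (
                    f">{t.neg_log10_p_ew:.2f}" if t.p_at_floor else t.neg_log10_p_ew
                ),
                "passes_ew": t.passes_ew,
                "highly_significant": t.highly_significant,
                "selected": t.selected,
                "degenerate": t.degenerate,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
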