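"""Core domain types and genotype-to-coefficient coding.

Genotypes are biallelic calls in {QQ, Qq, qq, NA} where ``Q`` is the
non-reference (non-B73) allele and ``q`` the reference (B73) allele.
The additive coefficient codes QQ as +1 and qq as -1; the dominance
coefficient is the heterozygote indicator.  Missing calls are coded as
heterozygotes throughout (the indicator-variable device for missing
genotypes is algebraically equivalent to this imputation under the
chosen coding).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# genotype codes
# ---------------------------------------------------------------------------

QQ = "QQ"
HET = "Qq"
qq = "qq"
MISSING = "NA"

GENOTYPE_CODES = (QQ, HET, qq, MISSING)

#: string call -> internal int8 code
STR_TO_INT = {qq: 0, HET: 1, QQ: 2, MISSING: -1}
INT_TO_STR = {v: k for k, v in STR_TO_INT.items()}

# lookup tables indexed by (int code + 1): NA, qq, Qq, QQ
_ADD_TABLE = np.array([0, -1, 0, 1], dtype=np.int8)
_DOM_TABLE = np.array([1, 0, 1, 0], dtype=np.int8)

#: effect kinds that enter the fixed block of the full model
FIXED_KINDS = ("a", "d", "aa", "ad", "da", "dd")
#: environment-interaction kinds, modeled as random blocks
RANDOM_KINDS = ("ae", "de", "aae", "ade", "dae", "dde")
#: kinds whose contribution involves at least one dominance coefficient
DOMINANCE_KINDS = frozenset({"d", "ad", "da", "dd", "de", "ade", "dae", "dde"})


def encode_additive(call: str) -> int:
    """Additive coefficient of a genotype call: QQ -> +1, qq -> -1,
    Qq -> 0; missing calls are treated as heterozygotes (0)."""
    try:
        return int(_ADD_TABLE[STR_TO_INT[call] + 1])
    except (KeyError, TypeError):
        raise ValueError(
            f"unknown genotype code: {call!r} (expected one of {GENOTYPE_CODES})"
        ) from None


def encode_dominance(call: str) -> int:
    """Dominance (heterozygote-indicator) coefficient: Qq -> 1,
    homozygotes -> 0; missing calls are treated as heterozygotes (1)."""
    try:
        return int(_DOM_TABLE[STR_TO_INT[call] + 1])
    except (KeyError, TypeError):
        raise ValueError(
            f"unknown genotype code: {call!r} (expected one of {GENOTYPE_CODES})"
        ) from None


def additive_coefficients(calls: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_additive` over an int8 call array."""
    return _ADD_TABLE[calls.astype(np.int64) + 1].astype(np.float64)


def dominance_coefficients(calls: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_dominance` over an int8 call array."""
    return _DOM_TABLE[calls.astype(np.int64) + 1].astype(np.float64)


# ---------------------------------------------------------------------------
# markers and genotype matrices
# ---------------------------------------------------------------------------

_MARKER_RE = re.compile(r"^S(\d+)_(\d+)$")


@dataclass(frozen=True, order=True)
class Marker:
    """A biallelic marker named ``S{chrom}_{pos}``."""

    chrom: int
    pos: int
    id: str = field(compare=False)

    def __init__(self, id: str, chrom: int | None = None, pos: int | None = None):
        if chrom is None or pos is None:
            m = _MARKER_RE.match(id)
            if not m:
                raise ValueError(f"marker id {id!r} does not match 'S{{chrom}}_{{pos}}'")
            chrom, pos = int(m.group(1)), int(m.group(2))
        if chrom < 1 or pos < 1:
            raise ValueError(f"marker {id!r}: chrom and pos must be positive")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)

    @classmethod
    def from_id(cls, id: str) -> "Marker":
        return cls(id)


class GenotypeMatrix:
    """Lines x markers genotype calls with family labels.

    Parameters
    ----------
    lines : ordered line identifiers
    family : map line id -> family label
    markers : ordered :class:`Marker` objects
    calls : int8 array of shape ``(n_lines, n_markers)`` using the
        internal coding (qq=0, Qq=1, QQ=2, NA=-1)
    """

    def __init__(
        self,
        lines: Sequence[str],
        family: Mapping[str, str],
        markers: Sequence[Marker],
        calls: np.ndarray,
    ):
        self.lines = list(lines)
        self.family = dict(family)
        self.markers = list(markers)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        bad = ~np.isin(calls, [-1, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {calls[i, j]} at line {self.lines[i]!r}, "
                f"marker {self.markers[j].id!r}"
            )
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate marker ids: {dup}")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line ids")
        missing_fam = [l for l in self.lines if l not in self.family]
        if missing_fam:
            raise ValueError(f"lines without family label: {missing_fam[:5]}")
        self.calls = calls
        self._line_index = {l: i for i, l in enumerate(self.lines)}
        self._marker_index = {m.id: j for j, m in enumerate(self.markers)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def line_index(self, line: str) -> int:
        return self._line_index[line]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def calls_for(self, marker_ids: Sequence[str]) -> np.ndarray:
        cols = [self.marker_index(m) for m in marker_ids]
        return self.calls[:, cols]

    # -- summary statistics -------------------------------------------------

    def heterozygote_ratio(self) -> np.ndarray:
        """Per-marker fraction of observed heterozygote calls."""
        return (self.calls == 1).mean(axis=0)

    def missing_ratio(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == -1).mean(axis=0)

    def call_strings(self) -> np.ndarray:
        """Calls as an object array of strings (QQ/Qq/qq/NA)."""
        out = np.empty(self.calls.shape, dtype=object)
        for code, s in INT_TO_STR.items():
            out[self.calls == code] = s
        return out

    @classmethod
    def from_strings(
        cls,
        lines: Sequence[str],
        family: Mapping[str, str],
        marker_ids: Sequence[str],
        calls: Sequence[Sequence[str]],
    ) -> "GenotypeMatrix":
        markers = [Marker(m) for m in marker_ids]
        arr = np.empty((len(lines), len(markers)), dtype=np.int8)
        for i, row in enumerate(calls):
            for j, c in enumerate(row):
                try:
                    arr[i, j] = STR_TO_INT[c]
                except KeyError:
                    raise ValueError(
                        f"unknown genotype code {c!r} at line {lines[i]!r}, "
                        f"marker {marker_ids[j]!r}"
                    ) from None
        return cls(lines, family, markers, arr)


_FAMILY_ID_RE = re.compile(r"^(Z\d+)E\d+$")


def family_from_line_id(line_id: str) -> str | None:
    """Extract the family label from a ``Z{family}E{line}`` id, if present."""
    m = _FAMILY_ID_RE.match(line_id)
    return m.group(1) if m else None


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


class PhenotypeTable:
    """Long-format phenotype records (line, environment, trait, value)."""

    COLUMNS = ("line", "environment", "trait", "value")

    def __init__(self, records: pd.DataFrame, units: Mapping[str, str] | None = None):
        df = records.copy()
        missing_cols = [c for c in self.COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table missing columns {missing_cols}")
        df["environment"] = df["environment"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        dup = df.duplicated(subset=["line", "environment", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate phenotype record for "
                f"(line={row['line']!r}, environment={row['environment']}, "
                f"trait={row['trait']!r})"
            )
        self.df = df.reset_index(drop=True)
        self.units = dict(units or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def environments(self) -> list[int]:
        return sorted(self.df["environment"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.df[self.df["trait"] == trait]
        if sub.empty:
            raise ValueError(f"trait {trait!r} absent from phenotype table")
        return sub.reset_index(drop=True)

    def check_lines(self, gm: GenotypeMatrix) -> None:
        """Raise if any record names a line absent from the genotype matrix."""
        unknown = set(self.df["line"]) - set(gm.lines)
        if unknown:
            raise ValueError(f"phenotype lines absent from genotypes: {sorted(unknown)[:5]}")

    @classmethod
    def from_records(cls, records: Iterable[tuple], units=None) -> "PhenotypeTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df, units)


# ---------------------------------------------------------------------------
# genetic architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusEffect:
    marker: str
    a: float = 0.0
    d: float = 0.0


@dataclass(frozen=True)
class PairEffect:
    """Digenic epistasis between two loci.

    ``ad`` is (additive at ``marker_i``) x (dominance at ``marker_j``);
    ``da`` is the reverse.  ``marker_i`` must precede ``marker_j`` in the
    genotype matrix marker order.
    """

    marker_i: str
    marker_j: str
    aa: float = 0.0
    ad: float = 0.0
    da: float = 0.0
    dd: float = 0.0

    def __post_init__(self):
        if self.marker_i == self.marker_j:
            raise ValueError(f"pair with identical loci: {self.marker_i}")


@dataclass(frozen=True)
class EnvLocusEffect:
    marker: str
    env: int
    ae: float = 0.0
    de: float = 0.0


@dataclass(frozen=True)
class EnvPairEffect:
    marker_i: str
    marker_j: str
    env: int
    aae: float = 0.0
    ade: float = 0.0
    dae: float = 0.0
    dde: float = 0.0

    def __post_init__(self):
        if self.marker_i == self.marker_j:
            raise ValueError(f"pair with identical loci: {self.marker_i}")


@dataclass
class GeneticArchitecture:
    """Population mean plus per-locus / per-pair effect sets."""

    mu: float = 0.0
    loci: list[LocusEffect] = field(default_factory=list)
    pairs: list[PairEffect] = field(default_factory=list)
    env_loci: list[EnvLocusEffect] = field(default_factory=list)
    env_pairs: list[EnvPairEffect] = field(default_factory=list)
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")

    def locus_ids(self) -> list[str]:
        """All marker ids referenced by any effect, locus-entry order first."""
        seen: dict[str, None] = {}
        for l in self.loci:
            seen.setdefault(l.marker)
        for p in self.pairs:
            seen.setdefault(p.marker_i)
            seen.setdefault(p.marker_j)
        for e in self.env_loci:
            seen.setdefault(e.marker)
        for e in self.env_pairs:
            seen.setdefault(e.marker_i)
            seen.setdefault(e.marker_j)
        return list(seen)

    def pair_ids(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for p in self.pairs:
            seen.setdefault((p.marker_i, p.marker_j))
        for e in self.env_pairs:
            seen.setdefault((e.marker_i, e.marker_j))
        return list(seen)

    def n_environments(self) -> int:
        envs = [e.env for e in self.env_loci] + [e.env for e in self.env_pairs]
        return max(envs) if envs else 0


def canonical_pair(i: str, j: str, gm: GenotypeMatrix) -> tuple[str, str]:
    """Order a marker pair by genotype-matrix marker order (lower index first)."""
    if i == j:
        raise ValueError(f"pair with identical loci: {i}")
    return (i, j) if gm.marker_index(i) < gm.marker_index(j) else (j, i)


# ---------------------------------------------------------------------------
# coefficient design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnInfo:
    """Registry entry mapping a design column (or block) to its meaning."""

    kind: str  # one of FIXED_KINDS, RANDOM_KINDS, or 'intercept'/'env'
    markers: tuple[str, ...]
    env: int | None = None


@dataclass
class CoefficientDesign:
    """Response, fixed block and random environment-interaction blocks.

    The fixed block ``X`` has named columns (intercept, environment
    indicators, then one column per fixed genetic term).  Each random
    block is an ``n x E`` matrix whose column ``h`` holds the term's
    genetic coefficient masked to environment ``h``.
    """

    y: np.ndarray
    env: np.ndarray  # 1-based environment index per row
    n_env: int
    X: np.ndarray
    fixed_names: list[str]
    random_blocks: dict[str, np.ndarray]
    column_registry: dict[str, ColumnInfo]
    lines: list[str]  # line id per row
    trait: str
    model: str

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def fixed_index(self, name: str) -> int:
        return self.fixed_names.index(name)

    def genetic_fixed_names(self) -> list[str]:
        return [
            n
            for n in self.fixed_names
            if self.column_registry[n].kind in FIXED_KINDS
        ]

    def term_groups(self) -> list[str]:
        """Testable term names: each fixed genetic column plus each
        random block (tested as an E-column group)."""
        return self.genetic_fixed_names() + list(self.random_blocks)

    def full_matrix(
        self, include: Iterable[str] | None = None
    ) -> tuple[np.ndarray, dict[str, list[int]], list[int]]:
        """Stack fixed and random columns into one matrix.

        Returns ``(M, groups, base_cols)`` where ``groups`` maps each
        included term name to its column indices in ``M`` and
        ``base_cols`` are the untestable intercept/environment columns.
        ``include`` restricts the genetic terms (None keeps all).
        """
        keep = None if include is None else set(include)
        cols: list[np.ndarray] = []
        groups: dict[str, list[int]] = {}
        base_cols: list[int] = []
        k = 0
        for j, name in enumerate(self.fixed_names):
            info = self.column_registry[name]
            if info.kind in FIXED_KINDS:
                if keep is not None and name not in keep:
                    continue
                groups[name] = [k]
            else:
                base_cols.append(k)
            cols.append(self.X[:, j][:, None])
            k += 1
        for name, Z in self.random_blocks.items():
            if keep is not None and name not in keep:
                continue
            groups[name] = list(range(k, k + Z.shape[1]))
            cols.append(Z)
            k += Z.shape[1]
        M = np.hstack(cols) if cols else np.empty((self.n_obs, 0))
        return M, groups, base_cols


def build_design(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str,
    loci: Sequence[str],
    pairs: Sequence[tuple[str, str]] = (),
    model: str = "full",
) -> CoefficientDesign:
    """Assemble the coefficient design for one trait.

    The full model emits ``a``/``d`` fixed columns per locus, the four
    epistasis columns per pair, and one random E-column block per
    environment-interaction term.  The additive model emits only ``a``
    columns and ``ae`` blocks.
    """
    if model not in ("full", "additive"):
        raise ValueError(f"model must be 'full' or 'additive', got {model!r}")
    if not loci:
        raise ValueError("empty locus set")
    ph.check_lines(gm)
    records = ph.for_trait(trait)

    loci = sorted(dict.fromkeys(loci), key=gm.marker_index)
    locus_set = set(loci)
    canon_pairs = []
    for (i, j) in pairs:
        ci, cj = canonical_pair(i, j, gm)
        if ci not in locus_set or cj not in locus_set:
            raise ValueError(f"pair ({i}, {j}) references a locus not in the locus set")
        canon_pairs.append((ci, cj))
    canon_pairs = list(dict.fromkeys(canon_pairs))
    canon_pairs.sort(key=lambda p: (gm.marker_index(p[0]), gm.marker_index(p[1])))

    y = records["value"].to_numpy(dtype=float)
    env_values = ph.environments
    env_map = {e: h for h, e in enumerate(env_values, start=1)}
    env = records["environment"].map(env_map).to_numpy(dtype=int)
    n_env = len(env_values)
    row_lines = records["line"].tolist()
    row_idx = np.array([gm.line_index(l) for l in row_lines])

    calls = gm.calls_for(loci)[row_idx]  # n_obs x n_loci
    xA = additive_coefficients(calls)
    xD = dominance_coefficients(calls)
    col_of = {m: k for k, m in enumerate(loci)}

    names: list[str] = ["intercept"]
    registry: dict[str, ColumnInfo] = {"intercept": ColumnInfo("intercept", ())}
    columns: list[np.ndarray] = [np.ones(len(y))]
    for h in range(2, n_env + 1):
        name = f"env_{h}"
        names.append(name)
        registry[name] = ColumnInfo("env", (), h)
        columns.append((env == h).astype(float))

    def add_fixed(name: str, kind: str, markers: tuple[str, ...], col: np.ndarray):
        names.append(name)
        registry[name] = ColumnInfo(kind, markers)
        columns.append(col)

    for m in loci:
        add_fixed(f"a:{m}", "a", (m,), xA[:, col_of[m]])
        if model == "full":
            add_fixed(f"d:{m}", "d", (m,), xD[:, col_of[m]])
    if model == "full":
        for (i, j) in canon_pairs:
            ai, di = xA[:, col_of[i]], xD[:, col_of[i]]
            aj, dj = xA[:, col_of[j]], xD[:, col_of[j]]
            add_fixed(f"aa:{i}:{j}", "aa", (i, j), ai * aj)
            add_fixed(f"ad:{i}:{j}", "ad", (i, j), ai * dj)
            add_fixed(f"da:{i}:{j}", "da", (i, j), di * aj)
            add_fixed(f"dd:{i}:{j}", "dd", (i, j), di * dj)

    # interaction blocks use sum-to-zero environment coding: column h is
    # the genetic coefficient times (1[env=h] - 1/E).  This keeps the
    # per-environment deviations identifiable next to the main-effect
    # column (with raw indicators the block would span it exactly).
    env_ind = np.stack(
        [(env == h).astype(float) - 1.0 / n_env for h in range(1, n_env + 1)], axis=1
    )

    random_blocks: dict[str, np.ndarray] = {}

    def add_random(name: str, kind: str, markers: tuple[str, ...], coef: np.ndarray):
        random_blocks[name] = coef[:, None] * env_ind
        registry[name] = ColumnInfo(kind, markers)

    for m in loci:
        add_random(f"ae:{m}", "ae", (m,), xA[:, col_of[m]])
        if model == "full":
            add_random(f"de:{m}", "de", (m,), xD[:, col_of[m]])
    if model == "full":
        for (i, j) in canon_pairs:
            ai, di = xA[:, col_of[i]], xD[:, col_of[i]]
            aj, dj = xA[:, col_of[j]], xD[:, col_of[j]]
            add_random(f"aae:{i}:{j}", "aae", (i, j), ai * aj)
            add_random(f"ade:{i}:{j}", "ade", (i, j), ai * dj)
            add_random(f"dae:{i}:{j}", "dae", (i, j), di * aj)
            add_random(f"dde:{i}:{j}", "dde", (i, j), di * dj)

    return CoefficientDesign(
        y=y,
        env=env,
        n_env=n_env,
        X=np.column_stack(columns),
        fixed_names=names,
        random_blocks=random_blocks,
        column_registry=registry,
        lines=row_lines,
        trait=trait,
        model=model,
    )
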