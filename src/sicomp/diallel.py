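"""Data model, I/O and quality control for diallel compatibility matrices.

A diallel cross pollinates every genotype with itself and every other
genotype, in both directions.  Scores are ordinal 0–10 (0 = fully
incompatible, 4 = half-compatible, 7 = three-quarters compatible,
10 = fully compatible).  The matrix convention throughout the package is
row = pollen recipient (♀), column = pollen donor (♂); the diagonal holds
self-pollinations.  Reciprocal crosses may legitimately differ, and cells
may be missing — missingness is a first-class mask (NaN internally, "NA"
on disk), never a sentinel score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sicomp.errors import (
    DuplicateGenotypeError,
    NonSquareMatrixError,
    ScoreRangeError,
    UndefinedCorrelationError,
    UnknownFamilyError,
)

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class GenotypeLabel:
    """One plant of the study population.

    Parameters
    ----------
    id : unique identifier within the study.
    family : half-sib family label (progeny of one maternal parent).
    replicate_presence : tags of the replicates (years) the genotype was
        scored in.
    """

    id: str
    family: str
    replicate_presence: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise DuplicateGenotypeError("genotype id must be non-empty")
        if not self.family:
            raise UnknownFamilyError(f"genotype {self.id!r}: family must be non-empty")


@dataclass(frozen=True)
class ReciprocalFlag:
    """A reciprocal cross pair whose two directions disagree by more than 3."""

    pair: tuple[str, str]
    score_fw: int
    score_rev: int

    @property
    def abs_difference(self) -> int:
        return abs(self.score_fw - self.score_rev)


class DiallelMatrix:
    """An n×n grid of ordinal compatibility scores with a missing mask.

    ``scores[i, j]`` is the score of pollen from genotype ``j`` (♂) on the
    stigma of genotype ``i`` (♀); NaN marks a missing cell.  Non-missing
    scores are validated to be integers in [0, 10].
    """

    def __init__(
        self,
        genotypes: Sequence[GenotypeLabel],
        scores: np.ndarray,
        replicate_tag: str = "",
    ) -> None:
        scores = np.asarray(scores, dtype=float)
        n = len(genotypes)
        if scores.shape != (n, n):
            raise NonSquareMatrixError(
                f"scores shape {scores.shape} does not match {n} genotypes"
            )
        ids = [g.id for g in genotypes]
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateGenotypeError(f"duplicated genotype ids: {dupes}")
        present = ~np.isnan(scores)
        vals = scores[present]
        if vals.size and (
            np.any(vals < 0) or np.any(vals > 10) or np.any(vals != np.round(vals))
        ):
            bad = vals[(vals < 0) | (vals > 10) | (vals != np.round(vals))]
            raise ScoreRangeError(
                f"scores must be integers in [0, 10]; offending values: {bad[:5]}"
            )
        self.genotypes: list[GenotypeLabel] = list(genotypes)
        self.scores = scores
        self.replicate_tag = replicate_tag
        self._index = {g.id: k for k, g in enumerate(self.genotypes)}

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.genotypes)

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genotypes]

    @property
    def families(self) -> list[str]:
        return [g.family for g in self.genotypes]

    @property
    def family_set(self) -> set[str]:
        return set(self.families)

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where a score is present."""
        return ~np.isnan(self.scores)

    def index_of(self, genotype_id: str) -> int:
        return self._index[genotype_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long interchange format: female_id, male_id, score, replicate_tag."""
        rows = []
        for i, fem in enumerate(self.ids):
            for j, mal in enumerate(self.ids):
                if not np.isnan(self.scores[i, j]):
                    rows.append((fem, mal, int(self.scores[i, j]), self.replicate_tag))
        return pd.DataFrame(
            rows, columns=["female_id", "male_id", "score", "replicate_tag"]
        )

    def family_members(self, family: str) -> list[int]:
        if family not in self.family_set:
            raise UnknownFamilyError(f"unknown family label {family!r}")
        return [k for k, g in enumerate(self.genotypes) if g.family == family]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_families(
    families: Mapping[str, str] | str | Path | None, ids: Iterable[str]
) -> dict[str, str]:
    if families is None:
        return {i: "F0" for i in ids}
    if isinstance(families, (str, Path)):
        meta = pd.read_csv(families, sep="\t", dtype=str)
        if not {"genotype_id", "family"} <= set(meta.columns):
            raise UnknownFamilyError(
                "metadata table must have columns genotype_id, family"
            )
        return dict(zip(meta["genotype_id"], meta["family"]))
    return dict(families)


def read_diallel(
    path: str | Path,
    families: Mapping[str, str] | str | Path | None = None,
    replicate_tag: str = "",
    sep: str = "\t",
) -> DiallelMatrix:
    """Read a wide-format diallel matrix.

    The file's first row and first column carry genotype ids; ♀ recipients
    in rows, ♂ donors in columns; missing cells are empty or ``NA``.
    ``families`` attaches half-sib family labels, either as a mapping or as
    the path of a two-column (genotype_id, family) TSV.
    """
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False
    )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        if sorted(row_ids) != sorted(col_ids):
            raise NonSquareMatrixError(
                f"{path}: row ids and column ids differ "
                f"({len(row_ids)} rows, {len(col_ids)} columns)"
            )
        df = df[row_ids]  # same set, different order: align columns to rows
        col_ids = row_ids
    if len(set(row_ids)) != len(row_ids):
        dupes = sorted({i for i in row_ids if row_ids.count(i) > 1})
        raise DuplicateGenotypeError(f"{path}: duplicated genotype ids {dupes}")

    scores = np.full((len(row_ids), len(row_ids)), np.nan)
    for i in range(len(row_ids)):
        for j in range(len(col_ids)):
            cell = str(df.iat[i, j]).strip()
            if cell in ("", MISSING_TOKEN, "nan"):
                continue
            try:
                val = float(cell)
            except ValueError as exc:
                raise ScoreRangeError(f"{path}: unparsable score {cell!r}") from exc
            scores[i, j] = val

    fam_map = _parse_families(families, row_ids)
    genos = [GenotypeLabel(i, fam_map.get(i, "F0")) for i in row_ids]
    return DiallelMatrix(genos, scores, replicate_tag=replicate_tag)


def write_diallel(m: DiallelMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the wide format read back by :func:`read_diallel`."""
    df = m.to_frame()
    out = df.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=sep, index_label="id")


def read_long(
    path: str | Path, families: Mapping[str, str] | str | Path | None = None
) -> DiallelMatrix:
    """Read the long interchange format (female_id, male_id, score[, replicate_tag])."""
    df = pd.read_csv(path, sep="\t", dtype={"female_id": str, "male_id": str})
    ids = sorted(set(df["female_id"]) | set(df["male_id"]))
    idx = {g: k for k, g in enumerate(ids)}
    scores = np.full((len(ids), len(ids)), np.nan)
    for _, row in df.iterrows():
        scores[idx[row["female_id"]], idx[row["male_id"]]] = row["score"]
    tag = str(df["replicate_tag"].iloc[0]) if "replicate_tag" in df else ""
    fam_map = _parse_families(families, ids)
    genos = [GenotypeLabel(i, fam_map.get(i, "F0")) for i in ids]
    return DiallelMatrix(genos, scores, replicate_tag=tag)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def reciprocal_flags(m: DiallelMatrix) -> list[ReciprocalFlag]:
    """Flag reciprocal pairs whose scores differ by more than 3.

    The rule is strict (|Δ| ≥ 4); both directions must be scored; selfs are
    never flagged.  Such pairs mark crosses compatible in one direction but
    not the other — behaviour a plain two-locus gametophytic model cannot
    produce, hence worth review.
    """
    flags = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            fw, rev = m.scores[i, j], m.scores[j, i]
            if np.isnan(fw) or np.isnan(rev):
                continue
            if abs(fw - rev) > 3:
                flags.append(
                    ReciprocalFlag(
                        pair=(m.ids[i], m.ids[j]),
                        score_fw=int(fw),
                        score_rev=int(rev),
                    )
                )
    return flags


def _cell_selector(m: DiallelMatrix, subset) -> np.ndarray:
    """Boolean cell mask for a cross-set selector.

    ``None`` selects every cell; ``("family", f)`` the cells with both
    parents in half-sib family ``f``; ``("female", g)`` genotype ``g``'s row
    (its pollinations as recipient); ``("male", g)`` its column (as donor).
    """
    sel = np.zeros((m.n, m.n), dtype=bool)
    if subset is None:
        sel[:] = True
        return sel
    kind, label = subset
    if kind == "family":
        members = m.family_members(label)
        sel[np.ix_(members, members)] = True
    elif kind == "female":
        sel[m.index_of(label), :] = True
    elif kind == "male":
        sel[:, m.index_of(label)] = True
    else:
        raise ValueError(f"unknown selector kind {kind!r}")
    return sel


def replicate_correlation(
    m1: DiallelMatrix,
    m2: DiallelMatrix,
    subset=None,
    method: str = "pearson",
) -> tuple[float, int]:
    """Correlation between two replicates over jointly scored cells.

    Cells are aligned by genotype id (the replicates need not contain the
    same genotype set — e.g. plants added in a later year are dropped).
    Returns ``(r, n_shared)``.  ``method`` is ``"pearson"`` (default) or
    ``"spearman"``.
    """
    shared = [g for g in m1.ids if g in set(m2.ids)]
    if len(shared) == 0:
        raise UndefinedCorrelationError("no shared genotypes between replicates")
    i1 = [m1.index_of(g) for g in shared]
    i2 = [m2.index_of(g) for g in shared]
    s1 = m1.scores[np.ix_(i1, i1)]
    s2 = m2.scores[np.ix_(i2, i2)]

    sub = DiallelMatrix(
        [m1.genotypes[k] for k in i1], s1, replicate_tag=m1.replicate_tag
    )
    sel = _cell_selector(sub, subset)
    both = sel & ~np.isnan(s1) & ~np.isnan(s2)
    n_shared = int(both.sum())
    if n_shared < 3:
        raise UndefinedCorrelationError(
            f"only {n_shared} shared scored cells; need at least 3"
        )
    x, y = s1[both], s2[both]
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant scores: correlation undefined")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, n_shared


def subset_scores(
    m: DiallelMatrix,
    family_a: str,
    family_b: str,
    include_selfs: bool = False,
    pool_reciprocal: bool = False,
) -> list[int]:
    """All non-missing scores with ♀ parent in ``family_a`` and ♂ in ``family_b``.

    For ``family_a == family_b`` both cross directions are inside the block
    already; selfs (the diagonal) are excluded unless ``include_selfs``.
    ``pool_reciprocal`` additionally pools the transposed block when the two
    families differ.
    """
    rows = m.family_members(family_a)
    cols = m.family_members(family_b)
    out: list[int] = []
    for i in rows:
        for j in cols:
            if i == j and not include_selfs:
                continue
            v = m.scores[i, j]
            if not np.isnan(v):
                out.append(int(v))
    if pool_reciprocal and family_a != family_b:
        out.extend(subset_scores(m, family_b, family_a, include_selfs))
    return out
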