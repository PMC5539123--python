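"""Compatibility Components (CCs).

A diallel matrix is distilled into per-genotype latent phenotypes in four
steps: (1) each genotype's pollination profile is the concatenation of its
row (scores as ♀) and its column (scores as ♂); (2) pairwise Euclidean
distances between profiles are computed pairwise-complete, rescaling the
sum of squares by p/m for m jointly observed of p coordinates; (3) the
distance matrix rows are column-centred (not variance-scaled) and
decomposed by SVD — the component scores are the genotype projections;
(4) because component ORDER is not stable across replicate years (nearby
variance fractions let adjacent components swap), components are matched
across replicates by greedy pairing on |Pearson correlation| with a sign
fix, and the matched pairs are relabelled CC1…CCk.  Ward hierarchical
clustering of the first four component scores groups genotypes by
pollination behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from sicomp.diallel import DiallelMatrix
from sicomp.errors import NoSharedCoordinatesError, ValidationError


@dataclass
class PollinationProfile:
    """One genotype's pollination behaviour vector (length 2n): its matrix
    row (as ♀ against every genotype) then its column (as ♂); NaN where the
    underlying cell is missing."""

    genotype_id: str
    values: np.ndarray


@dataclass
class CCResult:
    """Component scores and variance decomposition for one replicate.

    ``scores`` is genotypes × components (labelled PC1…PCk, or CC1…CCk
    after cross-replicate matching); ``variance_fraction`` the share of
    total variance per component.
    """

    scores: pd.DataFrame
    variance_fraction: np.ndarray
    replicate_tag: str = ""
    clusters: pd.Series | None = None
    degenerate: bool = False

    @property
    def ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


@dataclass
class ComponentMatch:
    """Bijective pairing of leading components across two replicates."""

    mapping: dict[int, int]  # replicate-1 component -> replicate-2 component (1-based)
    correlation: dict[int, float]  # |r| per replicate-1 component
    sign: dict[int, int] = field(default_factory=dict)


PROFILE_MODES = ("both", "row", "column")


def build_profiles(m: DiallelMatrix, mode: str = "both") -> list[PollinationProfile]:
    """One profile per genotype, in matrix order.

    ``mode`` selects the ♀ row, the ♂ column, or (default) their
    concatenation, so reciprocal asymmetry informs similarity.
    """
    if mode not in PROFILE_MODES:
        raise ValidationError(f"profile mode must be one of {PROFILE_MODES}")
    profiles = []
    for k, gid in enumerate(m.ids):
        row, col = m.scores[k, :], m.scores[:, k]
        if mode == "row":
            vec = row.copy()
        elif mode == "column":
            vec = col.copy()
        else:
            vec = np.concatenate([row, col])
        profiles.append(PollinationProfile(gid, vec))
    return profiles


def distance_matrix(profiles: list[PollinationProfile]) -> pd.DataFrame:
    """Pairwise-complete Euclidean distance between pollination profiles.

    d(a,b) = sqrt((p/m) Σ_shared (a_c − b_c)²) with p the profile length
    and m the jointly observed coordinate count — the proportional
    rescaling makes distances comparable across pairs with different
    missingness.  A pair with no shared coordinate is a hard error.
    """
    n = len(profiles)
    if n == 0:
        raise ValidationError("no profiles")
    vals = np.vstack([p.values for p in profiles])
    p_len = vals.shape[1]
    present = ~np.isnan(vals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m_ab = int(both.sum())
            if m_ab == 0:
                raise NoSharedCoordinatesError(
                    f"profiles {profiles[i].genotype_id!r} and "
                    f"{profiles[j].genotype_id!r} share no observed coordinate"
                )
            ss = float(np.sum((vals[i, both] - vals[j, both]) ** 2))
            d[i, j] = d[j, i] = np.sqrt(p_len / m_ab * ss)
    ids = [p.genotype_id for p in profiles]
    return pd.DataFrame(d, index=ids, columns=ids)


def pca_components(
    dist: pd.DataFrame,
    k: int = 4,
    center: bool = True,
    replicate_tag: str = "",
) -> CCResult:
    """Unscaled PCA (via SVD) of the distance matrix rows.

    Each genotype's feature vector is its row of distances to every
    genotype; columns are centred but not variance-scaled; scores are the
    SVD projections and variance fractions come from the squared singular
    values.  Component signs are fixed so each score column's largest-
    magnitude entry is positive (SVD leaves signs arbitrary).
    """
    X = np.asarray(dist, dtype=float)
    n = X.shape[0]
    if X.shape[0] != X.shape[1] or not np.allclose(X, X.T, atol=1e-8):
        raise ValidationError("distance grid must be square and symmetric")
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n} genotypes")
    Xc = X - X.mean(axis=0, keepdims=True) if center else X.copy()
    degenerate = bool(np.allclose(Xc, 0))
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    for col in range(scores.shape[1]):  # deterministic sign convention
        j = np.argmax(np.abs(scores[:, col]))
        if scores[j, col] < 0:
            scores[:, col] = -scores[:, col]
    total = float(np.sum(s**2))
    var_frac = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(
        scores[:, :k], index=dist.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return CCResult(
        scores=df, variance_fraction=var_frac,
        replicate_tag=replicate_tag, degenerate=degenerate,
    )


def diallel_components(
    m: DiallelMatrix, k: int = 4, mode: str = "both", center: bool = True
) -> CCResult:
    """Convenience: profiles → distances → PCA for one diallel replicate."""
    res = pca_components(
        distance_matrix(build_profiles(m, mode=mode)), k=k, center=center,
        replicate_tag=m.replicate_tag,
    )
    return res


def match_components(
    r1: CCResult, r2: CCResult, n_components: int = 4
) -> tuple[ComponentMatch, CCResult, CCResult]:
    """Match the leading components of two replicates and relabel them CCs.

    Greedy assignment on descending |Pearson correlation| between score
    vectors yields a bijection on the first ``n_components``; each matched
    replicate-2 component is sign-flipped so the matched correlation is
    positive.  Matched pairs are relabelled CC1…CCk in replicate-1 variance
    order.  Returns (match, relabelled r1, relabelled/reordered r2).
    """
    if list(r1.scores.index) != list(r2.scores.index):
        raise ValidationError("replicates contain different genotype sets")
    k = n_components
    if r1.scores.shape[1] < k or r2.scores.shape[1] < k:
        raise ValidationError(f"both results need at least {k} components")
    s1 = r1.scores.to_numpy()[:, :k]
    s2 = r2.scores.to_numpy()[:, :k]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(s1.T, s2.T)[:k, k:]
    corr = np.nan_to_num(corr)

    mapping: dict[int, int] = {}
    sign: dict[int, int] = {}
    strength: dict[int, float] = {}
    cand = np.abs(corr).copy()
    for _ in range(k):
        i, j = map(int, np.unravel_index(np.argmax(cand), cand.shape))
        mapping[i + 1] = j + 1
        sign[i + 1] = 1 if corr[i, j] >= 0 else -1
        strength[i + 1] = float(abs(corr[i, j]))
        cand[i, :] = -1
        cand[:, j] = -1

    cc_labels = [f"CC{i + 1}" for i in range(k)]
    out1 = r1.scores.iloc[:, :k].copy()
    out1.columns = cc_labels
    cols2 = []
    for i in range(1, k + 1):
        col = s2[:, mapping[i] - 1] * sign[i]
        cols2.append(col)
    out2 = pd.DataFrame(np.column_stack(cols2), index=r2.scores.index,
                        columns=cc_labels)
    m1 = CCResult(out1, r1.variance_fraction[:k], r1.replicate_tag)
    var2 = np.array([r2.variance_fraction[mapping[i] - 1] for i in range(1, k + 1)])
    m2 = CCResult(out2, var2, r2.replicate_tag)
    return ComponentMatch(mapping, strength, sign), m1, m2


def cluster_genotypes(scores: pd.DataFrame, n_clusters: int = 4) -> pd.Series:
    """Ward hierarchical clustering of the first four component scores,
    cut at ``n_clusters``; labels are 1-based."""
    X = scores.to_numpy()[:, : min(4, scores.shape[1])]
    if n_clusters > X.shape[0]:
        raise ValidationError(
            f"n_clusters={n_clusters} exceeds {X.shape[0]} genotypes"
        )
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="cluster")
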