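"""Single-marker genome-wide association of component phenotypes.

Each marker is tested one at a time with ordinary least squares:

    phenotype ~ intercept + dosage + structure covariates

where dosage is the additive 0/1/2 minor-allele count and the structure
covariates are leading principal-component axes of the centred dosage
matrix.  The p-value is the two-sided t-test on the dosage coefficient.
Markers with minor allele frequency below 0.05 are excluded before
testing, and the genome-wide significance line is the Bonferroni
threshold −log₁₀(α/m) for the m markers actually tested.

Implementation note: with missing dosages mean-imputed the covariate block
is identical for every marker, so the scan partials the covariates out of
the phenotype once (Frisch–Waugh) and reduces each marker test to a simple
regression on the residualised dosage — algebraically the same t statistic
as the full per-marker OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from sicomp.errors import ValidationError

UNMAPPED = "U"
NEG_LOG10_P_CAP = 15.0  # reported −log₁₀p for numerically perfect fits


@dataclass
class GenotypeTable:
    """Marker dosages plus map annotation.

    ``dosages``: markers × genotypes, values in {0, 1, 2, NaN};
    ``marker_map``: per marker linkage_group (``"U"`` if unmapped) and
    position_cM (NaN allowed for unmapped markers).
    """

    dosages: pd.DataFrame
    marker_map: pd.DataFrame  # index = marker; columns linkage_group, position_cM

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosages must be 0/1/2 or missing")
        if list(self.dosages.index) != list(self.marker_map.index):
            raise ValidationError("dosage and map marker order disagree")

    @property
    def markers(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def maf(self) -> pd.Series:
        """Minor allele frequency per marker from non-missing dosages:
        min(p̄, 1 − p̄) with p̄ = mean dosage / 2."""
        p = self.dosages.mean(axis=1, skipna=True) / 2.0
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1).rename("maf")


@dataclass
class AssociationResult:
    """Per-marker scan results plus the global testing context."""

    table: pd.DataFrame  # marker-indexed: beta, t, p, neg_log10_p, n_used, reason
    phenotype_label: str
    alpha: float
    m_tested: int

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_tested)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the genotype TSV (marker, linkage_group, position_cM, dosage
    columns; "NA" for missing; unmapped markers use LG "U")."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "linkage_group": str},
                     na_values=["NA"])
    for col in ("marker", "linkage_group", "position_cM"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df = df.set_index("marker")
    marker_map = df[["linkage_group", "position_cM"]].copy()
    dosages = df.drop(columns=["linkage_group", "position_cM"]).astype(float)
    return GenotypeTable(dosages=dosages, marker_map=marker_map)


def maf_filter(
    g: GenotypeTable, threshold: float = 0.05
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Exclude markers with MAF strictly below ``threshold``.

    Returns the retained table and an exclusion report (marker, maf,
    reason); markers with no scored genotype are excluded with reason
    "no data".
    """
    maf = g.maf()
    no_data = maf.isna()
    low = (maf < threshold) & ~no_data
    keep = ~(no_data | low)
    report = pd.DataFrame({"maf": maf})
    report["reason"] = np.where(
        no_data, "no data", np.where(low, f"maf<{threshold}", "retained")
    )
    kept = GenotypeTable(
        dosages=g.dosages.loc[keep], marker_map=g.marker_map.loc[keep]
    )
    return kept, report


def structure_covariates(g: GenotypeTable, n_axes: int = 2) -> pd.DataFrame:
    """Leading PCA axes of the genotype × marker dosage matrix, used as
    population-structure covariates.

    Missing dosages are marker-mean imputed for this step only; columns of
    the genotype × marker matrix are centred; axes are SVD score vectors.
    """
    n = len(g.genotype_ids)
    if n_axes >= n:
        raise ValidationError(f"n_axes={n_axes} must be < {n} genotypes")
    if n_axes == 0:
        return pd.DataFrame(index=g.genotype_ids)
    X = g.dosages.to_numpy(dtype=float).T  # genotypes × markers
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = (u * s)[:, :n_axes]
    for col in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, col]))
        if scores[j, col] < 0:
            scores[:, col] = -scores[:, col]
    return pd.DataFrame(
        scores, index=g.genotype_ids,
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )


def single_marker_scan(
    phenotype: pd.Series,
    g: GenotypeTable,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    phenotype_label: str = "",
    impute: str = "mean",
) -> AssociationResult:
    """OLS scan of one phenotype over every marker.

    Per marker: phenotype ~ intercept + dosage (+ covariates) over
    genotypes with finite phenotype; missing dosages are marker-mean
    imputed (``impute="mean"``, default, keeping n constant) or dropped
    marker-wise (``impute="complete"``).  Two-sided t-test p-values on the
    dosage coefficient; numerically perfect fits are reported at the
    −log₁₀p cap with a flag; markers collinear with the covariates are
    skipped with a reason.
    """
    pheno = phenotype.reindex(g.genotype_ids).astype(float)
    use = np.isfinite(pheno.to_numpy())
    if use.sum() < 10:
        raise ValidationError(
            f"phenotype finite for only {int(use.sum())} genotypes; need >= 10"
        )
    y = pheno.to_numpy()[use]
    n = len(y)
    if covariates is None or covariates.shape[1] == 0:
        Q = np.ones((n, 1))
    else:
        C = covariates.reindex(g.genotype_ids).to_numpy(dtype=float)[use]
        Q = np.column_stack([np.ones(n), C])
    q = Q.shape[1]
    # residualise phenotype on covariate block once
    coef, *_ = np.linalg.lstsq(Q, y, rcond=None)
    ry = y - Q @ coef

    D = g.dosages.to_numpy(dtype=float)[:, use]  # markers × n
    markers = g.markers
    if impute == "mean":
        mu = np.nanmean(D, axis=1)
        miss = np.isnan(D)
        D = np.where(miss, mu[:, None], D)
        n_used = np.full(len(markers), n)
    elif impute == "complete":
        n_used = (~np.isnan(D)).sum(axis=1)
    else:
        raise ValidationError("impute must be 'mean' or 'complete'")

    beta = np.full(len(markers), np.nan)
    tval = np.full(len(markers), np.nan)
    pval = np.full(len(markers), np.nan)
    reason = np.full(len(markers), "ok", dtype=object)

    if impute == "mean":
        # vectorised Frisch–Waugh: residualise all dosage rows on Q at once
        coefs, *_ = np.linalg.lstsq(Q, D.T, rcond=None)
        RX = D.T - Q @ coefs  # n × markers
        sxx = np.einsum("ij,ij->j", RX, RX)
        df = n - q - 1
        valid = sxx > 1e-12 * n
        sxy = ry @ RX
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(valid, sxy / sxx, np.nan)
            rss = ry @ ry - np.where(valid, b * sxy, 0.0)
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / np.maximum(df, 1) / np.where(valid, sxx, np.nan))
            t = b / se
        beta[valid] = b[valid]
        tval[valid] = t[valid]
        pval[valid] = 2 * stats.t.sf(np.abs(t[valid]), df)
        reason[~valid] = "collinear with covariates"
    else:
        for k in range(len(markers)):
            x = D[k]
            ok = ~np.isnan(x)
            if ok.sum() <= q + 1:
                reason[k] = "too few complete cases"
                continue
            Qk, yk, xk = Q[ok], y[ok], x[ok]
            ck, *_ = np.linalg.lstsq(Qk, yk, rcond=None)
            ryk = yk - Qk @ ck
            cxk, *_ = np.linalg.lstsq(Qk, xk, rcond=None)
            rxk = xk - Qk @ cxk
            sxx = float(rxk @ rxk)
            if sxx <= 1e-12 * ok.sum():
                reason[k] = "collinear with covariates"
                continue
            b = float(ryk @ rxk) / sxx
            rss = max(float(ryk @ ryk) - b * float(ryk @ rxk), 0.0)
            dfk = int(ok.sum()) - q - 1
            se = np.sqrt(rss / max(dfk, 1) / sxx)
            beta[k] = b
            with np.errstate(divide="ignore"):
                tval[k] = b / se if se > 0 else np.inf
            pval[k] = 2 * stats.t.sf(abs(tval[k]), dfk) if np.isfinite(tval[k]) else 0.0

    with np.errstate(divide="ignore"):
        nlp = -np.log10(pval)
    capped = np.isfinite(pval) & (nlp > NEG_LOG10_P_CAP)
    nlp = np.where(capped, NEG_LOG10_P_CAP, nlp)
    reason = np.where(capped & (reason == "ok"), "perfect fit (p capped)", reason)

    table = pd.DataFrame(
        {
            "beta": beta,
            "t": tval,
            "p": pval,
            "neg_log10_p": nlp,
            "n_used": n_used,
            "reason": reason,
        },
        index=pd.Index(markers, name="marker"),
    )
    m_tested = int((table["reason"].isin(["ok", "perfect fit (p capped)"])).sum())
    return AssociationResult(
        table=table, phenotype_label=phenotype_label, alpha=alpha,
        m_tested=m_tested,
    )


def bonferroni_threshold(alpha: float, m_tested: int) -> float:
    """Genome-wide significance line: −log₁₀(α / m)."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m_tested < 1:
        raise ValidationError("m_tested must be >= 1")
    return float(-np.log10(alpha / m_tested))


def manhattan_export(res: AssociationResult, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Per-marker table ordered by linkage group then cM, unmapped markers
    ("U") in a trailing block; columns marker, linkage_group, position_cM,
    neg_log10_p, above_threshold."""
    t = res.table.join(marker_map[["linkage_group", "position_cM"]], how="left")
    t = t[t["reason"].isin(["ok", "perfect fit (p capped)"])]
    lg = t["linkage_group"].astype(str)
    lg_sort = np.where(lg == UNMAPPED, np.inf,
                       pd.to_numeric(lg, errors="coerce"))
    t = t.assign(_lg=lg_sort).sort_values(
        ["_lg", "position_cM"], kind="stable"
    ).drop(columns="_lg")
    thr = res.threshold
    out = t.reset_index()[
        ["marker", "linkage_group", "position_cM", "neg_log10_p"]
    ].copy()
    out["above_threshold"] = t["neg_log10_p"].to_numpy() >= thr
    return out
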