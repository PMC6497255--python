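"""Age-association scans, FDR adjustment, subgroup summaries, regression.

Analyses operate on a cohort table with one row per image; association and
regression first reduce the table to one row per participant (the first
image by id), so no participant is counted twice.  The crossing-count
trait j3 is excluded from default scan panels — apparent crossings are
mostly projections of distinct vessels, not true junctions — but can be
re-included explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "bh_fdr",
    "one_row_per_participant",
    "pearson_age_scan",
    "young_old_summary",
    "regress_trait",
    "regress_all",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("sbp", "dbp", "waist", "hip", "weight", "height", "bmi", "imt")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, q_i = min_{j >= i} p_j * n / j, then restored to the
    original order; adjusted values are capped at 1.  NaN entries are left
    NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adjusted, 1.0)
    out[mask] = adj
    return out


def one_row_per_participant(
    cohort: pd.DataFrame, participant_col: str = "participant_id", image_col: str = "image_id"
) -> pd.DataFrame:
    """Keep the first image (by image id) of each participant."""
    if participant_col not in cohort.columns:
        return cohort
    df = cohort.sort_values([participant_col, image_col] if image_col in cohort else [participant_col])
    return df.groupby(participant_col, as_index=False).first()


def pearson_age_scan(
    cohort: pd.DataFrame,
    traits: Sequence[str] | None = None,
    age_col: str = "age",
    include_j3: bool = False,
    per_participant: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each trait with age, FDR-adjusted.

    The FDR family is the set of traits scanned in this one call.  Traits
    with fewer than 4 complete observations, or that are constant, yield
    NaN statistics and do not enter the family.
    """
    df = one_row_per_participant(cohort) if per_participant else cohort
    if traits is None:
        reserved = {age_col, "participant_id", "image_id", "sex"}
        traits = [
            c
            for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    if not include_j3:
        traits = [t for t in traits if t != "j3" and not t.endswith("_j3")]
    rows = []
    for trait in traits:
        sub = df[[age_col, trait]].dropna()
        n = len(sub)
        if n < 4 or sub[trait].nunique() <= 1:
            rows.append({"trait": trait, "n": n, "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(sub[age_col], sub[trait])
        rows.append({"trait": trait, "n": n, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class SubgroupSummary:
    """Young/old split of one trait: means and shared-bin histograms."""

    trait: str
    cut: float
    young_n: int
    old_n: int
    young_mean: float
    old_mean: float
    bin_edges: np.ndarray
    young_hist: np.ndarray
    old_hist: np.ndarray


def young_old_summary(
    cohort: pd.DataFrame,
    traits: Sequence[str],
    cut: float | None = None,
    age_col: str = "age",
    bins: int = 20,
    per_participant: bool = True,
) -> dict[str, SubgroupSummary]:
    """Summarize each trait in young (< cut) vs old (>= cut) subgroups.

    ``cut`` defaults to the cohort's median age.  Histograms share bin
    edges between the subgroups so their shapes are directly comparable.
    """
    df = one_row_per_participant(cohort) if per_participant else cohort
    if cut is None:
        cut = float(df[age_col].median())
    young = df[df[age_col] < cut]
    old = df[df[age_col] >= cut]
    if young.empty or old.empty:
        raise ValueError(f"age cut {cut} leaves an empty subgroup")
    out = {}
    for trait in traits:
        ys = young[trait].dropna().to_numpy()
        os_ = old[trait].dropna().to_numpy()
        lo = min(ys.min(), os_.min())
        hi = max(ys.max(), os_.max())
        edges = np.histogram_bin_edges(np.concatenate([ys, os_]), bins=bins, range=(lo, hi))
        out[trait] = SubgroupSummary(
            trait=trait,
            cut=cut,
            young_n=len(ys),
            old_n=len(os_),
            young_mean=float(ys.mean()),
            old_mean=float(os_.mean()),
            bin_edges=edges,
            young_hist=np.histogram(ys, bins=edges)[0],
            old_hist=np.histogram(os_, bins=edges)[0],
        )
    return out


def _design_matrix(
    df: pd.DataFrame,
    age_col: str,
    sex_col: str,
    covariates: Sequence[str],
) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["A"] = df[age_col]
    X["A2"] = df[age_col] ** 2
    X["AxS"] = df[age_col] * df[sex_col]
    X["S"] = df[sex_col]
    for c in covariates:
        X[c] = df[c]
    return sm.add_constant(X, has_constant="add")


def regress_trait(
    cohort: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_col: str = "age",
    sex_col: str = "sex",
    per_participant: bool = True,
) -> pd.DataFrame:
    """OLS fit of ``trait ~ A + A^2 + A*S + S + x1 + ... + x8``.

    Returns one row per model term with its coefficient and two-sided
    p-value.  Complete cases only; a rank-deficient design raises with the
    names of the collinear columns.
    """
    df = one_row_per_participant(cohort) if per_participant else cohort
    cols = [trait, age_col, sex_col, *covariates]
    sub = df[cols].dropna()
    n_terms = 4 + len(covariates)
    if len(sub) < n_terms + 2:
        raise ValueError(
            f"regression for {trait!r} needs >= {n_terms + 2} complete rows, got {len(sub)}"
        )
    X = _design_matrix(sub, age_col, sex_col, covariates)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(sub[trait], X).fit()
    return pd.DataFrame(
        {"trait": trait, "term": fit.params.index, "beta": fit.params.to_numpy(), "p": fit.pvalues.to_numpy()}
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns loading on the null space of a rank-deficient design."""
    _, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    null_rows = vt[s < tol] if (s < tol).any() else vt[-1:]
    load = np.abs(null_rows).max(axis=0)
    return [c for c, w in zip(X.columns, load) if w > 0.1]


def regress_all(
    cohort: pd.DataFrame,
    traits: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **kwargs,
) -> pd.DataFrame:
    """Fit the covariate model for several traits and FDR-adjust per term.

    Mirrors reporting of per-covariate significance across a trait panel:
    for each model term, the family of p-values collected over traits is
    adjusted jointly.
    """
    frames = [regress_trait(cohort, t, covariates, **kwargs) for t in traits]
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = np.nan
    for term in out["term"].unique():
        sel = out["term"] == term
        out.loc[sel, "p_adj"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    return out
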