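"""Buffa hypoxia scoring and nested-model association testing.

The Buffa score reduces a hypoxia gene signature to one integer per sample:
for every signature gene, a sample scores +1 if its abundance is strictly
above the median abundance of that gene across *tumour* samples, else -1
(ties score -1); the hypoxia score is the sum over signature genes. Because
only the sign of the comparison enters, the score is invariant to any
monotone per-gene transformation of the abundances, and it lies in
[-G, +G] with the parity of G for a signature of G genes.

Associations between the hypoxia score and a mutational feature are tested
by comparing nested least-squares models

    full: hypoxia ~ feature + age + sex + purity
    null: hypoxia ~ age + sex + purity

with the exact F test between the two fits. P values across features are
Bonferroni-adjusted when fewer than 20 tests were run, Benjamini-Hochberg
otherwise, and calls are made at adjusted p < 0.1. Model adequacy is
checked with a simulation-based residual-uniformity test: responses are
simulated from the fitted Gaussian model, each observation is placed as a
quantile within its simulated distribution, and the quantiles are tested
against Uniform(0, 1) with Kolmogorov-Smirnov.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .copy_number import cnv_density
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "buffa_score",
    "feature_matrix",
    "FeatureMatrix",
    "associate",
    "AssociationResult",
    "adjust_pvalues",
    "residual_uniformity",
]

ADJUSTED_P_CALL = 0.1
BONFERRONI_MAX_TESTS = 20

VARIANT_COUNT_METRICS = (
    "n_all",
    "n_coding",
    "n_noncoding",
    "n_nonsynonymous",
    "n_snv",
    "n_dnv",
    "n_tnv",
    "n_del",
    "n_ins",
    "n_indel",
)
SV_TYPES = ("deletion", "inversion", "tandem_duplication", "translocation")


def buffa_score(
    expression: pd.DataFrame,
    signature_genes: Sequence[str],
    tumour_ids: Sequence[str],
) -> pd.Series:
    """Buffa hypoxia score for every sample column of ``expression``.

    Parameters
    ----------
    expression
        Genes x samples abundance matrix (any monotone scale, e.g.
        log2(TPM+1)).
    signature_genes
        Hypoxia signature gene set; all must be rows of the matrix.
    tumour_ids
        Sample columns over which the per-gene reference medians are taken.
        Controls are scored against the same tumour medians.
    """
    missing = [g for g in signature_genes if g not in expression.index]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    tumour_ids = list(tumour_ids)
    if len(tumour_ids) < 2:
        raise ValidationError("need >= 2 tumour samples for reference medians")
    absent = [s for s in tumour_ids if s not in expression.columns]
    if absent:
        raise ValidationError(f"tumour ids absent from matrix: {absent}")
    sig = expression.loc[list(signature_genes)]
    medians = sig[tumour_ids].median(axis=1)
    above = sig.gt(medians, axis=0)
    scores = above.sum(axis=0) - (~above).sum(axis=0)
    scores.name = "hypoxia_score"
    return scores.astype(int)


class FeatureMatrix(NamedTuple):
    """Per-sample mutational-density metrics, their decile bins, covariates."""

    metrics: pd.DataFrame
    deciles: pd.DataFrame
    covariates: pd.DataFrame


def _decile_bins(metrics: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in metrics.columns:
        x = metrics[col]
        if x.nunique(dropna=True) <= 1:
            warnings.warn(
                f"metric {col!r} constant across cohort; decile bins degenerate",
                stacklevel=3,
            )
            out[col] = pd.Series(np.nan, index=metrics.index)
            continue
        ranks = x.rank(method="average")
        out[col] = pd.qcut(ranks, 10, labels=False, duplicates="drop")
    return pd.DataFrame(out, index=metrics.index)


def feature_matrix(
    variants: pd.DataFrame | None = None,
    segments: pd.DataFrame | None = None,
    svs: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    genome_size_bp: float | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the 22 mutational-density metrics per sample.

    10 variant-count metrics (all, coding, non-coding, nonsynonymous, SNV,
    DNV, TNV, DEL, INS, INDEL), 8 CNV density metrics, 4 SV counts, plus
    clonal/subclonal counts when the variant table carries a ``clonal``
    column. Tables that are not supplied leave their metric block missing
    (NaN), never zero. Samples with a table present but no rows count as
    zero.
    """
    index = None
    if sample_ids is not None:
        index = pd.Index(sample_ids, name="sample_id")
    else:
        ids: set[str] = set()
        for t in (variants, segments, svs, clinical):
            if t is not None and "sample_id" in t:
                ids |= set(t["sample_id"])
        index = pd.Index(sorted(ids), name="sample_id")

    blocks = []
    if variants is not None:
        v = variants
        by = v.groupby("sample_id")
        counts = pd.DataFrame(index=index)
        counts["n_all"] = by.size()
        counts["n_coding"] = by.apply(
            lambda d: (d["region"] == "coding").sum(), include_groups=False
        )
        counts["n_noncoding"] = by.apply(
            lambda d: (d["region"] == "noncoding").sum(), include_groups=False
        )
        counts["n_nonsynonymous"] = by.apply(
            lambda d: d["nonsynonymous"].astype(bool).sum(), include_groups=False
        )
        for cls, col in (
            ("SNV", "n_snv"),
            ("DNV", "n_dnv"),
            ("TNV", "n_tnv"),
            ("DEL", "n_del"),
            ("INS", "n_ins"),
        ):
            counts[col] = by.apply(
                lambda d, c=cls: (d["variant_class"] == c).sum(),
                include_groups=False,
            )
        counts["n_indel"] = counts["n_del"] + counts["n_ins"]
        if "clonal" in v.columns:
            counts["n_clonal"] = by.apply(
                lambda d: d["clonal"].astype(bool).sum(), include_groups=False
            )
            counts["n_subclonal"] = by.apply(
                lambda d: (~d["clonal"].astype(bool)).sum(), include_groups=False
            )
        blocks.append(counts.fillna(0).astype(float))

    if segments is not None:
        if genome_size_bp is None:
            raise ValidationError("genome_size_bp required with a segment table")
        dens = cnv_density(segments, genome_size_bp).set_index("sample_id")
        blocks.append(dens.reindex(index))

    if svs is not None:
        sv_counts = pd.DataFrame(index=index)
        by = svs.groupby("sample_id")
        for t in SV_TYPES:
            sv_counts[f"sv_{t}"] = by.apply(
                lambda d, t=t: (d["sv_type"] == t).sum(), include_groups=False
            )
        blocks.append(sv_counts.fillna(0).astype(float))

    metrics = (
        pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=index)
    )
    metrics = metrics.reindex(index)

    cov_cols = ["age", "sex", "purity"]
    if clinical is not None:
        cov = clinical.set_index("sample_id").reindex(index)
        covariates = cov[[c for c in cov_cols if c in cov.columns]]
    else:
        covariates = pd.DataFrame(index=index, columns=cov_cols)

    numeric = metrics.select_dtypes(include=[np.number])
    return FeatureMatrix(
        metrics=metrics, deciles=_decile_bins(numeric), covariates=covariates
    )


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    f_stat: float
    p_value: float
    direction: int  # sign of the feature coefficient in the full model
    n_obs: int
    coefficient: float
    adjusted_p: float | None = None
    adjust_method: str | None = None
    residual_uniformity_p: float | None = None


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design block: categorical covariates dummy-coded."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


def associate(
    scores: pd.Series,
    feature: pd.Series,
    covariates: pd.DataFrame,
    min_complete: int = 10,
    residual_check: bool = False,
    n_sim: int = 250,
    seed: int | None = None,
) -> AssociationResult:
    """Nested-model F test of one feature against the hypoxia score.

    The full model regresses the score on the feature plus covariates, the
    null model drops the feature; the p value is from the exact F comparison
    of the two least-squares fits. Complete cases only. The result is
    invariant to affine rescaling of the feature.
    """
    data = pd.concat(
        [scores.rename("hypoxia"), feature.rename("feature"), covariates],
        axis=1,
    ).dropna()
    if len(data) < min_complete:
        raise InsufficientDataError(
            f"only {len(data)} complete cases (< {min_complete})"
        )
    if data["feature"].nunique() <= 1:
        raise ValidationError("feature is constant over complete cases")
    X_null = sm.add_constant(_design(data[covariates.columns]))
    X_full = pd.concat([data[["feature"]].astype(float), X_null], axis=1)
    rank = np.linalg.matrix_rank(X_full.to_numpy(dtype=float))
    if rank < X_full.shape[1]:
        raise ValidationError("design matrix is rank deficient (collinear)")
    y = data["hypoxia"].astype(float)
    fit_full = sm.OLS(y, X_full.astype(float)).fit()
    fit_null = sm.OLS(y, X_null.astype(float)).fit()
    f_stat, p_value, _ = fit_full.compare_f_test(fit_null)
    coef = float(fit_full.params["feature"])
    res_p = None
    if residual_check:
        res_p = residual_uniformity(fit_full, n_sim=n_sim, seed=seed)
    return AssociationResult(
        feature=str(feature.name or "feature"),
        f_stat=float(f_stat),
        p_value=float(p_value),
        direction=int(np.sign(coef)) if coef != 0 else 0,
        n_obs=int(len(data)),
        coefficient=coef,
        residual_uniformity_p=res_p,
    )


def adjust_pvalues(
    pvalues: Sequence[float], n_tests: int | None = None
) -> tuple[np.ndarray, str]:
    """Multiple-testing adjustment with the <20-tests Bonferroni switch.

    Bonferroni when fewer than ``BONFERRONI_MAX_TESTS`` (20) tests were
    conducted, Benjamini-Hochberg otherwise. Returns the adjusted p values
    and the procedure name.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p values must lie in [0, 1]")
    if n_tests is None:
        n_tests = len(p)
    if n_tests < BONFERRONI_MAX_TESTS:
        adjusted = np.minimum(p * n_tests, 1.0)
        method = "bonferroni"
    else:
        adjusted = multipletests(p, method="fdr_bh")[1]
        method = "fdr_bh"
    return adjusted, method


def residual_uniformity(
    fit, n_sim: int = 250, seed: int | None = None
) -> float:
    """Simulation-based residual-uniformity KS p value for an OLS fit.

    ``n_sim`` response vectors are simulated from the fitted Gaussian model
    (mean = fitted values, variance = residual variance); each observed
    response is converted to its quantile within the simulated values at
    that observation, and the quantiles are tested against Uniform(0, 1)
    with a Kolmogorov-Smirnov test. A correctly specified model yields an
    approximately uniform KS p over replications.
    """
    if n_sim < 20:
        raise ValidationError(f"n_sim must be >= 20, got {n_sim}")
    rng = np.random.default_rng(seed)
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    y = fitted + np.asarray(fit.resid, dtype=float)
    sigma = float(np.sqrt(fit.scale))
    sims = rng.normal(loc=fitted, scale=sigma, size=(n_sim, fitted.size))
    below = (sims < y).sum(axis=0)
    quantiles = (below + 0.5) / (n_sim + 1.0)
    return float(sps.kstest(quantiles, "uniform").pvalue)
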