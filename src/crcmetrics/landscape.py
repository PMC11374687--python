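"""Cohort-level mutation-burden classification and co-mutation testing.

Hypermutated (HM) tumours are separated from non-hypermutated (nHM) ones by an
iterative quantile rule on total somatic short-variant counts: a sample is
flagged when its count exceeds the cohort median plus ``iqr_factor`` times the
interquartile range. Every flagged sample is then split into two artificial
samples of half its count, quantiles are recomputed on the updated pool, and
the procedure repeats until no sample is flagged. A tumour is HM if it - or
any artificial descendant - was flagged in any round, and its "outlier times"
is the number of rounds in which that happened.

Quantiles use linear interpolation of order statistics at positions
``(n - 1) * p`` (the numpy/R default), pinned so that worked examples are
exact.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "HMResult",
    "BurdenRecord",
    "ComutationResult",
    "classify_hypermutation",
    "compute_tmb",
    "classify_msi",
    "pairwise_comutation",
]

#: Default multiplier on the interquartile range in the HM rule.
DEFAULT_IQR_FACTOR = 1.5

#: Default MSI score threshold (paired-module instability score).
DEFAULT_MSI_THRESHOLD = 3.5

#: Default callable genome size in megabases (GRCh38 non-gap autosomes + X).
DEFAULT_GENOME_SIZE_MB = 2859.0


@dataclass(frozen=True)
class HMResult:
    """Per-sample outcome of the iterative hypermutation classification."""

    sample_id: str
    is_hm: bool
    outlier_times: int
    rounds_total: int
    threshold_trace: tuple[float, ...] = field(repr=False)


@dataclass(frozen=True)
class BurdenRecord:
    """Total somatic short-variant count and mutations per megabase."""

    sample_id: str
    n_snv: int
    tmb: float


@dataclass(frozen=True)
class ComutationResult:
    """Pairwise Fisher exact-test result for one gene pair."""

    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float
    fdr: float
    direction: str  # "co-occurring" | "exclusive"


def _quantile_threshold(counts: np.ndarray, iqr_factor: float) -> float:
    med = float(np.median(counts))
    q25, q75 = np.percentile(counts, [25.0, 75.0])
    return med + iqr_factor * float(q75 - q25)


def classify_hypermutation(
    counts: Mapping[str, float] | pd.Series,
    iqr_factor: float = DEFAULT_IQR_FACTOR,
) -> dict[str, HMResult]:
    """Classify samples as hypermutated by the iterative median + IQR rule.

    Parameters
    ----------
    counts
        Mapping of sample id to total somatic short-variant count.
    iqr_factor
        Multiplier on the interquartile range (default 1.5).

    Returns
    -------
    dict
        One :class:`HMResult` per input sample. ``rounds_total`` and
        ``threshold_trace`` are cohort-level and identical across samples;
        the trace includes the final, non-flagging round.
    """
    series = pd.Series(dict(counts), dtype=float)
    if len(series) < 3:
        raise InsufficientDataError(
            f"hypermutation classification needs >= 3 samples, got {len(series)}"
        )
    if (series < 0).any():
        bad = series.index[series < 0].tolist()
        raise ValidationError(f"negative mutation counts for samples: {bad}")

    # Pool of (owning sample, count); artificial half-samples keep the owner.
    pool: list[tuple[str, float]] = [(s, c) for s, c in series.items()]
    flagged_rounds: dict[str, set[int]] = {s: set() for s in series.index}
    thresholds: list[float] = []
    round_idx = 0
    while True:
        round_idx += 1
        arr = np.array([c for _, c in pool], dtype=float)
        thr = _quantile_threshold(arr, iqr_factor)
        thresholds.append(thr)
        flagged = [i for i, (_, c) in enumerate(pool) if c > thr]
        if not flagged:
            break
        flagged_set = set(flagged)
        for i in flagged:
            flagged_rounds[pool[i][0]].add(round_idx)
        # A count below 2 cannot be reduced by splitting; if only such
        # counts are flagged (possible only in degenerate zero-IQR pools)
        # the procedure has converged. This keeps the termination bound
        # rounds <= ceil(log2(max count)) + 1.
        if all(pool[i][1] < 2 for i in flagged):
            break
        new_pool: list[tuple[str, float]] = []
        for i, (owner, c) in enumerate(pool):
            if i in flagged_set:
                # Split conserving the total; floor/ceil halves for odd
                # integer counts, exact halves otherwise.
                if float(c).is_integer():
                    lo = float(int(c) // 2)
                    hi = float(c) - lo
                else:
                    lo = hi = c / 2.0
                new_pool.append((owner, lo))
                new_pool.append((owner, hi))
            else:
                new_pool.append((owner, c))
        pool = new_pool

    trace = tuple(thresholds)
    return {
        s: HMResult(
            sample_id=s,
            is_hm=bool(flagged_rounds[s]),
            outlier_times=len(flagged_rounds[s]),
            rounds_total=round_idx,
            threshold_trace=trace,
        )
        for s in series.index
    }


def compute_tmb(
    counts: Mapping[str, float] | pd.Series,
    genome_size_mb: float = DEFAULT_GENOME_SIZE_MB,
    hm: Mapping[str, bool] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Tumour mutation burden per sample plus the HM TMB cut-off.

    The cut-off is the minimum TMB among hypermutated samples (the boundary
    that separates the HM group in burden space), reported only when at
    least one sample is HM.

    Parameters
    ----------
    counts
        Sample id -> total somatic short-variant count.
    genome_size_mb
        Callable genome size in megabases; must be positive.
    hm
        Optional precomputed sample -> is_hm mapping. When omitted it is
        derived with :func:`classify_hypermutation` (cohorts below three
        samples then report no cut-off).
    """
    if genome_size_mb <= 0:
        raise ValidationError(f"genome_size_mb must be > 0, got {genome_size_mb}")
    series = pd.Series(dict(counts), dtype=float)
    if (series < 0).any():
        raise ValidationError("negative mutation counts")
    if hm is None:
        if len(series) >= 3:
            hm = {s: r.is_hm for s, r in classify_hypermutation(series).items()}
        else:
            hm = {s: False for s in series.index}
    table = pd.DataFrame(
        {
            "sample_id": series.index,
            "n_snv": series.to_numpy(),
            "tmb": series.to_numpy() / genome_size_mb,
            "is_hm": [bool(hm.get(s, False)) for s in series.index],
        }
    ).reset_index(drop=True)
    hm_tmb = table.loc[table["is_hm"], "tmb"]
    cutoff = float(hm_tmb.min()) if len(hm_tmb) else None
    return table, cutoff


def classify_msi(
    msi_score: float, threshold: float = DEFAULT_MSI_THRESHOLD
) -> str:
    """Classify a paired-module microsatellite-instability score.

    MSI if ``msi_score >= threshold`` (boundary inclusive), MSS otherwise.
    """
    if np.isnan(msi_score):
        raise ValidationError("MSI score is NaN")
    if msi_score < 0:
        raise ValidationError(f"MSI score must be >= 0, got {msi_score}")
    return "MSI" if msi_score >= threshold else "MSS"


def pairwise_comutation(
    mutation_matrix: pd.DataFrame,
    fdr_threshold: float = 0.1,
) -> list[ComutationResult]:
    """Pairwise Fisher exact tests for co-occurrence / mutual exclusivity.

    Parameters
    ----------
    mutation_matrix
        Genes x samples boolean (or 0/1) matrix of mutation status.
    fdr_threshold
        Benjamini-Hochberg FDR level used downstream (recorded only; all
        pairs are returned with their adjusted p).

    Returns
    -------
    list of :class:`ComutationResult`
        One entry per testable gene pair, ordered by (gene_a, gene_b).
        Genes mutated in no or all samples carry no information and their
        pairs are skipped with a warning.
    """
    mat = mutation_matrix.astype(bool)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValidationError("need >= 2 genes and >= 2 samples")
    variable = [g for g in mat.index if 0 < mat.loc[g].sum() < mat.shape[1]]
    skipped = [g for g in mat.index if g not in variable]
    if skipped:
        warnings.warn(
            f"genes with zero variance skipped from co-mutation testing: {skipped}",
            stacklevel=2,
        )
    rows: list[dict] = []
    for ga, gb in itertools.combinations(variable, 2):
        a = mat.loc[ga].to_numpy()
        b = mat.loc[gb].to_numpy()
        both = int(np.sum(a & b))
        a_only = int(np.sum(a & ~b))
        b_only = int(np.sum(~a & b))
        neither = int(np.sum(~a & ~b))
        odds, p = sps.fisher_exact(
            [[both, a_only], [b_only, neither]], alternative="two-sided"
        )
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "both": both,
                "a_only": a_only,
                "b_only": b_only,
                "neither": neither,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    if not rows:
        return []
    pvals = np.array([r["p_value"] for r in rows])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for r, q in zip(rows, fdr):
        results.append(
            ComutationResult(
                direction="co-occurring" if r["odds_ratio"] > 1 else "exclusive",
                fdr=float(q),
                **r,
            )
        )
    return results


def comutation_table(results: Sequence[ComutationResult]) -> pd.DataFrame:
    """Flatten co-mutation results into a DataFrame."""
    return pd.DataFrame([vars(r) for r in results])
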