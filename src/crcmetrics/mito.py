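"""Mitochondrial somatic-variant filtering and copy-number estimation.

Whole-genome tumour/control pairs call many mtDNA variant candidates that are
really nuclear-embedded mitochondrial segments (NuMTs): such artifacts show
low heteroplasmy, support in the matched control reads, and recur across
unrelated tumours. The filter combines

1. a control-VAF rule (control VAF must be below a small cutoff),
2. a control/tumour rate-ratio rule
   ``r = (Nc/RDc) / (Nc/RDc + Nt/RDt)`` with r below a cutoff,
3. a cohort-recurrence rule applied only to low-heteroplasmy candidates
   (tumour VAF < 0.10), removing variants carried by too large a fraction
   of tumours,
4. a heteroplasmy window (tumour VAF strictly inside it),

plus a rescue step guarding against false negatives: a variant whose cohort
VAF maximum is < 0.1 and median < 0.05 is re-adjudicated per carrier, being
retained only where the tumour VAF exceeds 0.05 (the recurrence rule is
waived for it; the control-based rules and the window still apply).

Cutoffs can be re-derived from the data as median + 2 x IQR of the relevant
statistic over all candidates, the same quantile convention as the burden
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "MitoFilterReport",
    "ratio_statistic",
    "derive_cutoff",
    "filter_candidates",
    "heteroplasmy_class",
    "mtdna_copy_number",
]

DEFAULT_CTRL_VAF_CUTOFF = 0.0034
DEFAULT_RATIO_CUTOFF = 0.0629
DEFAULT_RECURRENCE_CUTOFF = 0.023
DEFAULT_HET_WINDOW = (0.01, 0.95)
NEAR_HOMOPLASMIC_VAF = 0.60

#: Tumour-VAF band below which the cohort-recurrence rule applies.
LOW_HETEROPLASMY_VAF = 0.10

#: Rescue-rule qualification and carrier-retention thresholds.
RESCUE_VAF_MAX = 0.10
RESCUE_VAF_MEDIAN = 0.05
RESCUE_CARRIER_VAF = 0.05


def ratio_statistic(
    n_mut_ctrl: float, rd_ctrl: float, n_mut_tum: float, rd_tum: float
) -> float:
    """Control-vs-tumour mutant-rate ratio in [0, 1].

    ``r = (Nc/RDc) / (Nc/RDc + Nt/RDt)``. Monotone increasing in the
    control mutant count, decreasing in the tumour one. When both mutant
    counts are zero the statistic is undefined and NaN is returned (such a
    candidate trivially passes the ratio rule).
    """
    if rd_ctrl <= 0 or rd_tum <= 0:
        raise ValidationError("read depths must be positive")
    if n_mut_ctrl < 0 or n_mut_tum < 0:
        raise ValidationError("mutant allele counts must be nonnegative")
    rc = n_mut_ctrl / rd_ctrl
    rt = n_mut_tum / rd_tum
    if rc + rt == 0:
        return float("nan")
    return float(rc / (rc + rt))


def derive_cutoff(values, iqr_factor: float = 2.0) -> float:
    """Data-driven cutoff: median + ``iqr_factor`` x IQR of the statistic.

    Quantiles by linear interpolation at positions (n-1)p, matching the
    burden classifier's convention.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise InsufficientDataError(
            f"cutoff derivation needs >= 4 values, got {arr.size}"
        )
    q25, q75 = np.percentile(arr, [25.0, 75.0])
    return float(np.median(arr) + iqr_factor * (q75 - q25))


@dataclass
class MitoFilterReport:
    """Per-candidate filter outcome plus the cutoffs that produced it.

    ``table`` has one row per input candidate with boolean columns
    ``fail_control_vaf``, ``fail_ratio``, ``fail_recurrence``,
    ``fail_het_window``, ``rescued``, the variant-level cohort
    ``recurrence`` frequency, and the final ``retained`` flag.
    """

    table: pd.DataFrame
    cutoffs: dict


def filter_candidates(
    cohort: pd.DataFrame,
    ctrl_vaf_cutoff: float = DEFAULT_CTRL_VAF_CUTOFF,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    recurrence_cutoff: float = DEFAULT_RECURRENCE_CUTOFF,
    het_window: tuple[float, float] = DEFAULT_HET_WINDOW,
    n_tumours: int | None = None,
) -> MitoFilterReport:
    """Apply the NuMT/artifact filter to a cohort candidate table.

    Parameters
    ----------
    cohort
        Columns sample_id, pos, ref, alt, n_mut_tum, rd_tum, n_mut_ctrl,
        rd_ctrl, vaf_tum, vaf_ctrl. One row per candidate per tumour.
    n_tumours
        Denominator of the cohort recurrence frequency; defaults to the
        number of distinct sample ids in the table.

    Notes
    -----
    The filter is a pure function of the table and the cutoffs; permuting
    rows permutes the report.
    """
    for name, c in (
        ("ctrl_vaf_cutoff", ctrl_vaf_cutoff),
        ("ratio_cutoff", ratio_cutoff),
        ("recurrence_cutoff", recurrence_cutoff),
        ("het_window low", het_window[0]),
        ("het_window high", het_window[1]),
    ):
        if not 0 <= c <= 1:
            raise ValidationError(f"{name} must lie in [0, 1], got {c}")

    tab = cohort.copy().reset_index(drop=True)
    if n_tumours is None:
        n_tumours = tab["sample_id"].nunique()
    if n_tumours <= 0:
        raise ValidationError("cohort size for recurrence denominator is 0")

    r = np.array(
        [
            ratio_statistic(nc, dc, nt, dt)
            for nc, dc, nt, dt in zip(
                tab["n_mut_ctrl"], tab["rd_ctrl"], tab["n_mut_tum"], tab["rd_tum"]
            )
        ]
    )
    tab["ratio_stat"] = r

    key = list(zip(tab["pos"], tab["ref"], tab["alt"]))
    tab["_variant"] = key
    grp = tab.groupby("_variant")["vaf_tum"]
    carriers = grp.transform("size").astype(float)
    tab["recurrence"] = carriers / float(n_tumours)
    vaf_max = grp.transform("max")
    vaf_median = grp.transform("median")

    tab["fail_control_vaf"] = ~(tab["vaf_ctrl"] < ctrl_vaf_cutoff)
    # NaN ratio (no mutant reads on either side) trivially passes.
    tab["fail_ratio"] = ~(np.isnan(r) | (r < ratio_cutoff))
    low_het = tab["vaf_tum"] < LOW_HETEROPLASMY_VAF
    tab["fail_recurrence"] = low_het & ~(tab["recurrence"] < recurrence_cutoff)
    lo, hi = het_window
    tab["fail_het_window"] = ~((tab["vaf_tum"] > lo) & (tab["vaf_tum"] < hi))

    rescue_variant = (vaf_max < RESCUE_VAF_MAX) & (vaf_median < RESCUE_VAF_MEDIAN)
    tab["rescued"] = rescue_variant & (tab["vaf_tum"] > RESCUE_CARRIER_VAF)

    base_pass = ~(
        tab["fail_control_vaf"] | tab["fail_ratio"] | tab["fail_het_window"]
    )
    # Rescue-class variants: recurrence rule waived, carrier VAF rule instead.
    retained = np.where(
        rescue_variant,
        base_pass & (tab["vaf_tum"] > RESCUE_CARRIER_VAF),
        base_pass & ~tab["fail_recurrence"],
    )
    tab["retained"] = retained.astype(bool)
    tab = tab.drop(columns="_variant")
    return MitoFilterReport(
        table=tab,
        cutoffs={
            "ctrl_vaf_cutoff": ctrl_vaf_cutoff,
            "ratio_cutoff": ratio_cutoff,
            "recurrence_cutoff": recurrence_cutoff,
            "het_window": het_window,
            "n_tumours": int(n_tumours),
        },
    )


def heteroplasmy_class(vaf: float) -> str:
    """Band a tumour VAF: near-homoplasmic when strictly above 60%."""
    if not 0 <= vaf <= 1:
        raise ValidationError(f"VAF must lie in [0, 1], got {vaf}")
    return "near_homoplasmic" if vaf > NEAR_HOMOPLASMIC_VAF else "heteroplasmic"


def mtdna_copy_number(
    mt_mean_depth: float,
    autosomal_mean_depth: float,
    purity: float | None = None,
    control_raw_cn: float | None = None,
) -> tuple[float, float]:
    """Raw and purity-normalised mitochondrial genome copy number.

    raw = 2 x mtDNA depth / autosomal depth (copies per diploid nuclear
    genome). With tumour purity and the matched control's raw copy number
    available, the tumour-cell copy number is recovered as
    ``(raw - (1 - purity) x control) / purity``; otherwise the raw value is
    reported for both.
    """
    if autosomal_mean_depth <= 0 or mt_mean_depth <= 0:
        raise ValidationError("depths must be positive")
    raw = 2.0 * mt_mean_depth / autosomal_mean_depth
    if purity is None or control_raw_cn is None:
        return raw, raw
    if not 0 < purity <= 1:
        raise ValidationError(f"purity must lie in (0, 1], got {purity}")
    normalized = (raw - (1.0 - purity) * control_raw_cn) / purity
    return raw, float(normalized)
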