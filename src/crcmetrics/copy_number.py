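"""Allele-specific copy-number state calling and CNV density metrics.

Segments carry a total copy number (tcn), a minor copy number (lcn, possibly
missing at low coverage) and a tumour/control log2 ratio. States follow the
eight-class taxonomy: wild type (2,1), homozygous deletion (0,0), LOH (1,0),
copy-neutral LOH (2,0), gain-LOH (tcn 3-4, lcn 0), gain (tcn 3-4, lcn>=1),
amp-LOH (tcn>=5, lcn 0) and amp (tcn>=5, lcn>=1). When lcn is missing a
coarse label is derived from tcn alone and flagged as LOH-indeterminate
rather than dropping the segment, which would bias genome-altered fractions.

Density metrics per sample: fraction of the genome with total copy-number
aberration (PGA total / gain / loss, aberration meaning tcn != 2 relative to
the diploid baseline), their gain:loss ratio, and average aberrant segment
lengths. Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CNState",
    "CnvDensity",
    "classify_state",
    "classify_state_table",
    "classify_focal",
    "annotate_genes",
    "cnv_density",
]

DEFAULT_AMP_THRESHOLD = 0.9
DEFAULT_DEL_THRESHOLD = -0.3

STATE_LABELS = (
    "wild_type",
    "homozygous_deletion",
    "loh",
    "copy_neutral_loh",
    "gain_loh",
    "gain",
    "amp_loh",
    "amp",
    "indeterminate",
)


class CNState(NamedTuple):
    label: str
    loh_indeterminate: bool = False


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_state(tcn: int, lcn: int | float | None) -> CNState:
    """Assign the allele-specific copy-number state of one segment.

    With lcn missing, a coarse tcn-only label is returned with
    ``loh_indeterminate=True`` (except tcn=0, which forces lcn=0); tcn=2
    without lcn is ``indeterminate`` since wild type and copy-neutral LOH
    cannot be told apart.
    """
    if _is_missing(tcn) or tcn < 0 or float(tcn) != int(tcn):
        raise ValidationError(f"tcn must be a nonnegative integer, got {tcn!r}")
    tcn = int(tcn)
    if _is_missing(lcn):
        if tcn == 0:
            return CNState("homozygous_deletion", False)
        coarse = {1: "loh", 2: "indeterminate"}.get(
            tcn, "gain" if tcn <= 4 else "amp"
        )
        return CNState(coarse, True)
    if lcn < 0 or float(lcn) != int(lcn):
        raise ValidationError(f"lcn must be a nonnegative integer, got {lcn!r}")
    lcn = int(lcn)
    if lcn > tcn:
        raise ValidationError(f"lcn ({lcn}) exceeds tcn ({tcn})")
    if lcn > tcn - lcn:
        raise ValidationError(
            f"minor copy number {lcn} exceeds major ({tcn - lcn}); not allele-sorted"
        )
    if tcn == 0:
        return CNState("homozygous_deletion")
    if tcn == 1:
        return CNState("loh")
    if tcn == 2:
        return CNState("copy_neutral_loh" if lcn == 0 else "wild_type")
    if tcn <= 4:
        return CNState("gain_loh" if lcn == 0 else "gain")
    return CNState("amp_loh" if lcn == 0 else "amp")


def classify_state_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify_state` over a segment table.

    Returns a copy with ``state`` and ``loh_indeterminate`` columns.
    """
    out = segments.copy()
    states = [
        classify_state(t, l) for t, l in zip(out["tcn"], out["lcn"])
    ]
    out["state"] = [s.label for s in states]
    out["loh_indeterminate"] = [s.loh_indeterminate for s in states]
    return out


def classify_focal(
    log2_ratio: float,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
) -> str:
    """Focal classification of a log2 ratio; strict inequalities.

    amplification if ratio > amp_threshold, deletion if ratio < del_threshold,
    neutral otherwise (both boundaries inclusive of neutral).
    """
    if log2_ratio is None or not np.isfinite(log2_ratio):
        raise ValidationError(f"log2 ratio must be finite, got {log2_ratio!r}")
    if log2_ratio > amp_threshold:
        return "amplification"
    if log2_ratio < del_threshold:
        return "deletion"
    return "neutral"


def annotate_genes(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene, per sample, the state of its overlapping segment.

    Multi-segment overlaps resolve to the segment with the largest overlap
    (ties broken by leftmost segment start). Genes with no overlapping
    segment get state ``missing``.

    Parameters
    ----------
    segments
        Columns sample_id, chrom, start, end, tcn, lcn (1-based inclusive).
    genes
        Columns gene, chrom, start, end (1-based inclusive; BED input
        should be converted on read).

    Returns
    -------
    DataFrame with columns sample_id, gene, state, loh_indeterminate,
    overlap_bp.
    """
    seg = classify_state_table(segments)
    rows = []
    for sample_id, sub in seg.groupby("sample_id", sort=True):
        for g in genes.itertuples(index=False):
            on_chrom = sub[sub["chrom"] == g.chrom]
            if len(on_chrom):
                ov = (
                    np.minimum(on_chrom["end"].to_numpy(), g.end)
                    - np.maximum(on_chrom["start"].to_numpy(), g.start)
                    + 1
                )
                ok = ov > 0
            else:
                ok = np.zeros(0, dtype=bool)
            if not ok.any():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": g.gene,
                        "state": "missing",
                        "loh_indeterminate": False,
                        "overlap_bp": 0,
                    }
                )
                continue
            cand = on_chrom.loc[ok].assign(_ov=ov[ok])
            cand = cand.sort_values(["_ov", "start"], ascending=[False, True])
            best = cand.iloc[0]
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": g.gene,
                    "state": best["state"],
                    "loh_indeterminate": bool(best["loh_indeterminate"]),
                    "overlap_bp": int(best["_ov"]),
                }
            )
    return pd.DataFrame(rows)


def _check_non_overlapping(sub: pd.DataFrame, sample_id: str) -> None:
    for chrom, c in sub.groupby("chrom"):
        c = c.sort_values("start")
        ends = c["end"].to_numpy()
        starts = c["start"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise ValidationError(
                f"overlapping segments for sample {sample_id} on {chrom}"
            )


class CnvDensity(NamedTuple):
    """Per-sample copy-number aberration density metrics."""

    sample_id: str
    pga_total: float
    pga_gain: float
    pga_loss: float
    pga_gain_loss_ratio: float  # NaN when pga_loss == 0
    avg_len: float  # NaN when no aberrant segment
    avg_len_gain: float
    avg_len_loss: float
    avg_len_gain_loss_ratio: float


def cnv_density(
    segments: pd.DataFrame, genome_size_bp: float, baseline_tcn: int = 2
) -> pd.DataFrame:
    """Compute the eight CNV density metrics per sample.

    Gain means tcn above the baseline (diploid 2 by default), loss below.
    Ratios are NaN when their denominator is zero; average lengths are NaN
    when no qualifying segment exists. Segments must be non-overlapping
    within a sample.
    """
    if genome_size_bp <= 0:
        raise ValidationError("genome_size_bp must be > 0")
    rows = []
    for sample_id, sub in segments.groupby("sample_id", sort=True):
        _check_non_overlapping(sub, sample_id)
        lengths = (sub["end"] - sub["start"] + 1).to_numpy(dtype=float)
        tcn = sub["tcn"].to_numpy(dtype=float)
        gain = tcn > baseline_tcn
        loss = tcn < baseline_tcn
        aberrant = gain | loss
        pga_gain = float(lengths[gain].sum() / genome_size_bp)
        pga_loss = float(lengths[loss].sum() / genome_size_bp)
        pga_total = float(lengths[aberrant].sum() / genome_size_bp)

        def _avg(mask):
            return float(lengths[mask].mean()) if mask.any() else float("nan")

        avg_gain = _avg(gain)
        avg_loss = _avg(loss)
        rows.append(
            CnvDensity(
                sample_id=sample_id,
                pga_total=pga_total,
                pga_gain=pga_gain,
                pga_loss=pga_loss,
                pga_gain_loss_ratio=(
                    pga_gain / pga_loss if pga_loss > 0 else float("nan")
                ),
                avg_len=_avg(aberrant),
                avg_len_gain=avg_gain,
                avg_len_loss=avg_loss,
                avg_len_gain_loss_ratio=(
                    avg_gain / avg_loss
                    if np.isfinite(avg_gain) and np.isfinite(avg_loss)
                    else float("nan")
                ),
            )._asdict()
        )
    return pd.DataFrame(rows)
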