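"""Mutational-signature profile comparison and activity correlation.

A signature profile is a probability vector over a fixed mutation-channel set
(96 SBS / 78 DBS / 83 ID trinucleotide-style channels). Profiles from
different catalogues are compared by cosine similarity after re-indexing by
channel label (never by position). A de novo signature is called novel when
its best cosine similarity to *both* reference catalogues falls strictly
below a threshold (default 0.85).

Signature activities (per-sample mutation counts attributed to each
signature) are correlated pairwise with Spearman's rank correlation; the p
value comes from exact permutation enumeration for small cohorts (n < 10)
and from the usual t approximation otherwise, with Benjamini-Hochberg
adjustment across pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "cosine_similarity",
    "novelty_flag",
    "NoveltyResult",
    "activity_correlation",
]

DEFAULT_NOVELTY_THRESHOLD = 0.85

#: Below this cohort size, Spearman p values are computed by exact
#: enumeration of rank permutations.
EXACT_SPEARMAN_N = 10


def _align(u: pd.Series, v: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if set(u.index) != set(v.index):
        raise ValidationError("profiles are defined on different channel sets")
    v = v.reindex(u.index)
    return u.to_numpy(dtype=float), v.to_numpy(dtype=float)


def cosine_similarity(u: pd.Series, v: pd.Series) -> float:
    """Cosine similarity of two channel-indexed nonnegative profiles."""
    a, b = _align(u, v)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("profiles must be nonnegative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero profile")
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


@dataclass(frozen=True)
class NoveltyResult:
    novel: bool
    best_match: str | None
    best_similarity: float
    best_per_catalogue: dict


def novelty_flag(
    profile: pd.Series,
    catalogue_a: pd.DataFrame,
    catalogue_b: pd.DataFrame,
    threshold: float = DEFAULT_NOVELTY_THRESHOLD,
) -> NoveltyResult:
    """Novelty call against two reference catalogues (channels x signatures).

    Novel iff the maximum similarity within *each* catalogue is strictly
    below ``threshold``; otherwise the overall best-matching signature name
    and its similarity are reported.
    """
    best: dict[str, tuple[str, float]] = {}
    for name, cat in (("a", catalogue_a), ("b", catalogue_b)):
        if cat.shape[1] == 0:
            raise ValidationError(f"catalogue {name} is empty")
        sims = {
            sig: cosine_similarity(profile, cat[sig]) for sig in cat.columns
        }
        top = max(sims, key=sims.get)
        best[name] = (top, sims[top])
    novel = all(sim < threshold for _, sim in best.values())
    overall = max(best.values(), key=lambda t: t[1])
    return NoveltyResult(
        novel=novel,
        best_match=None if novel else overall[0],
        best_similarity=overall[1],
        best_per_catalogue={k: {"name": n, "similarity": s} for k, (n, s) in best.items()},
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (ties by average rank)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    sy = ry_c.std()
    if sy == 0:
        return float("nan")
    ry_c /= sy
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(rx, ry_c[list(perm)])) / n
        total += 1
        if abs(rho) >= target:
            count += 1
    return count / total


def activity_correlation(activities: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of signature activities.

    Parameters
    ----------
    activities
        Samples x signatures matrix of nonnegative attributed mutation
        counts.

    Returns
    -------
    DataFrame with columns sig_a, sig_b, rho, p_value, fdr, significant
    (FDR < 0.05). Constant-activity signatures are skipped with a warning.
    """
    if activities.shape[0] < 5:
        raise ValidationError("need >= 5 samples for activity correlation")
    if (activities.to_numpy() < 0).any():
        raise ValidationError("activities must be nonnegative")
    cols = [
        c for c in activities.columns if activities[c].nunique() > 1
    ]
    dropped = [c for c in activities.columns if c not in cols]
    if dropped:
        warnings.warn(
            f"constant-activity signatures skipped: {dropped}", stacklevel=2
        )
    n = activities.shape[0]
    rows = []
    for a, b in itertools.combinations(cols, 2):
        x = activities[a].to_numpy(dtype=float)
        y = activities[b].to_numpy(dtype=float)
        rho, p_t = sps.spearmanr(x, y)
        if n < EXACT_SPEARMAN_N:
            p = _exact_spearman_p(x, y, rho)
        else:
            p = float(p_t)
        rows.append({"sig_a": a, "sig_b": b, "rho": float(rho), "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["sig_a", "sig_b", "rho", "p_value", "fdr", "significant"]
        )
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < 0.05
    return out
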