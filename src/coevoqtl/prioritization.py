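"""Benjamini-Hochberg FDR thresholding and coevolution-prioritized eQTL
detection.

The step-up rule, as used here: sort the n nominal p-values ascending and
find the largest K (1-based) with P_(K) < K * alpha / n; reject the K
smallest hypotheses and call P = K * alpha / n the significance threshold.
(The strict "<" is the default; ``strict=False`` gives the conventional
"<=" variant, which differs only on exact ties.)

Prioritizing by a coevolution-score threshold keeps a fraction gamma of all
hypotheses; if that subset holds a fraction beta of the significant
interactions, the prioritized threshold satisfies P' = beta*K*alpha /
(gamma*n), so P'/P = beta/gamma: the ratio of thresholds *is* the
enrichment of the retained set for significant interactions, and the
threshold relaxes exactly when beta > gamma. Random downsampling has
beta ~= gamma and leaves the threshold essentially unchanged; matching the
mean pair distance instead of the score isolates how much of the
relaxation is mere proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BhResult",
    "EnrichmentReport",
    "bh_threshold",
    "prioritize_by_score",
    "threshold_curve",
    "enrichment_ratio",
    "enrichment_report",
    "random_downsample",
    "distance_matched_subset",
]


@dataclass
class BhResult:
    """Outcome of one Benjamini-Hochberg step-up pass."""

    alpha: float
    n_tests: int
    k: int  # number of rejections
    threshold: float  # K * alpha / n (0 when K = 0)
    rejected: np.ndarray  # boolean mask over the input order


def _pvalues(catalog) -> np.ndarray:
    if isinstance(catalog, pd.DataFrame):
        p = catalog["nominal_p"].to_numpy(dtype=float)
    else:
        p = np.asarray(catalog, dtype=float)
    if p.size == 0:
        raise ValueError("empty hypothesis catalog")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_threshold(catalog, alpha: float = 0.05, strict: bool = True) -> BhResult:
    """Benjamini-Hochberg step-up at FDR level ``alpha``.

    ``catalog`` is a DataFrame with a ``nominal_p`` column or a plain
    p-value array. K = 0 yields threshold 0 and nothing rejected.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = _pvalues(catalog)
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # compare n * P_(k) against k * alpha (scale-equivalent to
    # P_(k) < k * alpha / n). Decimal inputs like p = 0.03 vs 3*0.05/5 are
    # ties in intent but not in binary floats, so values within 1e-12
    # relative count as tied: a tie fails the strict rule and passes the
    # lenient one.
    lhs = sorted_p * n
    rhs = np.arange(1, n + 1) * alpha
    tie = np.isclose(lhs, rhs, rtol=1e-12, atol=0.0)
    ok = (lhs < rhs) & ~tie if strict else (lhs <= rhs) | tie
    k = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
    threshold = k * alpha / n
    rejected = np.zeros(n, dtype=bool)
    rejected[order[:k]] = True
    return BhResult(alpha=alpha, n_tests=n, k=k, threshold=threshold, rejected=rejected)


def prioritize_by_score(
    catalog: pd.DataFrame, score_threshold: float
) -> tuple[pd.DataFrame, float]:
    """Retain tests whose coevolution score is defined and >= threshold.

    Returns (sub-catalog, gamma) where gamma is the retained fraction of
    the full catalog. Undefined (NaN) scores are never retained.
    """
    if "score" not in catalog.columns:
        raise ValueError("catalog has no score column")
    s = catalog["score"].to_numpy(dtype=float)
    if np.all(np.isnan(s)):
        raise ValueError("all coevolution scores are undefined")
    keep = ~np.isnan(s) & (s >= score_threshold)
    return catalog.loc[keep], float(keep.sum() / len(catalog))


def threshold_curve(
    catalog: pd.DataFrame,
    score_thresholds,
    alpha: float = 0.05,
    strict: bool = True,
) -> pd.DataFrame:
    """BH threshold of the retained subset per coevolution-score cutoff.

    Rows with an empty retained subset are marked empty rather than raising.
    """
    thresholds = list(score_thresholds)
    if not thresholds:
        raise ValueError("at least one score threshold required")
    rows = []
    for t in thresholds:
        sub, gamma = prioritize_by_score(catalog, t)
        if len(sub) == 0:
            rows.append((t, 0, gamma, np.nan, np.nan, True))
            continue
        res = bh_threshold(sub, alpha=alpha, strict=strict)
        rows.append((t, len(sub), gamma, res.k, res.threshold, False))
    return pd.DataFrame(
        rows,
        columns=["score_threshold", "n_retained", "gamma", "k", "p_threshold", "empty"],
    )


@dataclass
class EnrichmentReport:
    """P, P', beta, gamma and the threshold-relaxation identity."""

    p_full: float
    p_prioritized: float
    ratio: float  # P'/P
    beta: float | None = None
    gamma: float | None = None
    identity_residual: float | None = None  # |P'/P - beta/gamma|


def enrichment_ratio(
    full: BhResult,
    prioritized: BhResult,
    beta: float | None = None,
    gamma: float | None = None,
) -> EnrichmentReport:
    """Relaxation ratio P'/P of a prioritized BH run over the full run."""
    if full.k == 0:
        raise ValueError("full catalog rejected nothing; ratio undefined")
    ratio = prioritized.threshold / full.threshold
    residual = None
    if beta is not None and gamma is not None and gamma > 0:
        residual = abs(ratio - beta / gamma)
    return EnrichmentReport(
        p_full=full.threshold,
        p_prioritized=prioritized.threshold,
        ratio=ratio,
        beta=beta,
        gamma=gamma,
        identity_residual=residual,
    )


def enrichment_report(
    catalog: pd.DataFrame,
    score_threshold: float,
    alpha: float = 0.05,
    strict: bool = True,
) -> EnrichmentReport:
    """Run full and score-prioritized BH on one catalog and report the
    enrichment: beta is the fraction of the full run's significant
    interactions that pass the score threshold, gamma the fraction of all
    hypotheses that do."""
    full = bh_threshold(catalog, alpha=alpha, strict=strict)
    sub, gamma = prioritize_by_score(catalog, score_threshold)
    if len(sub) == 0:
        raise ValueError("prioritized subset is empty")
    prioritized = bh_threshold(sub, alpha=alpha, strict=strict)
    if full.k == 0:
        raise ValueError("full catalog rejected nothing; ratio undefined")
    s = catalog["score"].to_numpy(dtype=float)
    passing = ~np.isnan(s) & (s >= score_threshold)
    beta = float(passing[full.rejected].mean())
    return enrichment_ratio(full, prioritized, beta=beta, gamma=gamma)


def random_downsample(
    catalog: pd.DataFrame, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Uniform seeded subsample (without replacement) of the catalog."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return catalog
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * len(catalog)))
    idx = rng.choice(len(catalog), size=n_keep, replace=False)
    return catalog.iloc[np.sort(idx)]


def distance_matched_subset(
    catalog: pd.DataFrame, target_mean_distance: float
) -> pd.DataFrame:
    """Deterministic distance-based prioritization: keep the smallest-
    distance tests up to the largest prefix whose mean distance stays at or
    below the target. Used to match the mean distance of a score-prioritized
    subset so the proximity effect can be separated from coevolution."""
    d = catalog["distance"].to_numpy(dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("distance-matching requires defined (cis) distances")
    order = np.argsort(d, kind="stable")
    if target_mean_distance < d[order[0]]:
        raise ValueError(
            f"target mean distance {target_mean_distance} is below the "
            f"minimum pair distance {d[order[0]]}"
        )
    cummean = np.cumsum(d[order]) / np.arange(1, d.size + 1)
    m = int(np.max(np.nonzero(cummean <= target_mean_distance)[0]) + 1)
    return catalog.iloc[np.sort(order[:m])]
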