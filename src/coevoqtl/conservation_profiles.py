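"""Conservation profiling around loci: extraction, logarithmic binning,
K-means classification into high/low conservation, and the co-conservation
contingency analysis.

A profile is the 2001 per-base scores centered on a length-1 locus (1000
bases either side). The logarithmic binning reduces it to 19 values: the
locus in a bin of its own, then bins doubling in size moving outward
(2, 4, ..., 256) with a terminal 490-base bin absorbing the remainder on
each side. Binning this way weights the bases nearest the locus most
heavily in the reduced profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .io_formats import ConservationTrack, GenomicInterval

__all__ = [
    "BIN_SIZES",
    "ConservationProfile",
    "BinnedProfile",
    "ClusterModel",
    "ContingencyTable2x2",
    "ChiSquareResult",
    "extract_profile",
    "bin_profile",
    "average_pileup",
    "kmeans_cluster",
    "label_centroids",
    "contingency_table",
    "chi_squared_yates",
    "ks_compare",
]

# center bin of 1, doubling outward, 490-base terminal bins: sums to 2001
BIN_SIZES = (490, 256, 128, 64, 32, 16, 8, 4, 2, 1, 2, 4, 8, 16, 32, 64, 128, 256, 490)
assert sum(BIN_SIZES) == 2001
_BIN_EDGES = np.concatenate([[0], np.cumsum(BIN_SIZES)])

HIGH, LOW = "high_conservation", "low_conservation"


@dataclass
class ConservationProfile:
    """Per-base scores at positions -flank..+flank around a length-1 locus,
    ordered 5'->3' in the locus's transcriptional orientation."""

    locus: GenomicInterval
    scores: np.ndarray  # NaN where missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size % 2 != 1:
            raise ValueError("profile must be a 1-d odd-length array")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.scores)

    @property
    def center(self) -> float:
        return float(self.scores[self.scores.size // 2])


@dataclass
class BinnedProfile:
    """The 19-bin logarithmic reduction of a 2001-base profile."""

    values: np.ndarray  # 19 bin means, NaN for all-missing bins
    bin_sizes: tuple[int, ...] = BIN_SIZES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.bin_sizes):
            raise ValueError("one value per bin required")


def extract_profile(
    track: ConservationTrack, locus: GenomicInterval, flank: int = 1000
) -> ConservationProfile:
    """Per-base scores for the locus and ``flank`` bases either side.

    Minus-strand loci get the reversed window so that the profile reads
    5'->3' in transcriptional orientation; positions off the chromosome
    are missing (NaN).
    """
    if locus.length != 1:
        raise ValueError(f"locus must have length 1, got {locus.length}")
    scores = track.window(locus.chrom, locus.start - flank, locus.start + flank + 1)
    if locus.strand == "-":
        scores = scores[::-1].copy()
    return ConservationProfile(locus, scores)


def bin_profile(profile: ConservationProfile) -> BinnedProfile:
    """Reduce a 2001-base profile to 19 logarithmic bin means.

    Missing bases are excluded from their bin's mean (0 is a meaningful
    neutral score, so missing is never imputed as 0); a bin with every base
    missing gets NaN.
    """
    if profile.scores.size != 2001:
        raise ValueError(f"expected a 2001-base profile, got {profile.scores.size}")
    values = np.empty(len(BIN_SIZES))
    for i in range(len(BIN_SIZES)):
        chunk = profile.scores[_BIN_EDGES[i] : _BIN_EDGES[i + 1]]
        good = chunk[~np.isnan(chunk)]
        values[i] = good.mean() if good.size else np.nan
    return BinnedProfile(values)


def average_pileup(
    profiles: list[ConservationProfile], half_width: int | None = None
) -> np.ndarray:
    """Per-position mean over non-missing values across profiles.

    ``half_width`` optionally restricts the output to the central
    ``2 * half_width + 1`` positions (e.g. 100 for a close-up view).
    """
    if not profiles:
        raise ValueError("average_pileup requires at least one profile")
    width = profiles[0].scores.size
    mat = np.vstack([p.scores for p in profiles])
    if mat.shape[1] != width:
        raise ValueError("profiles have inconsistent widths")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    if half_width is not None:
        c = width // 2
        mean = mean[c - half_width : c + half_width + 1]
    return mean


@dataclass
class ClusterModel:
    """K-means clustering of binned profiles with HC/LC centroid labels."""

    centroids: np.ndarray  # (K, 19)
    assignments: np.ndarray  # profile index -> cluster index
    inertia: float
    seed: int
    restarts: int
    labels: dict[int, str] = field(default_factory=dict)  # set by label_centroids

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def assignment_labels(self) -> list[str]:
        if not self.labels:
            raise ValueError("centroids are unlabeled; run label_centroids first")
        return [self.labels[int(a)] for a in self.assignments]


def _impute(binned: list[BinnedProfile]) -> np.ndarray:
    mat = np.vstack([b.values for b in binned])
    for row in mat:
        bad = np.isnan(row)
        if bad.all():
            raise ValueError("cannot cluster an all-missing profile")
        if bad.any():
            row[bad] = row[~bad].mean()  # impute by the profile's own mean
    return mat


def kmeans_cluster(
    binned: list[BinnedProfile], k: int = 2, seed: int = 0, restarts: int = 10
) -> ClusterModel:
    """Euclidean K-means on 19-dimensional binned profiles.

    Best of ``restarts`` seeded initializations by within-cluster sum of
    squares; deterministic given ``seed``. Missing bins are imputed by the
    profile's own mean before clustering.
    """
    if len(binned) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(binned)}")
    mat = _impute(binned)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    assignments = km.fit_predict(mat)
    return ClusterModel(
        centroids=km.cluster_centers_.copy(),
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def label_centroids(model: ClusterModel) -> ClusterModel:
    """Label the K=2 centroids high/low conservation.

    The centroid with the larger mean over its 19 bin values is the high
    conservation centroid; ties break by center-bin value, then by index.
    """
    if model.k != 2:
        raise ValueError("centroid labeling is defined for K=2 only")
    c = model.centroids
    center = len(BIN_SIZES) // 2
    keys = [(c[i].mean(), c[i][center], -i) for i in range(2)]
    hi = max(range(2), key=lambda i: keys[i])
    model.labels = {hi: HIGH, 1 - hi: LOW}
    return model


@dataclass
class ContingencyTable2x2:
    """Counts of eQTL interactions by (SNP class) x (target gene class)."""

    a: int  # HC SNP, HC target
    b: int  # LC SNP, HC target
    c: int  # HC SNP, LC target
    d: int  # LC SNP, LC target

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_table(
    pairs, snp_labels: dict[str, str], gene_labels: dict[str, str]
) -> ContingencyTable2x2:
    """Cross-tabulate interactions (not unique loci) by conservation class.

    ``pairs`` is a DataFrame with snp_id / gene_id columns; labels map locus
    id -> "high"/"low" (the HIGH/LOW constants are also accepted).
    """
    def norm(x: str) -> str:
        return "high" if x in ("high", HIGH) else "low" if x in ("low", LOW) else x

    missing = [
        s for s in pairs["snp_id"] if s not in snp_labels
    ] + [g for g in pairs["gene_id"] if g not in gene_labels]
    if missing:
        raise ValueError(f"unlabeled loci in catalog: {sorted(set(missing))[:10]}")
    counts = {"hh": 0, "lh": 0, "hl": 0, "ll": 0}
    for s, g in zip(pairs["snp_id"], pairs["gene_id"]):
        key = ("h" if norm(snp_labels[s]) == "high" else "l") + (
            "h" if norm(gene_labels[g]) == "high" else "l"
        )
        counts[key] += 1
    return ContingencyTable2x2(
        a=counts["hh"], b=counts["lh"], c=counts["hl"], d=counts["ll"]
    )


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    corrected: bool


def chi_squared_yates(
    table: ContingencyTable2x2, correction: bool = True
) -> ChiSquareResult:
    """2x2 chi-squared test of independence with Yates continuity correction.

    Each cell contributes (max(|O - E| - 0.5, 0))^2 / E; the p-value comes
    from the chi-squared distribution with 1 degree of freedom. Set
    ``correction=False`` for the uncorrected statistic.
    """
    obs = table.counts
    if table.total <= 0:
        raise ValueError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal: expected counts undefined")
    expected = np.outer(rows, cols) / table.total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return ChiSquareResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        corrected=correction,
    )


_KS_ALTERNATIVES = {
    # ours -> scipy's ks_2samp alternative for that direction
    "two_sided": "two-sided",
    "a_less": "greater",  # a stochastically less than b => ECDF of a above b's
    "a_greater": "less",
}


def ks_compare(
    sample_a, sample_b, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    ``a_less`` tests the alternative that sample_a is stochastically smaller
    than sample_b (its ECDF lies above); ``a_greater`` the reverse.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires nonempty samples")
    if alternative not in _KS_ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.ks_2samp(
        a, b, alternative=_KS_ALTERNATIVES[alternative], method="asymp"
    )
    return float(res.statistic), float(res.pvalue)
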