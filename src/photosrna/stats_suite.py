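"""Comparative statistics for the de-etiolation analysis.

Covers the determinant analysis of target cleavage (two-sample
Kolmogorov-Smirnov comparisons of sRNA abundance, target abundance and
sRNA-to-target ratios between pairs with and without degradome support),
light/dark fold-change t-tests, the transposable-element enrichment Fisher
test, and k-means clustering of light-response log2 fold-change profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from photosrna.quantify import _welch_t

RPKM_EXPRESSED_MIN = 0.01
EXACT_KS_MAX_PRODUCT = 100


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov result: D = sup |F1 - F2|."""

    D: float
    p_value: float
    n1: int
    n2: int


@dataclass
class RatioRecord:
    """One sRNA-target pair with abundances and their ratio.

    Dark snapshots pair sRNA W0 RPM with mRNA W0 RPKM; light snapshots pair
    sRNA W3 RPM with mRNA W4 RPKM (the external mRNA dataset's sampling
    grid is offset by 1 h).  ``degradome_status`` is 'plus' when a valid
    cleavage call supports the pair.
    """

    srna_id: str
    target_id: str
    srna_abundance: float
    target_abundance: float
    ratio: float
    degradome_status: str


@dataclass
class ClusterResult:
    labels: dict[str, int]
    k: int
    centroids: pd.DataFrame
    inertia: float


def ks_two_sample(a, b) -> KSResult:
    """Two-sample K-S test.

    D is the supremum gap between the empirical CDFs; the p-value is exact
    (enumeration over label assignments) when n1 * n2 <= 100 and asymptotic
    otherwise.  D is invariant under any strictly monotone transform of
    both samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    method = "exact" if a.size * b.size <= EXACT_KS_MAX_PRODUCT else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(D=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                    n1=a.size, n2=b.size)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by summing hypergeometric
    point probabilities <= that of the observed table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be > 0")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def fold_change_compare(
    light_over_dark: dict[str, float], grouping: dict[str, str]
) -> float:
    """Two-sided t-test between 'plus' and 'minus' groups on log2 light/dark
    ratios.  Requires >= 2 features per group."""
    groups: dict[str, list[float]] = {"plus": [], "minus": []}
    for fid, ratio in light_over_dark.items():
        status = grouping.get(fid)
        if status in groups and ratio > 0 and np.isfinite(ratio):
            groups[status].append(float(np.log2(ratio)))
    if min(len(groups["plus"]), len(groups["minus"])) < 2:
        raise ValueError("fold_change_compare requires >= 2 features per group")
    return _welch_t(np.array(groups["plus"]), np.array(groups["minus"]))


def ratio_analysis(
    srna_rpm: pd.Series,
    target_rpkm: pd.Series,
    calls,
    pairs: list[tuple[str, str]],
    condition: str = "dark",
) -> tuple[list[RatioRecord], dict[str, KSResult]]:
    """sRNA-to-target determinant analysis for one condition.

    ``pairs`` enumerates the candidate sRNA-target pairs (predicted plus
    degradome-identified); ``srna_rpm`` and ``target_rpkm`` are the
    condition's abundance snapshots indexed by id.  Pairs whose target is
    not expressed (RPKM <= 0.01) are excluded.  Returns the per-pair
    records (degradome 'plus' when a valid cleavage call links the pair)
    and three K-S comparisons between the plus and minus strata: sRNA
    abundance, target abundance and pairwise ratio.  The K-S statistic is
    rank-invariant, so no log transform is applied before testing.
    """
    if condition not in ("dark", "light"):
        raise ValueError("condition must be 'dark' or 'light'")
    valid_pairs = {
        (c.alignment.srna_id, c.alignment.transcript_id)
        for c in calls
        if getattr(c, "valid", False)
    }
    all_pairs = sorted(set(pairs) | valid_pairs)
    records: list[RatioRecord] = []
    for sid, tid in all_pairs:
        s_ab = float(srna_rpm.get(sid, 0.0))
        t_ab = float(target_rpkm.get(tid, 0.0))
        if t_ab <= RPKM_EXPRESSED_MIN:
            continue
        records.append(
            RatioRecord(
                srna_id=sid,
                target_id=tid,
                srna_abundance=s_ab,
                target_abundance=t_ab,
                ratio=s_ab / t_ab,
                degradome_status="plus" if (sid, tid) in valid_pairs else "minus",
            )
        )
    plus = [r for r in records if r.degradome_status == "plus"]
    minus = [r for r in records if r.degradome_status == "minus"]
    tests: dict[str, KSResult] = {}
    if plus and minus:
        tests["srna_abundance"] = ks_two_sample(
            [r.srna_abundance for r in plus], [r.srna_abundance for r in minus]
        )
        tests["target_abundance"] = ks_two_sample(
            [r.target_abundance for r in plus], [r.target_abundance for r in minus]
        )
        tests["ratio"] = ks_two_sample(
            [r.ratio for r in plus], [r.ratio for r in minus]
        )
    else:
        warnings.warn(
            "a degradome stratum is empty; K-S comparisons omitted", stacklevel=2
        )
    return records, tests


def ratio_records_table(records: list[RatioRecord]) -> pd.DataFrame:
    """Export table with log10-transformed abundances/ratios for plotting."""
    return pd.DataFrame(
        {
            "srna_id": [r.srna_id for r in records],
            "target_id": [r.target_id for r in records],
            "log10_srna_rpm": np.log10([max(r.srna_abundance, 1e-6) for r in records]),
            "log10_target_rpkm": np.log10([r.target_abundance for r in records]),
            "log10_ratio": np.log10(
                [max(r.ratio, 1e-6) for r in records]
            ),
            "degradome_status": [r.degradome_status for r in records],
        }
    )


def cluster_profiles(
    log2fc_matrix: pd.DataFrame,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """K-means (Euclidean) clustering of light-response log2FC profiles.

    Rows are features, columns the time points (W0 column identically 0,
    anchoring profiles at darkness).  ``n_restarts`` random initializations
    are run and the best-inertia solution kept; deterministic given
    (seed, n_restarts).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > log2fc_matrix.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of features ({log2fc_matrix.shape[0]})"
        )
    X = log2fc_matrix.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd"
    ).fit(X)
    centroids = pd.DataFrame(
        km.cluster_centers_, columns=log2fc_matrix.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    return ClusterResult(
        labels=dict(zip(log2fc_matrix.index, (int(v) for v in km.labels_))),
        k=k,
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def load_reference_clusters() -> pd.DataFrame:
    """Packaged reference table of light-regulated miRNA log2FC profiles.

    Columns: cluster label (I = induced from near-zero darkness expression,
    II = gradually up-regulated, III = down-regulated) and the six
    time-point log2 fold changes relative to W0.  Values transcribed from a
    published de-etiolation profiling study; used as the worked example for
    :func:`cluster_profiles`.
    """
    with resources.files("photosrna.data").joinpath(
        "light_response_clusters.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="srna_id")
    return df


def load_reference_phas_loci() -> pd.DataFrame:
    """Packaged reference table of expressed PHAS/TAS loci (n, k, p rows)
    used to calibrate the phasing-statistic convention."""
    with resources.files("photosrna.data").joinpath(
        "reference_phas_loci.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
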