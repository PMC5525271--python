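"""Expression quantification and expressed / light-regulated classification.

Counting follows standard sRNA-seq practice for this design: reads matching
a mature sRNA exactly are counted, multi-family hits are weighted by equal
division across family members, libraries are normalized to reads per
million (RPM) using the per-library total of mapped 20-24 nt reads, and a
feature is called *expressed* when every biological replicate reaches >= 5
reads in at least one time point.  Light regulation is a per-time-point
two-sample t-test of the five light time points against darkness (W0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from photosrna.core_io import (
    AlignedRead,
    ExpressionMatrix,
    Transcript,
    revcomp,
)

EXPRESSED_MIN_COUNT = 5
DEFAULT_MAX_HITS = 5


@dataclass
class FamilyMap:
    """family name -> set of member sRNA ids; each member in exactly one family."""

    families: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, members in self.families.items():
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"sRNA {m!r} appears in families {seen[m]!r} and {fam!r}"
                    )
                seen[m] = fam
        self._member_to_family = seen

    def family_of(self, srna_id: str) -> str | None:
        return self._member_to_family.get(srna_id)

    def members(self, family: str) -> set[str]:
        return self.families[family]


@dataclass
class RegulationCall:
    """Expressed / light-regulated verdict for one sRNA.

    ``p_values`` maps each light time point to the t-test p-value against W0;
    ``log2_fold_changes`` maps every time point (W0 included, identically 0)
    to the log2 fold change of replicate-mean RPM relative to W0.
    """

    srna_id: str
    expressed: bool
    light_regulated: bool
    p_values: dict[str, float] = field(default_factory=dict)
    log2_fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.light_regulated and not self.expressed:
            raise ValueError("light_regulated implies expressed")


def map_exact(
    reads: list[tuple[str, int]],
    references: list[Transcript],
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[AlignedRead]:
    """Place reads on references by exact full-length match on either strand.

    Reads with more than ``max_hits`` placements are discarded entirely
    (multi-mapper cutoff).  Output order is deterministic: reads in input
    order, placements by (reference order, position, strand).
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    out: list[AlignedRead] = []
    for i, (seq, count) in enumerate(reads):
        placements: list[tuple[int, int, str]] = []
        rc = revcomp(seq)
        for ref_idx, ref in enumerate(references):
            for query, strand in ((seq, "+"), (rc, "-")):
                pos = ref.sequence.find(query)
                while pos != -1:
                    placements.append((ref_idx, pos, strand))
                    pos = ref.sequence.find(query, pos + 1)
        if not placements or len(placements) > max_hits:
            continue
        placements.sort()
        for ref_idx, pos, strand in placements:
            out.append(
                AlignedRead(
                    read_id=f"read{i + 1}",
                    sequence=seq,
                    count=count,
                    ref_id=references[ref_idx].id,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                )
            )
    return out


def rpm_normalize(
    counts: ExpressionMatrix, mapped_20_24_totals: pd.Series
) -> ExpressionMatrix:
    """Normalize raw counts to reads per million mapped 20-24 nt reads.

    ``mapped_20_24_totals`` is indexed by library, i.e. by the same
    (time_point, replicate) MultiIndex as the matrix columns; each library is
    normalized independently: value = count / total * 1e6.
    """
    if counts.unit != "raw_count":
        raise ValueError("rpm_normalize expects a raw_count matrix")
    totals = mapped_20_24_totals.reindex(counts.values.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"missing library totals for {missing}")
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    rpm = counts.values / totals * 1e6
    return ExpressionMatrix(rpm, unit="RPM", library_totals=totals)


def weight_family_counts(read_count: float, members_hit: set[str]) -> dict[str, float]:
    """Divide a read count equally across the family members it matches.

    The assignments sum exactly to ``read_count``.
    """
    if not members_hit:
        raise ValueError("members_hit must be non-empty")
    share = read_count / len(members_hit)
    return {m: share for m in sorted(members_hit)}


def is_expressed(
    raw_counts: pd.DataFrame,
    min_count: int = EXPRESSED_MIN_COUNT,
    same_time_point: bool = False,
) -> bool:
    """Expressed-sRNA criterion: >= ``min_count`` reads in >= 1 time point
    for every replicate.

    ``raw_counts`` is a time_point x replicate table for one feature
    (missing values are treated as 0).  By default each replicate may
    qualify at a different time point; ``same_time_point=True`` requires one
    common time point at which all replicates reach the threshold.
    """
    m = raw_counts.fillna(0).to_numpy()
    if same_time_point:
        return bool((m >= min_count).all(axis=1).any())
    return bool((m >= min_count).any(axis=0).all())


def _welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value, p = 1 for degenerate zero-variance
    ties (both groups constant and equal)."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p) if np.isfinite(p) else 1.0


def light_regulation_test(
    rpm: pd.DataFrame,
    srna_id: str = "",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> RegulationCall:
    """Test one expressed feature for light regulation.

    ``rpm`` is a time_point x replicate RPM table with W0 first.  For each
    light time point a two-sided two-sample t-test (Welch by default)
    compares its replicates against W0; the feature is light-regulated when
    any time point has p < ``alpha``.  Log2 fold changes use replicate-mean
    RPM with W0 as the reference (the W0 entry is identically 0; a zero W0
    mean yields +/-inf, flagging a feature only detectable after the light
    switch).
    """
    tps = list(rpm.index)
    w0 = rpm.loc[tps[0]].to_numpy(dtype=float)
    w0_mean = w0.mean()
    p_values: dict[str, float] = {}
    log2fc: dict[str, float] = {tps[0]: 0.0}
    for tp in tps[1:]:
        vals = rpm.loc[tp].to_numpy(dtype=float)
        p_values[tp] = _welch_t(vals, w0, equal_var=equal_var)
        mean = vals.mean()
        if w0_mean == 0.0:
            log2fc[tp] = float("inf") if mean > 0 else 0.0
        elif mean == 0.0:
            log2fc[tp] = float("-inf")
        else:
            log2fc[tp] = float(np.log2(mean / w0_mean))
    return RegulationCall(
        srna_id=srna_id,
        expressed=True,
        light_regulated=min(p_values.values()) < alpha,
        p_values=p_values,
        log2_fold_changes=log2fc,
    )


def count_catalog_matches(
    reads: list[tuple[str, int]],
    catalog_sequences: dict[str, str],
    family_map: FamilyMap | None = None,
) -> dict[str, float]:
    """Count reads perfectly matching mature sRNA sequences, family-weighted.

    A read matching several catalog entries of one family contributes its
    count divided equally among the members hit (mass-conserving); entries
    sharing the identical sequence are treated as one family hit even
    without a family map.
    """
    counts: dict[str, float] = {sid: 0.0 for sid in catalog_sequences}
    by_seq: dict[str, list[str]] = {}
    for sid, seq in catalog_sequences.items():
        by_seq.setdefault(seq, []).append(sid)
    for seq, count in reads:
        hits = by_seq.get(seq)
        if not hits:
            continue
        for sid, share in weight_family_counts(count, set(hits)).items():
            counts[sid] += share
    return counts


def pooled_light_mean(rpm: ExpressionMatrix) -> pd.Series:
    """Equal-weight mean RPM of the five light time points, per feature.

    Mirrors a degradome design in which the light library is pooled equally
    from the five light-treated time points: mean of per-time-point
    replicate-mean RPM, not a sum of counts.
    """
    light_tps = [tp for tp in rpm.time_points if tp != "W0"]
    per_tp = pd.concat(
        {tp: rpm.values[tp].mean(axis=1) for tp in light_tps}, axis=1
    )
    return per_tp.mean(axis=1)
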