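"""Model/Results entry points, statsmodels-style.

Each model is built from data, ``fit()`` runs the analysis, and the
returned Results object carries the estimates plus a ``summary()`` table:

* :class:`PhasingScan` -> :class:`PhasingResults` (PHAS locus calls),
* :class:`DegradomeTargeting` -> :class:`TargetingResults` (cleavage calls),
* :class:`LightResponseModel` -> :class:`LightResponseResults` (expressed /
  light-regulated classification, log2FC profiles, clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from photosrna import core_io, degradome, phasing, quantify, stats_suite
from photosrna.core_io import (
    DegradomeProfile,
    ExpressionMatrix,
    SrnaCatalogEntry,
    Transcript,
)


class PhasingScan:
    """Sliding-window phasing scan over a set of references."""

    def __init__(
        self,
        alignments: Sequence[core_io.AlignedRead],
        references: Sequence[Transcript] | dict[str, int],
        params: phasing.PhasingParams | None = None,
    ):
        self.alignments = list(alignments)
        self.references = references
        self.params = params or phasing.PhasingParams()

    def fit(self) -> "PhasingResults":
        calls = phasing.scan_phas(self.alignments, self.references, self.params)
        return PhasingResults(calls=calls, params=self.params)


@dataclass
class PhasingResults:
    calls: list[phasing.PhasLocusCall]
    params: phasing.PhasingParams

    def summary(self) -> pd.DataFrame:
        """Locus report with 1-based inclusive coordinates."""
        return pd.DataFrame(
            [
                {
                    "locus": c.ref_id,
                    "start": c.start + 1,
                    "end": c.end,
                    "trigger": c.trigger or ".",
                    "n": c.n,
                    "k": c.k,
                    "p_value": c.p_value,
                }
                for c in self.calls
            ],
            columns=["locus", "start", "end", "trigger", "n", "k", "p_value"],
        )

    def to_gff3(self, path) -> None:
        core_io.write_locus_gff3(self.calls, path)


class DegradomeTargeting:
    """sRNA target-cleavage calling from degradome profiles."""

    def __init__(
        self,
        srnas: Sequence[SrnaCatalogEntry],
        transcripts: Sequence[Transcript],
        profiles: dict[str, DegradomeProfile],
        params: degradome.DegradomeParams | None = None,
    ):
        self.srnas = list(srnas)
        self.transcripts = list(transcripts)
        self.profiles = profiles
        self.params = params or degradome.DegradomeParams()

    def fit(self) -> "TargetingResults":
        calls = degradome.call_targets(
            self.srnas, self.transcripts, self.profiles, self.params
        )
        return TargetingResults(calls=calls, profiles=self.profiles)


@dataclass
class TargetingResults:
    calls: list[degradome.CleavageCall]
    profiles: dict[str, DegradomeProfile]

    @property
    def valid_calls(self) -> list[degradome.CleavageCall]:
        return [c for c in self.calls if c.valid]

    def summary(self) -> pd.DataFrame:
        return degradome.calls_table(self.calls)

    def tplot_data(self, transcript_id: str) -> pd.DataFrame:
        """Per-position degradome series with valid call sites flagged."""
        return degradome.tplot_data(self.profiles[transcript_id], self.valid_calls)


class LightResponseModel:
    """Expression classification and light-response analysis of a raw-count
    time-course matrix (features x (time point, replicate))."""

    def __init__(
        self,
        counts: ExpressionMatrix,
        library_totals: pd.Series | None = None,
        alpha: float = 0.05,
        same_time_point: bool = False,
        equal_var: bool = False,
    ):
        if counts.unit != "raw_count":
            raise ValueError("LightResponseModel expects raw counts")
        self.counts = counts
        totals = library_totals if library_totals is not None else counts.library_totals
        if totals is None:
            raise ValueError("library totals are required for RPM normalization")
        self.library_totals = totals
        self.alpha = alpha
        self.same_time_point = same_time_point
        self.equal_var = equal_var

    def fit(self) -> "LightResponseResults":
        rpm = quantify.rpm_normalize(self.counts, self.library_totals)
        calls: dict[str, quantify.RegulationCall] = {}
        for fid in self.counts.values.index:
            expressed = quantify.is_expressed(
                self.counts.feature(fid), same_time_point=self.same_time_point
            )
            if not expressed:
                calls[fid] = quantify.RegulationCall(
                    srna_id=fid, expressed=False, light_regulated=False
                )
                continue
            call = quantify.light_regulation_test(
                rpm.feature(fid), srna_id=fid, alpha=self.alpha,
                equal_var=self.equal_var,
            )
            calls[fid] = call
        return LightResponseResults(calls=calls, rpm=rpm, counts=self.counts)


@dataclass
class LightResponseResults:
    calls: dict[str, quantify.RegulationCall]
    rpm: ExpressionMatrix
    counts: ExpressionMatrix
    _cluster_result: stats_suite.ClusterResult | None = field(default=None, repr=False)

    @property
    def expressed_ids(self) -> list[str]:
        return [fid for fid, c in self.calls.items() if c.expressed]

    @property
    def light_regulated_ids(self) -> list[str]:
        return [fid for fid, c in self.calls.items() if c.light_regulated]

    def log2fc_matrix(self, finite_only: bool = True) -> pd.DataFrame:
        """Light-regulated features x time points log2FC matrix (W0 = 0).

        ``finite_only`` drops features with infinite fold changes (zero W0
        mean), which cannot enter Euclidean clustering.
        """
        rows = {}
        tps = self.rpm.time_points
        for fid in self.light_regulated_ids:
            fc = self.calls[fid].log2_fold_changes
            vec = [fc.get(tp, 0.0) for tp in tps]
            if finite_only and not np.all(np.isfinite(vec)):
                continue
            rows[fid] = vec
        return pd.DataFrame.from_dict(rows, orient="index", columns=tps)

    def cluster(self, k: int = 3, n_restarts: int = 20, seed: int = 0):
        """K-means clustering of the light-regulated log2FC profiles."""
        self._cluster_result = stats_suite.cluster_profiles(
            self.log2fc_matrix(), k=k, n_restarts=n_restarts, seed=seed
        )
        return self._cluster_result

    def summary(self) -> pd.DataFrame:
        tps = self.rpm.time_points
        rows = []
        for fid, call in self.calls.items():
            row = {
                "feature": fid,
                "expressed": call.expressed,
                "light_regulated": call.light_regulated,
                "min_p": min(call.p_values.values()) if call.p_values else np.nan,
            }
            for tp in tps[1:]:
                row[f"log2FC_{tp}"] = call.log2_fold_changes.get(tp, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("feature")
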