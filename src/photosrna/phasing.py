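"""PHAS/TAS locus detection via a hypergeometric phasing statistic.

A phased-siRNA locus sheds 21-nt reads whose 5' ends fall on a common
register modulo 21.  Within a sliding window we count distinct alignment
positions ``n`` (unique (start, strand) pairs) and the number ``k`` of those
on the best-supported register, minus-strand starts offset by +2 nt for the
2-nt 3' overhang of the dicing duplex.  Significance is the upper tail of a
hypergeometric distribution: drawing n of the N addressable positions in the
window, of which K are in-register, P(X >= k).

The (N, K) convention and the register-selection correction are not uniquely
determined by the statistic's name; the defaults here (N = 2W, K = 2*ceil(W/L),
m_reg = 1) were fixed by :func:`calibrate_convention`, a sweep over candidate
conventions scored against a published twelve-locus reference table (see
docs/methods.md for the calibration and its residual).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from photosrna.core_io import AlignedRead, Transcript


@dataclass
class PhasingParams:
    """Tunable parameters of the phasing scan.

    ``total_positions`` (N) and ``phased_positions`` (K) default to the
    both-strand convention N = 2W, K = 2*ceil(W/L); ``register_multiplicity``
    (m_reg) is a Bonferroni-style factor for the registers tested per window.
    """

    window_length: int = 251
    phase_length: int = 21
    total_positions: int | None = None
    phased_positions: int | None = None
    register_multiplicity: int = 1
    min_read_length: int = 21
    max_read_length: int = 21
    p_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if self.total_positions is None:
            self.total_positions = 2 * self.window_length
        if self.phased_positions is None:
            self.phased_positions = 2 * math.ceil(self.window_length / self.phase_length)
        if self.phased_positions > self.total_positions:
            raise ValueError("phased_positions K must be <= total_positions N")
        if not 1 <= self.register_multiplicity <= self.phase_length:
            raise ValueError("register_multiplicity must be in [1, phase_length]")


@dataclass
class PhasLocusCall:
    """A candidate PHAS window: distinct alignments n, phased k, p-value."""

    ref_id: str
    start: int
    end: int
    n: int
    k: int
    p_value: float
    trigger: str | None = None
    best_register: int = 0
    clipped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


MINUS_STRAND_OFFSET = 2  # 2-nt 3' overhang of the dicing duplex


def phase_position(read: AlignedRead) -> int:
    """The register-defining coordinate of an alignment (minus strand +2)."""
    return read.start + (MINUS_STRAND_OFFSET if read.strand == "-" else 0)


def count_window(
    alignments: Sequence[AlignedRead],
    ref_id: str,
    start: int,
    params: PhasingParams,
    ref_length: int | None = None,
) -> tuple[int, int, int]:
    """Count distinct and phased alignment positions in one window.

    Returns ``(n, k, best_register)`` where n is the number of distinct
    (start, strand) alignment positions whose phase coordinate falls in
    ``[start, start + W)``, and k is the count on the register (residue
    class modulo L of the phase coordinate relative to the window start)
    that maximizes it.  Windows running past the reference end are clipped.
    """
    L = params.phase_length
    end = start + params.window_length
    if ref_length is not None:
        end = min(end, ref_length)
    positions: set[tuple[int, str]] = set()
    for read in alignments:
        if read.ref_id != ref_id:
            continue
        if not params.min_read_length <= len(read) <= params.max_read_length:
            continue
        pos = phase_position(read)
        if start <= pos < end:
            positions.add((pos, read.strand))
    if not positions:
        return 0, 0, 0
    registers = np.zeros(L, dtype=int)
    for pos, _strand in positions:
        registers[(pos - start) % L] += 1
    best_register = int(np.argmax(registers))
    return len(positions), int(registers[best_register]), best_register


def phasing_pvalue(n: int, k: int, params: PhasingParams) -> float:
    """Upper-tail hypergeometric phasing p-value, register-corrected.

    P(X >= k) for X ~ Hypergeom(N, K, n), multiplied by
    ``register_multiplicity`` and capped at 1.
    """
    N, K = params.total_positions, params.phased_positions
    if k > K:
        raise ValueError(f"k={k} exceeds phased positions K={K}")
    if n > N:
        raise ValueError(f"n={n} exceeds total positions N={N}")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = float(hypergeom.sf(k - 1, N, K, n)) * params.register_multiplicity
    return min(max(p, np.nextafter(0, 1)), 1.0)


def scan_phas(
    alignments: Sequence[AlignedRead],
    references: Sequence[Transcript] | dict[str, int],
    params: PhasingParams | None = None,
) -> list[PhasLocusCall]:
    """Slide phasing windows over each reference and report significant loci.

    Windows advance by one phase cycle (L nt); overlapping significant
    windows are merged keeping the minimum-p window's statistics while the
    merged interval spans their union.  Only calls with p < ``p_threshold``
    are returned, sorted by p within each reference.
    """
    params = params or PhasingParams()
    if isinstance(references, dict):
        ref_lengths = dict(references)
    else:
        ref_lengths = {t.id: len(t) for t in references}
    by_ref: dict[str, list[AlignedRead]] = {rid: [] for rid in ref_lengths}
    for read in alignments:
        if read.ref_id in by_ref:
            by_ref[read.ref_id].append(read)

    calls: list[PhasLocusCall] = []
    for ref_id, length in ref_lengths.items():
        reads = by_ref[ref_id]
        if not reads:
            continue
        windows: list[PhasLocusCall] = []
        n_starts = max(1, math.ceil(max(length - params.window_length, 0) / params.phase_length) + 1)
        for w in range(n_starts):
            start = w * params.phase_length
            end = min(start + params.window_length, length)
            n, k, reg = count_window(reads, ref_id, start, params, ref_length=length)
            if n == 0:
                continue
            p = phasing_pvalue(n, k, params)
            if p < params.p_threshold:
                windows.append(
                    PhasLocusCall(
                        ref_id=ref_id,
                        start=start,
                        end=end,
                        n=n,
                        k=k,
                        p_value=p,
                        best_register=reg,
                        clipped=end - start < params.window_length,
                    )
                )
        calls.extend(_merge_overlapping(windows))
    calls.sort(key=lambda c: (c.ref_id, c.p_value, c.start))
    return calls


def _merge_overlapping(windows: list[PhasLocusCall]) -> list[PhasLocusCall]:
    """Merge overlapping significant windows, keeping the minimum-p stats."""
    if not windows:
        return []
    windows = sorted(windows, key=lambda c: c.start)
    merged = [windows[0]]
    for win in windows[1:]:
        last = merged[-1]
        if win.start < last.end:
            best = min(last, win, key=lambda c: c.p_value)
            merged[-1] = replace(
                best, start=min(last.start, win.start), end=max(last.end, win.end)
            )
        else:
            merged.append(win)
    return merged


def annotate_triggers(
    calls: list[PhasLocusCall], cleavage_calls: Iterable
) -> list[PhasLocusCall]:
    """Attach trigger sRNA ids to locus calls from valid cleavage events
    whose cleavage site falls inside the locus on the same reference."""
    out = []
    for call in calls:
        trigger = None
        for cc in cleavage_calls:
            if not getattr(cc, "valid", False):
                continue
            if (
                cc.alignment.transcript_id == call.ref_id
                and call.start < cc.alignment.expected_cleavage_position <= call.end
            ):
                trigger = cc.alignment.srna_id
                break
        out.append(replace(call, trigger=trigger))
    return out


# ---------------------------------------------------------------------------
# Convention calibration
# ---------------------------------------------------------------------------

@dataclass
class ConventionFit:
    total_positions: int
    phased_positions: int
    register_multiplicity: int
    n_exact_2sf: int
    max_ratio: float
    p_values: list[float] = field(repr=False, default_factory=list)


def calibrate_convention(
    reference_rows: Sequence[tuple[int, int, float]],
    window_length: int = 251,
    phase_length: int = 21,
) -> list[ConventionFit]:
    """Score candidate (N, K, m_reg) conventions against reference (n, k, p) rows.

    Candidates: N in {W, 2W, L*ceil(W/L), 2L*ceil(W/L)}, K in {ceil(W/L),
    2*ceil(W/L)}, m_reg in {1, L}.  Conventions that cannot accommodate a
    row (k > K or n > N) are excluded.  The returned list is sorted best
    first: by number of rows reproduced to 2 significant figures, then by
    the smallest worst-case printed/computed ratio.
    """
    W, L = window_length, phase_length
    c = math.ceil(W / L)
    fits = []
    max_n = max(n for n, _, _ in reference_rows)
    max_k = max(k for _, k, _ in reference_rows)
    for N, K, m in itertools.product(
        (W, 2 * W, L * c, 2 * L * c), (c, 2 * c), (1, L)
    ):
        if K < max_k or N < max_n:
            continue  # convention cannot accommodate the reference rows
        params = PhasingParams(
            window_length=W,
            phase_length=L,
            total_positions=N,
            phased_positions=K,
            register_multiplicity=m,
        )
        pvals, ok, max_ratio = [], 0, 0.0
        for n, k, p_ref in reference_rows:
            p = phasing_pvalue(n, k, params)
            pvals.append(p)
            if f"{p:.1e}" == f"{p_ref:.1e}":
                ok += 1
            max_ratio = max(max_ratio, p / p_ref, p_ref / p)
        fits.append(ConventionFit(N, K, m, ok, max_ratio, pvals))
    fits.sort(key=lambda f: (-f.n_exact_2sf, f.max_ratio))
    return fits
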