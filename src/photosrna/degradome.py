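"""Degradome (PARE) cleavage-site calling.

An sRNA guiding AGO-mediated slicing leaves a sharp degradome 5'-end peak on
its target opposite sRNA positions 10-11.  This module scores
sRNA-transcript complementarity with an Allen-style penalty (mismatch 1,
G:U wobble 0.5, bulge 1, doubled at sRNA positions 2-13), locates candidate
sites, classifies the degradome signal at the expected cleavage position
into categories 0-4 by its rank among the transcript's 5'-end counts,
attaches an empirical p-value from dinucleotide-preserving sRNA shuffles,
and applies the validity filter: category <= 2, p <= 0.05 and >= 5 reads at
the site.

The site accessibility (RNA-folding) filter of structure-aware target
predictors is deliberately not implemented; candidate sites are ranked by
complementarity alone (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from photosrna.core_io import DegradomeProfile, SrnaCatalogEntry, Transcript, normalize_sequence

SEED_START, SEED_END = 2, 13  # sRNA positions (1-based, from the 5' end)
DEFAULT_MAX_SCORE = 3.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# penalty[srna_base, target_base] for an antiparallel duplex in DNA space:
# 0 = Watson-Crick, 0.5 = G:U wobble (sRNA G : target T, sRNA T : target G),
# 1 = mismatch.  Row/column 4 is any ambiguous base (always a mismatch).
_PENALTY = np.ones((5, 5))
for _s, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PENALTY[_BASE_INDEX[_s], _BASE_INDEX[_t]] = 0.0
_PENALTY[_BASE_INDEX["G"], _BASE_INDEX["T"]] = 0.5
_PENALTY[_BASE_INDEX["T"], _BASE_INDEX["G"]] = 0.5


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(b, 4) for b in seq), dtype=np.int8, count=len(seq))


def _position_weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[SEED_START - 1 : SEED_END] = 2.0
    return w


@dataclass
class TargetAlignment:
    """One sRNA binding site on a transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates of the
    site; ``expected_cleavage_position`` is the 1-based transcript
    coordinate paired to sRNA position 10.
    """

    srna_id: str
    transcript_id: str
    start: int
    end: int
    match_states: list[str]
    allen_score: float
    expected_cleavage_position: int

    def __post_init__(self) -> None:
        if not self.start < self.expected_cleavage_position <= self.end:
            raise ValueError("cleavage position must lie inside the binding site")


@dataclass
class CleavageCall:
    """One sRNA-transcript cleavage event with its validity verdict."""

    alignment: TargetAlignment
    site_reads: int
    site_position: int
    category: int
    p_value: float
    valid: bool = field(init=False)
    site_rpm: float = 0.0

    def __post_init__(self) -> None:
        self.valid = (
            self.category <= 2 and self.p_value <= 0.05 and self.site_reads >= 5
        )


@dataclass
class DegradomeParams:
    max_score: float = DEFAULT_MAX_SCORE
    min_site_reads: int = 5
    max_category: int = 2
    p_threshold: float = 0.05
    n_shuffles: int = 100
    site_tolerance: int = 1
    seed: int = 0


def allen_score(
    srna_sequence: str, target_site_sequence: str
) -> tuple[float, list[str]]:
    """Allen-style complementarity penalty of an ungapped antiparallel duplex.

    Both sequences are 5'->3' (the target site in transcript sense); sRNA
    position i pairs with target position L-i+1.  Penalties: mismatch 1.0,
    G:U wobble 0.5, bulge ('-' in either strand) 1.0, each doubled when the
    sRNA position lies within 2-13 from the sRNA 5' end.  Returns the total
    and per-sRNA-position match states.
    """
    if not srna_sequence or not target_site_sequence:
        raise ValueError("empty sequence")
    if len(srna_sequence) != len(target_site_sequence):
        raise ValueError("duplex sequences must have equal length after anchoring")
    s = normalize_sequence(srna_sequence)
    t = normalize_sequence(target_site_sequence)[::-1]  # antiparallel pairing
    states, score = [], 0.0
    for i, (sb, tb) in enumerate(zip(s, t)):
        pos = i + 1
        weight = 2.0 if SEED_START <= pos <= SEED_END else 1.0
        if sb == "-" or tb == "-":
            states.append("bulge")
            score += 1.0 * weight
            continue
        pen = _PENALTY[_BASE_INDEX.get(sb, 4), _BASE_INDEX.get(tb, 4)]
        states.append("match" if pen == 0 else "wobble" if pen == 0.5 else "mismatch")
        score += pen * weight
    return score, states


def _window_scores(srna: str, transcript_seq: str) -> np.ndarray:
    """Vectorized Allen scores of every length-L window of a transcript."""
    L = len(srna)
    t = _encode(transcript_seq)
    if len(t) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    s = _encode(srna)
    return (_PENALTY[s[None, :], windows] * _position_weights(L)[None, :]).sum(axis=1)


def expected_cleavage_position(site_start: int, srna_length: int) -> int:
    """1-based transcript coordinate paired to sRNA position 10 for a site
    starting at 0-based ``site_start``."""
    return site_start + srna_length - 9


def find_candidate_sites(
    srna: SrnaCatalogEntry | str,
    transcript: Transcript,
    max_score: float = DEFAULT_MAX_SCORE,
    srna_id: str = "srna",
) -> list[TargetAlignment]:
    """All ungapped binding sites with Allen score <= ``max_score``.

    Overlapping qualifying sites are deduplicated keeping the minimum score
    (ties: leftmost).
    """
    if isinstance(srna, SrnaCatalogEntry):
        srna_id, seq = srna.srna_id, srna.sequence
    else:
        seq = normalize_sequence(srna)
    L = len(seq)
    if len(transcript) < L:
        return []
    scores = _window_scores(seq, transcript.sequence)
    hits = np.flatnonzero(scores <= max_score)
    sites: list[TargetAlignment] = []
    for start in hits:
        start = int(start)
        if sites and start < sites[-1].end:
            if scores[start] < sites[-1].allen_score:
                sites.pop()
            else:
                continue
        score, states = allen_score(seq, transcript.sequence[start : start + L])
        sites.append(
            TargetAlignment(
                srna_id=srna_id,
                transcript_id=transcript.id,
                start=start,
                end=start + L,
                match_states=states,
                allen_score=score,
                expected_cleavage_position=expected_cleavage_position(start, L),
            )
        )
    return sites


def categorize(profile: DegradomeProfile, position: int) -> int | None:
    """CleaveLand-style category of the degradome count at a 1-based position.

    With c the count at the position and ranking over the transcript's
    nonzero counts: 4 if c == 1; 0 if c > 1 and c is the unique maximum;
    1 if c > 1 and c ties the maximum; 2 if c > 1 and c exceeds the median
    of nonzero counts but is below the maximum; 3 otherwise.  A zero count
    has no category (``None``).
    """
    c = profile.count_at(position)
    if c == 0:
        return None
    if c == 1:
        return 4
    nonzero = profile.position_counts[profile.position_counts > 0]
    maximum = int(nonzero.max())
    if c == maximum:
        return 0 if int((nonzero == maximum).sum()) == 1 else 1
    if c > float(np.median(nonzero)):
        return 2
    return 3


def site_signal(
    profile: DegradomeProfile, expected_position: int, tolerance: int = 1
) -> tuple[int, int]:
    """Best degradome position within ``tolerance`` nt of the expected
    cleavage site; returns (position, count)."""
    lo = max(1, expected_position - tolerance)
    hi = min(len(profile.position_counts), expected_position + tolerance)
    window = profile.position_counts[lo - 1 : hi]
    if window.size == 0:
        return expected_position, 0
    best = int(np.argmax(window))
    return lo + best, int(window[best])


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle via a random Euler path on the
    dinucleotide multigraph (Altschul-Erikson).

    For every vertex except the path's terminal one, a random final out-edge
    is drawn and kept only if the chosen final edges form an arborescence
    into the terminal vertex; the remaining edges are shuffled freely.  The
    greedy edge walk is then guaranteed to realize a full Euler path, so the
    result always preserves the exact dinucleotide multiset.
    """
    seq = normalize_sequence(sequence)
    if len(seq) <= 2 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    while True:
        final_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # the chosen final edges must lead every vertex into the terminal one
        if all(_reaches(v, last, final_edge) for v in vertices):
            break
    for v, targets in edges.items():
        if v == last:
            rng.shuffle(targets)
            continue
        rest = list(targets)
        rest.remove(final_edge[v])
        rng.shuffle(rest)
        edges[v] = rest + [final_edge[v]]
    out = [seq[0]]
    cursors: dict[str, int] = {k: 0 for k in edges}
    for _ in range(len(seq) - 1):
        node = out[-1]
        out.append(edges[node][cursors[node]])
        cursors[node] += 1
    return "".join(out)


def _reaches(start: str, goal: str, final_edge: dict[str, str]) -> bool:
    node, seen = start, set()
    while node != goal:
        if node in seen or node not in final_edge:
            return False
        seen.add(node)
        node = final_edge[node]
    return True


def _best_shuffle_hit(
    shuffle: str,
    transcripts: Sequence[Transcript],
    profiles: dict[str, DegradomeProfile],
    max_score: float,
    tolerance: int,
) -> tuple[float, int] | None:
    """Best (score, category) pair achieved by a shuffled sRNA anywhere in
    the transcriptome, or None if no site scores under the cutoff."""
    best: tuple[float, int] | None = None
    L = len(shuffle)
    for tr in transcripts:
        if len(tr) < L:
            continue
        scores = _window_scores(shuffle, tr.sequence)
        for start in np.flatnonzero(scores <= max_score):
            profile = profiles.get(tr.id)
            if profile is None or profile.position_counts.sum() == 0:
                continue
            pos, count = site_signal(
                profile, expected_cleavage_position(int(start), L), tolerance
            )
            if count == 0:
                continue
            cat = categorize(profile, pos)
            cand = (float(scores[start]), int(cat))
            if best is None or cand < best:
                best = cand
    return best


def cleavage_pvalue(
    call_score: float,
    call_category: int,
    srna_sequence: str,
    transcripts: Sequence[Transcript],
    profiles: dict[str, DegradomeProfile],
    n_shuffles: int = 100,
    seed: int = 0,
    max_score: float = DEFAULT_MAX_SCORE,
    tolerance: int = 1,
) -> float:
    """Empirical shuffle-null p-value of a cleavage call.

    p = (1 + b) / (n_shuffles + 1), where b counts dinucleotide-preserving
    shuffles of the sRNA that achieve, anywhere in the transcriptome, a site
    with score <= the observed score whose degradome category is <= the
    observed category.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_shuffles):
        shuffled = dinucleotide_shuffle(srna_sequence, rng)
        hit = _best_shuffle_hit(shuffled, transcripts, profiles, max_score, tolerance)
        if hit is not None and hit[0] <= call_score and hit[1] <= call_category:
            b += 1
    return (1 + b) / (n_shuffles + 1)


def call_targets(
    srnas: Sequence[SrnaCatalogEntry],
    transcripts: Sequence[Transcript],
    profiles: dict[str, DegradomeProfile],
    params: DegradomeParams | None = None,
) -> list[CleavageCall]:
    """Full cleavage-calling pipeline: candidate sites -> site reads ->
    category -> shuffle p-value -> validity flag.

    Both valid and invalid calls are returned, valid first, then by
    ascending p-value and score.
    """
    params = params or DegradomeParams()
    library_size = max(
        1, sum(int(p.position_counts.sum()) for p in profiles.values())
    )
    calls: list[CleavageCall] = []
    for si, srna in enumerate(srnas):
        for tr in transcripts:
            for aln in find_candidate_sites(srna, tr, max_score=params.max_score):
                profile = profiles.get(tr.id)
                if profile is None or profile.position_counts.sum() == 0:
                    continue
                pos, count = site_signal(
                    profile, aln.expected_cleavage_position, params.site_tolerance
                )
                if count == 0:
                    continue
                category = categorize(profile, pos)
                p = cleavage_pvalue(
                    aln.allen_score,
                    category,
                    srna.sequence,
                    transcripts,
                    profiles,
                    n_shuffles=params.n_shuffles,
                    seed=params.seed + si,
                    max_score=params.max_score,
                    tolerance=params.site_tolerance,
                )
                calls.append(
                    CleavageCall(
                        alignment=aln,
                        site_reads=count,
                        site_position=pos,
                        category=category,
                        p_value=p,
                        site_rpm=count / library_size * 1e6,
                    )
                )
    calls.sort(
        key=lambda c: (not c.valid, c.p_value, c.alignment.allen_score, c.alignment.srna_id)
    )
    return calls


def tplot_data(
    profile: DegradomeProfile, calls: Iterable[CleavageCall]
) -> pd.DataFrame:
    """Per-position degradome series with called cleavage sites flagged.

    The flagged rows are the sites a T-plot marks with asterisks; the table
    is ready for TSV export / plotting.
    """
    flagged_positions = {
        c.site_position
        for c in calls
        if c.alignment.transcript_id == profile.transcript_id
    }
    n = len(profile.position_counts)
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "count": profile.position_counts,
            "flagged": [pos in flagged_positions for pos in range(1, n + 1)],
        }
    )


def calls_table(calls: Sequence[CleavageCall]) -> pd.DataFrame:
    """Flatten cleavage calls to the report table (one row per event)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "srna": c.alignment.srna_id,
                "transcript": c.alignment.transcript_id,
                "site": c.site_position,
                "score": c.alignment.allen_score,
                "site_reads": c.site_reads,
                "site_rpm": c.site_rpm,
                "category": c.category,
                "p": c.p_value,
                "valid": c.valid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "srna", "transcript", "site", "score", "site_reads",
            "site_rpm", "category", "p", "valid",
        ],
    )
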