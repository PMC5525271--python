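"""Deterministic synthetic inputs with ground truth for every pipeline stage.

The generator emulates the structure of a de-etiolation sRNA study at desk
scale: a small transcriptome with planted miRNA target sites, PHAS loci
shedding 21-nt reads on a known register, three-replicate time-course read
counts over W0/W1/W3/W6/W12/W24 following three light-response archetypes
(I: induced from near-zero darkness expression, II: gradual up-regulation,
III: ~2-fold decline by W24), and dark/light degradome profiles with
Poisson signal peaks at the planted cleavage coordinates over a geometric
background.  Everything derives from one ``numpy`` PCG64 generator seeded
from ``SimulationConfig.seed``, so identical configs give byte-identical
outputs.

What it does NOT emulate: sequencing error, adaptor artifacts, genomic
multi-mapping structure, or realistic transcript sequence composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from photosrna.core_io import (
    AlignedRead,
    Biotype,
    DegradomeProfile,
    ExpressionMatrix,
    SrnaCatalogEntry,
    SrnaClass,
    TIME_POINTS,
    Transcript,
    revcomp,
    write_degradome_tsv,
)
from photosrna.degradome import expected_cleavage_position

PHASE_LENGTH = 21
WINDOW_LENGTH = 251
_LOCUS_MARGIN = 63  # 3 phase cycles of flank around each planted window

# archetype mean-abundance multipliers per time point (see module docstring)
ARCHETYPE_MULTIPLIERS = {
    "I": np.array([0.0, 0.5, 1.5, 3.0, 3.0, 5.0]),
    "II": 2.0 ** np.array([0.0, 0.1, 0.3, 0.4, 0.6, 1.0]),
    "III": 2.0 ** np.array([0.0, 0.0, -0.2, -0.4, -0.7, -1.0]),
    "flat": np.ones(6),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 30
    transcript_length: int = 400
    n_mirnas: int = 80  # 66 light-regulated (archetypes I-III) + 14 flat
    mirna_length: int = 21
    n_phas_loci: int = 3
    phase_fraction: float = 1.0
    phas_reads_per_locus: int = 40
    n_decoy_windows: int = 0
    cluster_archetype_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 1, "II": 15, "III": 50}
    )
    nb_dispersion: float = 0.1
    degradome_signal: float = 10.0
    degradome_noise: float = 0.2
    light_only_fraction: float = 0.1
    te_fraction: float = 0.1
    n_replicates: int = 3
    base_abundance: float = 60.0
    desk_scale: float = 1e4  # divide ~20M-read libraries down to desk size

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_fraction <= 1.0:
            raise ValueError("phase_fraction must lie in [0, 1]")
        for name, size in self.cluster_archetype_sizes.items():
            if size < 0:
                raise ValueError(f"archetype {name!r} size must be >= 0")


@dataclass
class SyntheticWorld:
    """All generated inputs plus the truth tables that describe them."""

    config: SimulationConfig
    transcripts: list[Transcript]
    srnas: list[SrnaCatalogEntry]
    families: dict[str, set[str]]
    archetypes: dict[str, str]
    phas_references: list[Transcript]
    phas_alignments: list[AlignedRead]
    truth_targets: pd.DataFrame
    truth_phas: pd.DataFrame

    @property
    def all_references(self) -> list[Transcript]:
        return self.transcripts + self.phas_references


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_world(config: SimulationConfig) -> SyntheticWorld:
    """Generate transcriptome, sRNA catalog, PHAS loci and truth tables.

    Each miRNA gets one planted target site (the exact reverse complement
    of the miRNA spliced into a transcript); each PHAS locus gets its own
    reference with 21-nt reads whose 5' ends fall in register with
    probability ``phase_fraction``; decoy windows carry the same read load
    at uniform offsets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.mirna_length
    if cfg.transcript_length < 3 * L:
        raise ValueError(
            "transcripts too short to place target sites "
            f"(need >= {3 * L} nt, got {cfg.transcript_length})"
        )

    n_te = int(round(cfg.te_fraction * cfg.n_transcripts))
    transcripts: list[Transcript] = []
    raw_seqs: list[str] = [
        _random_seq(rng, cfg.transcript_length) for _ in range(cfg.n_transcripts)
    ]

    # miRNA catalog with planted sites; targets are assigned round-robin over
    # transcripts and sites never overlap, so every truth row stays intact
    srnas: list[SrnaCatalogEntry] = []
    families: dict[str, set[str]] = {}
    target_rows = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for i in range(cfg.n_mirnas):
        sid = f"syn-miR{i + 1}"
        seq = _random_seq(rng, L)
        srnas.append(SrnaCatalogEntry(sid, seq, srna_class=SrnaClass.miRNA, family=sid))
        families[sid] = {sid}
        t_idx = i % cfg.n_transcripts
        taken = occupied.setdefault(t_idx, [])
        start = None
        for _attempt in range(200):
            cand = int(rng.integers(L, cfg.transcript_length - 2 * L))
            if all(cand + L <= s or cand >= e for s, e in taken):
                start = cand
                break
        if start is None:
            raise ValueError(
                f"cannot place a non-overlapping target site for {sid}: "
                "transcript too short or too crowded"
            )
        taken.append((start, start + L))
        site = revcomp(seq)
        raw_seqs[t_idx] = (
            raw_seqs[t_idx][:start] + site + raw_seqs[t_idx][start + L:]
        )
        light_only = bool(rng.random() < cfg.light_only_fraction)
        target_rows.append(
            {
                "srna_id": sid,
                "transcript_id": f"synT{t_idx + 1}",
                "site_start": start,
                "cleavage_position": expected_cleavage_position(start, L),
                "light_only": light_only,
            }
        )
    for i, seq in enumerate(raw_seqs):
        biotype = Biotype.transposable_element if i < n_te else Biotype.protein_coding
        transcripts.append(Transcript(f"synT{i + 1}", seq, biotype=biotype))

    # archetype assignment: light-regulated archetypes first, remainder flat
    archetypes: dict[str, str] = {}
    ids = [s.srna_id for s in srnas]
    cursor = 0
    for name in ("I", "II", "III"):
        for _ in range(cfg.cluster_archetype_sizes.get(name, 0)):
            if cursor < len(ids):
                archetypes[ids[cursor]] = name
                cursor += 1
    for sid in ids[cursor:]:
        archetypes[sid] = "flat"

    # PHAS loci and decoy windows, one reference each
    phas_refs: list[Transcript] = []
    phas_reads: list[AlignedRead] = []
    phas_rows = []
    ref_len = WINDOW_LENGTH + 2 * _LOCUS_MARGIN
    read_counter = 0
    for j in range(cfg.n_phas_loci + cfg.n_decoy_windows):
        is_locus = j < cfg.n_phas_loci
        rid = f"synPHAS{j + 1}" if is_locus else f"synDECOY{j - cfg.n_phas_loci + 1}"
        ref_seq = _random_seq(rng, ref_len)
        ref = Transcript(rid, ref_seq, biotype=Biotype.TAS_noncoding)
        phas_refs.append(ref)
        ws = _LOCUS_MARGIN
        fraction = cfg.phase_fraction if is_locus else 1.0 / PHASE_LENGTH
        n_cycles = WINDOW_LENGTH // PHASE_LENGTH  # in-register 5' positions per strand
        for _ in range(cfg.phas_reads_per_locus):
            read_counter += 1
            if rng.random() < fraction:
                cycle = int(rng.integers(0, n_cycles))
                coord = ws + PHASE_LENGTH * cycle
            else:
                coord = ws + int(rng.integers(0, WINDOW_LENGTH - PHASE_LENGTH))
            strand = "+" if rng.random() < 0.5 else "-"
            start = coord if strand == "+" else coord - 2
            if start < 0 or start + PHASE_LENGTH > ref_len:
                strand, start = "+", coord
            sub = ref_seq[start : start + PHASE_LENGTH]
            phas_reads.append(
                AlignedRead(
                    read_id=f"phasread{read_counter}",
                    sequence=sub if strand == "+" else revcomp(sub),
                    count=1,
                    ref_id=rid,
                    start=start,
                    end=start + PHASE_LENGTH,
                    strand=strand,
                )
            )
        if is_locus:
            phas_rows.append(
                {"ref_id": rid, "start": ws, "end": ws + WINDOW_LENGTH, "register": 0}
            )

    truth_targets = pd.DataFrame(
        target_rows,
        columns=["srna_id", "transcript_id", "site_start", "cleavage_position", "light_only"],
    )
    truth_phas = pd.DataFrame(phas_rows, columns=["ref_id", "start", "end", "register"])
    return SyntheticWorld(
        config=cfg,
        transcripts=transcripts,
        srnas=srnas,
        families=families,
        archetypes=archetypes,
        phas_references=phas_refs,
        phas_alignments=phas_reads,
        truth_targets=truth_targets,
        truth_phas=truth_phas,
    )


def simulate_timecourse_counts(
    config: SimulationConfig, world: SyntheticWorld
) -> ExpressionMatrix:
    """Negative-binomial replicate counts around archetype mean trajectories.

    Each sRNA draws a lognormal baseline abundance; its per-time-point mean
    is baseline x archetype multiplier.  Counts are gamma-Poisson with
    dispersion ``nb_dispersion`` (the dispersion -> 0 limit returns the
    rounded means exactly).  Library totals emulate ~20 M mapped 20-24 nt
    reads divided by ``desk_scale``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    baselines = {
        s.srna_id: float(cfg.base_abundance * rng.lognormal(0.0, 0.5))
        for s in world.srnas
    }
    table: dict[str, dict[tuple[str, int], float]] = {}
    for srna in world.srnas:
        mult = ARCHETYPE_MULTIPLIERS[world.archetypes[srna.srna_id]]
        means = baselines[srna.srna_id] * mult
        row: dict[tuple[str, int], float] = {}
        for ti, tp in enumerate(TIME_POINTS):
            for rep in range(1, cfg.n_replicates + 1):
                mean = means[ti]
                if cfg.nb_dispersion <= 0:
                    count = int(round(mean))
                elif mean == 0:
                    count = 0
                else:
                    lam = rng.gamma(
                        shape=1.0 / cfg.nb_dispersion,
                        scale=mean * cfg.nb_dispersion,
                    )
                    count = int(rng.poisson(lam))
                row[(tp, rep)] = count
        table[srna.srna_id] = row
    matrix = ExpressionMatrix.from_feature_table(table, unit="raw_count")
    target_total = 20e6 / cfg.desk_scale
    totals = pd.Series(
        {
            col: float(
                max(
                    matrix.values[col].sum(),
                    round(rng.normal(target_total, target_total * 0.05)),
                )
            )
            for col in matrix.values.columns
        }
    )
    totals.index = matrix.values.columns
    matrix.library_totals = totals
    return matrix


def simulate_degradome(
    config: SimulationConfig, world: SyntheticWorld
) -> dict[str, dict[str, DegradomeProfile]]:
    """Dark and light degradome profiles with planted cleavage peaks.

    Every planted target site receives Poisson(``degradome_signal``) 5'-end
    reads at the coordinate opposite sRNA position 10; all positions
    receive geometric background with mean ``degradome_noise``.  Events
    flagged ``light_only`` in the truth table appear only in the light
    library (emulating cleavage detectable only after the light switch).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    out: dict[str, dict[str, DegradomeProfile]] = {}
    for condition in ("dark", "light"):
        profiles: dict[str, np.ndarray] = {
            t.id: np.zeros(len(t), dtype=np.int64) for t in world.transcripts
        }
        if cfg.degradome_noise > 0:
            p = 1.0 / (1.0 + cfg.degradome_noise)
            for t in world.transcripts:
                profiles[t.id] += rng.geometric(p, size=len(t)) - 1
        for _, row in world.truth_targets.iterrows():
            if row["light_only"] and condition == "dark":
                continue
            peak = int(rng.poisson(cfg.degradome_signal))
            profiles[row["transcript_id"]][row["cleavage_position"] - 1] += peak
        total = int(sum(a.sum() for a in profiles.values()))
        out[condition] = {
            tid: DegradomeProfile(tid, arr, library_size=max(total, 1))
            for tid, arr in profiles.items()
        }
    return out


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Write the generated world as plain-text files (FASTA/TSV/GFF3)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "transcriptome.fasta", "w") as fh:
        for t in world.all_references:
            fh.write(f">{t.id}\n{t.sequence}\n")
    with open(out / "srna_catalog.fasta", "w") as fh:
        for s in world.srnas:
            fh.write(f">{s.srna_id}\n{s.sequence}\n")
    fam_rows = [
        {"srna_id": sid, "family": fam, "class": "miRNA"}
        for fam, members in sorted(world.families.items())
        for sid in sorted(members)
    ]
    pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)
    world.truth_targets.to_csv(out / "truth_targets.tsv", sep="\t", index=False)
    world.truth_phas.to_csv(out / "truth_phas.tsv", sep="\t", index=False)
    biotype_rows = [
        {"transcript_id": t.id, "biotype": t.biotype.value}
        for t in world.all_references
    ]
    pd.DataFrame(biotype_rows).to_csv(out / "biotypes.tsv", sep="\t", index=False)
    aln_rows = [
        {
            "read_id": r.read_id,
            "sequence": r.sequence,
            "count": r.count,
            "ref_id": r.ref_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
        }
        for r in world.phas_alignments
    ]
    pd.DataFrame(aln_rows).to_csv(out / "phas_alignments.tsv", sep="\t", index=False)
    degradome = simulate_degradome(world.config, world)
    for condition, profiles in degradome.items():
        write_degradome_tsv(profiles, out / f"degradome_{condition}.tsv")
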