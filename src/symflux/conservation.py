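"""Pairwise-alignment conservation profiling of a sequence family.

Each family member is globally aligned to a single reference sequence
(Needleman–Wunsch, BLOSUM62, affine gaps −10/−1 by default), projected
onto reference coordinates, filtered by regional gap content (alignments
with more than 10% gaps in the region of interest are excluded), and the
surviving set is reduced to a per-reference-column residue frequency
matrix with information content in bits — the matrix a sequence logo is
drawn from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "SequenceRecord",
    "PairwiseAlignment",
    "ConservationProfile",
    "AlignParams",
    "read_fasta",
    "nw_align",
    "filter_by_gaps",
    "conservation_matrix",
    "region_coverage_percent",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_LETTERS = set(AMINO_ACIDS) | {"X"}
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - _VALID_LETTERS
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid letters {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    """A global alignment projected onto reference coordinates.

    ``ref_map[i]`` is the family residue aligned to reference position
    i+1, or '-' when the reference position is deleted in the family
    sequence. Insertions relative to the reference do not appear in the
    map (reference coordinates cannot address them).
    """

    seq_id: str
    ref_map: str
    score: float

    def gap_fraction(self, region: tuple[int, int]) -> float:
        start, end = region
        if not (1 <= start <= end <= len(self.ref_map)):
            raise ValueError(
                f"region {region} outside reference length {len(self.ref_map)}"
            )
        window = self.ref_map[start - 1 : end]
        return window.count(GAP) / len(window)


@dataclass
class ConservationProfile:
    frequencies: pd.DataFrame  # index = reference position, columns = AAs + gap
    information: pd.Series  # bits; NaN where a column holds only gaps
    n_sequences: int


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def nw_align(
    seq: SequenceRecord,
    ref: SequenceRecord,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of ``seq`` to ``ref``.

    Affine gap cost: a run of L gaps scores gap_open + (L-1)*gap_extend.
    The alignment is projected to the reference: every reference position
    maps to exactly one family residue or a gap.
    """
    params = params or AlignParams()
    aligner = _make_aligner(params)
    alignment = aligner.align(ref.residues, seq.residues)[0]
    ref_gapped = str(alignment[0])
    seq_gapped = str(alignment[1])
    ref_map = [
        s for r, s in zip(ref_gapped, seq_gapped) if r != GAP
    ]
    assert len(ref_map) == len(ref)
    return PairwiseAlignment(seq_id=seq.id, ref_map="".join(ref_map), score=float(alignment.score))


def filter_by_gaps(
    alignments: Sequence[PairwiseAlignment],
    region: tuple[int, int],
    max_gap_frac: float = 0.10,
) -> tuple[list[PairwiseAlignment], float]:
    """Keep alignments whose gap fraction inside ``region`` is <= ``max_gap_frac``.

    The boundary is inclusive: exactly 10% gaps is not "more than 10%"
    and is kept. ``region`` is a 1-based inclusive reference interval.
    Returns (kept alignments, kept/total coverage fraction).
    """
    start, end = region
    if start > end or start < 1:
        raise ValueError(f"empty or invalid region {region}")
    if not alignments:
        raise ValueError("no alignments to filter")
    # small numerical guard so 3/30 compares as == 0.10, not > 0.10
    kept = [a for a in alignments if a.gap_fraction(region) <= max_gap_frac + 1e-12]
    return kept, len(kept) / len(alignments)


def conservation_matrix(alignments: Sequence[PairwiseAlignment]) -> ConservationProfile:
    """Per-reference-column residue/gap frequencies and information content.

    Frequencies (including the gap category) sum to 1 per column. The
    information content is log2(20) minus the Shannon entropy of the
    gap-excluded, renormalized residue distribution; a column holding
    only gaps has undefined information, reported as NaN.
    """
    if not alignments:
        raise ValueError("no alignments to profile")
    length = len(alignments[0].ref_map)
    if any(len(a.ref_map) != length for a in alignments):
        raise ValueError("alignments map different reference lengths")
    columns = list(AMINO_ACIDS) + ["X", GAP]
    counts = np.zeros((length, len(columns)))
    col_index = {c: i for i, c in enumerate(columns)}
    for a in alignments:
        for pos, letter in enumerate(a.ref_map):
            counts[pos, col_index[letter]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)

    max_bits = math.log2(20)
    information = np.full(length, np.nan)
    residue_counts = counts[:, : len(AMINO_ACIDS)]  # X carries no conservation signal
    totals = residue_counts.sum(axis=1)
    for pos in range(length):
        if totals[pos] == 0:
            continue
        p = residue_counts[pos] / totals[pos]
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        information[pos] = max_bits - entropy

    index = pd.RangeIndex(1, length + 1, name="position")
    return ConservationProfile(
        frequencies=pd.DataFrame(freq, index=index, columns=columns),
        information=pd.Series(information, index=index, name="bits"),
        n_sequences=len(alignments),
    )


def region_coverage_percent(n_pass: int, n_total: int) -> int:
    """Integer coverage percent, rounded half away from zero (8515/22242 -> 38)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_pass <= n_total):
        raise ValueError("n_pass must be between 0 and n_total")
    return int(math.floor(100.0 * n_pass / n_total + 0.5))
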