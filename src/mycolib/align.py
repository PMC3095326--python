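"""Pairwise sequence identity for amplicon comparison.

Identity is defined on a global alignment with free end gaps (the overlap
semantics of contig assembly): terminal gap columns are excluded, and
identity = matches / aligned columns, with internal gap columns counted as
mismatch columns.  Scoring is match +1, mismatch -1, gap -2 (linear); clone
ends vary in practice, so end gaps are not penalised.

The aligner itself is Biopython's :class:`Bio.Align.PairwiseAligner`.  For
best-reference searches over many equal-length candidates a Hamming-distance
prefilter narrows the candidate set before the full alignment is computed;
this is a screening heuristic in the usearch tradition and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


def make_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> Align.PairwiseAligner:
    """Global aligner with free end gaps and linear gap cost."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.internal_gap_score = gap
    aligner.end_gap_score = 0.0
    return aligner


_DEFAULT_ALIGNER = make_aligner()


@dataclass(frozen=True)
class AlignmentStats:
    """Column statistics of the optimal alignment (terminal gaps excluded)."""

    matches: int
    mismatches: int
    internal_gaps: int
    score: float

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.internal_gaps

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def alignment_stats(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> AlignmentStats:
    """Align two sequences and tabulate match/mismatch/gap columns.

    Terminal gap columns (overhangs where one sequence has not started or has
    already ended) are trimmed before counting.  Characters match only if
    identical, so IUPAC ambiguity codes never match their expansions.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or _DEFAULT_ALIGNER
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    start = 0
    end = len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    matches = mismatches = gaps = 0
    for x, y in zip(ga[start:end], gb[start:end]):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    return AlignmentStats(matches, mismatches, gaps, float(alignment.score))


def pairwise_identity(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
    min_overlap: float = 0.5,
) -> float:
    """Fraction of identical aligned columns between two sequences, in [0, 1].

    Overlap semantics need a guard: with free end gaps the score-optimal
    alignment of two unrelated sequences can be a tiny chance overlap of a
    few perfectly matching bases.  An alignment spanning fewer columns than
    ``min_overlap`` times the shorter sequence is therefore not an
    acceptable overlap and scores identity 0 (the pair is not comparable),
    mirroring the minimum-overlap parameter of contig assemblers.

    The pair is aligned in a canonical order so the value is exactly
    symmetric even when co-optimal alignments exist.
    """
    if (len(b), b) < (len(a), a):
        a, b = b, a
    stats = alignment_stats(a, b, aligner=aligner)
    if stats.columns < min_overlap * min(len(a), len(b)):
        return 0.0
    return stats.identity


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    return int((_seq_to_array(a) != _seq_to_array(b)).sum())


class ReferenceIndex:
    """Best-match search over a fixed panel of reference sequences.

    Equal-length candidates are ranked first by vectorised Hamming identity
    and only the leading ``n_refine`` are re-scored with the full alignment;
    length-mismatched candidates always receive the full alignment.  With
    ``prefilter=False`` every candidate is aligned (the exact, slow route).
    """

    def __init__(
        self,
        sequences: Sequence[str],
        prefilter: bool = True,
        n_refine: int = 5,
        aligner: Align.PairwiseAligner | None = None,
    ):
        if len(sequences) == 0:
            raise ValueError("reference panel is empty")
        self.sequences = list(sequences)
        self.prefilter = prefilter
        self.n_refine = n_refine
        self.aligner = aligner or _DEFAULT_ALIGNER
        self._by_length: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        lengths = np.array([len(s) for s in self.sequences])
        for length in np.unique(lengths):
            idx = np.nonzero(lengths == length)[0]
            mat = np.stack([_seq_to_array(self.sequences[i]) for i in idx])
            self._by_length[int(length)] = (idx, mat)

    def best_match(self, query: str) -> tuple[int, float]:
        """Return (index of best reference, alignment identity to it)."""
        if not query:
            raise ValueError("empty query")
        candidates: list[int]
        if self.prefilter:
            candidates = []
            q = _seq_to_array(query)
            for length, (idx, mat) in self._by_length.items():
                if length == len(query):
                    ham = (mat != q).sum(axis=1)
                    order = np.argsort(ham, kind="stable")[: self.n_refine]
                    candidates.extend(int(i) for i in idx[order])
                else:
                    candidates.extend(int(i) for i in idx)
        else:
            candidates = list(range(len(self.sequences)))
        best_idx, best_ident = -1, -1.0
        for i in candidates:
            ident = pairwise_identity(query, self.sequences[i], aligner=self.aligner)
            if ident > best_ident:
                best_idx, best_ident = i, ident
        return best_idx, best_ident
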