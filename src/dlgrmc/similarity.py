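"""Drug and target similarity construction from raw representations.

Drug–drug similarity is the set-overlap (Jaccard/Tanimoto) coefficient
S(c, c') = |c ∩ c'| / |c ∪ c'| over substructure or fingerprint token
sets supplied by the caller (fingerprinting engines themselves are out of
scope — precomputed similarity files remain the canonical input path).

Target–target similarity is the normalized Smith–Waterman score
S(g, g') = SW(g, g') / sqrt(SW(g, g) · SW(g', g')), computed by exact
local alignment (affine gaps) over amino-acid sequences.  Alignment is
delegated to Bio.Align.PairwiseAligner; defaults are BLOSUM62 with gap
open 10 and gap extend 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SWScoring",
    "jaccard_similarity",
    "smith_waterman_score",
    "normalized_sw",
    "pairwise_similarity_matrix",
    "read_fasta",
    "load_substructure_sets",
    "sequence_similarity_matrix",
    "substructure_similarity_matrix",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


def jaccard_similarity(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b| over token sets.

    Two empty sets are defined as identical (similarity 1); an empty set
    against a non-empty one scores 0.
    """
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class SWScoring:
    """Local-alignment scoring scheme: substitution matrix + affine gaps.

    ``gap_open`` is the (positive) cost of the first gapped residue and
    ``gap_extend`` the cost of each further one, so a length-L gap costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def aligner(self) -> PairwiseAligner:
        al = PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load(self.matrix)
        al.open_gap_score = -self.gap_open
        al.extend_gap_score = -self.gap_extend
        return al


_DEFAULT_SCORING = SWScoring()


def _normalize_sequence(seq: str) -> str:
    seq = str(seq).strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    return seq


def smith_waterman_score(
    g: str, g2: str, scoring: SWScoring = _DEFAULT_SCORING
) -> float:
    """Optimal local-alignment score of two amino-acid sequences.

    Exact dynamic programming (no heuristics); symmetric in its arguments
    and always ≥ 0 (the empty alignment is admissible).
    """
    g, g2 = _normalize_sequence(g), _normalize_sequence(g2)
    return float(scoring.aligner().score(g, g2))


def normalized_sw(g: str, g2: str, scoring: SWScoring = _DEFAULT_SCORING) -> float:
    """SW(g, g') / sqrt(SW(g, g) · SW(g', g')), in [0, 1].

    Self-similarity is exactly 1.  If the ratio ever exceeds 1 (possible
    only for unusual scoring schemes) it is clipped with a warning.
    """
    al = scoring.aligner()
    g, g2 = _normalize_sequence(g), _normalize_sequence(g2)
    self_a, self_b = float(al.score(g, g)), float(al.score(g2, g2))
    if self_a <= 0 or self_b <= 0:
        raise ValueError("zero self-alignment score; cannot normalize")
    if g == g2:
        return 1.0
    s = float(al.score(g, g2)) / float(np.sqrt(self_a * self_b))
    if s > 1.0:
        if s > 1.0 + 1e-12:
            warnings.warn(
                f"normalized alignment score {s:.6g} exceeds 1; clipping",
                stacklevel=2,
            )
        s = 1.0
    return s


def pairwise_similarity_matrix(
    records: Sequence[tuple[str, object]],
    scorer: Callable[[object, object], float],
) -> tuple[tuple[str, ...], np.ndarray]:
    """Apply a symmetric similarity ``scorer`` to all item pairs.

    ``records`` is a sequence of (id, payload) pairs with unique IDs.
    Returns the ID tuple and a symmetric matrix with unit diagonal and
    entries clipped to [0, 1].
    """
    ids = tuple(r[0] for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate IDs in records")
    n = len(records)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = float(scorer(records[i][1], records[j][1]))
    return ids, np.clip(S, 0.0, 1.0)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file, uppercased."""
    records = [(rec.id, _normalize_sequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def load_substructure_sets(path: str | Path) -> list[tuple[str, frozenset]]:
    """Load substructure/fingerprint token sets from a JSON mapping
    ``{drug_id: [token, ...]}``; duplicates within a list collapse."""
    with open(path) as fh:
        data = json.load(fh)
    return [(str(k), frozenset(v)) for k, v in data.items()]


def sequence_similarity_matrix(
    records: Sequence[tuple[str, str]], scoring: SWScoring = _DEFAULT_SCORING
) -> tuple[tuple[str, ...], np.ndarray]:
    """Normalized Smith–Waterman similarity over all sequence pairs."""
    return pairwise_similarity_matrix(
        records, lambda a, b: normalized_sw(a, b, scoring)
    )


def substructure_similarity_matrix(
    records: Sequence[tuple[str, frozenset]]
) -> tuple[tuple[str, ...], np.ndarray]:
    """Jaccard similarity over all substructure-set pairs."""
    return pairwise_similarity_matrix(records, jaccard_similarity)
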