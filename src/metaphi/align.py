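"""Local protein alignment: bit scores S' and E-values for bin attribution.

A peptide's candidate proteins are aligned against the protein complement
of each taxonomic bin; the candidate with the lowest E-value (< 0.01)
defines the peptide-bin association whose bit score S' enters the phi
normalization. Alignment is exhaustive Smith-Waterman under affine gaps
(via Biopython's PairwiseAligner), which at desk scale replaces a
heuristic search tool without changing the optimum; precomputed tabular
alignment results can be substituted instead.

Bit-score / E-value conversion uses the Karlin-Altschul statistics
conventional for gapped BLOSUM62 with gap open 11 / extend 1
(lambda = 0.267, K = 0.041):

    bits = (lambda * raw - ln K) / ln 2
    E    = m * n * 2**(-bits)

with m the query length and n the total residue count of the bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from metaphi.model import BinAlignment, TaxonBin

#: Evalue threshold below which a peptide-bin alignment qualifies for phi.
DEFAULT_EVALUE_GATE = 0.01


def _blosum62_x0() -> substitution_matrices.Array:
    """BLOSUM62 with 'X' (unknown residue) scored 0 against everything."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine-gap and Karlin-Altschul parameters.

    A gap of length g costs ``gap_open + g * gap_extend`` (the BLAST
    convention, where the opening penalty is charged in addition to the
    per-residue extension).
    """

    matrix: substitution_matrices.Array = field(default_factory=_blosum62_x0)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        cached = getattr(self, "_aligner", None)
        if cached is not None:
            return cached
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score for the first gapped
        # position, so first-position cost = gap_open + gap_extend.
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        object.__setattr__(self, "_aligner", a)
        return a


DEFAULT_SCHEME = ScoringScheme()


def _check_sequence(seq: str, what: str, alphabet: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"illegal character {ch!r} at position {i + 1} of {what}")


def local_align(
    query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[int, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Optimal local (Smith-Waterman) alignment score under affine gaps.

    Returns ``(raw_score, spans)`` where spans pairs the aligned query and
    subject segments ``((qstart, qend), (sstart, send))`` (0-based,
    end-exclusive) of one optimal alignment. Empty input gives (0, []);
    an all-negative scoring situation gives the empty local alignment.
    """
    if not query or not subject:
        return 0, []
    alphabet = str(scheme.matrix.alphabet)
    _check_sequence(query, "query", alphabet)
    _check_sequence(subject, "subject", alphabet)
    aligner = scheme.aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return 0, []
    aln = next(iter(aligner.align(query, subject)))
    spans = [
        ((int(q[0]), int(q[1])), (int(s[0]), int(s[1])))
        for q, s in zip(aln.aligned[0], aln.aligned[1])
    ]
    return int(round(score)), spans


def raw_score(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Alignment score only (no traceback); used in the all-pairs bin scan."""
    if not query or not subject:
        return 0
    s = scheme.aligner().score(query, subject)
    return int(round(s)) if s > 0 else 0


def bit_score(raw: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul normalized score in bits; increasing in raw score."""
    if raw < 0:
        raise ValueError("raw score must be >= 0")
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2.0)


def e_value(bits: float, query_len: int, db_len: int) -> float:
    """Expected chance alignments at this bit score in an m x n search space."""
    if query_len < 1 or db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return float(query_len) * float(db_len) * math.pow(2.0, -bits)


def best_bin_alignment(
    peptide: str,
    candidates: Sequence[tuple[str, str]],
    bin_: TaxonBin,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_gate: float = DEFAULT_EVALUE_GATE,
) -> Optional[BinAlignment]:
    """Select the candidate with the lowest-E-value alignment to this bin.

    Each candidate protein is aligned against every bin protein; the
    candidate's E-value uses its best raw score, its own length as query
    length, and the bin's total residue count as database length. Only
    alignments with E < ``evalue_gate`` are considered; ties on E-value
    break to the higher bit score, then the lexicographically smaller
    candidate id, making the result independent of input order.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    db_len = bin_.total_residues
    best: Optional[BinAlignment] = None
    for cand_id, cand_seq in sorted(candidates):
        if not cand_seq:
            continue
        raw = max(raw_score(cand_seq, prot_seq, scheme) for _, prot_seq in bin_.proteins)
        bits = bit_score(raw, scheme)
        ev = e_value(bits, len(cand_seq), db_len)
        if ev >= evalue_gate:
            continue
        contender = BinAlignment(
            peptide=peptide, bin_id=bin_.bin_id, candidate_id=cand_id,
            raw_score=raw, bit_score=bits, evalue=ev,
        )
        if best is None or (contender.evalue, -contender.bit_score, contender.candidate_id) < (
            best.evalue, -best.bit_score, best.candidate_id
        ):
            best = contender
    return best


def best_bin_alignment_from_table(
    peptide: str,
    candidate_ids: Sequence[str],
    alignments: pd.DataFrame,
    subject_to_bin: dict[str, str],
    bin_id: str,
    evalue_gate: float = DEFAULT_EVALUE_GATE,
) -> Optional[BinAlignment]:
    """Same selection rule, driven by a precomputed tabular alignment file.

    ``alignments`` is a 12-column table (see io.read_tabular_alignments)
    whose queries are candidate ids and whose subjects map to bins via
    ``subject_to_bin``.
    """
    cand_set = set(candidate_ids)
    best: Optional[BinAlignment] = None
    for row in alignments.itertuples(index=False):
        if row.query not in cand_set:
            continue
        if subject_to_bin.get(str(row.subject)) != bin_id:
            continue
        ev = float(row.evalue)
        if ev >= evalue_gate:
            continue
        contender = BinAlignment(
            peptide=peptide, bin_id=bin_id, candidate_id=str(row.query),
            raw_score=0, bit_score=float(row.bitscore), evalue=ev,
        )
        if best is None or (contender.evalue, -contender.bit_score, contender.candidate_id) < (
            best.evalue, -best.bit_score, best.candidate_id
        ):
            best = contender
    return best
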