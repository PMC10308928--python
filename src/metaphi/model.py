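"""Core domain types shared by every pipeline stage.

Symbols carried by these types
------------------------------
``PeptideRecord`` holds the NSAF ingredients: the peptide index *N*, its
spectral count *D_N*, the mean homolog length *L_N* (residues), and
``nsaf`` = (D_N / L_N) / sum_i (D_i / L_i) over the *n* peptides identified
in a sample.

``BinAlignment`` holds the bin-attribution ingredients: the bit score *S'*
of the best candidate-vs-bin local alignment, its E-value, and the min-max
normalized score (S' - S'_min) / (S'_max - S'_min) taken across a peptide's
qualifying (E < 0.01) bins.

``QuantMatrix`` holds the aggregated quantities phi_P (per-function sums of
phi_N = NSAF_N x normalized S'), Phi_bin (phi_P scaled to the maximum
across bins), and Phi_P (phi_P scaled to the maximum across functions
within a bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

#: The 20 standard amino acids. 'X' (unknown) is tolerated in sequences but
#: not in peptides, which come from spectral matching of real residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

UNASSIGNED = "unassigned"


def canonical_peptide(peptide: str) -> str:
    """Collapse isobaric residues for peptide identity.

    Leucine and isoleucine have identical mass and are indistinguishable by
    conventional shotgun MS, so peptides differing only by L/I are the same
    observation; the canonical form maps L to I.
    """
    return peptide.upper().replace("L", "I")


@dataclass(frozen=True)
class PSM:
    """One accepted peptide identification for one fragmentation spectrum.

    ``candidate_ids`` lists the database proteins (reads and/or contigs)
    that contain the peptide; one spectrum may match several.
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    candidate_ids: tuple[str, ...]
    search_score: float
    search_evalue: float
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if len(self.peptide) < 5:
            raise ValueError(
                f"peptide {self.peptide!r} shorter than 5 residues "
                f"(spectrum {self.spectrum_id})"
            )
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"peptide {self.peptide!r} contains non-standard residues {sorted(bad)}"
            )
        if not self.candidate_ids:
            raise ValueError(f"PSM {self.spectrum_id} has no candidate proteins")
        if len(set(self.candidate_ids)) != len(self.candidate_ids):
            raise ValueError(f"PSM {self.spectrum_id} has duplicate candidate ids")
        if self.search_evalue < 0:
            raise ValueError("search E-value must be >= 0")


@dataclass
class PeptideRecord:
    """Per-sample spectral evidence for one (canonical) peptide."""

    peptide: str
    D: int
    L: float
    nsaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError(f"spectral count must be >= 1, got {self.D}")
        if self.L <= 0:
            raise ValueError(f"mean homolog length must be > 0, got {self.L}")


@dataclass(frozen=True)
class CandidateHit:
    """One homolog hit of a PSM-protein candidate (e.g., a RefSeq subject).

    ``rank`` is 1-based in descending bit-score order; ``gene_family`` and
    ``description`` are the hit's orthologous-group annotation when known.
    """

    candidate_id: str
    subject_id: str
    bit_score: float
    rank: int
    gene_family: Optional[str] = None
    description: Optional[str] = None
    subject_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("hit rank is 1-based")


@dataclass
class BinAlignment:
    """Best candidate-protein alignment between a peptide and one bin."""

    peptide: str
    bin_id: str
    candidate_id: str
    raw_score: int
    bit_score: float
    evalue: float
    norm_score: Optional[float] = None

    def qualifies(self, evalue_gate: float = 0.01) -> bool:
        return self.evalue < evalue_gate


@dataclass
class Metaprotein:
    """A set of PSMs whose surviving candidate hits all share one
    functional description string — the pipeline's quantification unit."""

    label: str
    psm_ids: frozenset[str]
    gene_family: Optional[str] = None
    functional_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.psm_ids:
            raise ValueError(f"metaprotein {self.label!r} has no member PSMs")


@dataclass
class FunctionalGroupMap:
    """Curated mapping (gene family, description) -> Functional Group label.

    Rows lacking a gene family act as description-only wildcards: any
    annotation with that description maps to the row's group. Unmapped
    pairs return ``"unassigned"``.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    by_description: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self.entries.values()) | frozenset(self.by_description.values())

    def lookup(self, gene_family: Optional[str], description: Optional[str]) -> str:
        if description is None:
            return UNASSIGNED
        if gene_family is not None:
            group = self.entries.get((gene_family, description))
            if group is not None:
                return group
        return self.by_description.get(description, UNASSIGNED)


@dataclass(frozen=True)
class TaxonBin:
    """A taxonomic sequence bin: the protein complement of one taxon."""

    bin_id: str
    taxon_label: str
    proteins: tuple[tuple[str, str], ...]  # (protein_id, sequence)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"bin {self.bin_id} is empty")
        for pid, seq in self.proteins:
            if not seq or seq != seq.upper():
                raise ValueError(f"bin {self.bin_id} protein {pid}: bad sequence")

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, seq in self.proteins)


#: Allowed QuantMatrix kinds.
MATRIX_KINDS = ("nsaf", "phi", "phi_bin", "phi_p")


@dataclass
class QuantMatrix:
    """Rectangular store of NSAF / phi / Phi values.

    Rows are function labels (metaproteins or Functional Groups), columns
    are bins or samples, depending on the stage. Backed by a pandas
    DataFrame so downstream multivariate code can consume it directly.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}")
        if (self.data.to_numpy(dtype=float) < -1e-12).any() and self.kind != "phi":
            # phi_bin/phi_p/nsaf are nonnegative by construction; ribosome-
            # normalized matrices are returned as plain DataFrames instead.
            raise ValueError(f"negative values in {self.kind} matrix")
        self.data = self.data.astype(float)

    @property
    def row_keys(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_keys(self) -> list[str]:
        return list(self.data.columns)

    def value(self, row: str, col: str) -> float:
        return float(self.data.at[row, col])


def align_frames(frames: Sequence[pd.DataFrame], fill: float = 0.0) -> list[pd.DataFrame]:
    """Align DataFrames on the union of their row/column labels.

    Missing cells are filled with ``fill`` (missing functions contribute
    zero signal, not NA, so averages and multivariate inputs stay dense).
    """
    if not frames:
        raise ValueError("no frames to align")
    rows = sorted(set().union(*(f.index for f in frames)))
    cols = sorted(set().union(*(f.columns for f in frames)))
    return [f.reindex(index=rows, columns=cols, fill_value=fill).astype(float) for f in frames]
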