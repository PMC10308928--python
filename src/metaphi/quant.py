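"""The quantification core: NSAF and the phi / Phi metric family.

For peptide N in one sample:

    NSAF_N = (D_N / L_N) / sum_i (D_i / L_i)

with D_N its spectral count, L_N the mean length of the homolog subject
sequences of its candidates, and the sum over all n identified peptides
(annotated or not), so NSAF sums to 1 per sample.

For each (peptide, bin) the best candidate alignment's bit score S' is
min-max normalized across the peptide's qualifying bins (E-value < 0.01):

    phi_N = NSAF_N * (S' - S'_min) / (S'_max - S'_min)   if E < 0.01
    phi_N = 0                                            otherwise

phi is summed per function P (metaprotein or Functional Group) and bin,
then rescaled:

    Phi_bin = phi_P / phi_P,max-over-bins        (per-function row)
    Phi_P   = phi_P / phi_P,max-over-functions   (per-bin column)

An all-zero phi row or column yields Phi = 0 everywhere; every nonzero
row/column attains exactly 1. Two published edge behaviors are kept as-is:
with a degenerate normalization range (one qualifying bin, or all
qualifying S' equal) every qualifying bin scores 1; with a nondegenerate
range the weakest qualifying bin receives a normalized score of 0 and so
contributes no phi even though it aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from metaphi.align import DEFAULT_EVALUE_GATE
from metaphi.model import BinAlignment, PeptideRecord, QuantMatrix, align_frames

log = logging.getLogger(__name__)


@dataclass
class PhiRecord:
    """phi_N for one (peptide, bin) in one sample."""

    peptide: str
    bin_id: str
    phi_n: float
    nsaf: float
    norm_score: float = 0.0


def compute_nsaf(peptides: Sequence[PeptideRecord]) -> list[PeptideRecord]:
    """Set each record's NSAF; the values sum to 1 across the sample.

    Spectral counts are normalized to mean homolog length because longer
    proteins shed more tryptic peptides and are more likely to be observed.
    """
    if not peptides:
        raise ValueError("no peptides: NSAF undefined")
    saf = np.array([p.D / p.L for p in peptides], dtype=float)
    total = saf.sum()
    if total <= 0:
        raise ValueError("nonpositive SAF total")
    for p, v in zip(peptides, saf / total):
        p.nsaf = float(v)
    return list(peptides)


def normalize_bin_scores(
    alignments: Sequence[Optional[BinAlignment]],
    evalue_gate: float = DEFAULT_EVALUE_GATE,
) -> list[Optional[BinAlignment]]:
    """Min-max normalize S' across one peptide's qualifying bins.

    Qualifying means present with E < ``evalue_gate``; only qualifying
    alignments define S'_min and S'_max. Non-qualifying or absent entries
    keep norm_score unset (phi will be 0). With no spread (a single
    qualifying bin, or all qualifying S' equal) every qualifying bin gets
    norm_score 1: with no range, every qualifying bin is the maximum.
    """
    qualifying = [a for a in alignments if a is not None and a.qualifies(evalue_gate)]
    if qualifying:
        smin = min(a.bit_score for a in qualifying)
        smax = max(a.bit_score for a in qualifying)
        span = smax - smin
        for a in qualifying:
            a.norm_score = 1.0 if span == 0 else (a.bit_score - smin) / span
    return list(alignments)


def compute_phi_n(
    nsaf: float,
    alignment: Optional[BinAlignment],
    evalue_gate: float = DEFAULT_EVALUE_GATE,
) -> float:
    """phi_N = NSAF_N x normalized S' if the alignment qualifies, else 0."""
    if alignment is None or not alignment.qualifies(evalue_gate):
        return 0.0
    if alignment.norm_score is None:
        raise ValueError("alignment qualifies but norm_score is unset; "
                         "run normalize_bin_scores first")
    return nsaf * alignment.norm_score


def aggregate_phi_p(
    phi_records: Iterable[PhiRecord], membership: Mapping[str, str]
) -> QuantMatrix:
    """Sum phi_N per (function P, bin) into a phi matrix.

    ``membership`` maps peptide -> function label (metaprotein description
    or Functional Group); peptides without membership are skipped.
    """
    cells: dict[tuple[str, str], float] = {}
    bins: set[str] = set()
    for rec in phi_records:
        label = membership.get(rec.peptide)
        if label is None:
            continue
        bins.add(rec.bin_id)
        cells[(label, rec.bin_id)] = cells.get((label, rec.bin_id), 0.0) + rec.phi_n
    rows = sorted({k[0] for k in cells})
    cols = sorted(bins)
    df = pd.DataFrame(0.0, index=rows, columns=cols)
    for (label, bin_id), v in cells.items():
        df.at[label, bin_id] = v
    return QuantMatrix(data=df, kind="phi")


def _scale_rows_to_max(df: pd.DataFrame) -> pd.DataFrame:
    rowmax = df.max(axis=1)
    safe = rowmax.replace(0.0, 1.0)  # all-zero rows stay all-zero
    return df.div(safe, axis=0)


def compute_phi_bin(m: QuantMatrix) -> QuantMatrix:
    """Phi_bin: scale each function's phi row to its maximum across bins."""
    if m.kind != "phi":
        raise ValueError(f"expected a phi matrix, got {m.kind}")
    return QuantMatrix(data=_scale_rows_to_max(m.data), kind="phi_bin")


def compute_phi_function(m: QuantMatrix) -> QuantMatrix:
    """Phi_P: scale each bin's phi column to its maximum across functions."""
    if m.kind != "phi":
        raise ValueError(f"expected a phi matrix, got {m.kind}")
    return QuantMatrix(data=_scale_rows_to_max(m.data.T).T, kind="phi_p")


def ribosome_normalize(m: QuantMatrix, ribosome_label: str = "Ribosome") -> pd.DataFrame:
    """Subtract the ribosomal-protein row from every row of a Phi_bin matrix.

    Ribosomal protein expression proxies overall cellular activity, so the
    difference highlights functions a bin over- or under-expresses
    relative to its activity level. Values lie in [-1, 1]; the result is
    returned as a plain DataFrame because it is no longer nonnegative.
    """
    if m.kind != "phi_bin":
        raise ValueError(f"expected a phi_bin matrix, got {m.kind}")
    if ribosome_label not in m.data.index:
        raise ValueError(f"no {ribosome_label!r} row to normalize against")
    return m.data.sub(m.data.loc[ribosome_label], axis=1)


def average_over_samples(
    matrices: Mapping[str, QuantMatrix], group: Iterable[str]
) -> QuantMatrix:
    """Element-wise mean of per-sample matrices over a sample group.

    Matrices are aligned on the union of their labels first; a function
    absent from one sample contributes 0 to the mean for that sample.
    """
    group = list(group)
    if not group:
        raise ValueError("empty sample group")
    missing = [s for s in group if s not in matrices]
    if missing:
        raise ValueError(f"samples not found: {missing}")
    kinds = {matrices[s].kind for s in group}
    if len(kinds) != 1:
        raise ValueError(f"mixed matrix kinds {kinds}")
    frames = align_frames([matrices[s].data for s in group])
    mean = sum(frames) / len(frames)
    return QuantMatrix(data=mean, kind=kinds.pop())


def to_long(m: QuantMatrix, sample_id: Optional[str] = None) -> pd.DataFrame:
    """Long-format view (sample, function, bin, value) for TSV export."""
    long = m.data.stack().rename("value").reset_index()
    long.columns = ["function", "bin", "value"]
    if sample_id is not None:
        long.insert(0, "sample", sample_id)
    return long
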