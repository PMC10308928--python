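"""From raw PSMs to metaproteins and Functional Groups.

The stages, in pipeline order:

1. ``fdr_filter`` — target-decoy filtering at a q-value cutoff (default 1%).
2. ``filter_top_hits`` / ``subsample_hits`` — per-candidate homolog hits are
   trimmed to those within 10% of the top bit score, then evenly
   subsampled down to at most five in descending bit-score order.
3. ``consistent_description`` — a PSM survives only if every annotated hit
   of every candidate carries the identical functional description string.
4. ``build_metaproteins`` — surviving PSMs are grouped by description into
   metaproteins; ``assign_functional_group`` rolls descriptions up into
   curated Functional Groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from metaphi.model import PSM, CandidateHit, FunctionalGroupMap, Metaprotein

log = logging.getLogger(__name__)

DEFAULT_Q_CUTOFF = 0.01
DEFAULT_TOP_HIT_FRACTION = 0.10
DEFAULT_HIT_CAP = 5


@dataclass
class FDRResult:
    """Outcome of target-decoy filtering."""

    kept: list[PSM]
    q_values: dict[str, float]  # spectrum_id -> q
    threshold_score: float
    n_targets: int = 0
    n_decoys: int = 0


def fdr_filter(psms: Sequence[PSM], q_cutoff: float = DEFAULT_Q_CUTOFF) -> FDRResult:
    """Filter target PSMs at a target-decoy q-value cutoff.

    At each candidate score threshold t the false discovery rate is
    estimated as (#decoys >= t) / (#targets >= t); a PSM's q-value is the
    minimum estimated FDR over all thresholds at or below its score, which
    makes q non-increasing in score. Kept PSMs are the targets with
    q <= ``q_cutoff``.
    """
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    if not decoys:
        raise ValueError("no decoy PSMs present: target-decoy FDR is undefined")
    if not targets:
        raise ValueError("no target PSMs present")

    order = np.argsort([-p.search_score for p in psms], kind="stable")
    sorted_psms = [psms[i] for i in order]
    is_target = np.array([not p.is_decoy for p in sorted_psms])
    scores = np.array([p.search_score for p in sorted_psms])

    n_t = np.cumsum(is_target)
    n_d = np.cumsum(~is_target)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), 1.0)
    fdr = np.minimum(fdr, 1.0)
    # score ties share one threshold: propagate the FDR at the last index
    # of each tied block before taking the reverse cumulative minimum
    for i in range(len(scores) - 2, -1, -1):
        if scores[i] == scores[i + 1]:
            fdr[i] = fdr[i + 1]
    q = np.minimum.accumulate(fdr[::-1])[::-1]

    q_values = {p.spectrum_id: float(q[i]) for i, p in enumerate(sorted_psms)}
    kept = [p for i, p in enumerate(sorted_psms) if is_target[i] and q[i] <= q_cutoff]
    threshold = min((p.search_score for p in kept), default=math.inf)
    log.info("FDR filter: kept %d / %d targets at q <= %g (%d decoys)",
             len(kept), len(targets), q_cutoff, len(decoys))
    return FDRResult(kept=kept, q_values=q_values, threshold_score=threshold,
                     n_targets=len(targets), n_decoys=len(decoys))


def filter_top_hits(
    hits: Sequence[CandidateHit], top_fraction: float = DEFAULT_TOP_HIT_FRACTION
) -> list[CandidateHit]:
    """Retain hits with bit score within ``top_fraction`` of the maximum.

    "Within the top 10%" means bit_score >= (1 - top_fraction) * max;
    input is sorted by descending bit score if not already, and order is
    preserved among survivors.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: -h.bit_score)
    cutoff = (1.0 - top_fraction) * ordered[0].bit_score
    return [h for h in ordered if h.bit_score >= cutoff]


def subsample_hits(hits: Sequence[CandidateHit], cap: int = DEFAULT_HIT_CAP) -> list[CandidateHit]:
    """Evenly subsample at most ``cap`` hits in descending bit-score order.

    For m retained hits with m > cap, the 1-based ranks kept are
    floor(1 + i*(m-1)/(cap-1)) for i = 0..cap-1, which always includes the
    first and last hit (for m = 500, cap = 5: ranks 1, 125, 250, 375, 500).
    """
    if cap < 2:
        raise ValueError("subsample cap must be >= 2")
    m = len(hits)
    if m <= cap:
        return list(hits)
    ranks = [math.floor(1 + i * (m - 1) / (cap - 1)) for i in range(cap)]
    return [hits[r - 1] for r in ranks]


def consistent_description(
    psm: PSM,
    hits_per_candidate: Mapping[str, Sequence[CandidateHit]],
    casefold: bool = False,
) -> Optional[str]:
    """Return the functional description shared by all annotated hits.

    The description is returned only if at least one hit across the PSM's
    candidates is annotated and every annotated hit carries the identical
    description string; otherwise None. Matching is exact and
    case-sensitive by default; ``casefold=True`` ignores case (the first
    annotated hit's spelling is returned).
    """
    descriptions: dict[str, str] = {}
    for cand in psm.candidate_ids:
        for hit in hits_per_candidate.get(cand, ()):
            if hit.description is not None:
                key = hit.description.casefold() if casefold else hit.description
                descriptions.setdefault(key, hit.description)
                if len(descriptions) > 1:
                    return None
    if len(descriptions) == 1:
        return next(iter(descriptions.values()))
    return None


def build_metaproteins(
    psms: Sequence[PSM], descriptions: Mapping[str, str]
) -> list[Metaprotein]:
    """Group retained PSMs sharing one description into metaproteins.

    ``descriptions`` maps spectrum_id -> agreed description for annotated
    PSMs; PSMs absent from it are excluded (but reported). The resulting
    metaproteins partition the annotated PSMs.
    """
    members: dict[str, set[str]] = {}
    n_unannotated = 0
    for psm in psms:
        desc = descriptions.get(psm.spectrum_id)
        if desc is None:
            n_unannotated += 1
            continue
        members.setdefault(desc, set()).add(psm.spectrum_id)
    if n_unannotated:
        log.info("build_metaproteins: %d PSMs without consistent annotation excluded "
                 "(still counted in the NSAF denominator)", n_unannotated)
    return [Metaprotein(label=label, psm_ids=frozenset(ids))
            for label, ids in sorted(members.items())]


def assign_functional_group(
    gene_family: Optional[str], description: str, fgmap: FunctionalGroupMap
) -> str:
    """Map a (gene family, description) annotation to its Functional Group.

    Exact pair lookup first; rows curated without a gene family match on
    description alone; anything else is "unassigned".
    """
    return fgmap.lookup(gene_family, description)
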