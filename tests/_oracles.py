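"""Independent reference implementations used to cross-check the package.

These deliberately share no code with metaphi: the alignment oracle
enumerates alignment extensions recursively instead of running the
vectorized affine-gap machinery; the FDR oracle sweeps every threshold
quadratically; the phi oracle is a direct, scalar transcription of the
metric definitions.
"""

from __future__ import annotations

from functools import lru_cache


def sw_oracle(query: str, subject: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Best local alignment score by recursive path enumeration.

    A gap run of length g costs gap_open + g * gap_extend. Alignments may
    start and stop anywhere; the empty alignment scores 0.
    """

    n, m = len(query), len(subject)

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, last: str) -> float:
        best = 0.0  # stop the alignment here
        if i < n and j < m:
            best = max(best, matrix[query[i], subject[j]] + extend(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if last == "I" else gap_open + gap_extend
            best = max(best, -cost + extend(i + 1, j, "I"))
        if j < m:
            cost = gap_extend if last == "D" else gap_open + gap_extend
            best = max(best, -cost + extend(i, j + 1, "D"))
        return best

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, extend(i, j, "start"))
    extend.cache_clear()
    return int(best)


def fdr_sweep_oracle(
    scores: list[float], is_decoy: list[bool], q_cutoff: float
) -> tuple[list[int], dict[int, float]]:
    """Quadratic target-decoy sweep: kept target indices and q per index.

    FDR(t) = #decoys >= t / #targets >= t over every observed score
    threshold t; q(i) = min FDR over thresholds at or below score i.
    """
    thresholds = sorted(set(scores))

    def fdr_at(t: float) -> float:
        n_d = sum(1 for s, d in zip(scores, is_decoy) if d and s >= t)
        n_t = sum(1 for s, d in zip(scores, is_decoy) if not d and s >= t)
        if n_t == 0:
            return 1.0
        return min(1.0, n_d / n_t)

    q: dict[int, float] = {}
    for i, s in enumerate(scores):
        q[i] = min(fdr_at(t) for t in thresholds if t <= s)
    kept = [i for i, s in enumerate(scores) if not is_decoy[i] and q[i] <= q_cutoff]
    return kept, q


def phi_oracle(
    nsaf: dict[str, float],
    bits: dict[tuple[str, str], float],
    evalues: dict[tuple[str, str], float],
    membership: dict[str, str],
    bins: list[str],
    gate: float = 0.01,
):
    """Scalar transcription of the phi metric chain.

    Takes per-(peptide, bin) bit scores/E-values (absent pairs = no
    alignment) and returns (phi_P, Phi_bin, Phi_P) as dicts keyed by
    (function, bin).
    """
    phi_n: dict[tuple[str, str], float] = {}
    for pep in nsaf:
        qual = [b for b in bins
                if (pep, b) in bits and evalues.get((pep, b), 1.0) < gate]
        if qual:
            smin = min(bits[(pep, b)] for b in qual)
            smax = max(bits[(pep, b)] for b in qual)
        for b in bins:
            if b not in qual:
                phi_n[(pep, b)] = 0.0
            elif smax == smin:
                phi_n[(pep, b)] = nsaf[pep] * 1.0
            else:
                phi_n[(pep, b)] = nsaf[pep] * (bits[(pep, b)] - smin) / (smax - smin)

    functions = sorted(set(membership.values()))
    phi_p = {(f, b): 0.0 for f in functions for b in bins}
    for pep, f in membership.items():
        for b in bins:
            phi_p[(f, b)] += phi_n.get((pep, b), 0.0)

    phi_bin = {}
    for f in functions:
        mx = max(phi_p[(f, b)] for b in bins)
        for b in bins:
            phi_bin[(f, b)] = 0.0 if mx == 0 else phi_p[(f, b)] / mx
    phi_fn = {}
    for b in bins:
        mx = max(phi_p[(f, b)] for f in functions)
        for f in functions:
            phi_fn[(f, b)] = 0.0 if mx == 0 else phi_p[(f, b)] / mx
    return phi_p, phi_bin, phi_fn


def welch_oracle(x, y):
    """Hand transcription of Welch's statistic and Satterthwaite df."""
    import math

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
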