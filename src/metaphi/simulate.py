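"""Synthetic-community generator with known ground truth.

The generator emulates the statistical structure the phi metrics assume:
several taxonomic sequence bins carrying diverged orthologs of a set of
functions, candidate proteins derived from the expressed bin sequences,
tryptic peptides, per-sample spectral counts with ecotype-specific
multiplicative expression effects and negative-binomial noise, decoy PSMs
scoring below targets, and annotation / Functional Group tables.

It does not emulate spectra (m/z, fragmentation), chimeric identifications
or realistic proteome sizes: it exercises the pipeline's logic, it does
not mimic an instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from metaphi import io
from metaphi.model import PSM, FunctionalGroupMap, TaxonBin, canonical_peptide

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Default function roster: a desk-scale slice of the kinds of cellular and
#: biogeochemical functions a soil community expresses, including the
#: ribosomal row used as the activity proxy.
DEFAULT_FUNCTIONS: list[tuple[str, str]] = [
    ("Citrate synthase", "TCA Cycle"),
    ("Aconitate hydratase", "TCA Cycle"),
    ("Ribosomal protein S3", "Ribosome"),
    ("Chaperonin GroEL", "Chaperone"),
    ("Xylose isomerase", "Xylose Assimilation"),
    ("Ribose ABC transporter", "Ribose Transport"),
    ("Glutamine synthetase", "Nitrogen Assimilation"),
    ("Succinoglycan biosynthesis protein", "Succinoglycan Synthesis"),
]

#: Default sample layout: two well-replicated ecotypes plus a smaller
#: third, mirroring a field design where one vegetation class is rarer.
DEFAULT_SAMPLES: list[tuple[str, str]] = [
    ("T1", "tussock"), ("T2", "tussock"), ("T3", "tussock"),
    ("I1", "intertussock"), ("I2", "intertussock"), ("I3", "intertussock"),
    ("S1", "shrub"), ("S2", "shrub"),
]


@dataclass
class SimDesign:
    """Full specification of one synthetic community.

    ``expression`` maps (function label, bin_id, ecotype) to the mean
    total spectral count of that function's protein in that bin; absent
    keys mean zero expression. ``count_noise`` is the negative-binomial
    dispersion alpha (variance = mu + alpha * mu^2); 0 gives Poisson
    counts. ``seed`` fixes all randomness.
    """

    n_bins: int = 4
    protein_length: int = 120
    background_proteins_per_bin: int = 2
    inter_bin_divergence: float = 0.3
    functions: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_FUNCTIONS))
    expression: Optional[dict[tuple[str, str, str], float]] = None
    samples: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_SAMPLES))
    count_noise: float = 0.3
    decoy_fraction: float = 0.5
    candidate_truncation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.inter_bin_divergence <= 1.0):
            raise ValueError("inter_bin_divergence must lie in [0, 1]")
        if self.count_noise < 0 or self.decoy_fraction < 0:
            raise ValueError("count_noise and decoy_fraction must be >= 0")
        if not self.functions or not self.samples:
            raise ValueError("need at least one function and one sample")
        if self.expression is None:
            self.expression = self.default_expression()
        for (fn, b, eco), mu in self.expression.items():
            if mu < 0:
                raise ValueError(f"negative expression mean for {(fn, b, eco)}")

    @property
    def bin_ids(self) -> list[str]:
        return [f"bin{i + 1:02d}" for i in range(self.n_bins)]

    @property
    def ecotypes(self) -> list[str]:
        seen: list[str] = []
        for _, eco in self.samples:
            if eco not in seen:
                seen.append(eco)
        return seen

    def default_expression(self) -> dict[tuple[str, str, str], float]:
        """Each function dominated by one bin (30 spectra) with a weak
        baseline (5) in the others, identical across ecotypes."""
        expr: dict[tuple[str, str, str], float] = {}
        bins = self.bin_ids
        for i, (label, _) in enumerate(self.functions):
            main = bins[i % len(bins)]
            for b in bins:
                for eco in self.ecotypes:
                    expr[(label, b, eco)] = 30.0 if b == main else 5.0
        return expr


@dataclass
class Community:
    """In-memory community: every pipeline input plus the ground truth."""

    design: SimDesign
    bins: list[TaxonBin]
    candidates: list[tuple[str, str]]
    annotations: dict[str, tuple[Optional[str], Optional[str]]]
    fg_map: FunctionalGroupMap
    orthologs: dict[tuple[str, str], str]  # (function label, bin_id) -> sequence
    truth: pd.DataFrame  # peptide, canonical_peptide, function, bin_id, candidate_id


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _diverge(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute a ``divergence`` fraction of residues at random positions.

    Replacements are uniform over the 19 non-identical residues, which
    yields the mildly hostile mismatch scores typical of distant homologs
    and hence a realistic bit-score gradient across bins.
    """
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [a for a in AA20 if a != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def digest(
    protein: str, min_len: int = 6, max_len: int = 40, missed_cleavages: int = 0
) -> list[str]:
    """In-silico tryptic digest: cleave after K or R except before P.

    With ``missed_cleavages`` = c, every concatenation of at most c + 1
    adjacent fragments is included; peptides outside [min_len, max_len]
    are dropped.
    """
    if not protein:
        raise ValueError("empty protein")
    fragments: list[str] = []
    start = 0
    for i, ch in enumerate(protein):
        if ch in "KR" and not (i + 1 < len(protein) and protein[i + 1] == "P"):
            fragments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        fragments.append(protein[start:])
    peptides: list[str] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            pep = "".join(fragments[i : j + 1])
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def generate_community(design: SimDesign) -> Community:
    """Build bins, candidates, annotations, Functional Group map and truth."""
    rng = np.random.default_rng([design.seed, 0])
    bins = design.bin_ids

    base = {label: _random_protein(rng, design.protein_length)
            for label, _ in design.functions}
    orthologs: dict[tuple[str, str], str] = {}
    for label, _ in design.functions:
        for b in bins:
            orthologs[(label, b)] = _diverge(rng, base[label], design.inter_bin_divergence)

    taxon_bins: list[TaxonBin] = []
    for b in bins:
        proteins = [(f"{b}|orf{i + 1:03d}", orthologs[(label, b)])
                    for i, (label, _) in enumerate(design.functions)]
        proteins += [(f"{b}|bg{i + 1:03d}", _random_protein(rng, design.protein_length))
                     for i in range(design.background_proteins_per_bin)]
        taxon_bins.append(TaxonBin(bin_id=b, taxon_label=f"taxon_{b}", proteins=tuple(proteins)))

    candidates: list[tuple[str, str]] = []
    annotations: dict[str, tuple[Optional[str], Optional[str]]] = {}
    fgmap = FunctionalGroupMap()
    truth_rows: list[dict] = []
    for i, (label, group) in enumerate(design.functions):
        family = f"OG{i + 1:04d}"
        fgmap.entries[(family, label)] = group
        for b in bins:
            seq = orthologs[(label, b)]
            if design.candidate_truncation > 0:
                keep = max(20, int(round((1 - design.candidate_truncation) * len(seq))))
                start = int(rng.integers(0, len(seq) - keep + 1))
                seq = seq[start : start + keep]
            cand_id = f"cand|{b}|fn{i + 1:03d}"
            candidates.append((cand_id, seq))
            annotations[cand_id] = (family, label)
            for pep in digest(seq):
                truth_rows.append({
                    "peptide": pep,
                    "canonical_peptide": canonical_peptide(pep),
                    "function": label,
                    "bin_id": b,
                    "candidate_id": cand_id,
                })
    truth = pd.DataFrame(truth_rows)

    if design.n_bins > 1 and design.inter_bin_divergence > 0:
        by_fn_bin = truth.groupby("canonical_peptide")["bin_id"].nunique()
        if (by_fn_bin < 2).all():
            log.warning(
                "inter-bin divergence %.2f leaves no tryptic peptide shared "
                "between bins", design.inter_bin_divergence)

    return Community(design=design, bins=taxon_bins, candidates=candidates,
                     annotations=annotations, fg_map=fgmap, orthologs=orthologs,
                     truth=truth)


def _nb_count(rng: np.random.Generator, mu: float, alpha: float) -> int:
    """Negative-binomial count as a Gamma-Poisson mixture; alpha=0 -> Poisson."""
    if mu <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mu))
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return int(rng.poisson(lam))


def simulate_psm_table(community: Community, design: Optional[SimDesign] = None) -> list[PSM]:
    """Draw per-sample spectral counts and emit target plus decoy PSMs.

    A function's per-bin-per-ecotype mean total count is split evenly over
    its peptides, then each (peptide, sample) count is drawn from a
    negative binomial. Target search scores are drawn well above the decoy
    null so that a 1% FDR keeps most targets, as in a well-calibrated
    search. Decoy PSMs (random peptides, null scores) are appended at
    ``decoy_fraction`` times the target count.
    """
    design = design or community.design
    rng = np.random.default_rng([design.seed, 1])
    containing: dict[str, list[str]] = {}
    for cand_id, seq in community.candidates:
        for pep in set(digest(seq)):
            containing.setdefault(pep, []).append(cand_id)

    psms: list[PSM] = []
    spec_no = 0
    for sample_id, ecotype in design.samples:
        for i, (label, _) in enumerate(design.functions):
            for b in design.bin_ids:
                mu_total = design.expression.get((label, b, ecotype), 0.0)
                peptides = digest(community.orthologs[(label, b)])
                if not peptides or mu_total <= 0:
                    continue
                mu = mu_total / len(peptides)
                for pep in peptides:
                    count = _nb_count(rng, mu, design.count_noise)
                    cands = containing.get(pep)
                    if not cands:
                        continue
                    for _ in range(count):
                        spec_no += 1
                        psms.append(PSM(
                            sample_id=sample_id,
                            spectrum_id=f"{sample_id}:s{spec_no:06d}",
                            peptide=pep,
                            candidate_ids=tuple(cands),
                            search_score=float(rng.normal(60.0, 8.0)),
                            search_evalue=float(10.0 ** rng.uniform(-9, -4)),
                            is_decoy=False,
                        ))
    n_decoys = int(round(design.decoy_fraction * len(psms)))
    sample_ids = [s for s, _ in design.samples]
    for j in range(n_decoys):
        spec_no += 1
        length = int(rng.integers(7, 20))
        psms.append(PSM(
            sample_id=sample_ids[int(rng.integers(len(sample_ids)))],
            spectrum_id=f"decoy:s{spec_no:06d}",
            peptide=_random_protein(rng, length),
            candidate_ids=(f"decoy{j + 1:05d}",),
            search_score=float(rng.normal(25.0, 8.0)),
            search_evalue=float(10.0 ** rng.uniform(-3, 0)),
            is_decoy=True,
        ))
    log.info("simulated %d target + %d decoy PSMs", len(psms) - n_decoys, n_decoys)
    return psms


def write_bundle(community: Community, psms: Sequence[PSM], outdir: io.PathLike) -> Path:
    """Write a complete input bundle plus a truth/ subdirectory."""
    out = Path(outdir)
    (out / "bins").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for b in community.bins:
        io.write_fasta(list(b.proteins), out / "bins" / f"{b.bin_id}.fasta")
    io.write_fasta(community.candidates, out / "candidates.fasta")
    io.write_annotations(community.annotations, out / "annotations.tsv")
    io.write_fg_map(community.fg_map, out / "fg_map.tsv")
    io.write_psm_table(list(psms), out / "psms.tsv")
    pd.DataFrame(community.design.samples, columns=["sample_id", "ecotype"]).to_csv(
        out / "samples.tsv", sep="\t", index=False)
    community.truth.to_csv(out / "truth" / "peptides.tsv", sep="\t", index=False)
    expr = pd.DataFrame(
        [{"function": f, "bin_id": b, "ecotype": e, "mean_count": mu}
         for (f, b, e), mu in community.design.expression.items()])
    expr.to_csv(out / "truth" / "expression.tsv", sep="\t", index=False)
    return out


def simulate_bundle(design: SimDesign, outdir: io.PathLike) -> Path:
    community = generate_community(design)
    psms = simulate_psm_table(community)
    return write_bundle(community, psms, outdir)


# ---------------------------------------------------------------------------
# Canned study scenarios

def bin_exclusive_design(
    seed: int,
    exclusive_function: str = "Citrate synthase",
    exclusive_bin: str = "bin01",
) -> SimDesign:
    """Community where one function is expressed by a single bin.

    Three bins carry strongly diverged orthologs (90% of residues
    substituted, so a candidate protein aligns to foreign bins below the
    E-value gate) and ``exclusive_function`` has nonzero counts only in
    ``exclusive_bin``; two housekeeping functions are expressed everywhere
    so every bin contributes signal. With attribution working, Phi_bin of
    the exclusive function is 1 in its bin and 0 elsewhere.
    """
    functions = [(exclusive_function, "TCA Cycle"),
                 ("Ribosomal protein S3", "Ribosome"),
                 ("Chaperonin GroEL", "Chaperone")]
    bins = [f"bin{i + 1:02d}" for i in range(3)]
    expr: dict[tuple[str, str, str], float] = {}
    for b in bins:
        expr[(exclusive_function, b, "tussock")] = 40.0 if b == exclusive_bin else 0.0
        expr[("Ribosomal protein S3", b, "tussock")] = 20.0
        expr[("Chaperonin GroEL", b, "tussock")] = 20.0
    return SimDesign(n_bins=3, functions=functions, expression=expr,
                     samples=[("A", "tussock"), ("B", "tussock")],
                     inter_bin_divergence=0.9, seed=seed)


#: Functional Groups carrying the planted between-ecotype effect, with the
#: bin whose expression is induced in tussock samples (mirroring transport
#: and exopolysaccharide functions elevated under high root biomass and
#: dominated by particular taxa).
ECOTYPE_AFFECTED: dict[str, str] = {
    "Ribose Transport": "bin01",
    "Xylose Assimilation": "bin02",
    "Succinoglycan Synthesis": "bin03",
    "Nitrogen Assimilation": "bin01",
}

EXTRA_FUNCTIONS: list[tuple[str, str]] = [
    ("Pectate lyase", "Pectin Degradation"),
    ("Ammonium transporter", "Nitrogen Transport"),
    ("Phosphate ABC transporter", "Phosphate Transport"),
    ("Catalase", "Oxidative Stress"),
]


def ecotype_effect_design(seed: int, fold: float = 6.0) -> SimDesign:
    """Two-ecotype community with a bin-specific effect on four functions.

    Twelve functions over three bins, six samples per ecotype. Each
    affected function is induced ``fold``-fold in tussock samples in its
    dominant bin only, so both its overall relative abundance (Welch's
    t-test on Functional Group NSAF) and every bin's Phi_bin profile
    (LDA observations) shift between ecotypes; the eight unaffected
    functions keep ecotype-independent expression.
    """
    functions = list(DEFAULT_FUNCTIONS) + list(EXTRA_FUNCTIONS)
    bins = [f"bin{i + 1:02d}" for i in range(3)]
    expr: dict[tuple[str, str, str], float] = {}
    for i, (label, group) in enumerate(functions):
        for b in bins:
            for eco in ("tussock", "intertussock"):
                if group in ECOTYPE_AFFECTED:
                    main = ECOTYPE_AFFECTED[group]
                    base = 10.0 if b == main else 5.0
                    mu = base * fold if (eco == "tussock" and b == main) else base
                else:
                    mu = 30.0 if b == bins[i % len(bins)] else 5.0
                expr[(label, b, eco)] = mu
    samples = [(f"T{i}", "tussock") for i in range(1, 7)] + \
              [(f"I{i}", "intertussock") for i in range(1, 7)]
    return SimDesign(n_bins=3, functions=functions, expression=expr, samples=samples,
                     inter_bin_divergence=0.3, count_noise=0.2, seed=seed)
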