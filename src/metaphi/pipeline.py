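"""End-to-end orchestration: FDR -> inference -> alignment -> quant -> stats.

Every stage consumes and produces plain TSV (see ``metaphi.io``), so any
stage can be replaced by real external-tool output — e.g. a precomputed
candidate-vs-bin alignment table instead of the internal aligner, or a
homolog hit table from an external search instead of direct candidate
annotations. Reruns with an identical config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from metaphi import align as al
from metaphi import inference as inf
from metaphi import io
from metaphi import quant
from metaphi import stats as st
from metaphi.model import (
    PSM,
    BinAlignment,
    CandidateHit,
    FunctionalGroupMap,
    Metaprotein,
    PeptideRecord,
    QuantMatrix,
    TaxonBin,
    UNASSIGNED,
    canonical_peptide,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    Defaults match the method's stated operating point: 1% PSM-level FDR,
    E-value gate 0.01 for peptide-bin alignments, homolog hits kept within
    10% of the top bit score and evenly subsampled to at most five.
    """

    psm_table: str = ""
    bins_dir: str = ""
    candidates_fasta: str = ""
    annotations: str = ""
    fg_map: str = ""
    samples_table: Optional[str] = None
    hits_table: Optional[str] = None
    alignment_table: Optional[str] = None
    out_dir: str = "metaphi_out"
    q_cutoff: float = 0.01
    evalue_gate: float = 0.01
    top_hit_fraction: float = 0.10
    hit_cap: int = 5
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    ribosome_label: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml  # optional; JSON needs no extra dependency

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def scheme(self) -> al.ScoringScheme:
        return al.ScoringScheme(gap_open=self.gap_open, gap_extend=self.gap_extend,
                                lam=self.ka_lambda, K=self.ka_k)


@dataclass
class PipelineResult:
    """In-memory handles to everything the run wrote to out_dir."""

    fdr: inf.FDRResult
    metaproteins: list[Metaprotein]
    membership_metaprotein: dict[str, str]  # canonical peptide -> label
    membership_fg: dict[str, str]  # canonical peptide -> Functional Group
    nsaf: dict[str, list[PeptideRecord]]  # per sample
    alignments: dict[str, dict[str, Optional[BinAlignment]]]  # peptide -> bin
    phi: dict[str, QuantMatrix]  # per-sample phi at Functional Group level
    phi_metaprotein: dict[str, QuantMatrix]
    phi_bin: dict[str, QuantMatrix]
    phi_p: dict[str, QuantMatrix]
    sample_ecotype: dict[str, str] = field(default_factory=dict)
    cluster: Optional[st.ClusterResult] = None
    welch: Optional[pd.DataFrame] = None
    lda_scores: Optional[pd.DataFrame] = None
    lda_fractions: Optional[list[float]] = None
    pca_scores: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# stage helpers

def build_candidate_hits(
    psms: list[PSM],
    annotations: dict[str, tuple[Optional[str], Optional[str]]],
    candidates: dict[str, str],
    hits_df: Optional[pd.DataFrame] = None,
    top_hit_fraction: float = 0.10,
    hit_cap: int = 5,
) -> dict[str, list[CandidateHit]]:
    """Assemble the per-candidate homolog hit lists.

    With a homolog ``hits_df`` (candidate_id, subject_id, bit_score,
    subject_length), subjects carry the annotations and the top-fraction /
    even-subsampling filters apply. Without one, each candidate
    contributes a single self-hit annotated directly — the layout produced
    when the annotation tool is run on the candidates themselves.
    """
    needed = {c for p in psms for c in p.candidate_ids}
    out: dict[str, list[CandidateHit]] = {}
    if hits_df is not None:
        for cand, grp in hits_df.groupby("candidate_id"):
            if cand not in needed:
                continue
            hits = []
            for r, row in enumerate(
                grp.sort_values("bit_score", ascending=False).itertuples(index=False), start=1
            ):
                fam, desc = annotations.get(str(row.subject_id), (None, None))
                hits.append(CandidateHit(
                    candidate_id=str(cand), subject_id=str(row.subject_id),
                    bit_score=float(row.bit_score), rank=r,
                    gene_family=fam, description=desc,
                    subject_length=int(row.subject_length)
                    if "subject_length" in hits_df.columns else None,
                ))
            out[str(cand)] = inf.subsample_hits(
                inf.filter_top_hits(hits, top_hit_fraction), hit_cap)
    else:
        for cand in sorted(needed):
            fam, desc = annotations.get(cand, (None, None))
            length = len(candidates.get(cand, "")) or None
            out[cand] = [CandidateHit(
                candidate_id=cand, subject_id=cand, bit_score=1.0, rank=1,
                gene_family=fam, description=desc, subject_length=length,
            )]
    return out


def infer_functions(
    psms: list[PSM],
    hits_per_candidate: dict[str, list[CandidateHit]],
    fgmap: FunctionalGroupMap,
) -> tuple[list[Metaprotein], dict[str, str], dict[str, str], dict[str, str]]:
    """Consistent-description filtering, metaproteins, memberships.

    Returns (metaproteins, spectrum descriptions, peptide -> metaprotein
    label, peptide -> Functional Group). A peptide whose PSMs disagree on
    the description is excluded from function membership (reported), but
    all kept peptides still enter the NSAF denominator.
    """
    descriptions: dict[str, str] = {}
    for psm in psms:
        desc = inf.consistent_description(psm, hits_per_candidate)
        if desc is not None:
            descriptions[psm.spectrum_id] = desc
    metaproteins = inf.build_metaproteins(psms, descriptions)

    # majority gene family per metaprotein, for the Functional Group lookup
    label_by_spectrum = descriptions
    fam_votes: dict[str, Counter] = {}
    for psm in psms:
        label = label_by_spectrum.get(psm.spectrum_id)
        if label is None:
            continue
        for cand in psm.candidate_ids:
            for hit in hits_per_candidate.get(cand, ()):
                if hit.description == label and hit.gene_family is not None:
                    fam_votes.setdefault(label, Counter())[hit.gene_family] += 1
    for mp in metaproteins:
        votes = fam_votes.get(mp.label)
        if votes:
            mp.gene_family = min(votes, key=lambda f: (-votes[f], f))
        mp.functional_group = inf.assign_functional_group(mp.gene_family, mp.label, fgmap)

    pep_labels: dict[str, set[str]] = {}
    for psm in psms:
        label = descriptions.get(psm.spectrum_id)
        if label is not None:
            pep_labels.setdefault(canonical_peptide(psm.peptide), set()).add(label)
    conflicted = {p for p, ls in pep_labels.items() if len(ls) > 1}
    if conflicted:
        log.info("%d peptides with conflicting descriptions excluded from "
                 "function membership", len(conflicted))
    membership_mp = {p: next(iter(ls)) for p, ls in pep_labels.items() if p not in conflicted}
    fg_of_label = {mp.label: mp.functional_group for mp in metaproteins}
    membership_fg = {p: fg_of_label[l] for p, l in membership_mp.items()
                     if fg_of_label.get(l) not in (None, UNASSIGNED)}
    return metaproteins, descriptions, membership_mp, membership_fg


def peptide_records(
    psms: list[PSM],
    hits_per_candidate: dict[str, list[CandidateHit]],
    candidates: dict[str, str],
) -> dict[str, list[PeptideRecord]]:
    """Per-sample PeptideRecords over canonical peptides, NSAF set.

    D is the number of spectra matched to the peptide in the sample; L is
    the mean retained homolog subject length pooled across the peptide's
    candidates, falling back to the candidate's own length when a
    candidate has no subject hits.
    """
    per_sample: dict[str, dict[str, int]] = {}
    pep_candidates: dict[str, set[str]] = {}
    for psm in psms:
        pep = canonical_peptide(psm.peptide)
        per_sample.setdefault(psm.sample_id, {})
        per_sample[psm.sample_id][pep] = per_sample[psm.sample_id].get(pep, 0) + 1
        pep_candidates.setdefault(pep, set()).update(psm.candidate_ids)

    mean_len: dict[str, float] = {}
    for pep, cands in pep_candidates.items():
        lengths: list[float] = []
        for cand in cands:
            subject_lengths = [h.subject_length for h in hits_per_candidate.get(cand, ())
                               if h.subject_length is not None]
            if subject_lengths:
                lengths.extend(float(x) for x in subject_lengths)
            elif cand in candidates:
                lengths.append(float(len(candidates[cand])))
        mean_len[pep] = sum(lengths) / len(lengths) if lengths else float(len(pep))

    out: dict[str, list[PeptideRecord]] = {}
    for sample, counts in sorted(per_sample.items()):
        records = [PeptideRecord(peptide=p, D=d, L=mean_len[p])
                   for p, d in sorted(counts.items())]
        out[sample] = quant.compute_nsaf(records)
    return out


def align_peptides_to_bins(
    peptides: list[str],
    pep_candidates: dict[str, list[tuple[str, str]]],
    bins: list[TaxonBin],
    scheme: al.ScoringScheme,
    evalue_gate: float = 0.01,
    alignment_df: Optional[pd.DataFrame] = None,
    subject_to_bin: Optional[dict[str, str]] = None,
) -> dict[str, dict[str, Optional[BinAlignment]]]:
    """Best qualifying candidate alignment per (peptide, bin), normalized.

    Identical candidate sets share one alignment computation, since the
    peptide-bin association depends only on the candidates.
    """
    cache: dict[tuple[tuple[str, str], ...], dict[str, Optional[BinAlignment]]] = {}
    out: dict[str, dict[str, Optional[BinAlignment]]] = {}
    for pep in peptides:
        cands = tuple(sorted(pep_candidates.get(pep, [])))
        if not cands:
            out[pep] = {b.bin_id: None for b in bins}
            continue
        if cands in cache:
            template = cache[cands]
            per_bin = {
                b: None if a is None else dataclasses.replace(a, peptide=pep)
                for b, a in template.items()
            }
        else:
            per_bin = {}
            for b in bins:
                if alignment_df is not None:
                    a = al.best_bin_alignment_from_table(
                        pep, [c for c, _ in cands], alignment_df,
                        subject_to_bin or {}, b.bin_id, evalue_gate)
                else:
                    a = al.best_bin_alignment(pep, cands, b, scheme, evalue_gate)
                per_bin[b.bin_id] = a
            quant.normalize_bin_scores(list(per_bin.values()), evalue_gate)
            cache[cands] = per_bin
        out[pep] = per_bin
    return out


def phi_matrices(
    nsaf_by_sample: dict[str, list[PeptideRecord]],
    alignments: dict[str, dict[str, Optional[BinAlignment]]],
    membership: dict[str, str],
    bin_ids: list[str],
    evalue_gate: float = 0.01,
) -> dict[str, QuantMatrix]:
    """Per-sample phi matrices (function x bin) from NSAF and alignments."""
    out: dict[str, QuantMatrix] = {}
    for sample, records in nsaf_by_sample.items():
        phi_records = []
        for rec in records:
            per_bin = alignments.get(rec.peptide)
            if per_bin is None:
                continue
            for bin_id in bin_ids:
                a = per_bin.get(bin_id)
                phi = quant.compute_phi_n(rec.nsaf or 0.0, a, evalue_gate)
                phi_records.append(quant.PhiRecord(
                    peptide=rec.peptide, bin_id=bin_id, phi_n=phi,
                    nsaf=rec.nsaf or 0.0,
                    norm_score=(a.norm_score or 0.0) if a is not None else 0.0))
        m = quant.aggregate_phi_p(phi_records, membership)
        df = m.data.reindex(columns=bin_ids, fill_value=0.0)
        out[sample] = QuantMatrix(data=df, kind="phi")
    return out


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_json(str(out_dir / "run_config.json"))

    psms = io.read_psm_table(config.psm_table)
    bins = _load_bins(config.bins_dir)
    candidates = dict(io.read_fasta(config.candidates_fasta))
    annotations = io.read_annotations(config.annotations)
    fgmap = io.read_fg_map(config.fg_map)
    hits_df = None
    if config.hits_table:
        hits_df = pd.read_csv(config.hits_table, sep="\t")
    alignment_df = None
    subject_to_bin = None
    if config.alignment_table:
        alignment_df = io.read_tabular_alignments(config.alignment_table)
        subject_to_bin = {pid: b.bin_id for b in bins for pid, _ in b.proteins}

    # 1. FDR
    fdr = inf.fdr_filter(psms, config.q_cutoff)
    _write_fdr_report(fdr, out_dir / "fdr_report.tsv")
    log.info("stage fdr: %d PSMs in, %d kept", len(psms), len(fdr.kept))

    # 2. hits + metaproteins
    hits_per_candidate = build_candidate_hits(
        fdr.kept, annotations, candidates, hits_df,
        config.top_hit_fraction, config.hit_cap)
    metaproteins, descriptions, membership_mp, membership_fg = infer_functions(
        fdr.kept, hits_per_candidate, fgmap)
    _write_metaproteins(metaproteins, out_dir / "metaproteins.tsv")
    log.info("stage infer: %d metaproteins from %d annotated PSMs",
             len(metaproteins), len(descriptions))

    # 3. NSAF
    nsaf_by_sample = peptide_records(fdr.kept, hits_per_candidate, candidates)
    _write_nsaf(nsaf_by_sample, membership_mp, membership_fg, out_dir)

    # 4. alignment
    pep_candidates: dict[str, list[tuple[str, str]]] = {}
    for psm in fdr.kept:
        pep = canonical_peptide(psm.peptide)
        if pep not in membership_mp:
            continue
        entry = pep_candidates.setdefault(pep, [])
        for cand in psm.candidate_ids:
            seq = candidates.get(cand, "")
            if seq and (cand, seq) not in entry:
                entry.append((cand, seq))
    annotated_peptides = sorted(pep_candidates)
    alignments = align_peptides_to_bins(
        annotated_peptides, pep_candidates, bins, config.scheme(),
        config.evalue_gate, alignment_df, subject_to_bin)
    log.info("stage align: %d peptides x %d bins", len(annotated_peptides), len(bins))

    # 5. quantification
    bin_ids = [b.bin_id for b in bins]
    phi_fg = phi_matrices(nsaf_by_sample, alignments, membership_fg, bin_ids,
                          config.evalue_gate)
    phi_mp = phi_matrices(nsaf_by_sample, alignments, membership_mp, bin_ids,
                          config.evalue_gate)
    phi_bin = {s: quant.compute_phi_bin(m) for s, m in phi_fg.items()}
    phi_p = {s: quant.compute_phi_function(m) for s, m in phi_fg.items()}
    _write_long(phi_bin, out_dir / "phi_bin_fg.tsv")
    _write_long(phi_p, out_dir / "phi_p_fg.tsv")
    _write_long({s: quant.compute_phi_bin(m) for s, m in phi_mp.items()},
                out_dir / "phi_bin_metaprotein.tsv")

    result = PipelineResult(
        fdr=fdr, metaproteins=metaproteins,
        membership_metaprotein=membership_mp, membership_fg=membership_fg,
        nsaf=nsaf_by_sample, alignments=alignments,
        phi=phi_fg, phi_metaprotein=phi_mp, phi_bin=phi_bin, phi_p=phi_p)

    # 6. multivariate stats (needs sample metadata)
    if config.samples_table:
        meta = pd.read_csv(config.samples_table, sep="\t", dtype=str)
        result.sample_ecotype = dict(zip(meta["sample_id"], meta["ecotype"]))
        _run_stats(result, config, out_dir)
    return result


def _load_bins(bins_dir: str) -> list[TaxonBin]:
    paths = sorted(Path(bins_dir).glob("*.fasta")) + sorted(Path(bins_dir).glob("*.faa"))
    if not paths:
        raise ValueError(f"no bin FASTA files found under {bins_dir}")
    return [TaxonBin(bin_id=p.stem, taxon_label=p.stem, proteins=tuple(io.read_fasta(p)))
            for p in paths]


def _write_fdr_report(fdr: inf.FDRResult, path: Path) -> None:
    rows = [{"spectrum_id": sid, "q_value": q} for sid, q in sorted(fdr.q_values.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def _write_metaproteins(metaproteins: list[Metaprotein], path: Path) -> None:
    rows = [{
        "label": mp.label,
        "gene_family": mp.gene_family or "",
        "functional_group": mp.functional_group or "",
        "n_psms": len(mp.psm_ids),
        "spectrum_ids": ";".join(sorted(mp.psm_ids)),
    } for mp in metaproteins]
    pd.DataFrame(rows, columns=["label", "gene_family", "functional_group",
                                "n_psms", "spectrum_ids"]).to_csv(path, sep="\t", index=False)


def _write_nsaf(nsaf_by_sample, membership_mp, membership_fg, out_dir: Path) -> None:
    rows = []
    for sample, records in nsaf_by_sample.items():
        for rec in records:
            rows.append({
                "sample": sample, "peptide": rec.peptide, "D": rec.D, "L": rec.L,
                "nsaf": rec.nsaf,
                "metaprotein": membership_mp.get(rec.peptide, ""),
                "functional_group": membership_fg.get(rec.peptide, ""),
            })
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "nsaf_peptides.tsv", sep="\t", index=False, float_format="%.9g")
    if not df.empty:
        fg = (df[df["functional_group"] != ""]
              .groupby(["sample", "functional_group"])["nsaf"].sum().reset_index())
        fg.to_csv(out_dir / "nsaf_functional_groups.tsv", sep="\t", index=False,
                  float_format="%.9g")


def _write_long(matrices: dict[str, QuantMatrix], path: Path) -> None:
    frames = [quant.to_long(m, sample_id=s) for s, m in sorted(matrices.items())]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                    float_format="%.9g")


def fg_nsaf_matrix(result: PipelineResult) -> pd.DataFrame:
    """Functional Group NSAF (rows) by sample (columns)."""
    cells: dict[str, dict[str, float]] = {}
    for sample, records in result.nsaf.items():
        for rec in records:
            fg = result.membership_fg.get(rec.peptide)
            if fg is None:
                continue
            cells.setdefault(fg, {})[sample] = cells.setdefault(fg, {}).get(sample, 0.0) \
                + (rec.nsaf or 0.0)
    return pd.DataFrame(cells).T.fillna(0.0).sort_index()


def _run_stats(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    ecotypes: dict[str, list[str]] = {}
    for s, e in result.sample_ecotype.items():
        if s in result.phi_bin:
            ecotypes.setdefault(e, []).append(s)

    # k-means on Phi_bin averaged over every organic sample
    avg = quant.average_over_samples(result.phi_bin, sorted(result.phi_bin))
    io.write_matrix(avg, out_dir / "avg_phi_bin_fg.tsv")
    if config.ribosome_label and config.ribosome_label in avg.data.index:
        quant.ribosome_normalize(avg, config.ribosome_label).to_csv(
            out_dir / "phi_bin_ribosome_normalized.tsv", sep="\t", float_format="%.9g")
    max_k = min(6, max(3, len(avg.data.drop_duplicates()) - 1))
    if len(avg.data.drop_duplicates()) > 3:
        cluster = st.kmeans_sse(avg, k_range=range(1, max_k + 1), restarts=100,
                                seed=config.seed)
        result.cluster = cluster
        pd.DataFrame([{"function": f, "cluster": c} for f, c in cluster.labels.items()]
                     ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame([{"k": k, "sse": v} for k, v in sorted(cluster.sse_curve.items())]
                     ).to_csv(out_dir / "sse_curve.tsv", sep="\t", index=False,
                              float_format="%.9g")

    # Welch's t-test of Functional Group NSAF between the two best-replicated
    # ecotypes (sparser classes are ignored, as in the published comparison)
    eligible = sorted((e for e, ss in ecotypes.items() if len(ss) >= 2),
                      key=lambda e: (-len(ecotypes[e]), e))
    if len(eligible) >= 2:
        a, b = eligible[:2]
        nsaf_fg = fg_nsaf_matrix(result)
        cols = [s for s in ecotypes[a] + ecotypes[b] if s in nsaf_fg.columns]
        nsaf_fg = nsaf_fg.reindex(columns=cols, fill_value=0.0)
        welch = st.welch_tests(nsaf_fg, ecotypes[a], ecotypes[b])
        result.welch = welch
        welch.to_csv(out_dir / "welch_tests.tsv", sep="\t", float_format="%.9g")

        # LDA / PCA: observations are (ecotype, bin) Phi_bin profiles over
        # Functional Groups, ecotype-averaged
        obs, labels = {}, {}
        for e in eligible:
            avg_e = quant.average_over_samples(result.phi_bin, ecotypes[e])
            for bin_id in avg_e.data.columns:
                key = f"{e}:{bin_id}"
                obs[key] = avg_e.data[bin_id]
                labels[key] = e
        obs_df = pd.DataFrame(obs).T
        if len(set(labels.values())) >= 2 and min(
            Counter(labels.values()).values()) >= 2:
            scores, fractions = st.lda(obs_df, labels)
            result.lda_scores, result.lda_fractions = scores, list(fractions)
            scores.assign(ecotype=[labels[i] for i in scores.index]).to_csv(
                out_dir / "lda_scores.tsv", sep="\t", float_format="%.9g")
            pca_scores, _, var = st.pca(obs_df, n_components=min(2, len(obs_df) - 1))
            result.pca_scores = pca_scores
            pca_scores.to_csv(out_dir / "pca_scores.tsv", sep="\t", float_format="%.9g")
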