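"""Readers and writers for every external format the pipeline touches.

All tabular inputs are plain delimited text located by header name, never
by column position, so outputs of different external-tool versions can be
substituted stage for stage. Readers log per-file record counts and never
silently drop a row except under the documented warn-and-skip rule for
malformed annotation lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO

from metaphi.model import PSM, FunctionalGroupMap, QuantMatrix, TaxonBin

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_TRUE = {"true", "t", "1", "yes", "y", "decoy"}
_FALSE = {"false", "f", "0", "no", "n", "target", ""}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a protein FASTA into (id, sequence) records.

    Sequences are uppercased and terminal '*' stop characters stripped.
    Duplicate ids and empty sequences are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().strip("*")
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {rec.id!r}")
        records.append((rec.id, seq))
    log.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(records: list[tuple[str, str]], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bin_fastas(paths: dict[str, PathLike], taxon_labels: Optional[dict[str, str]] = None) -> list[TaxonBin]:
    """Load one FASTA per taxonomic bin; keys are bin ids."""
    bins = []
    for bin_id, path in paths.items():
        label = (taxon_labels or {}).get(bin_id, bin_id)
        bins.append(TaxonBin(bin_id=bin_id, taxon_label=label, proteins=tuple(read_fasta(path))))
    return bins


# ---------------------------------------------------------------------------
# PSM tables

@dataclass
class PSMTableDialect:
    """Column names of a tab-separated PSM table.

    Unknown extra columns are ignored; the candidate column holds a
    ``candidate_sep``-delimited list of protein ids.
    """

    sample: str = "sample_id"
    spectrum: str = "spectrum_id"
    peptide: str = "peptide"
    candidates: str = "candidate_ids"
    score: str = "score"
    evalue: str = "evalue"
    decoy: str = "is_decoy"
    delimiter: str = "\t"
    candidate_sep: str = ";"

    @property
    def required(self) -> list[str]:
        return [self.sample, self.spectrum, self.peptide, self.candidates,
                self.score, self.evalue, self.decoy]


def _parse_bool(value: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse decoy flag {value!r}")


def read_psm_table(path: PathLike, dialect: Optional[PSMTableDialect] = None) -> list[PSM]:
    """Read a PSM table, preserving row order.

    Candidate lists are split on the dialect separator and deduplicated
    (first occurrence wins). Missing required columns and non-numeric
    scores are hard errors naming the column / row.
    """
    dialect = dialect or PSMTableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    psms: list[PSM] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            score = float(rec[dialect.score])
            evalue = float(rec[dialect.evalue])
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: non-numeric score/evalue ({exc})") from None
        cands = []
        for c in rec[dialect.candidates].split(dialect.candidate_sep):
            c = c.strip()
            if c and c not in cands:
                cands.append(c)
        psms.append(
            PSM(
                sample_id=rec[dialect.sample],
                spectrum_id=rec[dialect.spectrum],
                peptide=rec[dialect.peptide].upper(),
                candidate_ids=tuple(cands),
                search_score=score,
                search_evalue=evalue,
                is_decoy=_parse_bool(rec[dialect.decoy], i),
            )
        )
    log.info("read %d PSMs from %s", len(psms), path)
    return psms


def write_psm_table(psms: list[PSM], path: PathLike, dialect: Optional[PSMTableDialect] = None) -> None:
    dialect = dialect or PSMTableDialect()
    rows = [
        {
            dialect.sample: p.sample_id,
            dialect.spectrum: p.spectrum_id,
            dialect.peptide: p.peptide,
            dialect.candidates: dialect.candidate_sep.join(p.candidate_ids),
            dialect.score: repr(p.search_score),
            dialect.evalue: repr(p.search_evalue),
            dialect.decoy: str(p.is_decoy),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=dialect.required).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Annotations (eggNOG-mapper style)

_QUERY_ALIASES = ("#query", "query", "#query_name", "query_name")
_FAMILY_ALIASES = ("Preferred_name", "preferred_name", "gene_family", "Gene_family")
_DESC_ALIASES = ("Description", "description", "eggNOG free text desc.", "free_text_desc")


def read_annotations(path: PathLike) -> dict[str, tuple[Optional[str], Optional[str]]]:
    """Read an emapper.annotations-style TSV.

    Returns candidate_id -> (gene_family, description); empty fields map
    to None, and candidates absent from the file are simply absent (their
    lookups return (None, None) via ``dict.get``). The header is located
    among the leading '#' comment lines; columns are matched by name.
    Malformed rows (wrong column count) are skipped with a warning.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: Optional[list[str]] = None
    data_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            cols = line.split("\t")
            if len(cols) >= 3 and any(cols[0] == a for a in _QUERY_ALIASES):
                header = cols
            continue
        if header is None:
            # headerless variants put the header in the first data line
            cols = line.split("\t")
            if any(cols[0] == a for a in _QUERY_ALIASES):
                header = cols
                continue
            raise ValueError(f"{path}: no header row found before data")
        data_lines.append((lineno, line))
    if header is None:
        raise ValueError(f"{path}: no header row found")

    def _find(aliases: tuple[str, ...], what: str) -> int:
        for a in aliases:
            if a in header:
                return header.index(a)
        raise ValueError(f"{path}: no {what} column (looked for {aliases})")

    qi = _find(_QUERY_ALIASES, "query")
    fi = _find(_FAMILY_ALIASES, "gene-family")
    di = _find(_DESC_ALIASES, "description")

    out: dict[str, tuple[Optional[str], Optional[str]]] = {}
    skipped = 0
    for lineno, line in data_lines:
        cols = line.split("\t")
        if len(cols) != len(header):
            skipped += 1
            log.warning("%s line %d: expected %d columns, got %d — skipped",
                        path, lineno, len(header), len(cols))
            continue
        fam = cols[fi].strip() or None
        if fam == "-":
            fam = None
        desc = cols[di].strip() or None
        if desc == "-":
            desc = None
        out[cols[qi]] = (fam, desc)
    log.info("read %d annotations from %s (%d malformed rows skipped)", len(out), path, skipped)
    return out


def write_annotations(annotations: dict[str, tuple[Optional[str], Optional[str]]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#query\tPreferred_name\tDescription\n")
        for cand, (fam, desc) in annotations.items():
            fh.write(f"{cand}\t{fam or '-'}\t{desc or '-'}\n")


# ---------------------------------------------------------------------------
# Functional Group map

def read_fg_map(path: PathLike) -> FunctionalGroupMap:
    """Read a Functional Group table (gene_family, description, functional_group).

    Rows with an empty gene family are indexed by description alone.
    Conflicting duplicate keys (same pair, two groups) are hard errors.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        fam_c, desc_c, grp_c = cols["gene_family"], cols["description"], cols["functional_group"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing column {exc}") from None
    fgmap = FunctionalGroupMap()
    for i, row in df.iterrows():
        fam = row[fam_c].strip()
        desc = row[desc_c].strip()
        grp = row[grp_c].strip()
        if not desc or not grp:
            raise ValueError(f"{path} row {i + 1}: empty description or group")
        if fam:
            key = (fam, desc)
            if fgmap.entries.get(key, grp) != grp:
                raise ValueError(f"{path}: conflicting groups for {key}")
            fgmap.entries[key] = grp
        else:
            if fgmap.by_description.get(desc, grp) != grp:
                raise ValueError(f"{path}: conflicting groups for description {desc!r}")
            fgmap.by_description[desc] = grp
    log.info("read Functional Group map: %d pairs, %d description-only rows, %d groups",
             len(fgmap.entries), len(fgmap.by_description), len(fgmap.groups))
    return fgmap


def write_fg_map(fgmap: FunctionalGroupMap, path: PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = [{"gene_family": f, "description": d, "functional_group": g}
            for (f, d), g in fgmap.entries.items()]
    rows += [{"gene_family": "", "description": d, "functional_group": g}
             for d, g in fgmap.by_description.items()]
    pd.DataFrame(rows, columns=["gene_family", "description", "functional_group"]).to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Quant matrices

def write_matrix(m: QuantMatrix, path: PathLike) -> None:
    """Write a QuantMatrix as TSV: row-label column + one column per key."""
    df = m.data.copy()
    df.index.name = "function"
    df.to_csv(path, sep="\t", float_format="%.9g")


def read_matrix(path: PathLike, kind: str) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return QuantMatrix(data=df, kind=kind)


# ---------------------------------------------------------------------------
# Precomputed tabular alignments (BLAST outfmt-6-like)

TABULAR_ALIGNMENT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_alignments(path: PathLike) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (headerless, tab-separated)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=TABULAR_ALIGNMENT_COLUMNS)
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    log.info("read %d tabular alignments from %s", len(df), path)
    return df
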