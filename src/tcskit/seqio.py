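"""Readers, writers and ingestion filters for the survey's external formats.

Sequence I/O is delegated to Biopython; this module adds the validation
layer (unique IDs, coordinate sanity, amino-acid alphabet normalisation)
and the E-value ingestion filters applied to external BLAST/HMM search
tables before classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

# Residues outside the 20-letter alphabet that are normalised to X.
_AMBIGUOUS = set("BZJUO*")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a unique identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a chromosome; 1-based inclusive coordinates.

    ``rank`` is the dense 1..n order index of the gene along its chromosome
    (by start coordinate); it is always computed, never read from a file.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )


@dataclass(frozen=True)
class ExternalHit:
    """One row of an external BLAST or HMM search table."""

    query_id: str
    target_id: str
    evalue: float
    score: float
    source: str  # "blast" | "hmm"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}: negative E-value")
        if self.source not in ("blast", "hmm"):
            raise ValidationError(f"hit {self.query_id}: unknown source {self.source!r}")


def _normalise_protein_seq(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    if _AMBIGUOUS & set(seq):
        log.warning("protein %s: ambiguous residues mapped to X", rec_id)
        seq = "".join("X" if c in _AMBIGUOUS else c for c in seq)
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValidationError(f"protein {rec_id}: invalid residues {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated, upper-cased records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        out.append(ProteinRecord(rec.id, _normalise_protein_seq(str(rec.seq), rec.id)))
    return out


def read_dna_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA (CDS, genome contigs, promoters) as a dict."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate sequence ID {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ID_ATTR = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a GFF3-subset gene table and assign dense per-chromosome ranks.

    Only the seqid, start, end, strand and ID/gene_id attribute columns are
    used; feature hierarchy is ignored.
    """
    raw: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _source, _type, start, end, _score, strand, _phase, attrs = cols[:9]
            m = _ID_ATTR.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: no ID/gene_id attribute")
            raw.append(GeneLocus(m.group(1), seqid, int(start), int(end), strand))
    return assign_ranks(raw)


def assign_ranks(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Sort loci per chromosome by start and assign dense 1..n ranks."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    out: list[GeneLocus] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        for i, loc in enumerate(ordered, 1):
            out.append(GeneLocus(loc.gene_id, loc.chromosome, loc.start, loc.end, loc.strand, i))
    return out


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chromosome}\ttcskit\tgene\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\tID={loc.gene_id}\n"
            )


def read_hits_table(path: str | Path) -> list[ExternalHit]:
    """Read a TSV of external search hits (query_id, target_id, evalue, score, source)."""
    hits: list[ExternalHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            hits.append(ExternalHit(cols[0], cols[1], float(cols[2]), float(cols[3]), cols[4]))
    return hits


def filter_external_hits(
    hits: Iterable[ExternalHit],
    blast_emax: float = 1e-5,
    hmm_emax: float = 0.1,
) -> list[ExternalHit]:
    """Apply the candidate-ingestion E-value thresholds and deduplicate queries.

    BLAST hits are kept at E <= ``blast_emax`` (default 1e-5); HMM hits at
    E strictly below ``hmm_emax`` (default 0.1).  One hit per query survives,
    the one with the smallest E-value (score breaks ties).
    """
    if blast_emax <= 0 or hmm_emax <= 0:
        raise ValidationError("E-value thresholds must be positive")
    kept: dict[str, ExternalHit] = {}
    for h in hits:
        ok = h.evalue <= blast_emax if h.source == "blast" else h.evalue < hmm_emax
        if not ok:
            continue
        prev = kept.get(h.query_id)
        if prev is None or (h.evalue, -h.score) < (prev.evalue, -prev.score):
            kept[h.query_id] = h
    return list(kept.values())


_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def collapse_isoforms(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse isoforms sharing a gene ID (``.1``/``.2`` suffixes); keep the longest.

    This is the redundancy-removal convention applied to proteome downloads
    before domain searching.
    """
    best: dict[str, ProteinRecord] = {}
    for rec in records:
        gene = _ISOFORM_SUFFIX.sub("", rec.id)
        prev = best.get(gene)
        if prev is None or rec.length > prev.length:
            best[gene] = ProteinRecord(gene, rec.seq)
    return list(best.values())


def write_newick(tree) -> str:
    """Serialise a phylogeny to Newick (with branch lengths and supports).

    Accepts the toolkit's :class:`tcskit.phylo.TreeNode`; labels containing
    Newick metacharacters are single-quoted.
    """
    from .phylo import TreeNode  # local import; phylo depends on seqio

    if not isinstance(tree, TreeNode):
        raise ValidationError("write_newick expects a tcskit.phylo.TreeNode")
    return tree.to_newick()
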