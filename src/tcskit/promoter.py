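"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 1.5 kb of genomic sequence immediately upstream of the
annotated translation start (strand-aware, truncated with a warning at
contig edges).  Element detection is exact IUPAC-consensus matching on
both strands; an N in the promoter matches nothing, and overlapping
occurrences are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .seqio import GeneLocus

log = logging.getLogger(__name__)

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElementDef:
    """An element consensus over the IUPAC DNA alphabet."""

    name: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC_DNA)
        if bad:
            raise ValidationError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")


@dataclass(frozen=True)
class CisHit:
    gene_id: str
    element: str
    category: str
    offset: int  # 0-based on the forward promoter strand
    strand: str  # "+" | "-"
    matched_seq: str


def load_cis_elements(path: str | Path | None = None) -> list[CisElementDef]:
    if path is None:
        text = resources.files("tcskit.data").joinpath("cis_elements.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return [CisElementDef(d["name"], d["pattern"].upper(), d["category"]) for d in doc["elements"]]


def extract_promoter(
    locus: GeneLocus, genome: Mapping[str, str], length_bp: int = 1500
) -> str:
    """Strand-aware upstream sequence of the translation start.

    Plus strand: the ``length_bp`` bases ending immediately before
    ``start``.  Minus strand: the reverse complement of the ``length_bp``
    bases beginning immediately after ``end``.  Truncated at contig edges
    with a logged warning.
    """
    if locus.chromosome not in genome:
        raise ValidationError(f"{locus.gene_id}: unknown sequence {locus.chromosome}")
    contig = genome[locus.chromosome]
    if locus.end > len(contig):
        raise ValidationError(f"{locus.gene_id}: locus beyond contig bounds")
    if locus.strand == "+":
        lo = max(0, locus.start - 1 - length_bp)
        region = contig[lo : locus.start - 1]
    else:
        region = reverse_complement(contig[locus.end : locus.end + length_bp])
    if len(region) < length_bp:
        log.warning(
            "promoter of %s truncated to %d bp at contig edge", locus.gene_id, len(region)
        )
    return region


def _iupac_match(window: str, pattern: str) -> bool:
    # N in the promoter never matches (unknown base)
    return all(b in IUPAC_DNA[p] for b, p in zip(window, pattern))


def scan_cis_elements(
    promoter: str,
    defs: Sequence[CisElementDef] | None = None,
    gene_id: str = "",
) -> list[CisHit]:
    """Exact IUPAC matching of all element consensi on both strands.

    Offsets always refer to the forward (given) promoter strand; a minus-
    strand hit at offset o means the reverse complement of the pattern
    occurs at o.
    """
    if defs is None:
        defs = load_cis_elements()
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise ValidationError(f"promoter contains non-DNA symbols {sorted(bad)}")
    hits: list[CisHit] = []
    for d in defs:
        plen = len(d.pattern)
        rc_pattern = reverse_complement(d.pattern)
        for off in range(len(promoter) - plen + 1):
            window = promoter[off : off + plen]
            if "N" in window:
                continue
            if _iupac_match(window, d.pattern):
                hits.append(CisHit(gene_id, d.name, d.category, off, "+", window))
            if _iupac_match(window, rc_pattern):
                hits.append(CisHit(gene_id, d.name, d.category, off, "-", window))
    return sorted(hits, key=lambda h: (h.offset, h.element, h.strand))


def scan_promoter_set(
    promoters: Mapping[str, str], defs: Sequence[CisElementDef] | None = None
) -> list[CisHit]:
    if defs is None:
        defs = load_cis_elements()
    hits: list[CisHit] = []
    for gene_id in sorted(promoters):
        hits.extend(scan_cis_elements(promoters[gene_id], defs, gene_id=gene_id))
    return hits


def summarize_elements(hits: Sequence[CisHit], genes: Iterable[str]) -> pd.DataFrame:
    """Per-category summary: genes with at least one hit, and total hits.

    Counts include both strands and overlapping occurrences.
    """
    genes = list(genes)
    categories = sorted({h.category for h in hits} | {d.category for d in load_cis_elements()})
    rows = []
    for cat in categories:
        cat_hits = [h for h in hits if h.category == cat]
        rows.append(
            {
                "category": cat,
                "genes_with_hit": len({h.gene_id for h in cat_hits}),
                "total_elements": len(cat_hits),
                "genes_surveyed": len(genes),
            }
        )
    return pd.DataFrame(rows)
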