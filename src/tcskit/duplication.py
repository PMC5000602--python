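"""Gene-duplication analysis: alignment similarity, tandem/segmental
detection, Nei-Gojobori Ka/Ks and molecular-clock dating.

Tandem duplicates are paralog pairs on the same chromosome that share at
least 40% amino-acid similarity and are separated by fewer than five
intervening genes (counted over all annotated genes).  Segmental
duplicates are paralog pairs that sit inside collinear blocks: chains of
at least ``min_chain`` high-similarity anchor pairs whose gene ranks run
monotonically on both chromosomes.

Ka/Ks follows the Nei-Gojobori (1986) counting method: synonymous and
nonsynonymous site fractions per codon position (changes to stop codons
excluded from the denominators), substitution counts averaged with equal
weight over all minimal pathways between differing codons (pathways
through stops excluded), and the Jukes-Cantor correction
``K = -3/4 ln(1 - 4/3 p)``.  Divergence times use the synonymous
molecular clock ``T = Ks / (2x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .errors import ValidationError
from .seqio import GeneLocus, ProteinRecord

PURIFYING = "purifying"
NEUTRAL_OR_POSITIVE = "neutral_or_positive"
UNDEFINED = "undefined"

# ---------------------------------------------------------------------------
# pairwise global alignment

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def global_align(a: ProteinRecord, b: ProteinRecord) -> AlignmentResult:
    """Needleman-Wunsch global alignment (BLOSUM62, affine gaps 10/0.5).

    ``percent_similarity`` is the percentage of alignment columns in which
    both sequences carry residues scoring positively against each other;
    ``percent_identity`` the percentage of columns with identical residues.
    Gap columns count in the denominators of both.
    """
    for rec in (a, b):
        bad = set(rec.seq) - _VALID_AA
        if bad:
            raise ValidationError(f"{rec.id}: invalid residues {sorted(bad)}")
    aligner = _make_aligner()
    aln = aligner.align(a.seq, b.seq)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ncol = len(row_a)
    ident = sim = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if _BLOSUM62[x, y] > 0:
            sim += 1
    return AlignmentResult(
        row_a, row_b, float(aln.score),
        100.0 * ident / ncol, 100.0 * sim / ncol,
    )


def percent_similarity(a: ProteinRecord, b: ProteinRecord) -> float:
    return global_align(a, b).percent_similarity


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _codon_site_fractions(codon: str) -> tuple[float, ...]:
    """Per-position fraction of single-base changes that are synonymous,
    among changes that do not create a stop codon."""
    fractions = []
    for pos in range(3):
        syn = nonstop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            nonstop += 1
            if _AA[alt] == _AA[codon]:
                syn += 1
        fractions.append(syn / nonstop if nonstop else 0.0)
    return tuple(fractions)


_SITE_FRACTIONS = {c: _codon_site_fractions(c) for c in _AA}


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) substitution counts over all
    minimal pathways between two codons; pathways through stops excluded
    (all pathways used as fallback if every one is blocked)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                # stop intermediate: pathway excluded; scored nonsynonymous
                # in the all-pathways fallback
                ok = False
                nd += 1
            elif _AA.get(nxt) == _AA.get(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else blocked).append((sd, nd))
    # if every minimal pathway passes through a stop, average over all of
    # them rather than dropping the codon pair
    use = valid if valid else blocked
    sd_avg = sum(p[0] for p in use) / len(use)
    nd_avg = sum(p[1] for p in use) / len(use)
    return sd_avg, nd_avg


def jukes_cantor(p: float) -> float:
    """JC correction; NaN when p >= 3/4 (saturation)."""
    if p < 0:
        raise ValidationError("proportion of differences cannot be negative")
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float  # NaN when undefined
    selection: str
    codons: int = 0


def _split_codons(cds: str, label: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValidationError(f"{label}: CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in _STOPS:
            raise ValidationError(f"{label}: internal stop codon at codon {i + 1}")
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    return codons


def ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks between two equal-length, in-frame CDS.

    Codons containing non-ACGT characters in either sequence are dropped
    pairwise.  Rates with p >= 3/4 are saturated (NaN); the ratio is NaN
    whenever Ka or Ks is undefined or Ks is zero.
    """
    if len(cds_a) != len(cds_b):
        raise ValidationError("CDS lengths differ")
    cod_a = _split_codons(cds_a, "cds_a")
    cod_b = _split_codons(cds_b, "cds_b")
    n_trimmed = min(len(cod_a), len(cod_b))
    pairs = [
        (x, y)
        for x, y in zip(cod_a[:n_trimmed], cod_b[:n_trimmed])
        if set(x) <= set(_BASES) and set(y) <= set(_BASES)
    ]
    if not pairs:
        raise ValidationError("no comparable codons")
    s_a = s_b = sd = nd = 0.0
    for x, y in pairs:
        s_a += sum(_SITE_FRACTIONS[x])
        s_b += sum(_SITE_FRACTIONS[y])
        if x != y:
            d_s, d_n = _pathway_counts(x, y)
            sd += d_s
            nd += d_n
    ncod = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * ncod - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    ratio, selection = kaks_ratio(Ka, Ks)
    return KaKsResult(S, N, sd, nd, ps, pn, Ks, Ka, ratio, selection, codons=ncod)


def kaks_ratio(ka: float, ks: float) -> tuple[float, str]:
    """Ka/Ks with the selection-regime call.

    Purifying selection is declared when the ratio, rounded to the two
    decimals used in reports, is below 1.  Undefined when Ks is zero or
    either rate is saturated.
    """
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        return math.nan, UNDEFINED
    ratio = ka / ks
    return ratio, PURIFYING if round(ratio, 2) < 1.0 else NEUTRAL_OR_POSITIVE


# ---------------------------------------------------------------------------
# molecular clock


@dataclass(frozen=True)
class ClockConfig:
    """Synonymous-substitution clock rate, substitutions/site/year."""

    x: float = 6.5e-9

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValidationError("clock rate must be positive")


def divergence_time(ks: float, clock: ClockConfig = ClockConfig()) -> float:
    """T = Ks / (2x), in million years."""
    if ks < 0:
        raise ValidationError("Ks cannot be negative")
    return ks / (2.0 * clock.x) / 1e6


# ---------------------------------------------------------------------------
# duplicate detection


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    dup_type: str  # "tandem" | "segmental"
    similarity: float | None = None
    kaks: KaKsResult | None = None
    T_mya: float | None = None

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass(frozen=True)
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]


def find_tandem(
    family_genes: Sequence[GeneLocus],
    proteins: Mapping[str, ProteinRecord],
    sim_min: float = 40.0,
    max_intervening: int = 4,
) -> list[DuplicatePair]:
    """Detect tandem duplicates among family genes.

    ``family_genes`` must carry ranks computed over the full gene table so
    that intervening-gene counts refer to all annotated genes, not only
    family members.
    """
    for g in family_genes:
        if g.gene_id not in proteins:
            raise ValidationError(f"no protein sequence for family gene {g.gene_id}")
    pairs: list[DuplicatePair] = []
    seen: set[tuple[str, str]] = set()
    for ga, gb in combinations(family_genes, 2):
        if ga.chromosome != gb.chromosome:
            continue
        if abs(ga.rank - gb.rank) - 1 > max_intervening:
            continue
        sim = percent_similarity(proteins[ga.gene_id], proteins[gb.gene_id])
        if sim < sim_min:
            continue
        key = tuple(sorted((ga.gene_id, gb.gene_id)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(DuplicatePair(key[0], key[1], "tandem", similarity=sim))
    return sorted(pairs, key=lambda p: p.key())


def _chain_anchors(
    points: list[tuple[int, int, str, str]], min_chain: int, max_rank_gap: int
) -> list[list[tuple[str, str]]]:
    """Longest-chain DP over anchor points (rank_a, rank_b, id_a, id_b);
    both rank coordinates must increase with per-step gaps <= max_rank_gap."""
    chains: list[list[tuple[str, str]]] = []
    remaining = sorted(points)
    while remaining:
        n = len(remaining)
        best = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                da = remaining[i][0] - remaining[j][0]
                db = remaining[i][1] - remaining[j][1]
                if 1 <= da <= max_rank_gap and 1 <= db <= max_rank_gap:
                    if best[j] + 1 > best[i]:
                        best[i] = best[j] + 1
                        prev[i] = j
        top = max(range(n), key=lambda i: best[i])
        if best[top] < min_chain:
            break
        chain_idx = []
        i = top
        while i != -1:
            chain_idx.append(i)
            i = prev[i]
        chain_idx.reverse()
        chains.append([(remaining[i][2], remaining[i][3]) for i in chain_idx])
        used = set(chain_idx)
        remaining = [p for i, p in enumerate(remaining) if i not in used]
    return chains


def find_segmental(
    all_loci: Sequence[GeneLocus],
    anchors: Sequence[tuple[str, str]],
    min_chain: int = 3,
    max_rank_gap: int = 10,
    family_ids: Iterable[str] | None = None,
    min_self_separation: int | None = None,
) -> tuple[list[SyntenyBlock], list[DuplicatePair]]:
    """Chain high-similarity anchor pairs into collinear synteny blocks.

    Anchor pairs whose gene ranks run monotonically (either orientation)
    on both chromosomes, with per-step rank gaps at most ``max_rank_gap``,
    form a block once the chain reaches ``min_chain`` anchors.  Anchors of
    family genes inside a block are reported as segmental duplicates.

    Same-chromosome anchors closer than ``min_self_separation`` ranks
    (default ``max_rank_gap``) are discarded: runs of adjacent paralogs —
    tandem arrays — would otherwise chain along the diagonal and
    masquerade as a duplicated segment.
    """
    if min_self_separation is None:
        min_self_separation = max_rank_gap
    loci = {l.gene_id: l for l in all_loci}
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in anchors:
        if a not in loci or b not in loci:
            raise ValidationError(f"anchor gene without locus: {a}/{b}")
        la, lb = loci[a], loci[b]
        if (lb.chromosome, lb.rank) < (la.chromosome, la.rank):
            la, lb = lb, la
        if la.chromosome == lb.chromosome and lb.rank - la.rank < min_self_separation:
            continue
        by_chrom_pair.setdefault((la.chromosome, lb.chromosome), []).append(
            (la.rank, lb.rank, la.gene_id, lb.gene_id)
        )
    fam = set(family_ids) if family_ids is not None else None
    blocks: list[SyntenyBlock] = []
    pairs: list[DuplicatePair] = []
    for (ca, cb), points in sorted(by_chrom_pair.items()):
        # try both orientations: rank_b ascending (forward) and descending
        found = _chain_anchors(points, min_chain, max_rank_gap)
        flipped = [(ra, -rb, ia, ib) for ra, rb, ia, ib in points]
        found += _chain_anchors(flipped, min_chain, max_rank_gap)
        claimed: set[tuple[str, str]] = set()
        for chain in found:
            if any(p in claimed for p in chain):
                continue
            claimed.update(chain)
            blocks.append(SyntenyBlock(ca, cb, tuple(chain)))
            for ia, ib in chain:
                if fam is None or (ia in fam and ib in fam):
                    key = tuple(sorted((ia, ib)))
                    pairs.append(DuplicatePair(key[0], key[1], "segmental"))
    uniq = {p.key(): p for p in pairs}
    return blocks, sorted(uniq.values(), key=lambda p: p.key())


# ---------------------------------------------------------------------------
# reporting


def annotate_pairs(
    pairs: Sequence[DuplicatePair],
    cds: Mapping[str, str] | None,
    clock: ClockConfig = ClockConfig(),
) -> list[DuplicatePair]:
    """Attach NG86 Ka/Ks and clock dates to duplicate pairs where CDS exist."""
    out: list[DuplicatePair] = []
    for p in pairs:
        if cds is None or p.gene_a not in cds or p.gene_b not in cds:
            out.append(p)
            continue
        res = ng86(cds[p.gene_a], cds[p.gene_b])
        t = divergence_time(res.Ks, clock) if not math.isnan(res.Ks) else math.nan
        out.append(DuplicatePair(p.gene_a, p.gene_b, p.dup_type, p.similarity, res, t))
    return out


def duplicate_report(pairs: Sequence[DuplicatePair]) -> pd.DataFrame:
    """Duplicate-pair table with Ks, Ka, Ka/Ks, type, selection call and
    divergence time, rounded to two decimals as in published surveys."""
    rows = []
    for p in pairs:
        k = p.kaks
        rows.append(
            {
                "pair": f"{p.gene_a}/{p.gene_b}",
                "Ks": round(k.Ks, 2) if k else None,
                "Ka": round(k.Ka, 2) if k else None,
                "Ka/Ks": round(k.ratio, 2) if k and not math.isnan(k.ratio) else None,
                "duplicated_type": p.dup_type,
                "purify_selection": (
                    {PURIFYING: "Yes", NEUTRAL_OR_POSITIVE: "No"}.get(k.selection, "-")
                    if k else "-"
                ),
                "time_mya": round(p.T_mya, 2) if p.T_mya is not None and not math.isnan(p.T_mya) else None,
            }
        )
    return pd.DataFrame(rows)
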