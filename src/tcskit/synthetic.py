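"""Seeded synthetic-data generators with recorded ground truth.

Every pipeline stage can be exercised without downloads: the generators
emit a small multi-chromosome genome annotation with two-component-system
members of every family (including pseudo variants), tandem arrays and
collinear segmental blocks, codon pairs evolved at a known dN/dS, promoters
with implanted cis-elements, and Ct tables built from a known fold plan.
All generators are pure functions of (parameters, seed).

Family member proteins are assembled from the same signature config the
scanner uses, separated by random linkers; backgrounds and linkers are
rejection-sampled to be signature-free so that recorded truth is exact.
The generators emulate the combinatorial structure of a plant genome
survey, not the sequence statistics of a real proteome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import DomainArchitecture, classify_protein
from .errors import ValidationError
from .expression import CtTable
from .duplication import _AA as _CODON_AA, _STOPS, percent_similarity
from .promoter import CisElementDef, IUPAC_DNA, load_cis_elements, reverse_complement, scan_cis_elements
from .seqio import GeneLocus, ProteinRecord, assign_ranks
from .signatures import SignatureDef, find_tm_segments, load_signature_defs, scan_signatures

# Background amino-acid composition (rounded average over well-annotated
# proteomes); used for both decoys and linkers.
AA_FREQS = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.068,
}
_AA_LETTERS = list(AA_FREQS)
_AA_P = np.array([AA_FREQS[a] for a in _AA_LETTERS])
_AA_P = _AA_P / _AA_P.sum()

_SENSE_CODONS = sorted(_CODON_AA)
_BASES = "ACGT"

# substitutes used when a key catalytic residue is knocked out
_KEY_SUBSTITUTES = {"H": "YNQ", "D": "ENG"}

CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 13))


@dataclass
class GroundTruth:
    """Recorded truth shipped beside each generated dataset."""

    family_labels: dict[str, str] = field(default_factory=dict)
    subgroups: dict[str, str] = field(default_factory=dict)
    expected_confidence: dict[str, str] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    anchor_pairs: list[tuple[str, str]] = field(default_factory=list)
    omega: float | None = None
    realized_syn: int | None = None
    realized_nonsyn: int | None = None
    cis_implants: list[tuple[str, str, int, str]] = field(default_factory=list)
    cis_chance_hits: list[tuple[str, str, int, str]] = field(default_factory=list)
    fold_plan: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["tandem_pairs"] = [tuple(p) for p in d.get("tandem_pairs", [])]
        d["segmental_pairs"] = [tuple(p) for p in d.get("segmental_pairs", [])]
        d["anchor_pairs"] = [tuple(p) for p in d.get("anchor_pairs", [])]
        d["cis_implants"] = [tuple(p) for p in d.get("cis_implants", [])]
        d["cis_chance_hits"] = [tuple(p) for p in d.get("cis_chance_hits", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# proteome with implanted signatures


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LETTERS, size=length, p=_AA_P))


def signature_free_protein(
    rng: np.random.Generator,
    length: int,
    defs: Sequence[SignatureDef],
    max_tries: int = 200,
) -> str:
    """A random background sequence with no signature call at max_mismatch=2."""
    for _ in range(max_tries):
        seq = random_protein(rng, length)
        if not scan_signatures(ProteinRecord("bg", seq), defs):
            return seq
    raise ValidationError("could not generate a signature-free background sequence")


def _realize(sig: SignatureDef, rng: np.random.Generator, pseudo: bool) -> str:
    """Turn a degenerate pattern into a concrete segment; knock out the key
    residue for pseudo members."""
    out = []
    for i, p in enumerate(sig.pattern):
        if i == sig.key_residue_offset:
            if pseudo:
                out.append(rng.choice(list(_KEY_SUBSTITUTES[sig.key_residue])))
            else:
                out.append(sig.key_residue)
        elif p == "X":
            out.append(rng.choice(_AA_LETTERS, p=_AA_P))
        else:
            out.append(p)
    return "".join(out)


_TM_SEGMENT = "LLIVALLVVAIFLLIVALLV"

# per-family architecture recipes: (signature name, pseudo_key) in order;
# "TM" inserts a hydrophobic stretch instead of a config signature
_HK_BOX_ORDER = ("HK_Hbox", "HK_Nbox", "HK_G1box", "HK_Fbox", "HK_G2box")


def _family_recipe(family: str) -> tuple[tuple[str, bool], ...]:
    boxes_ok = tuple((b, False) for b in _HK_BOX_ORDER)
    boxes_pseudo = (("HK_Hbox", True),) + tuple((b, False) for b in _HK_BOX_ORDER[1:])
    recipes = {
        "HK": (("TM", False), ("CHASE", False)) + boxes_ok + (("REC", False),),
        "HKL": (("GAF", False), ("PHY", False), ("PAS", False)) + boxes_pseudo,
        "HP": (("Hpt", False),),
        "PHP": (("Hpt", True),),
        "RR_typeA": (("REC", False),),
        "RR_typeB": (("REC", False), ("Myb", False)),
        "RR_typeC_or_A": (("REC", False),),
        "PRR_clock": (("REC", True), ("CCT", False)),
        "PRR_typeB": (("REC", True), ("Myb", False)),
    }
    if family not in recipes:
        raise ValidationError(f"no architecture recipe for family {family!r}")
    return recipes[family]


_EXPECTED_SUBGROUP = {
    "HK": "cytokinin_receptor",
    "HKL": "phytochrome_like",
}

_PSEUDO_OF = {
    "HK": "HKL",
    "HP": "PHP",
    "RR_typeA": "PRR_clock",
    "RR_typeB": "PRR_typeB",
    "RR_typeC_or_A": "PRR_clock",
}


def _assemble_member(
    family: str, protein_id: str, rng: np.random.Generator, defs: Sequence[SignatureDef]
) -> str:
    by_name = {d.name: d for d in defs}
    long_family = family in ("HK", "HKL", "RR_typeC_or_A")
    for _ in range(200):
        parts = []
        for name, pseudo in _family_recipe(family):
            linker_len = int(rng.integers(25, 40)) if long_family else int(rng.integers(12, 22))
            parts.append(signature_free_protein(rng, linker_len, defs))
            parts.append(_TM_SEGMENT if name == "TM" else _realize(by_name[name], rng, pseudo))
        parts.append(signature_free_protein(rng, int(rng.integers(12, 22)), defs))
        if family == "RR_typeC_or_A":
            parts.append(signature_free_protein(rng, 260, defs))
        seq = "".join(parts)
        rec = ProteinRecord(protein_id, seq)
        calls = scan_signatures(rec, defs) + find_tm_segments(rec)
        label = classify_protein(DomainArchitecture(protein_id, tuple(calls), rec.length))
        if label.family == family:
            return seq
    raise ValidationError(f"could not assemble a {family} member")


def simulate_proteome(
    n_background: int,
    family_plan: Mapping[str, int],
    pseudo_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[GeneLocus], GroundTruth]:
    """Generate a proteome + gene table with implanted TCS members.

    ``family_plan`` maps family names to member counts.  With probability
    ``pseudo_fraction`` a planned member of an authentic family is emitted
    as its pseudo counterpart (HK->HKL, HP->PHP, type-B RR->type-B PRR,
    REC-only RR->clock PRR); truth records the emitted family.  Loci are
    scattered over 12 chromosomes.
    """
    if not 0.0 <= pseudo_fraction <= 1.0:
        raise ValidationError("pseudo_fraction must be in [0, 1]")
    if any(v < 0 for v in family_plan.values()):
        raise ValidationError("family counts must be non-negative")
    rng = np.random.default_rng(seed)
    defs = load_signature_defs()
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []
    idx = 0
    for family in sorted(family_plan):
        for _ in range(family_plan[family]):
            emitted = family
            if family in _PSEUDO_OF and rng.random() < pseudo_fraction:
                emitted = _PSEUDO_OF[family]
            idx += 1
            pid = f"TCS{idx:03d}"
            seq = _assemble_member(emitted, pid, rng, defs)
            proteins.append(ProteinRecord(pid, seq))
            truth.family_labels[pid] = emitted
            if emitted in _EXPECTED_SUBGROUP:
                truth.subgroups[pid] = _EXPECTED_SUBGROUP[emitted]
            truth.expected_confidence[pid] = (
                "low" if emitted == "RR_typeC_or_A" else "high"
            )
    for b in range(n_background):
        pid = f"BG{b + 1:04d}"
        seq = signature_free_protein(rng, int(rng.integers(120, 400)), defs)
        proteins.append(ProteinRecord(pid, seq))
        truth.family_labels[pid] = "not_TCS"
        truth.expected_confidence[pid] = "high"
    # scatter loci over the chromosomes, deterministic given the rng state
    order = rng.permutation(len(proteins))
    loci: list[GeneLocus] = []
    positions = {c: 1000 for c in CHROMOSOMES}
    for k in order:
        rec = proteins[k]
        chrom = CHROMOSOMES[int(rng.integers(0, len(CHROMOSOMES)))]
        start = positions[chrom]
        end = start + rec.length * 3 - 1
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(rec.id, chrom, start, end, strand))
        positions[chrom] = end + int(rng.integers(500, 5000))
    return proteins, assign_ranks(loci), truth


# ---------------------------------------------------------------------------
# codon-pair evolution at known dN/dS


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    return [ _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))] for _ in range(n_codons) ]


def _evolve(
    codons: list[str], omega: float, t: float, rng: np.random.Generator
) -> tuple[list[str], int, int]:
    """Accept/reject substitution scheme: candidate single-base changes are
    proposed uniformly (expected ``t`` proposals per codon), synonymous
    changes always accepted, nonsynonymous accepted with probability
    ``omega``, changes creating stops rejected."""
    seq = list(codons)
    n_prop = rng.poisson(t * len(seq))
    syn = nonsyn = 0
    for _ in range(n_prop):
        ci = int(rng.integers(0, len(seq)))
        pos = int(rng.integers(0, 3))
        cur = seq[ci]
        alt_base = _BASES[int(rng.integers(0, 4))]
        if alt_base == cur[pos]:
            continue
        cand = cur[:pos] + alt_base + cur[pos + 1 :]
        if cand in _STOPS:
            continue
        if _CODON_AA[cand] == _CODON_AA[cur]:
            seq[ci] = cand
            syn += 1
        elif rng.random() < omega:
            seq[ci] = cand
            nonsyn += 1
    return seq, syn, nonsyn


def simulate_codon_pair(
    n_codons: int, omega: float, t: float, seed: int = 0
) -> tuple[str, str, GroundTruth]:
    """Two CDS diverged from a common ancestor at dN/dS = ``omega``.

    ``t`` is the expected number of proposed substitutions per codon per
    branch; realized accepted synonymous/nonsynonymous counts (both
    branches pooled) are recorded in the truth.
    """
    if n_codons < 10:
        raise ValidationError("need at least 10 codons")
    if omega < 0:
        raise ValidationError("omega cannot be negative")
    if t < 0:
        raise ValidationError("branch length t must be non-negative")
    rng = np.random.default_rng(seed)
    anc = _random_cds(rng, n_codons)
    a, syn_a, nonsyn_a = _evolve(anc, omega, t, rng)
    b, syn_b, nonsyn_b = _evolve(anc, omega, t, rng)
    truth = GroundTruth(
        omega=omega, realized_syn=syn_a + syn_b, realized_nonsyn=nonsyn_a + nonsyn_b
    )
    return "".join(a), "".join(b), truth


def evolve_cds_family(
    n_codons: int, n_members: int, omega: float, t: float, seed: int = 0
) -> list[str]:
    """A family of CDS evolved independently from one ancestral sequence,
    each branch under the same accept/reject scheme as simulate_codon_pair."""
    rng = np.random.default_rng(seed)
    anc = _random_cds(rng, n_codons)
    out = []
    for _ in range(n_members):
        seq, _, _ = _evolve(anc, omega, t, rng)
        out.append("".join(seq))
    return out


def _mutate_protein(seq: str, frac: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_mut = int(round(frac * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [a for a in _AA_LETTERS if a != out[p]]
        out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# duplication layout (tandem arrays + segmental block)


def simulate_duplication_layout(
    array_sizes: Sequence[int],
    block_size: int,
    seed: int = 0,
    max_intervening: int = 4,
    sim_min: float = 40.0,
    diverged_arrays: Sequence[bool] | None = None,
    shuffle_block: bool = False,
) -> tuple[list[GeneLocus], dict[str, ProteinRecord], GroundTruth]:
    """A genome layout with tandem arrays and one segmental block.

    Each tandem array of size k places k family genes on one chromosome
    separated by 0..``max_intervening`` background genes; members of a
    non-diverged array are high-similarity copies of a common base protein
    (expected tandem pairs are exactly those within the intervening-gene
    window).  A ``diverged_arrays[i]`` entry makes array i's members
    unrelated sequences, below the similarity threshold, so no pairs are
    expected.  One block of ``block_size`` anchor genes is copied — in
    order, or permuted when ``shuffle_block`` — to another chromosome;
    anchor pairs are recorded as truth for collinearity chaining.
    """
    if any(k < 2 for k in array_sizes):
        raise ValidationError("tandem arrays need at least 2 members")
    if block_size < 2:
        raise ValidationError("segmental block needs at least 2 genes")
    if diverged_arrays is None:
        diverged_arrays = [False] * len(array_sizes)
    if len(diverged_arrays) != len(array_sizes):
        raise ValidationError("diverged_arrays length mismatch")
    rng = np.random.default_rng(seed)
    defs = load_signature_defs()
    proteins: dict[str, ProteinRecord] = {}
    placements: dict[str, list[str]] = {c: [] for c in CHROMOSOMES}
    truth = GroundTruth()
    bg_count = 0

    def new_background() -> str:
        nonlocal bg_count
        bg_count += 1
        pid = f"BG{bg_count:04d}"
        proteins[pid] = ProteinRecord(pid, random_protein(rng, 150))
        return pid

    # tandem arrays on successive chromosomes
    for ai, (size, diverged) in enumerate(zip(array_sizes, diverged_arrays)):
        chrom = CHROMOSOMES[ai % 6]
        genes = [f"ARR{ai + 1}_{m + 1}" for m in range(size)]
        base = random_protein(rng, 220)
        member_pos: dict[str, int] = {}
        cursor = len(placements[chrom])
        for m, gid in enumerate(genes):
            if m > 0:
                for _ in range(int(rng.integers(0, max_intervening + 1))):
                    placements[chrom].append(new_background())
            member_pos[gid] = len(placements[chrom])
            placements[chrom].append(gid)
            if diverged:
                seq = random_protein(rng, 220)
                # ensure the pair really falls below the similarity rule
                for _ in range(50):
                    if all(
                        percent_similarity(ProteinRecord(g, proteins[g].seq), ProteinRecord(gid, seq)) < sim_min
                        for g in genes[:m]
                        if g in proteins
                    ):
                        break
                    seq = random_protein(rng, 220)
            else:
                seq = _mutate_protein(base, 0.15, rng)
            proteins[gid] = ProteinRecord(gid, seq)
        if not diverged:
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    gap = abs(member_pos[genes[i]] - member_pos[genes[j]]) - 1
                    if gap <= max_intervening:
                        truth.tandem_pairs.append(tuple(sorted((genes[i], genes[j])))
                        )
    # segmental block: source on one chromosome, ordered (or shuffled) copy
    # on another, interleaved with background genes
    src_chrom, dst_chrom = CHROMOSOMES[8], CHROMOSOMES[9]
    src_genes = [f"BLKA_{m + 1}" for m in range(block_size)]
    dst_genes = [f"BLKB_{m + 1}" for m in range(block_size)]
    for gid in src_genes:
        proteins[gid] = ProteinRecord(gid, random_protein(rng, 200))
        placements[src_chrom].append(gid)
        placements[src_chrom].append(new_background())
    copy_order = list(range(block_size))
    if shuffle_block:
        while True:
            rng.shuffle(copy_order)
            # adjacent copies must not form a monotone run a chainer could
            # mistake for collinearity
            if not _has_monotone_run(copy_order, 3):
                break
    # the copy is padded densely enough that skipping a member exceeds any
    # reasonable per-step rank-gap limit: only contiguous runs can chain
    for m in copy_order:
        proteins[dst_genes[m]] = ProteinRecord(
            dst_genes[m], _mutate_protein(proteins[src_genes[m]].seq, 0.1, rng)
        )
        placements[dst_chrom].append(dst_genes[m])
        for _ in range(6):
            placements[dst_chrom].append(new_background())
    for s, d in zip(src_genes, dst_genes):
        truth.anchor_pairs.append((s, d))
        if not shuffle_block:
            truth.segmental_pairs.append(tuple(sorted((s, d))))
    # materialise coordinates
    loci: list[GeneLocus] = []
    for chrom, genes in placements.items():
        pos = 1000
        for gid in genes:
            end = pos + 900
            loci.append(GeneLocus(gid, chrom, pos, end, "+"))
            pos = end + 1100
    return assign_ranks(loci), proteins, truth


def _has_monotone_run(order: Sequence[int], k: int) -> bool:
    """True if the permutation holds an increasing or decreasing contiguous
    run of length >= k (which a collinearity chain could pick up)."""
    for sign in (1, -1):
        run = 1
        for i in range(1, len(order)):
            if sign * (order[i] - order[i - 1]) > 0:
                run += 1
                if run >= k:
                    return True
            else:
                run = 1
    return False


# ---------------------------------------------------------------------------
# promoters with implanted cis-elements


@dataclass(frozen=True)
class CisImplant:
    gene_id: str
    element: str
    offset: int
    strand: str


def _markov_background(rng: np.random.Generator, length: int, order: int = 3) -> str:
    """Third-order Markov DNA with seeded Dirichlet conditionals."""
    contexts: dict[str, np.ndarray] = {}
    seq = list("".join(rng.choice(list(_BASES), size=order)))
    for _ in range(length - order):
        ctx = "".join(seq[-order:])
        if ctx not in contexts:
            contexts[ctx] = rng.dirichlet(np.ones(4) * 2.0)
        seq.append(_BASES[int(rng.choice(4, p=contexts[ctx]))])
    return "".join(seq[:length])


def _realize_dna(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_DNA[p])) for p in pattern)


def simulate_promoters(
    n: int,
    implant_plan: Sequence[CisImplant],
    seed: int = 0,
    length: int = 1500,
) -> tuple[dict[str, str], GroundTruth]:
    """Promoter set with elements implanted at planned offsets/strands.

    Every planned (gene, element, offset, strand) tuple is recoverable by
    the scanner; chance background occurrences — unavoidable for short
    motifs in kilobase promoters — are recorded separately in
    ``truth.cis_chance_hits`` so the full scanner output is
    implants + flagged chance hits, exactly.
    """
    rng = np.random.default_rng(seed)
    defs = load_cis_elements()
    by_name = {d.name: d for d in defs}
    genes = [f"PRM{i + 1:03d}" for i in range(n)]
    by_gene: dict[str, list[CisImplant]] = {g: [] for g in genes}
    for imp in implant_plan:
        if imp.gene_id not in by_gene:
            raise ValidationError(f"implant for unknown gene {imp.gene_id}")
        if imp.element not in by_name:
            raise ValidationError(f"unknown element {imp.element}")
        plen = len(by_name[imp.element].pattern)
        if not 0 <= imp.offset <= length - plen:
            raise ValidationError(f"implant offset {imp.offset} leaves no room")
        by_gene[imp.gene_id].append(imp)
    for g, plan in by_gene.items():
        spans = sorted((p.offset, p.offset + len(by_name[p.element].pattern)) for p in plan)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValidationError(f"overlapping implants in {g}")
    promoters: dict[str, str] = {}
    truth = GroundTruth()
    for g in genes:
        plan = by_gene[g]
        planned = {(g, p.element, p.offset, p.strand) for p in plan}
        for _ in range(50):
            seq = list(_markov_background(rng, length))
            for p in plan:
                realized = _realize_dna(by_name[p.element].pattern, rng)
                if p.strand == "-":
                    realized = reverse_complement(realized)
                seq[p.offset : p.offset + len(realized)] = realized
            cand = "".join(seq)
            found = {
                (h.gene_id, h.element, h.offset, h.strand)
                for h in scan_cis_elements(cand, defs, gene_id=g)
            }
            if planned <= found:
                promoters[g] = cand
                truth.cis_chance_hits.extend(sorted(found - planned))
                break
        else:
            raise ValidationError(f"could not realise implant plan for {g}")
    truth.cis_implants = sorted(
        (p.gene_id, p.element, p.offset, p.strand) for p in implant_plan
    )
    return promoters, truth


# ---------------------------------------------------------------------------
# Ct tables from a known fold plan


def simulate_ct_table(
    fold_plan: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "UBI",
    control_sample: str = "control",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> tuple[CtTable, GroundTruth]:
    """Ct table whose noiseless ddCt recovery equals the fold plan exactly.

    ``fold_plan[gene][sample]`` is the target fold change versus the
    control sample; the control itself is implicitly 1.  The reference
    gene's Ct is constant across samples by construction; Gaussian noise
    (sd ``ct_noise_sd``) is added independently per replicate.
    """
    if ct_noise_sd < 0:
        raise ValidationError("noise sd must be non-negative")
    for g, samples in fold_plan.items():
        for s, f in samples.items():
            if f <= 0:
                raise ValidationError(f"fold for {g}/{s} must be positive")
    rng = np.random.default_rng(seed)
    samples = sorted({s for d in fold_plan.values() for s in d} | {control_sample})
    rows = []
    for gene in sorted(fold_plan):
        for sample in samples:
            fold = fold_plan[gene].get(sample, 1.0) if sample != control_sample else 1.0
            ct = base_ct - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "sample": sample, "replicate": rep, "ct": ct + noise})
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {"gene": reference_gene, "sample": sample, "replicate": rep, "ct": reference_ct + noise}
            )
    table = CtTable(pd.DataFrame(rows), reference_gene, control_sample)
    truth = GroundTruth(fold_plan={g: dict(d) for g, d in fold_plan.items()})
    return table, truth
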