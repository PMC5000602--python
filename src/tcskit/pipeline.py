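"""End-to-end survey orchestration and the synthetic survey bundle.

``run_survey`` wires the stages together — signature scan, classification,
duplication analysis with Ka/Ks and clock dating, per-family NJ trees,
promoter scanning and (optionally) qPCR expression — on a single config,
writing classification counts, a duplicate-pair report, Newick trees and a
cis-element summary.  Stages whose inputs are absent are skipped with a
warning; any stage failure raises with the stage named.

``simulate_bundle`` materialises a complete synthetic input set with
ground-truth files so a survey run can be checked end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import seqio
from .classify import DomainArchitecture, classify_proteome
from .duplication import (
    ClockConfig,
    annotate_pairs,
    duplicate_report,
    find_segmental,
    find_tandem,
    global_align,
    percent_similarity,
)
from .errors import TcskitError, ValidationError
from .expression import CtTable, delta_delta_ct, hclust_order, log2_matrix
from .phylo import DistanceMatrix, Msa, bootstrap_support, nj_tree
from .promoter import extract_promoter, scan_promoter_set, summarize_elements
from .signatures import find_tm_segments, load_signature_defs, scan_signatures
from .synthetic import (
    CisImplant,
    evolve_cds_family,
    simulate_ct_table,
    simulate_duplication_layout,
    simulate_promoters,
    simulate_proteome,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every survey constant in one place (editable, YAML-serialisable)."""

    blast_emax: float = 1e-5
    hmm_emax: float = 0.1
    sim_min: float = 40.0
    max_intervening: int = 4
    clock_x: float = 6.5e-9
    promoter_length: int = 1500
    bootstrap_reps: int = 1000
    min_chain: int = 3
    max_rank_gap: int = 10
    typeA_maxlen: int = 250
    anchor_sim_min: float = 60.0
    max_mismatch: int = 2
    seed: int = 0
    # input paths (optional stages skip when their path is None)
    proteome: str | None = None
    gene_table: str | None = None
    cds: str | None = None
    genome: str | None = None
    promoters: str | None = None
    ct_table: str | None = None
    hits_table: str | None = None
    family_list: str | None = None
    msa: str | None = None
    reference_gene: str = "UBI"
    control_sample: str = "control"
    outdir: str = "survey_out"

    def __post_init__(self) -> None:
        for name in ("blast_emax", "hmm_emax", "sim_min", "clock_x", "promoter_length", "bootstrap_reps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class StageFailure(TcskitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scan_proteome(proteins, cfg: PipelineConfig) -> list[DomainArchitecture]:
    defs = load_signature_defs()
    archs = []
    for rec in proteins:
        calls = scan_signatures(rec, defs, max_mismatch=cfg.max_mismatch) + find_tm_segments(rec)
        archs.append(DomainArchitecture(rec.id, tuple(calls), rec.length))
    return archs


def run_survey(cfg: PipelineConfig) -> dict[str, object]:
    """Run every stage the config provides inputs for; return the reports.

    Writes TSV/Newick reports under ``cfg.outdir`` and returns them in a
    dict keyed by stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, object] = {}
    logging.basicConfig(level=logging.INFO)
    log.info("survey start: seed=%d outdir=%s", cfg.seed, cfg.outdir)
    cfg.to_yaml(out / "config_used.yaml")

    if cfg.proteome is None:
        raise ValidationError("config.proteome is required")
    proteins = seqio.collapse_isoforms(seqio.read_fasta(cfg.proteome))
    loci = seqio.read_gene_table(cfg.gene_table) if cfg.gene_table else []

    try:
        archs = _scan_proteome(proteins, cfg)
        table, counts = classify_proteome(archs, typeA_maxlen=cfg.typeA_maxlen)
        table.to_csv(out / "classification.tsv", sep="\t", index=False)
        counts.to_csv(out / "family_counts.tsv", sep="\t", index=False)
        reports["classification"] = table
        reports["family_counts"] = counts
    except Exception as e:  # noqa: BLE001
        raise StageFailure("classify", e) from e

    tcs_ids = set(table.loc[table.family != "not_TCS", "protein_id"])
    if cfg.family_list:
        tcs_ids |= {
            line.strip()
            for line in Path(cfg.family_list).read_text().splitlines()
            if line.strip()
        }
    prot_by_id = {p.id: p for p in proteins}

    if loci:
        try:
            family_loci = [l for l in loci if l.gene_id in tcs_ids]
            tandem = find_tandem(
                family_loci, prot_by_id, sim_min=cfg.sim_min, max_intervening=cfg.max_intervening
            )
            anchors = [
                (a.id, b.id)
                for a, b in combinations(proteins, 2)
                if percent_similarity(a, b) >= cfg.anchor_sim_min
            ]
            # collapse tandem components before collinearity chaining so a
            # tandem array cannot masquerade as a self-collinear segment
            comp: dict[str, str] = {}

            def _root(x: str) -> str:
                while comp.get(x, x) != x:
                    x = comp[x]
                return x

            for p in tandem:
                ra, rb = _root(p.gene_a), _root(p.gene_b)
                if ra != rb:
                    comp[ra] = rb
            anchors = [(a, b) for a, b in anchors if _root(a) != _root(b)]
            blocks, segmental = find_segmental(
                loci, anchors, min_chain=cfg.min_chain,
                max_rank_gap=cfg.max_rank_gap, family_ids=tcs_ids or None,
            )
            tandem_keys = {p.key() for p in tandem}
            pairs = tandem + [p for p in segmental if p.key() not in tandem_keys]
            cds = seqio.read_dna_fasta(cfg.cds) if cfg.cds else None
            if cds is None:
                log.warning("no CDS input: Ka/Ks and dating skipped")
            pairs = annotate_pairs(pairs, cds, ClockConfig(cfg.clock_x))
            report = duplicate_report(pairs)
            report.to_csv(out / "duplicates.tsv", sep="\t", index=False)
            reports["duplicates"] = report
            reports["synteny_blocks"] = blocks
        except Exception as e:  # noqa: BLE001
            raise StageFailure("duplication", e) from e
    else:
        log.warning("no gene table: duplication analysis skipped")

    try:
        trees = {}
        if cfg.msa:
            msa = Msa.from_fasta(cfg.msa)
            tree = bootstrap_support(msa, reps=cfg.bootstrap_reps, seed=cfg.seed)
            (out / "msa_nj.nwk").write_text(seqio.write_newick(tree) + "\n")
            trees["msa"] = tree
        # per-family NJ trees from pairwise alignment p-distances
        for family, sub in table[table.family != "not_TCS"].groupby("family"):
            ids = sorted(sub.protein_id)
            if len(ids) < 3:
                continue
            n = len(ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    aln = global_align(prot_by_id[ids[i]], prot_by_id[ids[j]])
                    cols = [
                        (x, y)
                        for x, y in zip(aln.aligned_a, aln.aligned_b)
                        if x != "-" and y != "-"
                    ]
                    d[i, j] = d[j, i] = (
                        sum(1 for x, y in cols if x != y) / len(cols) if cols else 1.0
                    )
            tree = nj_tree(DistanceMatrix(tuple(ids), d))
            (out / f"family_{family}_nj.nwk").write_text(seqio.write_newick(tree) + "\n")
            trees[family] = tree
        reports["trees"] = trees
    except Exception as e:  # noqa: BLE001
        raise StageFailure("phylo", e) from e

    promoters: dict[str, str] | None = None
    try:
        if cfg.promoters:
            promoters = seqio.read_dna_fasta(cfg.promoters)
        elif cfg.genome and loci:
            genome = seqio.read_dna_fasta(cfg.genome)
            promoters = {
                l.gene_id: extract_promoter(l, genome, cfg.promoter_length)
                for l in loci
                if l.gene_id in tcs_ids
            }
        if promoters is not None:
            hits = scan_promoter_set(promoters)
            hits_df = pd.DataFrame([h.__dict__ for h in hits])
            hits_df.to_csv(out / "cis_hits.tsv", sep="\t", index=False)
            summary = summarize_elements(hits, promoters.keys())
            summary.to_csv(out / "cis_summary.tsv", sep="\t", index=False)
            reports["cis_hits"] = hits
            reports["cis_summary"] = summary
        else:
            log.warning("no promoter/genome input: cis-element scan skipped")
    except Exception as e:  # noqa: BLE001
        raise StageFailure("promoter", e) from e

    try:
        if cfg.ct_table:
            ct = CtTable.read_tsv(cfg.ct_table, cfg.reference_gene, cfg.control_sample)
            fold = delta_delta_ct(ct)
            logm = log2_matrix(fold)
            order, _ = hclust_order(logm) if len(logm.values) >= 2 else (list(logm.values.index), None)
            ordered = logm.values.loc[order]
            ordered.to_csv(out / "expression_log2.tsv", sep="\t")
            reports["expression_log2"] = ordered
        else:
            log.info("no Ct table: expression stage skipped")
    except Exception as e:  # noqa: BLE001
        raise StageFailure("expression", e) from e

    log.info("survey complete: %s", ", ".join(sorted(reports)))
    return reports


# ---------------------------------------------------------------------------
# synthetic survey bundle

DEFAULT_FAMILY_PLAN = {
    "HK": 3, "HKL": 3, "HP": 2, "PHP": 1,
    "RR_typeA": 3, "RR_typeB": 4, "RR_typeC_or_A": 1,
    "PRR_clock": 2, "PRR_typeB": 1,
}


def simulate_bundle(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete synthetic input set with ground truth under outdir.

    Sub-datasets: ``classification/`` (proteome + gene table emulating a
    TCS inventory), ``duplication/`` (tandem arrays + segmental block with
    per-gene CDS evolved from shared ancestors), ``promoters/`` and
    ``expression/``.
    """
    rng = np.random.default_rng(seed)
    out = Path(outdir)
    paths: dict[str, Path] = {}

    cls_dir = out / "classification"
    cls_dir.mkdir(parents=True, exist_ok=True)
    proteins, loci, truth = simulate_proteome(40, DEFAULT_FAMILY_PLAN, seed=seed)
    seqio.write_fasta([(p.id, p.seq) for p in proteins], cls_dir / "proteome.faa")
    seqio.write_gene_table(loci, cls_dir / "genes.gff3")
    truth.to_json(cls_dir / "truth.json")
    paths["classification"] = cls_dir

    dup_dir = out / "duplication"
    dup_dir.mkdir(parents=True, exist_ok=True)
    loci_d, prot_d, truth_d = simulate_duplication_layout([6, 3], 5, seed=seed + 1)
    seqio.write_gene_table(loci_d, dup_dir / "genes.gff3")
    seqio.write_fasta(sorted((p.id, p.seq) for p in prot_d.values()), dup_dir / "proteins.faa")
    cds: list[tuple[str, str]] = []
    groups: dict[str, list[str]] = {}
    for gid in prot_d:
        if gid.startswith("BG"):
            continue
        head, num = gid.split("_")
        # tandem-array members share one ancestor; block source/copy genes
        # are homologous pairwise (BLKA_i with BLKB_i)
        key = f"BLK_{num}" if head in ("BLKA", "BLKB") else head
        groups.setdefault(key, []).append(gid)
    for key, members in sorted(groups.items()):
        members = sorted(members)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seqs = evolve_cds_family(220, len(members), omega=0.3, t=0.15, seed=sub_seed)
        cds.extend(zip(members, seqs))
    seqio.write_fasta(cds, dup_dir / "cds.fna")
    (dup_dir / "family_ids.txt").write_text(
        "\n".join(sorted(g for g in prot_d if not g.startswith("BG"))) + "\n"
    )
    truth_d.to_json(dup_dir / "truth.json")
    paths["duplication"] = dup_dir

    prm_dir = out / "promoters"
    prm_dir.mkdir(parents=True, exist_ok=True)
    plan = [
        CisImplant("PRM001", "ABRE", 100, "+"),
        CisImplant("PRM001", "HSE", 700, "-"),
        CisImplant("PRM002", "MBS", 420, "+"),
        CisImplant("PRM003", "LTR", 60, "-"),
        CisImplant("PRM003", "TGACG_MeJA", 900, "+"),
    ]
    promoters, truth_p = simulate_promoters(4, plan, seed=seed + 2)
    seqio.write_fasta(sorted(promoters.items()), prm_dir / "promoters.fna")
    truth_p.to_json(prm_dir / "truth.json")
    paths["promoters"] = prm_dir

    expr_dir = out / "expression"
    expr_dir.mkdir(parents=True, exist_ok=True)
    fold_plan = {
        "TCS001": {"drought": 2.0, "salt": 0.5},
        "TCS002": {"drought": 4.0, "salt": 1.0},
        "TCS003": {"drought": 0.25, "salt": 8.0},
    }
    ct, truth_e = simulate_ct_table(fold_plan, ct_noise_sd=0.15, seed=seed + 3)
    ct.write_tsv(expr_dir / "ct.tsv")
    truth_e.to_json(expr_dir / "truth.json")
    paths["expression"] = expr_dir
    return paths
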