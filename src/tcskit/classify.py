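"""The two-component-system classification decision tree.

Families follow the standard plant TCS taxonomy: histidine kinases (HK) and
HK-likes (HKL, transmitter His substituted), phosphotransfer proteins (HP)
and pseudo-HPs (PHP, Hpt His substituted), response regulators by subtype
(type-A: short REC-only; type-B: REC + Myb; type-C: REC-only, ARR22-like),
and pseudo-response regulators (PRR, receiver Asp substituted) split into
clock PRRs (CCT domain) and type-B PRRs (Myb domain).

REC-only proteins are intrinsically ambiguous between type-A, type-C and
Myb-lost type-B; the tree separates them only by a protein-length heuristic
and flags every such call with low confidence rather than guessing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .signatures import (
    KEY_CONSERVED,
    KEY_SUBSTITUTED,
    TRANSMITTER_AUTHENTIC,
    TRANSMITTER_LIKE,
    DomainCall,
    has_transmitter,
)

FAMILIES = (
    "HK", "HKL", "HP", "PHP",
    "RR_typeA", "RR_typeB", "RR_typeC_or_A",
    "PRR_clock", "PRR_typeB", "not_TCS",
)

#: families whose members are pseudo (non-phosphorylatable) by definition
PSEUDO_FAMILIES = {"HKL", "PHP", "PRR_clock", "PRR_typeB"}

DEFAULT_TYPEA_MAXLEN = 250


@dataclass(frozen=True)
class DomainArchitecture:
    """The ordered domain calls observed on one protein."""

    protein_id: str
    calls: tuple[DomainCall, ...]
    length: int

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.protein_id != self.protein_id:
                raise ValidationError(
                    f"architecture {self.protein_id}: foreign call {c.protein_id}"
                )
        object.__setattr__(self, "calls", tuple(sorted(self.calls, key=lambda c: c.start)))

    def names(self) -> set[str]:
        return {c.name for c in self.calls}

    def first(self, name: str) -> DomainCall | None:
        for c in self.calls:
            if c.name == name:
                return c
        return None


@dataclass(frozen=True)
class TcsLabel:
    """Family/subgroup assignment with authenticity and confidence."""

    protein_id: str
    family: str
    subgroup: str = "n/a"
    authentic: bool = False
    confidence: str = "high"
    evidence: tuple[str, ...] = ()


def _hk_subgroup(arch: DomainArchitecture) -> str:
    names = arch.names()
    if "CHASE" in names:
        return "cytokinin_receptor"
    if "EthyleneBinding" in names:
        return "ethylene_receptor"
    if "GAF" in names and "PHY" in names:
        return "phytochrome_like"
    # CKI1-like / AHK1-like / PDK-like cannot be told apart by architecture
    return "other"


def classify_protein(arch: DomainArchitecture, typeA_maxlen: int = DEFAULT_TYPEA_MAXLEN) -> TcsLabel:
    """Assign exactly one TCS family to a protein; first matching rule wins.

    Rule order: transmitter (HK/HKL with sensor-domain subgrouping), then
    Hpt (HP/PHP by key-His status), then receiver (RR subtypes and PRRs by
    key-Asp status and Myb/CCT context), else not_TCS.
    """
    evidence: list[str] = []
    transmitter = has_transmitter(arch.calls)
    if transmitter in (TRANSMITTER_AUTHENTIC, TRANSMITTER_LIKE):
        family = "HK" if transmitter == TRANSMITTER_AUTHENTIC else "HKL"
        sub = _hk_subgroup(arch)
        evidence.append(f"transmitter:{transmitter}")
        evidence.append(f"subgroup:{sub}")
        return TcsLabel(
            arch.protein_id, family, sub,
            authentic=(family == "HK"), evidence=tuple(evidence),
        )

    hpt = arch.first("Hpt")
    if hpt is not None:
        if hpt.key_status == KEY_CONSERVED:
            return TcsLabel(arch.protein_id, "HP", authentic=True,
                            evidence=("hpt:conserved",))
        return TcsLabel(arch.protein_id, "PHP", authentic=False,
                        evidence=(f"hpt:substituted:{hpt.observed_key}",))

    rec = arch.first("REC")
    if rec is not None:
        names = arch.names()
        if rec.key_status == KEY_SUBSTITUTED:
            # pseudo-receiver: a PRR
            if "CCT" in names:  # CCT wins over Myb if both present
                return TcsLabel(arch.protein_id, "PRR_clock", authentic=False,
                                evidence=("rec:substituted", "cct"))
            if "Myb" in names:
                return TcsLabel(arch.protein_id, "PRR_typeB", authentic=False,
                                evidence=("rec:substituted", "myb"))
            return TcsLabel(arch.protein_id, "PRR_clock", authentic=False,
                            confidence="low", evidence=("rec:substituted", "no_marker"))
        if "Myb" in names:
            return TcsLabel(arch.protein_id, "RR_typeB", authentic=True,
                            evidence=("rec:conserved", "myb"))
        if arch.length <= typeA_maxlen:
            return TcsLabel(arch.protein_id, "RR_typeA", authentic=True,
                            evidence=("rec:conserved", f"short<= {typeA_maxlen}"))
        # long REC-only: type-C, or a type-B that lost its Myb — ambiguous
        return TcsLabel(arch.protein_id, "RR_typeC_or_A", authentic=True,
                        confidence="low", evidence=("rec:conserved", "rec_only_long"))

    return TcsLabel(arch.protein_id, "not_TCS", evidence=("no_tcs_domains",))


def classify_proteome(
    archs: Sequence[DomainArchitecture], typeA_maxlen: int = DEFAULT_TYPEA_MAXLEN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every architecture; return (per-protein table, family counts).

    The counts table mirrors the family inventory layout of genome-survey
    papers: one row per family with member and subgroup tallies.
    """
    ids = [a.protein_id for a in archs]
    dup = [i for i, n in Counter(ids).items() if n > 1]
    if dup:
        raise ValidationError(f"duplicate protein IDs: {dup}")
    labels = [classify_protein(a, typeA_maxlen) for a in archs]
    table = pd.DataFrame(
        {
            "protein_id": [l.protein_id for l in labels],
            "family": [l.family for l in labels],
            "subgroup": [l.subgroup for l in labels],
            "authentic": [l.authentic for l in labels],
            "confidence": [l.confidence for l in labels],
            "evidence": [";".join(l.evidence) for l in labels],
        }
    )
    fam_counts = (
        table[table.family != "not_TCS"]
        .groupby(["family", "subgroup"])
        .size()
        .rename("n")
        .reset_index()
    )
    return table, fam_counts
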