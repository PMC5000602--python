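"""Signature-motif scanning on protein sequences.

Two-component-system proteins are recognised by short conserved signatures:
the five transmitter boxes of the histidine-kinase domain (H, N, G1, F, G2),
the Hpt phosphotransfer motif, the receiver (REC) motif around the
phospho-accepting Asp, and accessory sensor domains (CHASE, GAF/PHY/PAS,
ethylene-binding, CCT, Myb).  Patterns are degenerate strings (X = any
residue) shipped as editable YAML config.  The phospho-accepting key
residue inside a match is judged exactly and separately: a window that
matches everywhere else but carries a substituted key residue still yields
a call, flagged ``substituted`` — this is the authentic-vs-pseudo
discriminator for HKs, HPs and response regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ValidationError
from .seqio import ProteinRecord

KEY_CONSERVED = "conserved"
KEY_SUBSTITUTED = "substituted"
KEY_NA = "n/a"

# Kyte-Doolittle hydropathy index, used by the transmembrane heuristic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

HK_BOXES = ("HK_Hbox", "HK_Nbox", "HK_G1box", "HK_Fbox", "HK_G2box")
HK_AUX_BOXES = ("HK_Nbox", "HK_G1box", "HK_Fbox", "HK_G2box")


@dataclass(frozen=True)
class SignatureDef:
    """A degenerate pattern with an optional key catalytic residue."""

    name: str
    pattern: str
    key_residue_offset: int | None = None
    key_residue: str | None = None

    def __post_init__(self) -> None:
        if self.key_residue_offset is not None:
            if self.key_residue is None:
                raise ValidationError(f"{self.name}: key offset without key residue")
            if not 0 <= self.key_residue_offset < len(self.pattern):
                raise ValidationError(f"{self.name}: key offset outside pattern")


@dataclass(frozen=True)
class DomainCall:
    """One signature/domain occurrence on a protein (0-based half-open span)."""

    protein_id: str
    name: str
    start: int
    end: int
    key_status: str = KEY_NA
    observed_key: str | None = None
    source: str = "scan"  # "scan" | "external"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"{self.protein_id}/{self.name}: bad span")


def load_signature_defs(path: str | Path | None = None) -> list[SignatureDef]:
    """Load signature definitions from YAML (default: the packaged set)."""
    if path is None:
        text = resources.files("tcskit.data").joinpath("signatures.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return [
        SignatureDef(
            d["name"],
            d["pattern"].upper(),
            d.get("key_residue_offset"),
            d.get("key_residue"),
        )
        for d in doc["signatures"]
    ]


def _window_call(
    protein: ProteinRecord, sig: SignatureDef, pos: int, max_mismatch: int
) -> DomainCall | None:
    """Evaluate one window; key-residue position never counts as a mismatch."""
    window = protein.seq[pos : pos + len(sig.pattern)]
    mismatches = 0
    matches = 0
    for i, (p, c) in enumerate(zip(sig.pattern, window)):
        if p == "X" or i == sig.key_residue_offset:
            continue
        if p == c:
            matches += 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                return None
    if sig.key_residue_offset is None:
        status, observed = KEY_NA, None
    else:
        observed = window[sig.key_residue_offset]
        status = KEY_CONSERVED if observed == sig.key_residue else KEY_SUBSTITUTED
    return DomainCall(
        protein.id, sig.name, pos, pos + len(sig.pattern),
        key_status=status, observed_key=observed, score=float(matches),
    )


def _merge_overlapping_same_name(calls: list[DomainCall]) -> list[DomainCall]:
    """Within one signature name, keep the best-scoring window per overlap chain."""
    out: list[DomainCall] = []
    for call in sorted(calls, key=lambda c: (c.start, c.end)):
        if out and call.start < out[-1].end:
            if call.score > out[-1].score:
                out[-1] = call
        else:
            out.append(call)
    return out


def scan_signatures(
    protein: ProteinRecord,
    defs: Sequence[SignatureDef] | None = None,
    max_mismatch: int = 2,
) -> list[DomainCall]:
    """Scan a protein against the signature set.

    A window matches when it disagrees with the pattern at no more than
    ``max_mismatch`` non-X positions; the key-residue position is excluded
    from that count and evaluated into ``key_status`` instead.  Overlapping
    windows of the same signature collapse to the best-scoring one.
    """
    if defs is None:
        defs = load_signature_defs()
    if not defs:
        raise ValidationError("empty signature definition list")
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    calls: list[DomainCall] = []
    for sig in defs:
        if len(sig.pattern) > protein.length:
            continue
        hits = []
        for pos in range(protein.length - len(sig.pattern) + 1):
            c = _window_call(protein, sig, pos, max_mismatch)
            if c is not None:
                hits.append(c)
        calls.extend(_merge_overlapping_same_name(hits))
    return sorted(calls, key=lambda c: (c.start, c.end, c.name))


def find_tm_segments(protein: ProteinRecord, min_len: int = 17, min_kd: float = 1.6) -> list[DomainCall]:
    """Transmembrane-helix heuristic: runs of >= min_len residues whose mean
    Kyte-Doolittle hydropathy exceeds ``min_kd``.  Overlapping qualifying
    windows are fused into maximal segments."""
    seq = protein.seq
    if protein.length < min_len:
        return []
    kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    spans: list[list[int]] = []
    running = sum(kd[:min_len])
    for pos in range(protein.length - min_len + 1):
        if pos > 0:
            running += kd[pos + min_len - 1] - kd[pos - 1]
        if running / min_len > min_kd:
            if spans and pos <= spans[-1][1]:
                spans[-1][1] = pos + min_len
            else:
                spans.append([pos, pos + min_len])
    return [DomainCall(protein.id, "TM", s, e) for s, e in spans]


def merge_calls(
    scan_calls: Sequence[DomainCall], external_calls: Sequence[DomainCall]
) -> list[DomainCall]:
    """Union scan-derived and externally ingested calls for one protein.

    Where same-name spans overlap by more than half of the shorter span the
    scan call wins — external tables carry no key-residue status.
    """
    all_calls = list(scan_calls) + list(external_calls)
    ids = {c.protein_id for c in all_calls}
    if len(ids) > 1:
        raise ValidationError(f"merge_calls: mixed protein IDs {sorted(ids)}")
    kept = list(scan_calls)
    for ext in external_calls:
        shadowed = False
        for sc in scan_calls:
            if sc.name != ext.name:
                continue
            overlap = min(sc.end, ext.end) - max(sc.start, ext.start)
            if overlap > 0.5 * min(sc.end - sc.start, ext.end - ext.start):
                shadowed = True
                break
        if not shadowed:
            kept.append(replace(ext, source="external"))
    return sorted(kept, key=lambda c: (c.start, c.end, c.name))


TRANSMITTER_AUTHENTIC = "authentic_HK"
TRANSMITTER_LIKE = "HK_like"
TRANSMITTER_ABSENT = "absent"


def has_transmitter(calls: Iterable[DomainCall]) -> str:
    """Judge the histidine-kinase transmitter from the five-box signature.

    ``authentic_HK``: H-box present with its His conserved and at least two
    of the N/G1/F/G2 boxes.  ``HK_like``: boxes present but the H-box His is
    substituted, or the H-box is missing while at least three other boxes
    are found.  Otherwise ``absent``.
    """
    by_name: dict[str, DomainCall] = {}
    for c in calls:
        if c.name in HK_BOXES and c.name not in by_name:
            by_name[c.name] = c
    hbox = by_name.get("HK_Hbox")
    n_aux = sum(1 for b in HK_AUX_BOXES if b in by_name)
    if hbox is not None and hbox.key_status == KEY_CONSERVED and n_aux >= 2:
        return TRANSMITTER_AUTHENTIC
    if hbox is not None and hbox.key_status == KEY_SUBSTITUTED and n_aux >= 2:
        return TRANSMITTER_LIKE
    if hbox is None and n_aux >= 3:
        return TRANSMITTER_LIKE
    return TRANSMITTER_ABSENT
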