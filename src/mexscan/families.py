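"""Domain-architecture classification of AP2/ERF and MIKC gene families.

Subfamily rules for AP2/ERF follow the domain-count convention used across
the plant transcription-factor literature: one AP2 domain alone defines
ERF/DREB, two AP2 repeats define the AP2 subfamily, AP2 plus B3 defines RAV,
and AP2 plus any other recognized domain falls into "other". MIKC (type II
MADS-box) genes require both an SRF-TF (MADS-box) and a K-box domain;
type I genes (SRF-TF without K-box) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .io import DomainHit

FAMILY_AP2_ERF = "AP2/ERF"
FAMILY_MIKC = "MIKC"
FAMILY_NONE = "none"

SUBFAMILY_ERF = "ERF/DREB"
SUBFAMILY_AP2 = "AP2"
SUBFAMILY_RAV = "RAV"
SUBFAMILY_OTHER = "other"


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str = FAMILY_NONE
    subfamily: str | None = None
    evidence: list[DomainHit] = field(default_factory=list)

    def count(self, label: str) -> int:
        return sum(1 for h in self.evidence if h.label == label)


def classify_ap2_erf(hits_for_protein: list[DomainHit], gene_id: str = "") -> FamilyAssignment:
    """Assign an AP2/ERF subfamily from a protein's merged domain hits.

    Rules (priority order): >=2 AP2 -> AP2 subfamily; 1 AP2 + >=1 B3 -> RAV;
    1 AP2 + >=1 other labeled non-AP2/non-B3 domain -> other; exactly 1 AP2
    alone -> ERF/DREB; 0 AP2 -> no family.
    """
    n_ap2 = sum(1 for h in hits_for_protein if h.label == "AP2")
    n_b3 = sum(1 for h in hits_for_protein if h.label == "B3")
    n_extra = sum(1 for h in hits_for_protein if h.label not in ("AP2", "B3"))
    if n_ap2 == 0:
        return FamilyAssignment(gene_id=gene_id)
    if n_ap2 >= 2:
        sub = SUBFAMILY_AP2
    elif n_b3 >= 1:
        sub = SUBFAMILY_RAV
    elif n_extra >= 1:
        sub = SUBFAMILY_OTHER
    else:
        sub = SUBFAMILY_ERF
    return FamilyAssignment(
        gene_id=gene_id, family=FAMILY_AP2_ERF, subfamily=sub,
        evidence=list(hits_for_protein),
    )


def identify_mikc(hits_for_protein: list[DomainHit], gene_id: str = "") -> FamilyAssignment:
    """MIKC iff the protein carries both an SRF-TF and a K-box domain."""
    has_srf = any(h.label == "SRF-TF" for h in hits_for_protein)
    has_kbox = any(h.label == "K-box" for h in hits_for_protein)
    if has_srf and has_kbox:
        return FamilyAssignment(
            gene_id=gene_id, family=FAMILY_MIKC, evidence=list(hits_for_protein)
        )
    return FamilyAssignment(gene_id=gene_id)


def label_ap2_repeats(assignment: FamilyAssignment) -> FamilyAssignment:
    """Number AP2 hits R1, R2, ... by ascending protein start (N to C terminus).

    No-op unless the assignment is the AP2 subfamily.
    """
    if assignment.subfamily != SUBFAMILY_AP2:
        return assignment
    ap2 = sorted(
        (h for h in assignment.evidence if h.label == "AP2"), key=lambda h: h.start
    )
    for k, h in enumerate(ap2):
        h.repeat_label = f"R{k + 1}"
    return assignment


def classify_protein(hits_for_protein: list[DomainHit], gene_id: str = "") -> FamilyAssignment:
    """Full family dispatch: AP2/ERF takes precedence, then MIKC, else none."""
    a = classify_ap2_erf(hits_for_protein, gene_id=gene_id)
    if a.family == FAMILY_AP2_ERF:
        return label_ap2_repeats(a)
    m = identify_mikc(hits_for_protein, gene_id=gene_id)
    return m
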