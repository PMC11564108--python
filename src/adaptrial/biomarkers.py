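"""ctDNA biomarker classification for adaptive randomization.

Each patient's plasma variant table is reduced to four binary biomarkers --
AR (SNV/GSR) positivity, TP53 alteration, homologous recombination
deficiency (HRD) and TMPRSS2-ERG fusion positivity -- which jointly define
one of 16 biomarker subgroup combinations used to stratify randomization.
Because individual subgroups can be rare, efficacy is evaluated within five
overlapping biomarker *signatures* (prespecified unions of subgroups):

- ``all``            any subgroup (biomarker-unselected),
- ``ar_neg_tp53_wt`` no AR SNV/GSR and TP53 wild type,
- ``hrd``            qualifying alteration in a 17-gene DNA-repair panel,
- ``tp53_altered``   clonal TP53 alteration,
- ``terg_positive``  clonal TMPRSS2-ERG fusion.

Clonality rules: only *clonal* alterations qualify for TP53, HRD and
TMPRSS2-ERG, whereas any AR hotspot SNV or genomic structural rearrangement
counts regardless of clonality.  Whole-gene AR copy-number amplification is
deliberately not a qualifying event.  Patients with microsatellite
instability or undetectable ctDNA are ineligible for biomarker-driven
randomization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AlterationClass",
    "VariantOrigin",
    "VariantCall",
    "BiomarkerProfile",
    "HRD_GENES",
    "SIGNATURES",
    "classify_patient",
    "subgroup_index",
    "subgroup_booleans",
    "signature_membership",
    "signature_subgroups",
    "ctdna_band",
    "read_variant_table",
    "classify_variant_table",
    "write_profile_table",
]

# DNA-repair genes whose clonal somatic or germline alterations qualify as HRD.
HRD_GENES: frozenset[str] = frozenset(
    {
        "ATM", "ATR", "BARD1", "BRCA1", "BRCA2", "BRIP1", "CDK12", "CHEK2",
        "FANCA", "MRE11A", "NBN", "PALB2", "RAD50", "RAD51", "RAD51B",
        "RAD51C", "RAD51D",
    }
)

SIGNATURES: tuple[str, ...] = (
    "all",
    "ar_neg_tp53_wt",
    "hrd",
    "tp53_altered",
    "terg_positive",
)


class AlterationClass(str, Enum):
    HOTSPOT_SNV = "hotspot_snv"
    HIGH_IMPACT_SNV = "high_impact_snv"
    STRUCTURAL_REARRANGEMENT = "structural_rearrangement"
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    GENE_FUSION = "gene_fusion"


class VariantOrigin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"


@dataclass(frozen=True)
class VariantCall:
    """One called alteration in the patient's ctDNA (or germline) profile."""

    gene: str
    alteration_class: AlterationClass
    origin: VariantOrigin = VariantOrigin.SOMATIC
    clonal: bool = True
    known_benign: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(
            self, "alteration_class", AlterationClass(self.alteration_class)
        )
        object.__setattr__(self, "origin", VariantOrigin(self.origin))

    @property
    def effectively_clonal(self) -> bool:
        # Germline variants are carried by every cell and are treated as clonal.
        return self.clonal or self.origin is VariantOrigin.GERMLINE


@dataclass(frozen=True)
class BiomarkerProfile:
    """The four binary biomarkers plus eligibility metadata for one patient."""

    ar_positive: bool
    tp53_altered: bool
    hrd: bool
    terg_positive: bool
    ctdna_fraction: float
    msi: bool = False

    ctdna_band: str = field(init=False)
    subgroup_index: int = field(init=False)
    signatures: frozenset[str] = field(init=False)
    eligible: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ctdna_band", ctdna_band(self.ctdna_fraction))
        object.__setattr__(self, "subgroup_index", subgroup_index(self))
        object.__setattr__(self, "signatures", frozenset(signature_membership(self)))
        object.__setattr__(
            self, "eligible", (not self.msi) and self.ctdna_fraction > 0.0
        )


def ctdna_band(fraction: float) -> str:
    """Bin the ctDNA fraction: low (<5%), medium (5-40%), high (>=40%)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"ctDNA fraction must lie in [0, 1], got {fraction!r}")
    if fraction < 0.05:
        return "low"
    if fraction < 0.40:
        return "medium"
    return "high"


def subgroup_index(profile: BiomarkerProfile) -> int:
    """Binary encoding of the four biomarkers: AR*8 + TP53*4 + HRD*2 + TERG*1."""
    return (
        8 * profile.ar_positive
        + 4 * profile.tp53_altered
        + 2 * profile.hrd
        + 1 * profile.terg_positive
    )


def subgroup_booleans(index: int) -> tuple[bool, bool, bool, bool]:
    """Inverse of :func:`subgroup_index`: (ar, tp53, hrd, terg) for an index."""
    if not 0 <= index <= 15:
        raise ValueError(f"subgroup index must lie in 0..15, got {index}")
    return bool(index & 8), bool(index & 4), bool(index & 2), bool(index & 1)


def signature_membership(profile: BiomarkerProfile) -> set[str]:
    """Signatures this profile belongs to (a profile may be in several)."""
    sigs = {"all"}
    if not profile.ar_positive and not profile.tp53_altered:
        sigs.add("ar_neg_tp53_wt")
    if profile.hrd:
        sigs.add("hrd")
    if profile.tp53_altered:
        sigs.add("tp53_altered")
    if profile.terg_positive:
        sigs.add("terg_positive")
    return sigs


def signature_subgroups(signature: str) -> frozenset[int]:
    """The set of subgroup indices (0-15) belonging to a signature."""
    if signature not in SIGNATURES:
        raise ValueError(f"unknown signature {signature!r}")
    members = []
    for idx in range(16):
        ar, tp53, hrd, terg = subgroup_booleans(idx)
        prof = BiomarkerProfile(ar, tp53, hrd, terg, ctdna_fraction=0.1)
        if signature in prof.signatures:
            members.append(idx)
    return frozenset(members)


_AR_QUALIFYING = {
    AlterationClass.HOTSPOT_SNV,
    AlterationClass.STRUCTURAL_REARRANGEMENT,
}
_TP53_QUALIFYING = {
    AlterationClass.HOTSPOT_SNV,
    AlterationClass.HIGH_IMPACT_SNV,
    AlterationClass.STRUCTURAL_REARRANGEMENT,
    AlterationClass.HOMOZYGOUS_DELETION,
}
# HRD: structural variation, hotspot/high-impact point mutation not known
# benign, or homozygous deletion.
_HRD_QUALIFYING = _TP53_QUALIFYING
# TMPRSS2-ERG: fusion detected by structural rearrangement or by deletion.
_TERG_QUALIFYING = {
    AlterationClass.GENE_FUSION,
    AlterationClass.STRUCTURAL_REARRANGEMENT,
    AlterationClass.HOMOZYGOUS_DELETION,
}
_TERG_GENES = {"TMPRSS2-ERG", "TMPRSS2_ERG", "ERG", "TMPRSS2"}


def classify_patient(
    variants: Iterable[VariantCall],
    ctdna_fraction: float,
    msi: bool = False,
) -> BiomarkerProfile:
    """Classify a patient's variant calls into a :class:`BiomarkerProfile`.

    AR positivity requires a hotspot SNV or structural rearrangement in AR
    regardless of clonality; TP53, HRD and TMPRSS2-ERG positivity require a
    clonal qualifying alteration (germline counts as clonal for HRD genes).
    """
    if not 0.0 <= ctdna_fraction <= 1.0:
        raise ValueError(
            f"ctDNA fraction must lie in [0, 1], got {ctdna_fraction!r}"
        )
    ar = tp53 = hrd = terg = False
    for v in variants:
        if not isinstance(v, VariantCall):
            v = VariantCall(**v)  # allow plain dict rows
        if v.known_benign:
            continue
        if v.gene == "AR" and v.alteration_class in _AR_QUALIFYING:
            ar = True
        if (
            v.gene == "TP53"
            and v.effectively_clonal
            and v.alteration_class in _TP53_QUALIFYING
        ):
            tp53 = True
        if (
            v.gene in HRD_GENES
            and v.effectively_clonal
            and v.alteration_class in _HRD_QUALIFYING
        ):
            hrd = True
        if (
            v.gene in _TERG_GENES
            and v.effectively_clonal
            and v.alteration_class in _TERG_QUALIFYING
        ):
            terg = True
    return BiomarkerProfile(
        ar_positive=ar,
        tp53_altered=tp53,
        hrd=hrd,
        terg_positive=terg,
        ctdna_fraction=ctdna_fraction,
        msi=msi,
    )


# ---------------------------------------------------------------------------
# Tabular I/O: simple TSV of variant calls in, per-patient profile CSV out.
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = (
    "patient_id",
    "gene",
    "alteration_class",
    "origin",
    "clonal",
    "known_benign",
    "ctdna_fraction",
    "msi",
)

_TRUE = {"1", "true", "yes", "t"}


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in _TRUE


def read_variant_table(path: str | Path) -> dict[str, dict]:
    """Read a tab-delimited variant table into per-patient inputs.

    The table has one row per variant call with columns ``patient_id, gene,
    alteration_class, origin, clonal, known_benign, ctdna_fraction, msi``.
    A row with an empty ``gene`` records a patient with no qualifying calls
    (still carrying a ctDNA fraction and MSI flag).
    """
    patients: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty variant table")
        missing = set(_VARIANT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            pid = row["patient_id"].strip()
            entry = patients.setdefault(
                pid,
                {
                    "variants": [],
                    "ctdna_fraction": float(row["ctdna_fraction"]),
                    "msi": _parse_bool(row["msi"]),
                },
            )
            if row["gene"].strip():
                entry["variants"].append(
                    VariantCall(
                        gene=row["gene"],
                        alteration_class=AlterationClass(
                            row["alteration_class"].strip().lower()
                        ),
                        origin=VariantOrigin(row["origin"].strip().lower()),
                        clonal=_parse_bool(row["clonal"]),
                        known_benign=_parse_bool(row["known_benign"]),
                    )
                )
    return patients


def classify_variant_table(path: str | Path) -> dict[str, BiomarkerProfile]:
    """Classify every patient in a variant TSV."""
    return {
        pid: classify_patient(e["variants"], e["ctdna_fraction"], e["msi"])
        for pid, e in read_variant_table(path).items()
    }


def write_profile_table(
    profiles: dict[str, BiomarkerProfile], path: str | Path
) -> None:
    """Write classified profiles to CSV (one row per patient)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "patient_id", "ar", "tp53", "hrd", "terg",
                "subgroup_index", "signatures", "ctdna_band", "eligible",
            ]
        )
        for pid, p in profiles.items():
            writer.writerow(
                [
                    pid,
                    int(p.ar_positive), int(p.tp53_altered),
                    int(p.hrd), int(p.terg_positive),
                    p.subgroup_index,
                    ";".join(s for s in SIGNATURES if s in p.signatures),
                    p.ctdna_band,
                    int(p.eligible),
                ]
            )
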