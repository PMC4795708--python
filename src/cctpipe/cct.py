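"""Cerebral circulation time (CCT) indices.

A CCT is the venous-minus-arterial difference of time-to-peak measurements:
positive when the vein peaks later, which is the physiologic case.  On DSA
each carotid injection contributes two indices (ACA and insular MCA branch
against the ipsilateral superior sagittal sinus reading); on CT perfusion the
dominant A2 and both M2 branches are each referenced to the single SSS ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

from .tdc import MODALITY_CTP, MODALITY_DSA, TTPMeasurement

FLAG_NEGATIVE_CCT = "negative_cct"

#: index name -> (arterial ROI, venous ROI) per modality
DSA_PAIRING = {
    "XA-CCT_RA2": ("RA2", "SSS_right"),
    "XA-CCT_RM2": ("RM2", "SSS_right"),
    "XA-CCT_LA2": ("LA2", "SSS_left"),
    "XA-CCT_LM2": ("LM2", "SSS_left"),
}
CTP_PAIRING = {
    "CT-CCT_A2": ("A2", "SSS"),
    "CT-CCT_RM2": ("RM2", "SSS"),
    "CT-CCT_LM2": ("LM2", "SSS"),
}


class PairingError(ValueError):
    """Raised when two readers' records cannot be matched one-to-one."""


@dataclass
class CCTRecord:
    subject_id: str
    index_name: str
    value: float
    arterial_ttp: float
    venous_ttp: float
    reader_id: str = ""
    flags: set = field(default_factory=set)


def compute_cct(arterial: TTPMeasurement, venous: TTPMeasurement) -> float:
    """venous TTP minus arterial TTP, in seconds.

    Negative values are returned as-is; callers flag them (a vein peaking
    before its artery indicates an ROI or quality problem, not a valid
    physiologic state).
    """
    return float(venous.ttp - arterial.ttp)


def subject_ccts(ttps: Mapping[str, TTPMeasurement], modality: str,
                 dominant_aca_side: str = "", subject_id: str = "",
                 reader_id: str = "") -> Tuple[List[CCTRecord], List[str]]:
    """All circulation-time records one subject's modality supports.

    Returns ``(records, missing)`` where ``missing`` lists the index names
    that could not be formed because an ROI measurement was absent; four
    records are expected for DSA, three for CTP.  On CTP the A2 measurement
    is by convention taken at the dominant-side ACA; the side travels as
    metadata only.
    """
    if modality == MODALITY_DSA:
        pairing = DSA_PAIRING
    elif modality == MODALITY_CTP:
        pairing = CTP_PAIRING
    else:
        raise ValueError(f"unknown modality {modality!r}")
    records, missing = [], []
    for index_name, (art, ven) in pairing.items():
        if art not in ttps or ven not in ttps:
            missing.append(index_name)
            continue
        value = compute_cct(ttps[art], ttps[ven])
        flags = set(ttps[art].quality_flags) | set(ttps[ven].quality_flags)
        if value < 0:
            flags.add(FLAG_NEGATIVE_CCT)
        records.append(CCTRecord(subject_id=subject_id, index_name=index_name,
                                 value=value, arterial_ttp=ttps[art].ttp,
                                 venous_ttp=ttps[ven].ttp,
                                 reader_id=reader_id, flags=flags))
    return records, missing


def average_readers(records_a: List[CCTRecord],
                    records_b: List[CCTRecord]) -> List[CCTRecord]:
    """Arithmetic mean of two readers' values per (subject, index).

    Mirrors the two-observer protocol where discrepancies are resolved by
    averaging before any further analysis.  Records must match one-to-one on
    (subject_id, index_name); anything unmatched raises ``PairingError``.
    """
    def keyed(records) -> Dict[Tuple[str, str], CCTRecord]:
        out = {}
        for r in records:
            key = (r.subject_id, r.index_name)
            if key in out:
                raise PairingError(f"duplicate record for {key}")
            out[key] = r
        return out

    a, b = keyed(records_a), keyed(records_b)
    unmatched = sorted(set(a) ^ set(b))
    if unmatched:
        raise PairingError(f"unmatched (subject, index) records: {unmatched}")
    averaged = []
    for key in sorted(a):
        ra, rb = a[key], b[key]
        averaged.append(CCTRecord(
            subject_id=ra.subject_id, index_name=ra.index_name,
            value=0.5 * (ra.value + rb.value),
            arterial_ttp=0.5 * (ra.arterial_ttp + rb.arterial_ttp),
            venous_ttp=0.5 * (ra.venous_ttp + rb.venous_ttp),
            reader_id="mean", flags=set(ra.flags) | set(rb.flags)))
    return averaged
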