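"""Classify haplotypes as O / non-O alleles and call sample blood types.

The rules mirror serological O inference from the two marker sites: a
haplotype carrying the c.261 deletion is a deletional O allele; one carrying
c.802A without the deletion is a nondeletional O allele; a haplotype with
neither mutation is a non-O allele.  Because O alleles are recessive
loss-of-function, a sample types as O only when both haplotypes are O-class.

A haplotype carrying both mutations classifies as deletional O — the
frameshift truncates the transferase regardless of the downstream missense.
Samples with no diplotype (QC failure at either locus) get a missing call
rather than an assumed type.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .phasing import DiplotypePosterior


class AlleleClass(enum.Enum):
    O_DELETIONAL = "O_deletional"
    O_NONDELETIONAL = "O_nondeletional"
    NON_O = "non_O"

    @property
    def is_o(self) -> bool:
        return self is not AlleleClass.NON_O


class BloodType(enum.Enum):
    O = "O"
    NON_O = "non_O"
    MISSING = "missing"


@dataclass(frozen=True)
class BloodTypeCall:
    sample_id: str
    blood_type: BloodType
    allele_classes: Optional[tuple[AlleleClass, AlleleClass]]
    posterior: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError("posterior must lie in [0, 1]")


def classify_haplotype(h: tuple[int, int]) -> AlleleClass:
    """Map a (c261, c802) haplotype (0=ref, 1=alt) to its O/non-O class."""
    c261, c802 = h
    if c261 == 1:
        return AlleleClass.O_DELETIONAL
    if c802 == 1:
        return AlleleClass.O_NONDELETIONAL
    return AlleleClass.NON_O


def _config_type(pair: tuple[tuple[int, int], tuple[int, int]]) -> BloodType:
    a, b = classify_haplotype(pair[0]), classify_haplotype(pair[1])
    return BloodType.O if a.is_o and b.is_o else BloodType.NON_O


def call_blood_type(d: Optional[DiplotypePosterior], sample_id: str = "") -> BloodTypeCall:
    """Call O / non-O from a diplotype posterior.

    The reported type is that of the maximum-probability configuration; the
    posterior is the summed probability of all configurations sharing that
    type.  ``d=None`` (no diplotype) yields a missing call.
    """
    if d is None:
        return BloodTypeCall(sample_id, BloodType.MISSING, None, 1.0)
    if not d.configs:
        raise ValueError("diplotype posterior has no configurations")
    map_pair = d.map_config
    bt = _config_type(map_pair)
    posterior = sum(p for pair, p in d.configs if _config_type(pair) == bt)
    classes = (classify_haplotype(map_pair[0]), classify_haplotype(map_pair[1]))
    return BloodTypeCall(d.sample_id or sample_id, bt, classes, min(posterior, 1.0))


def calls_to_frame(calls: Sequence[BloodTypeCall]) -> pd.DataFrame:
    """Tabulate calls for TSV export."""
    rows = []
    for c in calls:
        a1, a2 = (
            (c.allele_classes[0].value, c.allele_classes[1].value)
            if c.allele_classes
            else ("", "")
        )
        rows.append(
            {
                "sample_id": c.sample_id,
                "blood_type": c.blood_type.value,
                "allele_class_1": a1,
                "allele_class_2": a2,
                "posterior": c.posterior,
            }
        )
    return pd.DataFrame(rows)
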