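"""Stage orchestration: genotype QC -> EM phasing -> blood-type calls."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import bloodtype as bt
from . import genotypes as gt
from . import phasing as ph


def type_cohort(
    calls: Sequence[gt.SampleGenotype],
    thresholds: gt.QCThresholds = gt.QCThresholds(),
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
) -> tuple[ph.HaplotypeFrequencies, list[bt.BloodTypeCall]]:
    """Full typing chain from raw per-locus calls to O / non-O calls.

    Samples failing QC at either locus are excluded from the EM and receive
    a missing blood type.
    """
    qced = [gt.apply_qc(c, thresholds) for c in calls]
    pairs = gt.paired_genotypes(qced)
    complete = {
        s: (a.alt_dosage, b.alt_dosage)
        for s, (a, b) in pairs.items()
        if a.qc_pass and b.qc_pass
    }
    freqs = ph.em_haplotype_frequencies(
        list(complete.values()), tol=em_tol, max_iter=em_max_iter
    )
    out: list[bt.BloodTypeCall] = []
    for s in pairs:
        if s in complete:
            d = ph.phase_individual(complete[s], freqs, sample_id=s)
            out.append(bt.call_blood_type(d))
        else:
            out.append(bt.call_blood_type(None, sample_id=s))
    return freqs, out


def frequencies_report(
    freqs: ph.HaplotypeFrequencies, n_samples: Optional[int] = None
) -> pd.DataFrame:
    """Haplotype-frequency table (haplotype, frequency, expected count)."""
    names = {
        (0, 0): "c261:G|c802:G",
        (0, 1): "c261:G|c802:A",
        (1, 0): "c261:del|c802:G",
        (1, 1): "c261:del|c802:A",
    }
    rows = []
    for h in ph.HAPLOTYPES:
        row = {"haplotype": names[h], "frequency": freqs[h]}
        if n_samples is not None:
            row["expected_count"] = 2 * n_samples * freqs[h]
        rows.append(row)
    return pd.DataFrame(rows)
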