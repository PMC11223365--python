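"""Read and quality-filter genotypes at the two ABO-determining sites.

Blood type O is a loss of glycosyltransferase function, marked in practice
by two variants in *ABO* (chromosome 9q34.2):

* ``c261delG`` — the single-base deletion c.261G>del (rs8176719), the
  "deletional" O-allele marker;
* ``c802GA`` — the missense change c.802G>A, the "nondeletional" O-allele
  marker.

This module extracts per-sample calls (GT, DP, GQ, AD) at exactly these two
configured sites from a VCF and applies read-level QC: a genotype is valid
when DP >= 9 and GQ >= 20, and heterozygotes additionally require >= 3 reads
supporting each observed allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

LOCUS_IDS = ("c261delG", "c802GA")


@dataclass(frozen=True)
class LocusSpec:
    """One of the two ABO-typing sites, located by chrom/pos/alleles.

    ``pos`` is 1-based as in VCF.  For c261delG the record is the
    left-aligned indel representation (e.g. ref ``TC`` alt ``T``); matching
    is by the declared alleles, with no re-normalisation.
    """

    locus_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.locus_id not in LOCUS_IDS:
            raise ValueError(f"locus_id must be one of {LOCUS_IDS}, got {self.locus_id!r}")


#: Default site definitions used by the simulator and the CLI.  Positions
#: approximate the GRCh38 ABO locus; real inputs should configure their own.
DEFAULT_LOCI = (
    LocusSpec("c261delG", "chr9", 133257521, "TC", "T"),
    LocusSpec("c802GA", "chr9", 133255801, "C", "T"),
)


@dataclass(frozen=True)
class QCThresholds:
    """Genotype validity thresholds: DP, GQ, and per-allele depth for hets."""

    min_depth: int = 9
    min_gq: int = 20
    min_het_allele_depth: int = 3

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_gq, self.min_het_allele_depth) < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass(frozen=True)
class SampleGenotype:
    """A per-sample, per-locus genotype call with its QC annotations.

    ``gt`` is an unphased pair of allele codes (0=ref, 1=alt) or ``None``
    when missing; a missing genotype never passes QC.
    """

    sample_id: str
    locus_id: str
    gt: Optional[tuple[int, int]]
    dp: Optional[int]
    gq: Optional[int]
    ad: Optional[tuple[int, int]]
    qc_pass: bool = False

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]

    @property
    def alt_dosage(self) -> Optional[int]:
        return None if self.gt is None else sum(self.gt)


def apply_qc(g: SampleGenotype, thresholds: QCThresholds = QCThresholds()) -> SampleGenotype:
    """Return ``g`` with ``qc_pass`` set; genotype content is unchanged.

    A call passes iff DP >= min_depth, GQ >= min_gq, and — when heterozygous
    — both observed alleles have AD >= min_het_allele_depth.  Missing
    genotype or missing numeric fields fail QC; failure is a state, not an
    error.  Idempotent and monotone in the thresholds.
    """
    if g.gt is None or g.dp is None or g.gq is None:
        return replace(g, qc_pass=False)
    ok = g.dp >= thresholds.min_depth and g.gq >= thresholds.min_gq
    if ok and g.is_het:
        if g.ad is None:
            ok = False
        else:
            ok = min(g.ad) >= thresholds.min_het_allele_depth
    return replace(g, qc_pass=ok)


def _match_record(rec: "pysam.VariantRecord", locus: LocusSpec) -> Optional[int]:
    """Return the ALT index (1-based allele code) matching the locus, or None."""
    if rec.chrom != locus.chrom or rec.pos != locus.pos or rec.ref != locus.ref_allele:
        return None
    if not rec.alts:
        return None
    for i, alt in enumerate(rec.alts):
        if alt == locus.alt_allele:
            return i + 1
    return None


def read_abo_sites(
    vcf_path: str, loci: Sequence[LocusSpec] = DEFAULT_LOCI
) -> list[SampleGenotype]:
    """Extract per-sample genotypes at the two configured ABO sites.

    Returns one :class:`SampleGenotype` per sample per locus (samples with
    no usable call at a locus get ``gt=None``).  In multiallelic records
    only the configured ref/alt pair is interpreted; a GT touching any other
    allele becomes missing.  A locus absent from the VCF is a hard error.
    """
    if len(loci) != 2 or len({l.locus_id for l in loci}) != 2:
        raise ValueError("exactly two loci with distinct locus_ids are required")

    out: list[SampleGenotype] = []
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        found: dict[str, dict[str, SampleGenotype]] = {}
        for rec in vcf:
            for locus in loci:
                alt_idx = _match_record(rec, locus)
                if alt_idx is None:
                    continue
                found[locus.locus_id] = {
                    s: _extract_call(rec, s, locus.locus_id, alt_idx) for s in samples
                }
    for locus in loci:
        if locus.locus_id not in found:
            raise ValueError(f"locus {locus.locus_id} not found in {vcf_path}")
    for s in samples:
        for locus in loci:
            out.append(found[locus.locus_id][s])
    return out


def _extract_call(
    rec: "pysam.VariantRecord", sample: str, locus_id: str, alt_idx: int
) -> SampleGenotype:
    fmt = rec.samples[sample]
    try:
        alleles = fmt.get("GT")
        dp = fmt.get("DP")
        gq = fmt.get("GQ")
        ad = fmt.get("AD")
    except Exception:  # malformed FORMAT block
        logger.warning("malformed FORMAT fields at %s for sample %s", locus_id, sample)
        return SampleGenotype(sample, locus_id, None, None, None, None)

    gt: Optional[tuple[int, int]] = None
    if alleles is not None and len(alleles) == 2 and None not in alleles:
        # only the configured biallelic pair is interpreted
        if set(alleles) <= {0, alt_idx}:
            gt = tuple(sorted(1 if a == alt_idx else 0 for a in alleles))
    ad_pair: Optional[tuple[int, int]] = None
    if ad is not None and len(ad) > alt_idx and ad[0] is not None and ad[alt_idx] is not None:
        ad_pair = (int(ad[0]), int(ad[alt_idx]))
    return SampleGenotype(
        sample,
        locus_id,
        gt,
        None if dp is None else int(dp),
        None if gq is None else int(gq),
        ad_pair,
    )


def paired_genotypes(
    calls: Sequence[SampleGenotype],
) -> dict[str, tuple[SampleGenotype, SampleGenotype]]:
    """Group calls into (c261delG, c802GA) pairs keyed by sample."""
    by_sample: dict[str, dict[str, SampleGenotype]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, {})[c.locus_id] = c
    out = {}
    for s, d in by_sample.items():
        if set(d) != set(LOCUS_IDS):
            raise ValueError(f"sample {s} lacks a call at one of the two loci")
        out[s] = (d["c261delG"], d["c802GA"])
    return out
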