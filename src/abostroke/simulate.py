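"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study's inputs end to end:

* diploid two-locus genotypes drawn from known haplotype frequencies under
  Hardy-Weinberg equilibrium, observed through a read-level model (depth
  Poisson, per-read error 0.5%, maximum-likelihood genotype call, GQ from
  the likelihood ratio) and written as a VCF;
* a cohort sample sheet with stroke-subtype labels drawn from
  blood-type-conditional multinomials (defaults anchored to the published
  CCS distribution) and log-normal baseline biomarkers with configurable
  per-blood-type shifts;
* a log-normal protein intensity matrix with planted differential proteins
  and a GMT term map containing one term enriched for them.

Default haplotype frequencies are skewed so the Hardy-Weinberg O-genotype
fraction is about 0.2954, matching the 29.54% O prevalence of the cohort.
All randomness flows from a single seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .bloodtype import classify_haplotype
from .genotypes import DEFAULT_LOCI, LocusSpec, SampleGenotype
from .phasing import HAPLOTYPES

#: Haplotype frequencies over ((ref,ref),(ref,alt),(alt,ref),(alt,alt)) at
#: (c261, c802): non-O 0.4565, nondeletional O 0.06, deletional O 0.48,
#: double-mutant 0.0035.  Total O-allele frequency 0.5435 so the HWE
#: O-genotype fraction is 0.5435^2 = 0.2954.
DEFAULT_HAPLOTYPE_FREQS = (0.4565, 0.06, 0.48, 0.0035)

#: Subtype multinomials conditional on blood type (LAA, CE, SAO, OE, UE),
#: the published row proportions of the CCS-by-blood-type table.
DEFAULT_SUBTYPE_PROBS = {
    "O": (708 / 2819, 193 / 2819, 806 / 2819, 21 / 2819, 1091 / 2819),
    "non_O": (2030 / 6723, 475 / 6723, 1770 / 6723, 55 / 6723, 2393 / 6723),
}

SUBTYPES = ("LAA", "CE", "SAO", "OE", "UE")


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator; ``seed`` fixes everything."""

    n_samples: int = 1000
    haplotype_freqs: tuple[float, float, float, float] = DEFAULT_HAPLOTYPE_FREQS
    mean_depth: float = 60.0
    read_error_rate: float = 0.005
    subtype_probs: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS))
    # biomarker model: log-normal LDL-C with a small non-O location excess
    ldl_median_o: float = 2.3
    ldl_log_sd: float = 0.42
    ldl_nonO_log_shift: float = 0.0426
    # proteomics: counts and effect profile
    n_proteins: int = 974
    n_de: int = 59
    n_de_up: int = 17
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_per_group: int = 30
    planted_term_size: int = 80
    n_random_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.haplotype_freqs, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or f.min() < 0:
            raise ValueError("haplotype_freqs must be a probability vector")
        for probs in self.subtype_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("subtype_probs rows must sum to 1")
        if self.n_de > self.n_proteins:
            raise ValueError("n_de cannot exceed n_proteins")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_truth(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw per-sample haplotype pairs and derive the true blood type."""
    rng = rng or cfg.rng()
    n = cfg.n_samples
    idx = rng.choice(4, size=(n, 2), p=np.asarray(cfg.haplotype_freqs))
    rows = []
    for i in range(n):
        h1, h2 = HAPLOTYPES[idx[i, 0]], HAPLOTYPES[idx[i, 1]]
        o = classify_haplotype(h1).is_o and classify_haplotype(h2).is_o
        rows.append(
            {
                "sample_id": f"S{i:05d}",
                "h1_c261": h1[0],
                "h1_c802": h1[1],
                "h2_c261": h2[0],
                "h2_c802": h2[1],
                "true_blood_type": "O" if o else "non_O",
            }
        )
    return pd.DataFrame(rows)


def _call_genotypes(
    depth: np.ndarray, alt_reads: np.ndarray, err: float
) -> tuple[np.ndarray, np.ndarray]:
    """ML diploid genotype call and phred GQ from the binomial likelihood ratio."""
    p_alt = np.array([err, 0.5, 1.0 - err])
    with np.errstate(divide="ignore"):
        ll = np.stack(
            [stats.binom.logpmf(alt_reads, depth, p) for p in p_alt], axis=0
        )
    order = np.argsort(ll, axis=0)
    best = order[-1]
    second = order[-2]
    lr = np.take_along_axis(ll, best[None], 0)[0] - np.take_along_axis(ll, second[None], 0)[0]
    gq = np.minimum(np.round(10.0 * lr / np.log(10)), 99).astype(int)
    return best, gq


def simulate_calls(
    truth: pd.DataFrame, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[SampleGenotype]:
    """Push the true diplotypes through the read-level observation model."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = len(truth)
    calls: list[SampleGenotype] = []
    for locus_id, c1, c2 in (
        ("c261delG", "h1_c261", "h2_c261"),
        ("c802GA", "h1_c802", "h2_c802"),
    ):
        dos = (truth[c1] + truth[c2]).to_numpy()
        depth = rng.poisson(cfg.mean_depth, size=n)
        p_read = np.array([cfg.read_error_rate, 0.5, 1.0 - cfg.read_error_rate])[dos]
        alt_reads = rng.binomial(depth, p_read)
        called, gq = _call_genotypes(depth, alt_reads, cfg.read_error_rate)
        gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for i, sid in enumerate(truth["sample_id"]):
            d = int(depth[i])
            gt = None if d == 0 else gt_of[int(called[i])]
            calls.append(
                SampleGenotype(
                    sid,
                    locus_id,
                    gt,
                    d,
                    0 if d == 0 else int(gq[i]),
                    (d - int(alt_reads[i]), int(alt_reads[i])),
                )
            )
    return calls


def write_vcf(
    calls: Sequence[SampleGenotype],
    path: str,
    loci: Sequence[LocusSpec] = DEFAULT_LOCI,
) -> str:
    """Write per-sample calls at the two ABO sites as an uncompressed VCF."""
    header = pysam.VariantHeader()
    for chrom in sorted({l.chrom for l in loci}):
        header.contigs.add(chrom, length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths for the ref and alt alleles")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    samples = sorted({c.sample_id for c in calls})
    for s in samples:
        header.add_sample(s)
    by_locus: dict[str, dict[str, SampleGenotype]] = {}
    for c in calls:
        by_locus.setdefault(c.locus_id, {})[c.sample_id] = c
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for locus in sorted(loci, key=lambda l: (l.chrom, l.pos)):
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=(locus.ref_allele, locus.alt_allele),
                id={"c261delG": "rs8176719", "c802GA": "c802GA"}[locus.locus_id],
            )
            for s in samples:
                g = by_locus[locus.locus_id][s]
                fmt = rec.samples[s]
                fmt["GT"] = (None, None) if g.gt is None else g.gt
                fmt["AD"] = g.ad
                fmt["DP"] = g.dp
                fmt["GQ"] = g.gq
            vcf.write(rec)
    return path


def gen_genotypes(
    cfg: SimConfig, vcf_path: str, truth_path: Optional[str] = None
) -> pd.DataFrame:
    """Generate a synthetic cohort VCF plus its truth table; returns the truth."""
    truth = draw_truth(cfg)
    calls = simulate_calls(truth, cfg)
    write_vcf(calls, vcf_path)
    if truth_path:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def gen_cohort_labels(
    blood_types: pd.Series,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    null_labels: bool = False,
) -> pd.DataFrame:
    """Draw a sample sheet conditional on each sample's (true) blood type.

    Subtypes come from the blood-type-conditional multinomials (or a single
    pooled multinomial when ``null_labels`` is set, for calibration runs);
    LDL-C is log-normal with a location excess in the non-O group; CRP is a
    null biomarker with no group effect.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    n = len(blood_types)
    probs = dict(cfg.subtype_probs)
    if null_labels:
        pooled = np.mean([probs["O"], probs["non_O"]], axis=0)
        probs = {"O": pooled, "non_O": pooled}
    subtype = [
        SUBTYPES[rng.choice(5, p=np.asarray(probs[bt]))] for bt in blood_types
    ]
    is_non_o = (blood_types == "non_O").to_numpy()
    shift = np.where(is_non_o, cfg.ldl_nonO_log_shift, 0.0)
    ldl = np.exp(np.log(cfg.ldl_median_o) + shift + rng.normal(0, cfg.ldl_log_sd, n))
    crp = np.exp(np.log(1.7) + rng.normal(0, 0.9, n))
    return pd.DataFrame(
        {
            "sample_id": blood_types.index,
            "subtype": subtype,
            "first_ever": rng.random(n) < 7368 / 9542,
            "case": 1,
            "ldl_c": ldl,
            "crp": crp,
        }
    )


def gen_proteome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict[str, set[str]]]:
    """Synthetic protein intensities with planted group effects.

    Returns (matrix proteins x samples, per-sample group, truth table with
    the planted direction per protein, GMT-style term map).  Intensities
    are log-normal: per-protein baseline plus a +/-``de_log2fc`` shift in
    the O group for the planted proteins, plus N(0, noise_sd) noise in log2
    space.  The term map holds one term enriched 3-fold for planted
    proteins among random decoy terms.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    pids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    de_idx = rng.choice(cfg.n_proteins, size=cfg.n_de, replace=False)
    direction = pd.Series("none", index=pids, name="direction")
    direction.iloc[de_idx[: cfg.n_de_up]] = "up"
    direction.iloc[de_idx[cfg.n_de_up :]] = "down"

    n_o, n_n = cfg.n_per_group, cfg.n_per_group
    group = pd.Series(
        ["O"] * n_o + ["non_O"] * n_n,
        index=[f"PS{i:03d}" for i in range(n_o + n_n)],
        name="blood_type",
    )
    base = rng.uniform(6.0, 14.0, size=cfg.n_proteins)
    log2i = base[:, None] + rng.normal(0, cfg.noise_sd, size=(cfg.n_proteins, n_o + n_n))
    eff = np.zeros(cfg.n_proteins)
    eff[de_idx[: cfg.n_de_up]] = cfg.de_log2fc
    eff[de_idx[cfg.n_de_up :]] = -cfg.de_log2fc
    log2i[:, :n_o] += eff[:, None]
    matrix = pd.DataFrame(2.0**log2i, index=pd.Index(pids, name="protein_id"), columns=group.index)

    terms = _make_terms(pids, de_idx, cfg, rng)
    return matrix, group, direction.to_frame(), terms


def _make_terms(
    pids: list[str], de_idx: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, set[str]]:
    """One planted term enriched 3-fold for true-DE proteins, plus decoys.

    "3-fold" is built deterministically: the planted term contains exactly
    round(3 * n_de/n_proteins * size) differential proteins.
    """
    frac = cfg.n_de / cfg.n_proteins
    size = cfg.planted_term_size
    n_de_in = min(int(round(3 * frac * size)), cfg.n_de, size)
    de_set = list(de_idx)
    non_de = [i for i in range(cfg.n_proteins) if i not in set(de_idx)]
    members = list(rng.choice(de_set, size=n_de_in, replace=False)) + list(
        rng.choice(non_de, size=size - n_de_in, replace=False)
    )
    terms = {"TERM_PLANTED": {pids[i] for i in members}}
    for t in range(cfg.n_random_terms):
        sz = int(rng.integers(30, 101))
        terms[f"TERM_{t:03d}"] = {pids[i] for i in rng.choice(cfg.n_proteins, sz, replace=False)}
    return terms
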