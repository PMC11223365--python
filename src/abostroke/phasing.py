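"""Two-locus haplotype frequency estimation and per-sample phasing.

With only two biallelic sites the haplotype-frequency likelihood under
Hardy–Weinberg equilibrium is an explicit multinomial and the classical
gene-counting EM is the exact maximum-likelihood solution, so no external
phasing software is needed.  Phase is ambiguous only for the double
heterozygote, whose cis (ref-ref / alt-alt) versus trans (ref-alt / alt-ref)
resolution is weighted by the estimated haplotype frequencies:

    P(cis)  ∝ 2·f(ref,ref)·f(alt,alt)
    P(trans) ∝ 2·f(ref,alt)·f(alt,ref)

The EM is deterministic (no randomness, fixed iteration order) and its
log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The four haplotypes over (c261delG, c802GA); 0 = ref, 1 = alt.
HAPLOTYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))
_H_INDEX = {h: i for i, h in enumerate(HAPLOTYPES)}


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Population frequencies of the four (c261, c802) haplotypes."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.min() < -1e-12:
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1, got {f.sum()}")

    def __getitem__(self, h: tuple[int, int]) -> float:
        return self.freqs[_H_INDEX[h]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @classmethod
    def from_array(cls, f: np.ndarray) -> "HaplotypeFrequencies":
        f = np.clip(np.asarray(f, dtype=float), 0.0, None)
        return cls(tuple(f / f.sum()))


@dataclass
class DiplotypePosterior:
    """Posterior over haplotype-pair configurations for one individual.

    ``configs`` holds (unordered haplotype pair, probability); only the
    double heterozygote has two entries.
    """

    sample_id: str
    configs: list[tuple[tuple[tuple[int, int], tuple[int, int]], float]]
    map_config: tuple[tuple[int, int], tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.configs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("configuration probabilities must sum to 1")
        self.map_config = max(self.configs, key=lambda cp: cp[1])[0]


def genotype_counts(pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Tabulate (alt dosage at c261, alt dosage at c802) into a 3x3 matrix."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for g1, g2 in pairs:
        counts[g1, g2] += 1
    return counts


def _cell_prob_grid(f: np.ndarray, i: int, j: int) -> np.ndarray:
    """HWE probability of genotype cell (i, j) for an array of frequency rows."""
    f00, f01, f10, f11 = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    table = {
        (0, 0): f00**2,
        (0, 1): 2 * f00 * f01,
        (0, 2): f01**2,
        (1, 0): 2 * f00 * f10,
        (1, 1): 2 * f00 * f11 + 2 * f01 * f10,
        (1, 2): 2 * f01 * f11,
        (2, 0): f10**2,
        (2, 1): 2 * f10 * f11,
        (2, 2): f11**2,
    }
    return table[(i, j)]


def log_likelihood(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype counts under HWE."""
    ll = 0.0
    for i in range(3):
        for j in range(3):
            n = counts[i, j]
            if n:
                p = _cell_prob_grid(f[None, :], i, j)[0]
                if p <= 0:
                    return -np.inf
                ll += n * np.log(p)
    return ll


# deterministic haplotype composition of each phase-unambiguous genotype cell
_UNAMBIGUOUS = {
    (0, 0): ((0, 0), (0, 0)),
    (0, 1): ((0, 0), (0, 1)),
    (0, 2): ((0, 1), (0, 1)),
    (1, 0): ((0, 0), (1, 0)),
    (1, 2): ((0, 1), (1, 1)),
    (2, 0): ((1, 0), (1, 0)),
    (2, 1): ((1, 0), (1, 1)),
    (2, 2): ((1, 1), (1, 1)),
}


def linkage_equilibrium_init(counts: np.ndarray) -> HaplotypeFrequencies:
    """Product-of-allele-frequency start, floored to stay strictly positive."""
    n = counts.sum()
    p1 = (counts * np.arange(3)[:, None]).sum() / (2 * n)  # alt freq at c261
    p2 = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    f = np.array([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2])
    f = np.clip(f, 1e-6, None)
    return HaplotypeFrequencies.from_array(f)


def expected_haplotype_counts(counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """E-step: expected counts of the four haplotypes given frequencies ``f``.

    Sums to 2n exactly.
    """
    exp = np.zeros(4)
    for (i, j), (h1, h2) in _UNAMBIGUOUS.items():
        n = counts[i, j]
        if n:
            exp[_H_INDEX[h1]] += n
            exp[_H_INDEX[h2]] += n
    n_dh = counts[1, 1]
    if n_dh:
        p_cis = 2 * f[0] * f[3]
        p_trans = 2 * f[1] * f[2]
        tot = p_cis + p_trans
        w = 0.5 if tot <= 0 else p_cis / tot
        exp[0] += n_dh * w
        exp[3] += n_dh * w
        exp[1] += n_dh * (1 - w)
        exp[2] += n_dh * (1 - w)
    return exp


def em_haplotype_frequencies(
    genotype_pairs: Sequence[tuple[int, int]],
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: Optional[HaplotypeFrequencies] = None,
) -> HaplotypeFrequencies:
    """Gene-counting EM for the four two-locus haplotype frequencies.

    ``genotype_pairs`` are per-sample alt dosages (d261, d802) for samples
    passing QC at both loci.  Converges when the largest absolute frequency
    change drops below ``tol``.  Raises on an empty cohort or a non-finite
    likelihood.

    Note the caveat inherent to the model: a cohort consisting solely of
    double heterozygotes is unidentifiable (cis and trans fit equally well)
    and the EM then returns its starting point.
    """
    counts = genotype_counts(genotype_pairs)
    n = counts.sum()
    if n == 0:
        raise ValueError("no QC-passed samples available for EM")
    f = (init or linkage_equilibrium_init(counts)).as_array()
    if f.min() <= 0:
        raise ValueError("initial frequencies must be strictly positive")
    ll_prev = log_likelihood(counts, f)
    if not np.isfinite(ll_prev):
        raise ValueError("non-finite likelihood at initialization")
    for _ in range(max_iter):
        f_new = expected_haplotype_counts(counts, f) / (2 * n)
        ll = log_likelihood(counts, f_new)
        if not np.isfinite(ll) and counts[1, 1] != n:
            raise ValueError("non-finite likelihood during EM")
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        delta = np.max(np.abs(f_new - f))
        f, ll_prev = f_new, ll
        if delta < tol:
            break
    return HaplotypeFrequencies.from_array(f)


def phase_individual(
    g: tuple[int, int], f: HaplotypeFrequencies, sample_id: str = ""
) -> DiplotypePosterior:
    """Resolve one individual's two-locus genotype into haplotype pairs.

    All genotypes except the double heterozygote have a unique configuration
    (probability 1).  For the double heterozygote the cis/trans split follows
    the frequency-weighted proportionality; if both products vanish the
    posterior falls back to 0.5/0.5 with a warning.
    """
    if g in _UNAMBIGUOUS:
        return DiplotypePosterior(sample_id, [(_UNAMBIGUOUS[g], 1.0)])
    if g != (1, 1):
        raise ValueError(f"invalid two-locus genotype {g}")
    p_cis = 2 * f[(0, 0)] * f[(1, 1)]
    p_trans = 2 * f[(0, 1)] * f[(1, 0)]
    tot = p_cis + p_trans
    if tot <= 0:
        logger.warning(
            "degenerate frequencies for double heterozygote %s; using 0.5/0.5", sample_id
        )
        w = 0.5
    else:
        w = p_cis / tot
    return DiplotypePosterior(
        sample_id,
        [(((0, 0), (1, 1)), w), (((0, 1), (1, 0)), 1.0 - w)],
    )


def grid_search_frequencies(
    genotype_pairs: Sequence[tuple[int, int]],
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
) -> HaplotypeFrequencies:
    """Direct maximisation of the multinomial likelihood over the simplex.

    Hierarchical grid: an exhaustive scan at ``coarse_step`` resolution over
    the full 4-frequency simplex, then an exhaustive rescan at ``fine_step``
    within one coarse step of the coarse optimum.  Serves as an independent
    cross-check of the EM solution.
    """
    counts = genotype_counts(genotype_pairs)

    def _scan(grid: np.ndarray) -> np.ndarray:
        ll = np.zeros(len(grid))
        for i in range(3):
            for j in range(3):
                c = counts[i, j]
                if c:
                    with np.errstate(divide="ignore"):
                        ll += c * np.log(_cell_prob_grid(grid, i, j))
        return grid[int(np.argmax(ll))]

    best = _scan(_simplex_grid(coarse_step))
    lo = np.clip(best - coarse_step, 0.0, 1.0)
    hi = np.clip(best + coarse_step, 0.0, 1.0)
    best = _scan(_simplex_grid(fine_step, lo, hi))
    return HaplotypeFrequencies.from_array(best)


def _simplex_grid(
    step: float, lo: Optional[np.ndarray] = None, hi: Optional[np.ndarray] = None
) -> np.ndarray:
    """All frequency 4-vectors on a lattice of the simplex, optionally boxed."""
    m = int(round(1.0 / step))
    lo_i = np.zeros(4, dtype=int) if lo is None else np.ceil(lo * m - 1e-9).astype(int)
    hi_i = np.full(4, m, dtype=int) if hi is None else np.floor(hi * m + 1e-9).astype(int)
    pts = []
    for a in range(lo_i[0], hi_i[0] + 1):
        for b in range(lo_i[1], min(hi_i[1], m - a) + 1):
            rem = m - a - b
            c_lo = max(lo_i[2], rem - hi_i[3])
            c_hi = min(hi_i[2], rem - lo_i[3])
            for c in range(c_lo, c_hi + 1):
                pts.append((a, b, c, rem - c))
    if not pts:  # box missed the lattice; fall back to nearest point
        pts = [tuple(np.round((lo + hi) / 2 * m).astype(int))]
    return np.asarray(pts, dtype=float) / m
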