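"""Differential plasma-protein analysis between blood-type groups.

Per protein, a Welch two-sample t-test on log2 intensities (O versus non-O)
with log2 fold change = mean(log2 O) - mean(log2 non-O).  A protein is
"up" when p < alpha and log2FC > fc_threshold, "down" when p < alpha and
log2FC < -fc_threshold, otherwise not significant — the volcano-plot
classification.  The default threshold is the literal |log2FC| > 1.2; set
``fc_scale="linear"`` to threshold the linear fold change instead
(|log2FC| > log2 1.2).

Over-representation analysis (ORA): for each annotation term, a
hypergeometric upper-tail test of the query set against the background of
all detected proteins, with Benjamini-Hochberg control across terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ProteinMatrix:
    """Protein intensities (proteins x samples) with a blood-type grouping."""

    protein_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    group: np.ndarray  # per-sample labels, two distinct values

    def __post_init__(self) -> None:
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein_ids")
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.group = np.asarray(self.group)
        if self.intensities.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError("intensity matrix shape mismatch")
        if self.intensities.min() < 0:
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_tsv(cls, matrix_path: str, groups_path: str) -> "ProteinMatrix":
        m = pd.read_csv(matrix_path, sep="\t", index_col=0)
        g = pd.read_csv(groups_path, sep="\t", index_col=0)["blood_type"]
        g = g.reindex(m.columns)
        if g.isna().any():
            raise ValueError("group map does not cover all samples")
        return cls(list(m.index), list(m.columns), m.to_numpy(), g.to_numpy())


@dataclass(frozen=True)
class DEResult:
    protein_id: str
    log2fc: float
    p_value: float
    volcano_class: str  # up | down | not_significant
    flagged: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap: int
    p_value: float
    q_value: float
    significant: bool


def impute_zeros(intensities: np.ndarray) -> np.ndarray:
    """Replace zeros with half the per-protein minimum positive intensity."""
    out = intensities.astype(float).copy()
    for i in range(out.shape[0]):
        row = out[i]
        if (row == 0).any():
            pos = row[row > 0]
            fill = pos.min() / 2 if len(pos) else np.nan
            row[row == 0] = fill
    return out


def differential_expression(
    m: ProteinMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.2,
    fc_scale: str = "log2",
    group_o: str = "O",
    welch: bool = True,
) -> list[DEResult]:
    """Volcano-style per-protein differential test, O versus non-O.

    Zeros are imputed with half the per-protein minimum positive value
    before the log2 transform.  A protein constant within both groups has
    an undefined p and is flagged not-significant.
    """
    if fc_scale not in ("log2", "linear"):
        raise ValueError("fc_scale must be 'log2' or 'linear'")
    thr = fc_threshold if fc_scale == "log2" else math.log2(fc_threshold)
    mask_o = m.group == group_o
    if mask_o.sum() < 2 or (~mask_o).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    log2i = np.log2(impute_zeros(m.intensities))
    a, b = log2i[:, mask_o], log2i[:, ~mask_o]
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    out = []
    for pid, fc, p in zip(m.protein_ids, log2fc, tt.pvalue):
        if not np.isfinite(p):
            out.append(DEResult(pid, float(fc), float("nan"), "not_significant", True))
            continue
        if p < alpha and fc > thr:
            cls = "up"
        elif p < alpha and fc < -thr:
            cls = "down"
        else:
            cls = "not_significant"
        out.append(DEResult(pid, float(fc), float(p), cls))
    return out


def de_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "volcano_class": [r.volcano_class for r in results],
        }
    )


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def overrepresentation(
    query: set[str],
    background: set[str],
    terms: Mapping[str, set[str]],
    q_cutoff: float = 0.05,
    min_term_size: int = 3,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``query`` against ``background`` per term.

    Term sets are intersected with the background before testing; terms
    whose intersection is smaller than ``min_term_size`` are skipped.  The
    upper-tail p is P(X >= overlap) for X hypergeometric with population
    |background|, successes |term|, draws |query|.
    """
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_q = len(background), len(query)
    tested = []
    for term_id, members in terms.items():
        inter = members & background
        if len(inter) < min_term_size:
            continue
        k = len(inter & query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(inter), n_q))
        tested.append((term_id, len(inter), k, min(p, 1.0)))
    if not tested:
        return []
    q = bh_qvalues([t[3] for t in tested])
    out = [
        EnrichmentResult(tid, size, k, p, float(qv), bool(qv < q_cutoff))
        for (tid, size, k, p), qv in zip(tested, q)
    ]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_size": [r.term_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT term-set file: term_id <tab> description <tab> members..."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(parts[2:])
    return terms


def write_gmt(terms: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w") as fh:
        for term_id, members in terms.items():
            fh.write("\t".join([term_id, term_id] + sorted(members)) + "\n")
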