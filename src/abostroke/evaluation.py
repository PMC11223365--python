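"""Simulation-based validation metrics for the pipeline stages.

Each function generates synthetic data with known truth, runs the relevant
stage, and scores it — typing accuracy against the generator's truth,
EM-versus-grid-search agreement, test calibration under the null, and
recovery of planted proteomic signal.  They back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .assoc import chi_square_test, wilcoxon_rank_sum
from .bloodtype import BloodType
from .phasing import em_haplotype_frequencies, grid_search_frequencies
from .pipeline import type_cohort
from .proteomics import ProteinMatrix, differential_expression, overrepresentation
from .simulate import DEFAULT_SUBTYPE_PROBS, SimConfig, draw_truth, gen_proteome, simulate_calls


def typing_accuracy(
    n_samples: int = 1000, n_seeds: int = 20, mean_depth: float = 60.0, seed0: int = 0
) -> float:
    """Pooled O/non-O call accuracy versus simulation truth, in percent.

    Accuracy is scored over samples receiving a call; the missing-call rate
    at the default depth is negligible and is folded into the denominator
    as errors.
    """
    n_correct = n_total = 0
    for s in range(n_seeds):
        cfg = SimConfig(n_samples=n_samples, mean_depth=mean_depth, seed=seed0 + s)
        truth = draw_truth(cfg)
        _, calls = type_cohort(simulate_calls(truth, cfg))
        truth_bt = truth.set_index("sample_id")["true_blood_type"]
        n_total += len(calls)
        n_correct += sum(
            c.blood_type is not BloodType.MISSING
            and c.blood_type.value == truth_bt[c.sample_id]
            for c in calls
        )
    return 100.0 * n_correct / n_total


def em_grid_max_diff(
    n_samples: int = 200,
    freqs: tuple[float, float, float, float] = (0.55, 0.05, 0.15, 0.25),
    seed: int = 7,
) -> float:
    """Largest per-haplotype gap between the EM and the grid-search oracle."""
    from .phasing import HAPLOTYPES

    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=(n_samples, 2), p=np.asarray(freqs))
    pairs = [
        (HAPLOTYPES[a][0] + HAPLOTYPES[b][0], HAPLOTYPES[a][1] + HAPLOTYPES[b][1])
        for a, b in idx
    ]
    em = em_haplotype_frequencies(pairs).as_array()
    grid = grid_search_frequencies(pairs).as_array()
    return float(np.abs(em - grid).max())


def chi2_null_rejection_rate(
    n_sims: int = 2000, n_samples: int = 500, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the subtype chi-square when labels ignore blood type.

    Subtype columns empty in a draw are dropped before testing (a category
    absent from the sample carries no information and would break the
    expected-count precondition).
    """
    rng = np.random.default_rng(seed)
    pooled = np.mean([DEFAULT_SUBTYPE_PROBS["O"], DEFAULT_SUBTYPE_PROBS["non_O"]], axis=0)
    p_o = 0.2954
    rej = 0
    for _ in range(n_sims):
        n_o = rng.binomial(n_samples, p_o)
        c_o = rng.multinomial(n_o, pooled)
        c_n = rng.multinomial(n_samples - n_o, pooled)
        counts = np.stack([c_o, c_n])
        counts = counts[:, counts.sum(axis=0) > 0]
        _, _, p = chi_square_test(counts)
        rej += p < alpha
    return rej / n_sims


def wilcoxon_null_rejection_rate(
    n_sims: int = 2000, n_per_group: int = 30, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the rank-sum test on exchangeable continuous data."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_sims):
        x = rng.normal(size=n_per_group)
        y = rng.normal(size=n_per_group)
        _, p = wilcoxon_rank_sum(x, y)
        rej += p < alpha
    return rej / n_sims


def chi2_table1_power(
    n_sims: int = 100, n_samples: int = 9542, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """(rejection rate at alpha, median p) resampling the published subtype
    multinomials at the cohort size."""
    rng = np.random.default_rng(seed)
    p_o = 2819 / 9542
    rej = 0
    ps = []
    for _ in range(n_sims):
        n_o = rng.binomial(n_samples, p_o)
        c_o = rng.multinomial(n_o, DEFAULT_SUBTYPE_PROBS["O"])
        c_n = rng.multinomial(n_samples - n_o, DEFAULT_SUBTYPE_PROBS["non_O"])
        _, _, p = chi_square_test(np.stack([c_o, c_n]))
        ps.append(p)
        rej += p < alpha
    return rej / n_sims, float(np.median(ps))


def de_recovery_percent(n_seeds: int = 10, seed0: int = 0) -> float:
    """Percent of planted differential proteins recovered in the correct
    volcano class."""
    correct = total = 0
    for s in range(n_seeds):
        matrix, group, truth, _ = gen_proteome(SimConfig(seed=seed0 + s))
        m = ProteinMatrix(
            list(matrix.index), list(matrix.columns), matrix.to_numpy(), group.to_numpy()
        )
        got = {r.protein_id: r.volcano_class for r in differential_expression(m)}
        planted = truth[truth["direction"] != "none"]["direction"]
        total += len(planted)
        correct += sum(got[p] == d for p, d in planted.items())
    return 100.0 * correct / total


def planted_term_top_rate(n_seeds: int = 100, seed0: int = 0) -> float:
    """Percent of seeds in which the planted term has the smallest ORA p.

    The query is the set of proteins the volcano stage actually flags, so
    the measurement exercises the full DE -> enrichment chain.
    """
    wins = 0
    for s in range(n_seeds):
        matrix, group, truth, terms = gen_proteome(SimConfig(seed=seed0 + s))
        m = ProteinMatrix(
            list(matrix.index), list(matrix.columns), matrix.to_numpy(), group.to_numpy()
        )
        res = differential_expression(m)
        query = {r.protein_id for r in res if r.volcano_class != "not_significant"}
        enr = overrepresentation(query, set(matrix.index), terms)
        wins += bool(enr) and enr[0].term_id == "TERM_PLANTED"
    return 100.0 * wins / n_seeds
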