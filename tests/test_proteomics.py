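"""Volcano differential expression and hypergeometric over-representation."""

import itertools
import math

import numpy as np
import pytest

from abostroke.proteomics import (
    ProteinMatrix,
    bh_qvalues,
    differential_expression,
    impute_zeros,
    overrepresentation,
    read_gmt,
    write_gmt,
)
from abostroke.simulate import SimConfig, gen_proteome


def _matrix(intensities, group):
    n_p, n_s = intensities.shape
    return ProteinMatrix(
        [f"P{i}" for i in range(n_p)],
        [f"S{j}" for j in range(n_s)],
        intensities,
        np.asarray(group),
    )


def test_null_matrix_has_nominal_false_positive_rate():
    rng = np.random.default_rng(0)
    m = _matrix(2.0 ** rng.normal(10, 1, size=(2000, 40)), ["O"] * 20 + ["non_O"] * 20)
    res = differential_expression(m)
    frac_small_p = np.mean([r.p_value < 0.05 for r in res])
    assert 0.03 < frac_small_p < 0.07
    # the fold-change gate keeps nearly everything out of the volcano tails
    assert sum(r.volcano_class != "not_significant" for r in res) < 20


def test_large_shift_classified_up():
    rng = np.random.default_rng(1)
    base = 2.0 ** rng.normal(10, 0.1, size=(1, 12))
    base[0, :6] *= 8  # log2fc = 3 in the O group
    m = _matrix(base, ["O"] * 6 + ["non_O"] * 6)
    res = differential_expression(m)
    assert res[0].volcano_class == "up"
    assert res[0].log2fc == pytest.approx(3.0, abs=0.2)


def test_constant_protein_is_flagged_not_significant():
    m = _matrix(np.full((1, 8), 64.0), ["O"] * 4 + ["non_O"] * 4)
    res = differential_expression(m)
    assert res[0].volcano_class == "not_significant"
    assert res[0].flagged


def test_planted_de_recovery_across_seeds():
    """>=90% of planted proteins land in the correct volcano class."""
    correct = total = 0
    for seed in range(10):
        cfg = SimConfig(seed=seed)
        matrix, group, truth, _ = gen_proteome(cfg)
        m = ProteinMatrix(list(matrix.index), list(matrix.columns), matrix.to_numpy(), group.to_numpy())
        got = {r.protein_id: r.volcano_class for r in differential_expression(m)}
        planted = truth[truth["direction"] != "none"]
        total += len(planted)
        correct += sum(got[p] == d for p, d in planted["direction"].items())
    assert correct / total >= 0.90


def test_scaling_and_column_order_invariance():
    rng = np.random.default_rng(3)
    inten = 2.0 ** rng.normal(10, 1, size=(50, 20))
    group = np.array(["O"] * 10 + ["non_O"] * 10)
    m = _matrix(inten, group)
    base = differential_expression(m)
    scaled = differential_expression(_matrix(inten * 1000.0, group))
    perm = rng.permutation(20)
    shuffled = differential_expression(
        ProteinMatrix([f"P{i}" for i in range(50)], [f"S{j}" for j in perm], inten[:, perm], group[perm])
    )
    for a, b, c in zip(base, scaled, shuffled):
        assert a.log2fc == pytest.approx(b.log2fc, abs=1e-9)
        assert a.p_value == pytest.approx(c.p_value, rel=1e-9)


def test_zero_imputation_uses_half_minimum_positive():
    out = impute_zeros(np.array([[0.0, 4.0, 8.0]]))
    assert out[0, 0] == 2.0


def test_bh_matches_brute_force_step_up():
    """BH adjusted p equals the textbook step-up on random p-vectors."""

    def brute(p):
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.random(rng.integers(1, 51))
        assert np.allclose(bh_qvalues(p), brute(p), atol=1e-12)


class TestOverrepresentation:
    def test_query_equals_background_gives_p_one(self):
        bg = {f"P{i}" for i in range(30)}
        terms = {"T1": {f"P{i}" for i in range(10)}, "T2": {f"P{i}" for i in range(5, 25)}}
        for r in overrepresentation(bg, bg, terms):
            assert r.p_value == pytest.approx(1.0)

    def test_closed_form_fully_contained_query(self):
        bg = {f"P{i}" for i in range(20)}
        term = {f"P{i}" for i in range(5)}
        res = overrepresentation(term, bg, {"T": term})
        assert res[0].p_value == pytest.approx(1 / math.comb(20, 5))

    def test_tail_matches_enumeration_small_background(self):
        """Hypergeometric upper tail equals exhaustive draw enumeration."""
        bg = [f"P{i}" for i in range(12)]
        term = set(bg[:5])
        query = set(bg[2:6])  # overlap 3
        res = overrepresentation(query, set(bg), {"T": term})
        k_obs = len(term & query)
        hits = total = 0
        for draw in itertools.combinations(bg, len(query)):
            total += 1
            hits += len(term & set(draw)) >= k_obs
        assert res[0].overlap == k_obs
        assert res[0].p_value == pytest.approx(hits / total)

    def test_small_terms_skipped_and_errors(self):
        bg = {f"P{i}" for i in range(10)}
        res = overrepresentation({"P1"}, bg, {"tiny": {"P1", "P2"}})
        assert res == []
        with pytest.raises(ValueError):
            overrepresentation(set(), bg, {})
        with pytest.raises(ValueError):
            overrepresentation({"X"}, bg, {})

    def test_planted_term_ranks_first(self):
        wins = 0
        for seed in range(20):
            cfg = SimConfig(seed=100 + seed)
            matrix, group, truth, terms = gen_proteome(cfg)
            query = set(truth.index[truth["direction"] != "none"])
            res = overrepresentation(query, set(matrix.index), terms)
            wins += res[0].term_id == "TERM_PLANTED"
        assert wins >= 19


def test_gmt_roundtrip(tmp_path):
    terms = {"A": ["P1", "P2", "P3"], "B": ["P2", "P4", "P5", "P6"]}
    path = str(tmp_path / "t.gmt")
    write_gmt(terms, path)
    back = read_gmt(path)
    assert back == {k: set(v) for k, v in terms.items()}
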