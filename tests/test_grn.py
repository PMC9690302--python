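"""Expression preprocessing, module initialisation, and network inference."""

import numpy as np
import pandas as pd
import pytest

from chloronet.grn import (
    EngineConfig,
    ExpressionMatrix,
    center_expression,
    filter_expression,
    infer_network,
    init_modules,
    score_edge,
)
from chloronet.synthetic_data import SynthExprConfig, simulate_expression


def _matrix(rows: dict, regulators=()):
    n = len(next(iter(rows.values())))
    values = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    return ExpressionMatrix(values=values, regulators=list(regulators))


def test_center_expression():
    m = _matrix({"g": [1.0, 2.0, 3.0]})
    out = center_expression(m)
    assert out.values.loc["g"].tolist() == [-1.0, 0.0, 1.0]
    again = center_expression(out)
    assert np.allclose(again.values, out.values)


def test_center_rejects_missing_values():
    m = _matrix({"g": [1.0, np.nan, 3.0]})
    with pytest.raises(ValueError):
        center_expression(m)


def test_center_random_matrix_row_means_vanish():
    rng = np.random.default_rng(0)
    m = _matrix({f"g{i}": rng.normal(5, 3, size=30) for i in range(20)})
    out = center_expression(m)
    assert np.abs(out.values.mean(axis=1)).max() < 1e-9


def test_filter_boundary_and_counts():
    row = [1.0] * 5 + [0.0] * 7  # exactly five samples at the threshold
    weak = [0.5] * 12
    m = _matrix({"keep": row, "drop": weak, "zero": [0.0] * 12})
    out, report = filter_expression(m)
    assert list(out.values.index) == ["keep"]
    assert report == {"kept": 1, "dropped": 2}


def test_filter_counting_oracle_and_regulator_exemption():
    rng = np.random.default_rng(1)
    rows = {f"g{i}": rng.normal(0, 0.8, size=40) for i in range(50)}
    m = _matrix(rows, regulators=["g0", "g1"])
    out, _ = filter_expression(m)
    expected = {
        g for g, row in rows.items() if np.sum(np.abs(row) >= 1.0) >= 5
    } | {"g0", "g1"}
    assert set(out.values.index) == expected
    strict, _ = filter_expression(m, keep_regulators=False)
    assert set(strict.values.index) == {
        g for g, row in rows.items() if np.sum(np.abs(row) >= 1.0) >= 5
    }


def test_init_modules_duplicated_blocks():
    rng = np.random.default_rng(2)
    a = rng.normal(size=30)
    b = rng.normal(size=30)
    m = _matrix({"t1": a, "t2": a + rng.normal(0, 1e-6, 30), "t3": b, "t4": b.copy()})
    modules = init_modules(m, cut_height=0.5)
    assert modules["t1"] == modules["t2"]
    assert modules["t3"] == modules["t4"]
    assert modules["t1"] != modules["t3"]
    # near-limit cut: everything merges into one module
    wide = init_modules(m, cut_height=1.999)
    assert len(set(wide.values())) == 1


def test_init_modules_constant_row_isolated():
    rng = np.random.default_rng(3)
    m = _matrix({"t1": rng.normal(size=20), "t2": rng.normal(size=20), "flat": np.zeros(20)})
    with pytest.warns(UserWarning):
        modules = init_modules(m)
    assert modules["flat"] not in {modules["t1"], modules["t2"]}


def test_init_modules_recovers_planted_modules(expression):
    sklearn = pytest.importorskip("sklearn.metrics")
    matrix, truth = expression
    modules = init_modules(matrix)
    targets = sorted(truth.modules)
    ari = sklearn.adjusted_rand_score(
        [truth.modules[t] for t in targets], [modules[t] for t in targets]
    )
    assert ari >= 0.9


def test_score_edge_orthogonal_and_perfect():
    n = 64
    y = np.zeros(n)
    y[: n // 2] = 1.0
    y -= y.mean()
    cand = np.tile([1.0, -1.0], n // 2)  # orthogonal to y
    config = EngineConfig(sparsity_penalty=1.0, module_prior_strength=0.0)
    assert score_edge(y, [], cand, 0.0, config) == pytest.approx(-1.0, abs=1e-9)
    perfect = score_edge(y, [], y.copy(), 0.0, config)
    assert perfect > 1e5  # capped large finite gain
    assert np.isfinite(perfect)


def test_score_edge_collinear_candidate_skipped():
    rng = np.random.default_rng(4)
    y = rng.normal(size=20)
    x = rng.normal(size=20)
    config = EngineConfig(sparsity_penalty=1.0)
    with pytest.warns(UserWarning):
        gain = score_edge(y, [x], 2.0 * x, 0.0, config)
    assert gain == -np.inf


def test_score_edge_matches_normal_equation_oracle():
    rng = np.random.default_rng(5)
    config = EngineConfig(sparsity_penalty=1.5, module_prior_strength=2.0)
    for _ in range(25):
        n = 20
        y = rng.normal(size=n)
        preds = [rng.normal(size=n) for _ in range(rng.integers(0, 3))]
        cand = rng.normal(size=n)
        support = float(rng.random())

        def rss(cols):
            if not cols:
                return float(y @ y)
            X = np.column_stack(cols)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        expected = (
            0.5 * n * np.log(rss(preds) / rss(preds + [cand]))
            - 1.5
            + 2.0 * support
        )
        assert score_edge(y, preds, cand, support, config) == pytest.approx(expected, abs=1e-6)


def test_infer_single_dominant_regulator():
    rng = np.random.default_rng(6)
    n = 100
    regs = {f"R{i}": rng.normal(size=n) for i in range(4)}
    target = 0.9 * regs["R1"] + rng.normal(0, 0.01, size=n)
    m = center_expression(_matrix({**regs, "t": target}, regulators=list(regs)))
    net = infer_network(m, EngineConfig(rng_seed=0))
    assert net.edge_set() == {("R1", "t")}
    weight = net.edges[("R1", "t")].weight
    assert weight == pytest.approx(0.9, abs=0.01)


def test_infer_pure_noise_yields_empty_network():
    rng = np.random.default_rng(7)
    n = 100
    rows = {f"R{i}": rng.normal(size=n) for i in range(3)}
    rows.update({f"t{i}": rng.normal(size=n) for i in range(5)})
    m = center_expression(_matrix(rows, regulators=["R0", "R1", "R2"]))
    net = infer_network(m, EngineConfig(rng_seed=0, sparsity_penalty=4.0))
    assert net.n_edges == 0


def test_infer_recovers_planted_edges(inferred):
    net, truth = inferred
    found = net.edge_set()
    tp = len(found & truth.edges)
    assert tp / len(truth.edges) >= 0.9  # recall
    assert tp / len(found) >= 0.9  # precision


def test_beta_zero_matches_independent_forward_selection():
    """With the module prior off, inference is plain per-target greedy
    forward selection; an independent implementation must agree."""
    rng = np.random.default_rng(8)
    n, lam = 60, 3.0
    regs = {f"R{i}": rng.normal(size=n) for i in range(5)}
    rows = dict(regs)
    for i in range(6):
        drivers = rng.choice(5, size=2, replace=False)
        rows[f"t{i}"] = sum(regs[f"R{d}"] for d in drivers) + rng.normal(0, 0.2, n)
    m = center_expression(_matrix(rows, regulators=list(regs)))
    net = infer_network(
        m, EngineConfig(rng_seed=0, sparsity_penalty=lam, module_prior_strength=0.0)
    )

    def forward_select(y, candidates):
        chosen = []
        while len(chosen) < 5:
            best, best_gain = None, 0.0
            rss_cur = _rss(y, [candidates[c] for c in chosen])
            for c in sorted(candidates):
                if c in chosen:
                    continue
                gain = 0.5 * n * np.log(rss_cur / _rss(y, [candidates[x] for x in chosen + [c]])) - lam
                if gain > best_gain:
                    best, best_gain = c, gain
            if best is None:
                return chosen
            chosen.append(best)
        return chosen

    def _rss(y, cols):
        if not cols:
            return float(y @ y)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    expected = set()
    values = m.values
    cands = {r: values.loc[r].to_numpy() for r in regs}
    for t in m.targets:
        for r in forward_select(values.loc[t].to_numpy(), cands):
            expected.add((r, t))
    assert net.edge_set() == expected


def test_edge_set_invariant_under_sample_permutation(expression):
    matrix, _ = expression
    small = ExpressionMatrix(
        values=matrix.values.iloc[:, :80], regulators=matrix.regulators
    )
    rng = np.random.default_rng(9)
    perm = rng.permutation(small.values.shape[1])
    shuffled = ExpressionMatrix(
        values=small.values.iloc[:, perm], regulators=small.regulators
    )
    config = EngineConfig(rng_seed=0)
    assert infer_network(small, config).edge_set() == infer_network(shuffled, config).edge_set()


def test_edge_count_monotone_in_sparsity(expression):
    matrix, _ = expression
    small = ExpressionMatrix(values=matrix.values.iloc[:120, :], regulators=matrix.regulators)
    counts = [
        infer_network(small, EngineConfig(rng_seed=0, sparsity_penalty=lam)).n_edges
        for lam in (0.5, 2.0, 4.0, 8.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_infer_requires_regulators():
    rng = np.random.default_rng(10)
    m = _matrix({"a": rng.normal(size=10), "b": rng.normal(size=10)})
    with pytest.raises(ValueError):
        infer_network(m)


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(sparsity_penalty=-1)
    with pytest.raises(ValueError):
        EngineConfig(module_cut_height=2.5)
    cfg = EngineConfig()
    assert cfg.resolve_sparsity(200, 10) == pytest.approx(
        0.5 * np.log(200) + 0.5 * np.log(10)
    )
    assert EngineConfig(sparsity_penalty=2.0).resolve_sparsity(200, 10) == 2.0
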