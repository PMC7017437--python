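"""Blomberg's K, Pagel's lambda and the GLS machinery behind them."""

import shutil
import subprocess

import numpy as np
import pytest

from dermovasc import (
    PhyloCovariance,
    TraitVector,
    blomberg_K,
    blomberg_K_test,
    gls_mean_mse,
    pagel_lambda_ml,
    phylo_covariance,
)
from dermovasc.signal import _lambda_loglik
from dermovasc.synthetic import SimulationSpec, simulate_tree, simulate_traits

from conftest import dense_K, dense_lambda_loglik


# ------------------------------------------------------------ gls_mean_mse

def test_gls_identity_covariance_reduces_to_ordinary_stats():
    rng = np.random.default_rng(0)
    x = rng.normal(size=9)
    C = PhyloCovariance(np.eye(9))
    a, mse, mse0 = gls_mean_mse(TraitVector(x), C)
    assert a == pytest.approx(x.mean())
    assert mse == pytest.approx(x.var(ddof=1))
    assert mse0 == pytest.approx(x.var(ddof=1))


def test_gls_constant_trait_zero_mse(tree6):
    C = phylo_covariance(tree6)
    a, mse, mse0 = gls_mean_mse(TraitVector(np.full(6, 0.4)), C)
    assert a == pytest.approx(0.4)
    assert mse == pytest.approx(0.0)
    assert mse0 == pytest.approx(0.0)


def test_gls_matches_dense_algebra_oracle(tree6):
    rng = np.random.default_rng(3)
    C = phylo_covariance(tree6)
    x = rng.normal(0.2, 0.1, size=6)
    a, mse, mse0 = gls_mean_mse(TraitVector(x, C.tip_order), C)
    Cinv = np.linalg.inv(C.matrix)
    ones = np.ones(6)
    a_o = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    r = x - a_o
    assert a == pytest.approx(a_o, abs=1e-10)
    assert mse == pytest.approx(r @ Cinv @ r / 5, abs=1e-10)
    assert mse0 == pytest.approx(r @ r / 5, abs=1e-10)


# ---------------------------------------------------------------- Blomberg K

def test_star_tree_K_is_exactly_one():
    star = simulate_tree(SimulationSpec(n_tips=12, tree_shape="star", depth=7.0))
    for seed in range(3):
        x = np.random.default_rng(seed).normal(size=12)
        assert blomberg_K(TraitVector(x, star.tip_labels), star) == pytest.approx(1.0)


def test_K_matches_from_scratch_formula_on_worked_instance(tree6):
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    C = phylo_covariance(tree6)
    ours = blomberg_K(TraitVector(x, C.tip_order), tree6)
    assert ours == pytest.approx(dense_K(x, C.matrix), abs=1e-12)


def test_K_affine_invariance(tree6):
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    t = TraitVector(x, tree6.tip_labels)
    t2 = TraitVector(5.0 * x - 1.3, tree6.tip_labels)
    assert blomberg_K(t2, tree6) == pytest.approx(blomberg_K(t, tree6))


def test_K_constant_trait_errors(tree6):
    with pytest.raises(ValueError, match="undefined"):
        blomberg_K(TraitVector(np.ones(6), tree6.tip_labels), tree6)


def test_K_mean_near_one_under_bm():
    spec = SimulationSpec(n_tips=32, tree_shape="yule-like", depth=100.0, sigma2=1e-4, seed=4)
    tree = simulate_tree(spec)
    C = phylo_covariance(tree)
    ks = [
        blomberg_K(simulate_traits(tree, spec, seed=1000 + i), C)
        for i in range(200)
    ]
    assert np.mean(ks) == pytest.approx(1.0, abs=0.1)


# ------------------------------------------------------------ K permutation

def test_K_test_detects_strong_signal():
    spec = SimulationSpec(n_tips=48, tree_shape="yule-like", depth=150.0, sigma2=1e-4, seed=8)
    tree = simulate_tree(spec)
    traits = simulate_traits(tree, spec, seed=8)
    res = blomberg_K_test(traits, tree, n_perm=499, seed=0)
    assert res.p_value < 0.05
    assert res.n_randomizations == 499


def test_K_test_type_I_rate_calibrated_under_shuffled_traits():
    spec = SimulationSpec(n_tips=24, tree_shape="yule-like", depth=80.0, sigma2=1e-4, seed=12)
    tree = simulate_tree(spec)
    C = phylo_covariance(tree)
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 200
    for i in range(n_rep):
        x = rng.normal(size=24)  # exchangeable across tips: null is true
        res = blomberg_K_test(TraitVector(x, C.tip_order), C, n_perm=199, seed=i)
        rejections += res.p_value <= 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


def test_K_test_rejects_zero_permutations(tree6):
    with pytest.raises(ValueError):
        blomberg_K_test(
            TraitVector(np.arange(6.0), tree6.tip_labels), tree6, n_perm=0
        )


def test_K_test_reproducible_under_seed(tree6):
    t = TraitVector(np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09]), tree6.tip_labels)
    a = blomberg_K_test(t, tree6, n_perm=99, seed=42)
    b = blomberg_K_test(t, tree6, n_perm=99, seed=42)
    assert a.p_value == b.p_value


# -------------------------------------------------------------- Pagel lambda

def test_lambda_loglik_matches_dense_oracle(tree6):
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    C = phylo_covariance(tree6)
    for lam in (0.0, 0.3, 0.7, 1.0):
        assert _lambda_loglik(x, C, lam) == pytest.approx(
            dense_lambda_loglik(x, C.matrix, lam), abs=1e-9
        )


def test_lambda_estimate_beats_dense_grid(tree6):
    rng = np.random.default_rng(21)
    spec = SimulationSpec(n_tips=24, tree_shape="yule-like", depth=90.0, sigma2=1e-4, lam=0.6, seed=21)
    tree = simulate_tree(spec)
    traits = simulate_traits(tree, spec, seed=21)
    C = phylo_covariance(tree)
    res = pagel_lambda_ml(traits, tree)
    grid = np.arange(0.0, 1.0 + 1e-12, 0.01)
    lls = [_lambda_loglik(traits.values, C, g) for g in grid]
    assert res.log_likelihoods["at_estimate"] >= max(lls) - 1e-9
    assert abs(res.estimate - grid[int(np.argmax(lls))]) <= 0.01 + 1e-4


def test_lambda_endpoints_interpretation(tree6):
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    C = phylo_covariance(tree6)
    # lambda=0: independent heteroscedastic tips (diagonal covariance)
    diag = PhyloCovariance(np.diag(np.diag(C.matrix)), C.tip_order)
    n = 6
    a, mse, _ = gls_mean_mse(TraitVector(x, C.tip_order), diag)
    s2 = mse * (n - 1) / n
    ll0_direct = -0.5 * (
        n * np.log(2 * np.pi)
        + n * np.log(s2)
        + np.log(np.diag(C.matrix)).sum()
        + n
    )
    assert _lambda_loglik(x, C, 0.0) == pytest.approx(ll0_direct, abs=1e-9)


def test_lambda_affine_invariance(tree6):
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    a = pagel_lambda_ml(TraitVector(x, tree6.tip_labels), tree6)
    b = pagel_lambda_ml(TraitVector(3.0 * x + 2.0, tree6.tip_labels), tree6)
    assert b.estimate == pytest.approx(a.estimate, abs=1e-5)
    assert b.p_value == pytest.approx(a.p_value, rel=1e-4)


def test_lambda_recovery_both_extremes():
    spec1 = SimulationSpec(n_tips=64, tree_shape="yule-like", depth=200.0, sigma2=5e-5, lam=1.0, seed=31)
    tree = simulate_tree(spec1)
    hats1 = [pagel_lambda_ml(simulate_traits(tree, spec1, seed=i), tree).estimate for i in range(30)]
    assert np.mean(hats1) >= 0.9

    spec0 = SimulationSpec(n_tips=64, tree_shape="yule-like", depth=200.0, sigma2=5e-5, lam=0.0, seed=31)
    hats0 = [pagel_lambda_ml(simulate_traits(tree, spec0, seed=i), tree).estimate for i in range(30)]
    assert np.mean(hats0) <= 0.1


def test_lambda_star_tree_flat_likelihood_warns():
    star = simulate_tree(SimulationSpec(n_tips=10, tree_shape="star", depth=5.0))
    x = np.random.default_rng(2).normal(size=10)
    with pytest.warns(UserWarning, match="flat"):
        res = pagel_lambda_ml(TraitVector(x, star.tip_labels), star)
    assert res.estimate == 0.0


def test_lambda_constant_trait_errors(tree6):
    with pytest.raises(ValueError):
        pagel_lambda_ml(TraitVector(np.ones(6), tree6.tip_labels), tree6)


# ------------------------------------------------- independent contrasts

def test_gls_mean_and_mse_match_independent_contrasts_on_binary_tree():
    """Felsenstein pruning gives the same phylogenetic mean and MSE."""
    spec = SimulationSpec(n_tips=16, tree_shape="yule-like", depth=60.0, sigma2=1e-4, seed=17)
    tree = simulate_tree(spec)
    traits = simulate_traits(tree, spec, seed=17)
    values = dict(zip(traits.tip_order, traits.values))

    contrasts = []

    def prune(node):
        # returns (value, extra branch length) at this node
        if node.is_leaf():
            return values[node.taxon.label], node.edge.length
        (xa, va), (xb, vb) = [prune(ch) for ch in node.child_nodes()]
        contrasts.append((xa - xb) / np.sqrt(va + vb))
        x = (xa / va + xb / vb) / (1 / va + 1 / vb)
        extra = (va * vb) / (va + vb)
        if node.parent_node is not None:
            extra += node.edge.length
        return x, extra

    root_x, _ = prune(tree.tree.seed_node)
    C = phylo_covariance(tree)
    a_hat, mse, _ = gls_mean_mse(traits, C)
    assert a_hat == pytest.approx(root_x, abs=1e-10)
    assert mse == pytest.approx(np.sum(np.square(contrasts)) / (len(values) - 1), abs=1e-10)


# ------------------------------------------------------------- R cross-check

def test_K_and_lambda_agree_with_phytools(tmp_path, tree6):
    """Independent oracle: the reference R implementation (phytools)."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    x = np.array([0.31, 0.25, 0.18, 0.22, 0.05, 0.09])
    traits = TraitVector(x, tree6.tip_labels)
    script = tmp_path / "phylosig.R"
    script.write_text(
        'suppressMessages(library(phytools))\n'
        f'tr <- read.tree(text="{tree6.to_newick()}")\n'
        'x <- c(A=0.31, B=0.25, C=0.18, D=0.22, E=0.05, F=0.09)\n'
        'k <- phylosig(tr, x, method="K")\n'
        'l <- phylosig(tr, x, method="lambda")\n'
        'cat(sprintf("%.10f %.10f %.6f\\n", k, l$lambda, l$logL))\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    k_r, lam_r, logl_r = map(float, out.stdout.split())
    assert blomberg_K(traits, tree6) == pytest.approx(k_r, abs=1e-8)
    res = pagel_lambda_ml(traits, tree6)
    assert res.estimate == pytest.approx(lam_r, abs=2e-3)
    assert res.log_likelihoods["at_estimate"] == pytest.approx(logl_r, abs=1e-3)
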