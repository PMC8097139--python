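"""Trees, independent contrasts, Blomberg's K, Brownian simulation.

The deep checks here are (1) the whitening property that defines
independent contrasts — the linear map they apply to tip values turns the
Brownian covariance into the identity — verified exhaustively over all
rooted binary topologies with up to 6 tips, and (2) agreement with the
independent R implementations (ape::pic, picante::Kcalc) on fixtures.
"""

import itertools
import shutil
import subprocess

import numpy as np
import pytest

from stomgeo.phylocomp import (
    Phylogeny,
    blomberg_k,
    generate_tree,
    parse_newick,
    pic,
    simulate_bm,
    sma_on_contrasts,
    vcv_matrix,
)


class TestParseNewick:
    def test_two_tips(self):
        p = parse_newick("(A:1,B:1);")
        assert p.n_tips == 2
        assert sorted(p.tip_labels) == ["A", "B"]

    def test_three_tip_bifurcating(self):
        p = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert p.n_tips == 3
        assert p.is_bifurcating()

    def test_syntax_error(self):
        with pytest.raises(ValueError, match="[Nn]ewick"):
            parse_newick("(A:1,B:1")

    def test_missing_branch_length(self):
        with pytest.raises(ValueError, match="branch length"):
            parse_newick("(A:1,B);")

    def test_zero_branch_length_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            parse_newick("(A:0,B:1);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A:1,A:1):1,B:2);")

    def test_tip_labels_normalized(self):
        p = parse_newick("('Pinus sylvestris':1,B:1);")
        assert "Pinus_sylvestris" in p.tip_labels


# -- exhaustive topology enumeration (rooted binary, labeled leaves) --------


def _all_topologies(labels):
    """Every rooted binary topology as nested tuples; (2n-3)!! of them."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for smaller in _all_topologies(rest):
        for t in _insert_everywhere(smaller, first):
            yield t


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)  # attach above the root
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def _to_newick(tree, rng):
    def fmt(node):
        if isinstance(node, tuple):
            return f"({fmt(node[0])},{fmt(node[1])}):{rng.uniform(0.2, 2.0):.6f}"
        return f"{node}:{rng.uniform(0.2, 2.0):.6f}"

    return f"({fmt(tree[0])},{fmt(tree[1])});"


def _contrast_matrix(phylo):
    """Extract the linear map tips -> contrasts by probing with unit vectors."""
    labels = phylo.tip_labels
    cols = []
    for lab in labels:
        traits = {l: (1.0 if l == lab else 0.0) for l in labels}
        cols.append(pic(phylo, traits).contrasts)
    return np.column_stack(cols), labels


class TestPic:
    def test_two_tip_closed_form(self):
        p = parse_newick("(A:1,B:1);")
        cs = pic(p, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2.0 / np.sqrt(2.0))

    def test_equal_traits_give_zero_contrasts(self):
        p = generate_tree(12, seed=5)
        cs = pic(p, {l: 7.0 for l in p.tip_labels})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    def test_balanced_four_tip_hand_values(self):
        p = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cs = pic(p, {"A": 1.0, "B": 3.0, "C": 6.0, "D": 10.0})
        # (1-3)/sqrt(2), (6-10)/sqrt(2), and (2-8)/sqrt(1.5+1.5) at the root
        got = sorted(np.abs(cs.contrasts))
        assert got == pytest.approx(
            sorted([2 / np.sqrt(2), 4 / np.sqrt(2), 6 / np.sqrt(3)])
        )

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_whitening_property_on_all_topologies(self, n_tips):
        """Contrasts of every <=6-tip tree are GLS-whitened tip differences:

        the probing matrix A satisfies A V A' = I and A 1 = 0, where V is
        the Brownian tip covariance — exactly the property defining
        independent contrasts.
        """
        labels = [chr(ord("A") + i) for i in range(n_tips)]
        rng = np.random.default_rng(n_tips)
        for topo in _all_topologies(labels):
            phylo = parse_newick(_to_newick(topo, rng))
            A, order = _contrast_matrix(phylo)
            _, V = vcv_matrix(phylo)
            np.testing.assert_allclose(
                A @ V @ A.T, np.eye(n_tips - 1), atol=1e-10
            )
            np.testing.assert_allclose(A @ np.ones(n_tips), 0.0, atol=1e-10)

    def test_contrast_count_on_bifurcating_tree(self):
        p = generate_tree(50, seed=9)
        cs = pic(p, {l: float(i) for i, l in enumerate(p.tip_labels)})
        assert len(cs) == 49

    def test_missing_trait_error(self):
        p = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            pic(p, {"A": 1.0})

    def test_polytomy_default_errors_resolve_works(self):
        p = parse_newick("(A:1,B:1,C:1);")
        traits = {"A": 1.0, "B": 2.0, "C": 4.0}
        with pytest.raises(ValueError, match="polytomy"):
            pic(p, traits)
        cs = pic(p, traits, polytomy_policy="resolve")
        assert len(cs) == 2
        assert cs.polytomy_policy == "resolve"


class TestSmaOnContrasts:
    def test_exact_negative_proportionality(self):
        p = generate_tree(20, seed=2)
        x = simulate_bm(p, sigma=1.0, seed=3)
        y = {k: -v for k, v in x.items()}
        cx, cy = pic(p, x), pic(p, y)
        fit = sma_on_contrasts(cx, cy, hypothesized_slope=-1.0)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.p_slope_test == 1.0

    def test_slope_recovery_under_correlated_bm(self):
        # y = 0.8*x + independent BM noise; through-origin SMA slope of
        # contrasts converges to sqrt(0.8^2 + sigma_e^2/sigma_x^2)
        p = generate_tree(150, seed=11)
        x = simulate_bm(p, sigma=1.0, seed=12)
        e = simulate_bm(p, sigma=0.3, seed=13)
        y = {k: 0.8 * x[k] + e[k] for k in x}
        fit = sma_on_contrasts(pic(p, x), pic(p, y))
        assert fit.slope == pytest.approx(np.sqrt(0.64 + 0.09), rel=0.12)

    def test_mismatched_sets_rejected(self):
        p1, p2 = generate_tree(8, seed=1), generate_tree(9, seed=1)
        c1 = pic(p1, {l: 1.0 + i for i, l in enumerate(p1.tip_labels)})
        c2 = pic(p2, {l: 1.0 + i for i, l in enumerate(p2.tip_labels)})
        with pytest.raises(ValueError, match="different"):
            sma_on_contrasts(c1, c2)


class TestBlombergK:
    def test_star_tree_k_is_exactly_one(self):
        p = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        traits = {"A": 1.0, "B": 5.0, "C": 2.0, "D": 9.0, "E": 3.0}
        res = blomberg_k(p, traits, n_perm=9, seed=0)
        assert res.k == pytest.approx(1.0, abs=1e-12)

    def test_seed_reproducibility(self):
        p = generate_tree(15, seed=4)
        traits = simulate_bm(p, seed=5)
        a = blomberg_k(p, traits, n_perm=199, seed=42)
        b = blomberg_k(p, traits, n_perm=199, seed=42)
        assert (a.k, a.p_perm) == (b.k, b.p_perm)

    def test_k_independent_of_trait_dict_order(self):
        p = generate_tree(10, seed=6)
        traits = simulate_bm(p, seed=7)
        rev = dict(reversed(list(traits.items())))
        assert blomberg_k(p, traits, 49, 1).k == blomberg_k(p, rev, 49, 1).k

    def test_random_traits_on_structured_tree_have_low_k(self):
        # traits independent of a deep tree: K << 1, permutation p large
        p = generate_tree(60, seed=8, birth_rate=1.0)
        rng = np.random.default_rng(3)
        traits = {l: float(rng.normal()) for l in p.tip_labels}
        res = blomberg_k(p, traits, n_perm=199, seed=9)
        assert res.k < 0.6
        assert res.p_perm > 0.05

    def test_strong_signal_detected(self):
        p = generate_tree(40, seed=14)
        traits = simulate_bm(p, sigma=1.0, seed=15)
        res = blomberg_k(p, traits, n_perm=199, seed=16)
        assert res.p_perm < 0.05

    def test_nperm_validation(self):
        p = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="n_perm"):
            blomberg_k(p, {"A": 1.0, "B": 2.0}, n_perm=0)


class TestSimulateBm:
    def test_zero_rate_returns_root_value(self):
        p = generate_tree(7, seed=1)
        traits = simulate_bm(p, sigma=0.0, root_value=4.2, seed=0)
        assert all(v == 4.2 for v in traits.values())

    def test_tip_covariance_matches_tree(self):
        p = generate_tree(5, seed=20)
        labels, V = vcv_matrix(p)
        reps = 4000
        draws = np.array(
            [
                [simulate_bm(p, sigma=1.0, seed=s)[l] for l in labels]
                for s in range(reps)
            ]
        )
        emp = np.cov(draws.T)
        # entrywise within 3 standard errors of a covariance estimate
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / reps)
        assert np.all(np.abs(emp - V) < 3.5 * se)

    def test_contrasts_of_bm_are_standard_normal(self):
        p = generate_tree(20, seed=30)
        pooled = np.concatenate(
            [
                pic(p, simulate_bm(p, sigma=1.5, seed=100 + s)).contrasts
                for s in range(100)
            ]
        )
        assert np.var(pooled) == pytest.approx(1.5**2, rel=0.1)
        assert np.mean(pooled) == pytest.approx(0.0, abs=0.1)


class TestGenerateTree:
    def test_two_tips_shape(self):
        p = generate_tree(2, seed=0)
        assert p.n_tips == 2
        lengths = [
            n.edge.length
            for n in p.tree.leaf_node_iter()
        ]
        assert lengths[0] == pytest.approx(lengths[1])

    def test_seed_determinism(self):
        assert generate_tree(10, seed=3).as_newick() == generate_tree(
            10, seed=3
        ).as_newick()

    def test_internal_node_count(self):
        p = generate_tree(50, seed=1)
        internal = sum(1 for _ in p.tree.preorder_internal_node_iter())
        assert internal == 49
        assert p.is_bifurcating()

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            generate_tree(1)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestAgainstR:
    """Cross-checks against the independent ape / picante implementations."""

    def _run_r(self, script, tmp_path):
        f = tmp_path / "oracle.R"
        f.write_text(script)
        out = subprocess.run(
            ["Rscript", str(f)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        return out.stdout

    def test_pic_matches_ape(self, tmp_path):
        phylo = generate_tree(8, seed=77)
        traits = simulate_bm(phylo, sigma=1.0, seed=78)
        newick = phylo.as_newick()
        vec = ", ".join(f"{traits[l]!r}" for l in phylo.tip_labels)
        labs = ", ".join(f"'{l}'" for l in phylo.tip_labels)
        out = self._run_r(
            "suppressMessages(library(ape))\n"
            f"tr <- read.tree(text='{newick}')\n"
            f"x <- c({vec}); names(x) <- c({labs})\n"
            "cat(sprintf('%.12f', sort(abs(pic(x[tr$tip.label], tr)))), sep='\\n')\n",
            tmp_path,
        )
        r_vals = sorted(float(v) for v in out.split())
        mine = sorted(np.abs(pic(phylo, traits).contrasts))
        np.testing.assert_allclose(mine, r_vals, rtol=1e-9)

    def test_blomberg_k_matches_picante(self, tmp_path):
        phylo = generate_tree(12, seed=80)
        traits = simulate_bm(phylo, sigma=1.0, seed=81)
        newick = phylo.as_newick()
        vec = ", ".join(f"{traits[l]!r}" for l in phylo.tip_labels)
        labs = ", ".join(f"'{l}'" for l in phylo.tip_labels)
        out = self._run_r(
            "suppressMessages({library(ape); library(picante)})\n"
            f"tr <- read.tree(text='{newick}')\n"
            f"x <- c({vec}); names(x) <- c({labs})\n"
            "cat(sprintf('%.12f', Kcalc(x[tr$tip.label], tr)))\n",
            tmp_path,
        )
        mine = blomberg_k(phylo, traits, n_perm=1, seed=0).k
        assert mine == pytest.approx(float(out), rel=1e-9)
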