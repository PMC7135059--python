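"""Inference layer: ANOVA vs independent oracles, GG ε, multiple comparisons,
paired/Bayesian tests, repeated-measures power."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pupilpipe.exceptions import InsufficientDataError
from pupilpipe.stats import (
    bayes_t,
    bf_from_bic,
    classify_bf,
    gg_epsilon,
    paired_t,
    pairwise_correct,
    required_n,
    rm_anova,
    rm_power,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: projection matrices on the S × A × B tensor
# ---------------------------------------------------------------------------


def projection_anova_oracle(Y: np.ndarray) -> dict:
    """Sums of squares of a fully-within S×A×B design via orthogonal
    projections (tensor products of centering and averaging operators) —
    an algebraic route independent of marginal-mean formulas."""
    n, a, b = Y.shape
    y = Y.reshape(-1)

    def J(k):
        return np.full((k, k), 1.0 / k)

    def C(k):
        return np.eye(k) - J(k)

    ops = {"S": (C(n), J(n)), "A": (C(a), J(a)), "B": (C(b), J(b))}

    def P(effect):
        mats = [ops[f][0] if f in effect else ops[f][1] for f in ("S", "A", "B")]
        return np.kron(np.kron(mats[0], mats[1]), mats[2])

    out = {}
    for effect in ("A", "B", "AB", "SA", "SB", "SAB"):
        out[effect] = float(y @ P(set(effect)) @ y)
    return out


def tidy(Y: np.ndarray) -> pd.DataFrame:
    n, a, b = Y.shape
    rows = [
        (s, f"a{i}", f"b{j}", Y[s, i, j])
        for s in range(n)
        for i in range(a)
        for j in range(b)
    ]
    return pd.DataFrame(rows, columns=["subj", "A", "B", "y"])


class TestRmAnovaOracle:
    @pytest.mark.parametrize("seed,n,a,b", [(0, 6, 3, 4), (1, 8, 3, 4), (2, 5, 2, 3)])
    def test_matches_projection_decomposition(self, seed, n, a, b):
        rng = np.random.default_rng(seed)
        Y = np.round(rng.normal(0, 2, (n, a, b)), 1)  # hand-enumerable values
        oracle = projection_anova_oracle(Y)
        res = {r.effect: r for r in rm_anova(tidy(Y), dv="y", within=["A", "B"], subject="subj", gg=False)}
        checks = {
            "A": ("A", "SA", (a - 1), (a - 1) * (n - 1)),
            "B": ("B", "SB", (b - 1), (b - 1) * (n - 1)),
            "A:B": ("AB", "SAB", (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
        }
        for name, (ss_k, err_k, df1, df2) in checks.items():
            F_oracle = (oracle[ss_k] / df1) / (oracle[err_k] / df2)
            pe2_oracle = oracle[ss_k] / (oracle[ss_k] + oracle[err_k])
            r = res[name]
            assert r.F == pytest.approx(F_oracle, abs=1e-10, rel=1e-10)
            assert r.partial_eta2 == pytest.approx(pe2_oracle, abs=1e-10)
            assert (r.df1, r.df2) == (df1, df2)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(42)
        Y = rng.normal(0, 1, (7, 3, 4)) + np.linspace(0, 1, 12).reshape(1, 3, 4)
        df = tidy(Y)
        mine = {r.effect: r for r in rm_anova(df, dv="y", within=["A", "B"], subject="subj", gg=False)}
        ref = AnovaRM(df, "y", "subj", within=["A", "B"]).fit().anova_table
        for eff, key in [("A", "A"), ("B", "B"), ("A:B", "A:B")]:
            assert mine[eff].F == pytest.approx(ref.loc[key, "F Value"], rel=1e-9)
            assert mine[eff].p == pytest.approx(ref.loc[key, "Pr > F"], abs=1e-12)

    def test_mixed_design_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        rows = []
        for g in ("vision", "audition"):
            for s in range(8):
                sid = f"{g}{s}"
                base = rng.normal()
                for i, lev in enumerate(("pos", "neg", "neu")):
                    rows.append((sid, g, lev, base + 0.3 * i + rng.normal()))
        df = pd.DataFrame(rows, columns=["subj", "G", "A", "y"])
        mine = {
            r.effect: r
            for r in rm_anova(df, dv="y", within=["A"], subject="subj", between="G", gg=False)
        }
        ref = pg.mixed_anova(data=df, dv="y", within="A", subject="subj", between="G")
        ref = ref.set_index("Source")
        assert mine["G"].F == pytest.approx(ref.loc["G", "F"], rel=1e-9)
        assert mine["A"].F == pytest.approx(ref.loc["A", "F"], rel=1e-9)
        assert mine["A:G"].F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert mine["A"].partial_eta2 == pytest.approx(ref.loc["A", "np2"], rel=1e-9)

    def test_two_level_factor_F_equals_squared_paired_t(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(0.4, 1, 10)
        df = pd.DataFrame(
            {
                "subj": list(range(10)) * 2,
                "A": ["x"] * 10 + ["y"] * 10,
                "y": np.concatenate([x, y]),
            }
        )
        r = rm_anova(df, dv="y", within=["A"], subject="subj")[0]
        t, dfree, p = paired_t(x, y)
        assert r.F == pytest.approx(t**2, rel=1e-12)
        assert (r.df1, r.df2) == (1, 9)
        assert r.p == pytest.approx(p, abs=1e-12)
        assert r.gg_epsilon == 1.0  # sphericity vacuous at 2 levels

    def test_incomplete_participant_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        df = tidy(rng.normal(size=(5, 3, 4)))
        df = df[~((df.subj == 4) & (df.A == "a0") & (df.B == "b0"))]
        with pytest.warns(UserWarning):
            res = rm_anova(df, dv="y", within=["A", "B"], subject="subj", gg=False)
        assert res[0].df2 == (3 - 1) * (4 - 1)  # n dropped to 4

    def test_too_few_participants_raise(self):
        df = tidy(np.zeros((1, 2, 2)))
        with pytest.raises(InsufficientDataError):
            rm_anova(df, dv="y", within=["A", "B"], subject="subj")

    def test_zero_error_variance_reports_infinite_F(self):
        Y = np.zeros((4, 3, 1))
        Y[:, 1, 0] = 1.0  # identical pattern for all subjects
        df = tidy(Y)
        with pytest.warns(UserWarning):
            r = rm_anova(df[df.B == "b0"], dv="y", within=["A"], subject="subj", bayes=False)[0]
        assert math.isinf(r.F) and r.p == 0.0


class TestGGEpsilon:
    def test_compound_symmetry_recovers_one(self):
        rng = np.random.default_rng(11)
        n, k = 4000, 4
        subj = rng.normal(0, 1, (n, 1))
        Y = subj + rng.normal(0, 1, (n, k))
        from scipy.linalg import helmert

        eps = gg_epsilon(Y, helmert(k, full=False))
        assert eps == pytest.approx(1.0, abs=0.02)

    def test_bounds_on_random_covariances(self):
        from scipy.linalg import helmert

        rng = np.random.default_rng(13)
        for _ in range(25):
            k = rng.integers(3, 6)
            A = rng.normal(size=(k, k))
            Y = rng.multivariate_normal(np.zeros(k), A @ A.T + np.eye(k), size=12)
            eps = gg_epsilon(Y, helmert(int(k), full=False))
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_r_car_value_for_mixed_design(self):
        # frozen from car::Anova (idesign GG) on the same 12-subject,
        # 2-group, 3-level dataset
        rng = np.random.default_rng(3)
        rng.normal(size=96)  # spend the stream as in the generating script
        rows = []
        for g, gn in enumerate(["v", "a"]):
            for s in range(6):
                for i, a in enumerate(["a1", "a2", "a3"]):
                    rows.append((f"{gn}{s}", gn, a, rng.normal() + 0.4 * i + 0.3 * g + 0.2 * g * i))
        df = pd.DataFrame(rows, columns=["subj", "G", "A", "y"])
        res = rm_anova(df, dv="y", within=["A"], subject="subj", between="G", gg=True)
        eps = {r.effect: r.gg_epsilon for r in res}
        assert eps["A"] == pytest.approx(0.9450527, abs=1e-6)


def holm_exhaustive(ps, alpha):
    """Literal rule application: for each hypothesis, rejected iff for every
    j with p_(j) ≤ p_i the step threshold holds up to i."""
    ps = np.asarray(ps)
    order = np.argsort(ps, kind="stable")
    rejected = np.zeros(len(ps), bool)
    for i, idx in enumerate(order):
        if all(ps[order[j]] <= alpha / (len(ps) - j) for j in range(i + 1)):
            rejected[idx] = True
        else:
            break
    return rejected


class TestPairwise:
    def test_holm_example(self):
        res = pairwise_correct([0.002, 0.030, 0.200], method="msrb_holm")
        assert [r.rejected for r in res] == [True, False, False]

    def test_shaffer_example_three_means(self):
        res = pairwise_correct([0.002, 0.030, 0.200], method="msrb_shaffer", n_means=3)
        assert [r.rejected for r in res] == [True, True, False]

    def test_all_ones_never_rejected(self):
        for method, kw in [("bonferroni", {}), ("msrb_holm", {}), ("msrb_shaffer", {"n_means": 3})]:
            res = pairwise_correct([1.0, 1.0, 1.0], method=method, **kw)
            assert not any(r.rejected for r in res)

    def test_holm_equals_exhaustive_on_all_orderings(self):
        """Step-down implementation vs literal rule application for every
        ordering of up to 4 hypotheses."""
        rng = np.random.default_rng(21)
        for k in (2, 3, 4):
            base = rng.uniform(0, 0.2, k)
            for perm in itertools.permutations(range(k)):
                ps = base[list(perm)]
                mine = np.array(
                    [r.rejected for r in pairwise_correct(ps, method="msrb_holm")]
                )
                np.testing.assert_array_equal(mine, holm_exhaustive(ps, 0.05))

    def test_rejection_monotone_in_p(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            ps = rng.uniform(0, 0.3, 6)
            res = pairwise_correct(ps, method="msrb_shaffer", n_means=4)
            rej_ps = [r.p for r in res if r.rejected]
            keep_ps = [r.p for r in res if not r.rejected]
            if rej_ps and keep_ps:
                assert max(rej_ps) <= min(keep_ps)

    def test_dominance_bonferroni_holm_shaffer(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            ps = rng.uniform(0, 0.2, 6)
            bon = {r.label for r in pairwise_correct(ps, "bonferroni") if r.rejected}
            holm = {r.label for r in pairwise_correct(ps, "msrb_holm") if r.rejected}
            shaf = {
                r.label
                for r in pairwise_correct(ps, "msrb_shaffer", n_means=4)
                if r.rejected
            }
            assert bon <= holm <= shaf

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correct([0.1, 1.2])


class TestPairedAndBayes:
    def test_identical_samples(self):
        x = np.arange(10.0)
        t, df, p = paired_t(x, x)
        assert (t, p) == (0.0, 1.0)
        assert bayes_t(x, x) < 1.0

    def test_closed_form_differences_one_two_three(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.zeros(3)
        t, df, p = paired_t(x, y)
        assert t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), rel=1e-9)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_bf_from_bic_formula(self):
        assert bf_from_bic(10.0, 8.0) == pytest.approx(math.e)
        assert bf_from_bic(5.0, 5.0) == 1.0

    def test_bf_classification_bands(self):
        assert classify_bf(0.2) == "moderate evidence for null"
        assert classify_bf(5.0) == "moderate evidence for alternative"
        assert classify_bf(1.0) == "anecdotal"


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert rm_power(24, 4, 0.0) == pytest.approx(0.05)

    def test_monotone_in_n(self):
        powers = [rm_power(n, 4, 0.25) for n in range(4, 60, 4)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_required_n_is_minimal(self):
        n = required_n(m=4, f=0.25, target_power=0.80)
        assert rm_power(n, 4, 0.25) >= 0.80
        assert rm_power(n - 1, 4, 0.25) < 0.80

    def test_zero_effect_has_no_finite_n(self):
        with pytest.raises(ValueError):
            required_n(m=4, f=0.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            rm_power(1, 4, 0.25)
        with pytest.raises(ValueError):
            rm_power(24, 4, 0.25, rho=1.0)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ps=st.lists(st.floats(0, 1), min_size=3, max_size=3))
def test_stepdown_dominance_property(ps):
    """Bonferroni rejections ⊆ Holm rejections ⊆ Shaffer rejections for any
    p-vector of a 3-mean pairwise family."""
    bon = {r.label for r in pairwise_correct(ps, "bonferroni") if r.rejected}
    holm = {r.label for r in pairwise_correct(ps, "msrb_holm") if r.rejected}
    shaf = {r.label for r in pairwise_correct(ps, "msrb_shaffer", n_means=3) if r.rejected}
    assert bon <= holm <= shaf


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    n=st.integers(3, 8),
    a=st.integers(2, 4),
)
def test_partial_eta2_identity_property(seed, n, a):
    """In a balanced one-way within design, partial η² = F·df1/(F·df1+df2)."""
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(n, a))
    df = pd.DataFrame(
        {
            "subj": np.repeat(np.arange(n), a),
            "A": np.tile([f"l{i}" for i in range(a)], n),
            "y": Y.reshape(-1),
        }
    )
    r = rm_anova(df, dv="y", within=["A"], subject="subj", gg=False, bayes=False)[0]
    assert r.partial_eta2 == pytest.approx(
        r.F * r.df1 / (r.F * r.df1 + r.df2), abs=1e-9
    )
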