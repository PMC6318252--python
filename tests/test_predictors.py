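"""POPPeT prediction/fitting, phenomenological model, COREX aggregation."""

import math
import warnings

import numpy as np
import pytest

from poppet import (CoefficientSet, Microstate, PHENOM_ALL_ATOMS,
                    PHENOM_BACKBONE, ResidueFeatures, corex_pf, get_preset,
                    microstate_probabilities, phenomenological_logpf,
                    poppet_fit, poppet_predict, simulate_pf_dataset)
from poppet.kinetics import INFINITE_PROTECTION, R_KCAL
from poppet.predictors import MissingCovariateError


def feat(**kw):
    base = dict(chain="A", residue=10, motion="L")
    base.update(kw)
    return ResidueFeatures(**base)


class TestPoppetPredict:
    def test_reference_levels_give_intercept(self, preset):
        assert poppet_predict(feat(), preset) == pytest.approx(2.19940)

    def test_burial_contribution(self, preset):
        delta = poppet_predict(feat(burial=30), preset) - \
            poppet_predict(feat(), preset)
        assert delta == pytest.approx(30 * 0.04371)
        assert round(delta, 2) == 1.31

    def test_motion_and_ss_increments(self, preset):
        base = poppet_predict(feat(), preset)
        assert poppet_predict(feat(motion="UD"), preset) - base == \
            pytest.approx(1.63431)
        assert poppet_predict(feat(ss="helix"), preset) - base == \
            pytest.approx(0.59534)
        assert poppet_predict(feat(ss="beta-sheet"), preset) - base == \
            pytest.approx(0.35710)

    def test_dropped_hbond_terms_contribute_zero(self, preset):
        a = poppet_predict(feat(hbond="Hbond-with-mainchain-O",
                                hbond_count=1), preset)
        assert a == poppet_predict(feat(), preset)

    def test_unset_motion_is_an_error(self, preset):
        with pytest.raises(MissingCovariateError):
            poppet_predict(feat(motion=None), preset)

    def test_affinity(self, preset):
        # prediction difference equals the coefficient-weighted covariate
        # difference, exactly
        f1 = feat(motion="UD+EX1", ss="helix", burial=52)
        f2 = feat(motion="L", ss="no", burial=40)
        expected = (preset["motion[UD+EX1]"].estimate
                    + preset["ss[helix]"].estimate
                    + 12 * preset["burial"].estimate)
        got = poppet_predict(f1, preset) - poppet_predict(f2, preset)
        assert got == pytest.approx(expected, abs=1e-12)


class TestPoppetFit:
    def test_noise_free_recovery_is_exact(self, preset):
        table, feats = simulate_pf_dataset(preset, n=120, sigma=0.0, seed=4)
        fit = poppet_fit(list(zip(feats, table["logpf_measured"])))
        for term in ("intercept", "motion[UD]", "motion[EX1]",
                     "motion[UD+EX1]", "ss[helix]", "ss[beta-sheet]",
                     "burial"):
            assert fit[term].estimate == \
                pytest.approx(preset[term].estimate, abs=1e-8)
            assert fit[term].retained
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_null_hbond_factor_is_usually_eliminated_whole(self, preset):
        # hbond has no effect in data simulated from the preset (its betas
        # are dropped there).  Factor-wise elimination keeps a factor when
        # any level looks significant, which happens by chance in
        # ~1-0.95^3 = 14% of null replicates, so require elimination in a
        # clear majority and signal retention always.
        eliminated = 0
        for seed in range(30):
            table, feats = simulate_pf_dataset(preset, n=200, sigma=0.3,
                                               seed=seed)
            fit = poppet_fit(list(zip(feats, table["logpf_measured"])))
            assert all(fit[t].retained for t in
                       ("motion[UD]", "motion[EX1]", "motion[UD+EX1]",
                        "burial"))
            if not any(fit[t].retained for t in
                       ("hbond[H2O]", "hbond[mainchain-O]",
                        "hbond[sidechain-O]")):
                eliminated += 1
        assert eliminated >= 20

    def test_factor_wise_keeps_marginal_level_term_wise_drops_it(self, preset):
        # a null beta-sheet effect next to a strong helix effect: the SS
        # factor stays significant through its helix level, so factor-wise
        # elimination retains ss[beta-sheet] while term-wise removes it
        null_sheet = CoefficientSet(
            coefficients={t: (c if t != "ss[beta-sheet]"
                              else type(c)(0.0, None, 1.0, retained=False))
                          for t, c in preset.coefficients.items()},
            name="null-sheet")
        table, feats = simulate_pf_dataset(null_sheet, n=150, sigma=0.3,
                                           seed=0)
        pairs = list(zip(feats, table["logpf_measured"]))
        fw = poppet_fit(pairs, elimination="factor-wise")
        tw = poppet_fit(pairs, elimination="term-wise")
        assert fw["ss[helix]"].retained and tw["ss[helix]"].retained
        assert fw["ss[beta-sheet]"].retained
        assert not tw["ss[beta-sheet]"].retained

    def test_unbiasedness_over_replicates(self, preset):
        errors = []
        terms = ["motion[UD]", "motion[EX1]", "motion[UD+EX1]",
                 "ss[helix]", "ss[beta-sheet]", "burial", "intercept"]
        for seed in range(60):
            table, feats = simulate_pf_dataset(preset, n=200, sigma=0.5,
                                               seed=seed)
            fit = poppet_fit(list(zip(feats, table["logpf_measured"])),
                             elimination="factor-wise")
            errors.append([fit[t].estimate - preset[t].estimate
                           for t in terms])
        mean_err = np.abs(np.mean(errors, axis=0))
        assert (mean_err < 0.05).all()

    def test_rank_deficient_category_reported(self, preset):
        feats = [feat(motion=m, burial=b)
                 for m, b in zip(["L", "UD"] * 10, range(20))]
        y = [poppet_predict(f, preset) for f in feats]
        with pytest.warns(UserWarning, match="dropped constant"):
            fit = poppet_fit(list(zip(feats, y)))
        assert not fit["motion[EX1]"].retained

    def test_too_few_rows_rejected(self, preset):
        feats = [feat(motion=m) for m in ("L", "UD", "EX1")]
        y = [0.0, 1.0, 2.0]
        with pytest.raises(ValueError, match="training rows"):
            poppet_fit(list(zip(feats, y)))

    def test_json_round_trip(self, preset, tmp_path):
        path = tmp_path / "coeffs.json"
        preset.to_json(path)
        back = CoefficientSet.from_json(path)
        assert back.coefficients == preset.coefficients
        assert back.name == preset.name


class TestPhenomenological:
    def test_zero_counts_give_zero(self):
        assert phenomenological_logpf(0, 0) == 0.0
        assert phenomenological_logpf(0, 0, assume_log10=True) == 0.0

    def test_all_atoms_preset_arithmetic(self):
        # ln PF = 2.0*1 + 0.35*10 = 5.5 -> log10 PF = 5.5/ln 10
        got = phenomenological_logpf(1, 10, PHENOM_ALL_ATOMS)
        assert got == pytest.approx(5.5 / math.log(10))
        assert got == pytest.approx(2.389, abs=1e-3)

    def test_backbone_preset_arithmetic(self):
        # ln PF = 5.0*1 + 1.0*10 = 15.0
        got = phenomenological_logpf(1, 10, PHENOM_BACKBONE,
                                     assume_log10=True)
        assert got == pytest.approx(15.0)

    def test_linear_and_monotone(self):
        a = phenomenological_logpf(1, 10)
        assert phenomenological_logpf(2, 10) > a
        assert phenomenological_logpf(1, 11) > a
        assert phenomenological_logpf(2, 20) == \
            pytest.approx(2 * phenomenological_logpf(1, 10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            phenomenological_logpf(-1, 0)


def states(dgs, folded=None, exposed=None):
    n = len(dgs)
    folded = folded or [True] * n
    exposed = exposed or [False] * n
    return [Microstate(f"s{i}", dg, {1: f}, {1: e})
            for i, (dg, f, e) in enumerate(zip(dgs, folded, exposed))]


class TestCorex:
    def test_equal_energies_give_equal_probabilities(self):
        p = microstate_probabilities(states([3.0, 3.0]))
        assert np.allclose(p, [0.5, 0.5])

    def test_closed_form_boltzmann_ratios(self):
        t = 293.15
        rt = R_KCAL * t
        p = microstate_probabilities(
            states([0.0, rt * math.log(2), rt * math.log(4)]), t)
        assert np.allclose(p, [4 / 7, 2 / 7, 1 / 7])

    def test_probabilities_sum_to_one_large_ensemble(self, rng):
        dgs = rng.normal(0, 5, size=10_000)
        p = microstate_probabilities(states(list(dgs)))
        assert abs(p.sum() - 1.0) < 1e-12

    def test_shift_invariance(self, rng):
        dgs = list(rng.normal(0, 3, size=50))
        folded = list(rng.random(50) < 0.6)
        exposed = [not f for f in folded]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = corex_pf(states(dgs, folded, exposed), 1)
            b = corex_pf(states([d + 42.0 for d in dgs], folded, exposed), 1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_always_folded_gives_infinite_protection(self):
        with pytest.warns(UserWarning, match="infinite|Pr"):
            pf = corex_pf(states([0.0, 1.0]), 1)
        assert pf is INFINITE_PROTECTION

    def test_pr_i_shifts_both_sums(self):
        s = states([0.0, 0.0], folded=[True, False], exposed=[False, True])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert corex_pf(s, 1) == pytest.approx(1.0)
        assert corex_pf(s, 1, pr_i=0.25) == pytest.approx(1.0)

    def test_missing_flags_keyed_error(self):
        s = states([0.0, 1.0])
        with pytest.raises(KeyError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corex_pf(s, 2)
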