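"""Weighted least-squares flux estimation on toy networks."""

import numpy as np
import pytest

from cnmfa.correction import FragmentSpec
from cnmfa.emu import EMU, SubstrateLabeling, decompose, simulate_mids
from cnmfa.fitting import (FitProblem, FitResult, Measurement, MeasurementSet,
                           chi2_goodness, confidence_interval_95, fit,
                           objective)
from cnmfa.network import free_flux_basis, parse_model

HEADER = "rxn_id,equation,atom_transition,class,lb,ub\n"

# identifiable split: the two routes to B rearrange atoms differently
SPLIT_MODEL = HEADER + """u,S -> A,abc > abc,measured,0,10
b1,A -> B,abc > abc,dependent,0,10
b2,A -> B,abc > cba,free,0,10
out,B -> X,abc > abc,dependent,0,10
"""

LAB = [SubstrateLabeling("S", (1.0, 0.5, 0.0))]

# a three-carbon pseudo-fragment measured on metabolite X; the formula is a
# synthetic stand-in (backbone carbons only) so no derivatization envelope
# enters these toy fits
TOY_LIB = {
    ("Xaa", "M-57"): FragmentSpec("Xaa", "M-57", 36, 3, "C3",
                                  metabolite="X"),
    # the sub-fragment losing C1 is what makes a pure atom reversal
    # observable: the full-fragment MID is permutation invariant
    ("Xaa", "M-85"): FragmentSpec("Xaa", "M-85", 24, 2, "C2",
                                  metabolite="X"),
}


def _toy_measurement(model, split, sd=0.01, perturb=None):
    b = free_flux_basis(model, {"u": 1.0})
    v = b.realize([split])
    full, sub = EMU("X", (1, 2, 3)), EMU("X", (2, 3))
    net = decompose(model, [full, sub])
    mids = simulate_mids(net, v, LAB)
    sim57 = np.asarray(mids[full])
    if perturb is not None:
        sim57 = sim57 + perturb
    return MeasurementSet([
        Measurement("toy", "Xaa", "M-57", sim57, np.full(4, sd)),
        Measurement("toy", "Xaa", "M-85", np.asarray(mids[sub]),
                    np.full(3, sd)),
    ]), v


@pytest.fixture
def split_model():
    return parse_model(SPLIT_MODEL)


class TestObjective:
    def test_exact_measurements_give_zero(self, split_model):
        ms, _ = _toy_measurement(split_model, 0.3)
        ssr = objective(split_model, [0.3], ms, LAB, {"u": 1.0},
                        fragment_lib=TOY_LIB)
        assert ssr == pytest.approx(0.0, abs=1e-16)

    def test_one_sd_perturbation_adds_exactly_one(self, split_model):
        delta = np.array([0.01, 0.0, 0.0, 0.0])
        ms, _ = _toy_measurement(split_model, 0.3, sd=0.01, perturb=delta)
        ssr = objective(split_model, [0.3], ms, LAB, {"u": 1.0},
                        fragment_lib=TOY_LIB)
        assert ssr == pytest.approx(1.0, abs=1e-9)

    def test_two_term_residual_matches_hand_arithmetic(self, split_model):
        # X MID is the 0.7/0.3 mix of the forward and reversed labelling
        # patterns: fwd = (0,...) for enrichment (1, .5, 0):
        # fwd MID = conv([0,1],[.5,.5],[1,0]) ; rev = reversed atoms
        fwd = np.convolve(np.convolve([0, 1], [0.5, 0.5]), [1, 0])
        rev = np.convolve(np.convolve([1, 0], [0.5, 0.5]), [0, 1])
        expect = 0.7 * fwd + 0.3 * rev
        meas = expect.copy()
        meas[1] += 0.02   # 2 SD high on M1
        meas[2] -= 0.01   # 1 SD low on M2
        ms = MeasurementSet([Measurement("toy", "Xaa", "M-57", meas,
                                         np.full(4, 0.01))])
        ssr = objective(split_model, [0.3], ms, LAB, {"u": 1.0},
                        fragment_lib=TOY_LIB)
        assert ssr == pytest.approx(2.0 ** 2 + 1.0 ** 2, abs=1e-9)

    def test_empty_measurement_set_is_an_error(self, split_model):
        with pytest.raises(ValueError, match="empty"):
            FitProblem(split_model, MeasurementSet([]), LAB, {"u": 1.0},
                       fragment_lib=TOY_LIB)


class TestFit:
    def test_noise_free_recovery_of_split_ratio(self, split_model):
        ms, truth = _toy_measurement(split_model, 0.3)
        res = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=5, seed=11,
                  fragment_lib=TOY_LIB)
        assert abs(res.best_fluxes["b2"] - 0.3) < 1e-4
        assert res.ssr < 1e-6

    def test_seeded_determinism(self, split_model):
        ms, _ = _toy_measurement(split_model, 0.3)
        r1 = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=1, seed=5,
                 fragment_lib=TOY_LIB)
        r2 = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=1, seed=5,
                 fragment_lib=TOY_LIB)
        assert r1.ssr == r2.ssr
        assert np.array_equal(r1.best_free, r2.best_free)

    def test_objective_invariant_to_entry_order(self, split_model):
        ms, _ = _toy_measurement(split_model, 0.4)
        extra = Measurement("toy", "Xaa", "M-57",
                            np.array([0.2, 0.3, 0.3, 0.2]), np.full(4, 0.02))
        fwd = MeasurementSet(list(ms) + [extra])
        rev = MeasurementSet([extra] + list(ms))
        s1 = objective(split_model, [0.4], fwd, LAB, {"u": 1.0},
                       fragment_lib=TOY_LIB)
        s2 = objective(split_model, [0.4], rev, LAB, {"u": 1.0},
                       fragment_lib=TOY_LIB)
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestConfidenceIntervals:
    def test_fully_determined_model_degenerate_interval(self, toy_models):
        m = toy_models["chain"]
        net_lib = {("Xaa", "M-57"):
                   FragmentSpec("Xaa", "M-57", 24, 2, "C2")}
        b = free_flux_basis(m, {"v1": 1.0})
        v = b.realize([])
        net = decompose(m, [EMU("C", (1, 2))])
        lab = [SubstrateLabeling("A", (0.99, 0.2))]
        sim = np.asarray(simulate_mids(net, v, lab)[EMU("C", (1, 2))])
        ms = MeasurementSet([Measurement("toy", "Xaa", "M-57", sim,
                                         np.full(3, 0.01))])
        # map the pseudo-fragment onto metabolite C via a renamed library
        res = fit(m, MeasurementSet([Measurement("toy", "C".lower(), "M-57",
                                                 sim, np.full(3, 0.01))]),
                  lab, {"v1": 1.0},
                  fragment_lib={("c", "M-57"):
                                FragmentSpec("c", "M-57", 24, 2, "C2")})
        ci = confidence_interval_95(res, "v2")
        assert ci.lower == ci.upper == ci.estimate == pytest.approx(1.0)

    def test_uninformative_flux_flagged_unidentifiable(self):
        m = parse_model(HEADER +
                        "u,S -> A,abc > abc,measured,0,10\n"
                        "b1,A -> B,abc > abc,dependent,0,10\n"
                        "side,A -> D,abc > abc,free,0,10\n"
                        "out,B -> X,abc > abc,dependent,0,10",
                        {"sinks": ["D", "X"]})
        b = free_flux_basis(m, {"u": 1.0})
        v = b.realize([0.4])
        net = decompose(m, [EMU("X", (1, 2, 3))])
        sim = np.asarray(simulate_mids(net, v, LAB)[EMU("X", (1, 2, 3))])
        ms = MeasurementSet([Measurement("toy", "Xaa", "M-57", sim,
                                         np.full(4, 0.01))])
        res = fit(m, ms, LAB, {"u": 1.0}, n_starts=4, seed=3,
                  fragment_lib=TOY_LIB)
        ci = confidence_interval_95(res, "side")
        assert not ci.identifiable
        assert ci.lower == pytest.approx(0.0, abs=1e-6)
        # the upper end runs to the feasibility edge (b1 >= 0), i.e. ~u
        assert ci.upper > 0.9

    def test_profile_matches_analytic_se_for_linear_problem(self,
                                                            split_model):
        ms, _ = _toy_measurement(split_model, 0.3)
        res = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=4, seed=2,
                  fragment_lib=TOY_LIB)
        prob = res.problem
        # the X MID is exactly linear in the split fraction, so the profile
        # interval must match +/- 1.96 SE from the Jacobian
        eps = 1e-6
        j = (prob.residuals(res.best_free + eps)
             - prob.residuals(res.best_free - eps)) / (2 * eps)
        se = 1.0 / np.sqrt(float(j @ j))
        ci = confidence_interval_95(res, "b2")
        half = 0.5 * (ci.upper - ci.lower)
        assert half == pytest.approx(1.96 * se, rel=0.02)


class TestChi2:
    def test_zero_ssr_passes(self, split_model):
        ms, _ = _toy_measurement(split_model, 0.3)
        res = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=3, seed=1,
                  fragment_lib=TOY_LIB)
        ok, dof, p = chi2_goodness(res)
        n_points = sum(m.mid.size for m in ms)
        assert ok and dof == n_points - 1

    def test_inflated_ssr_fails(self, split_model):
        ms, _ = _toy_measurement(split_model, 0.3)
        res = fit(split_model, ms, LAB, {"u": 1.0}, n_starts=3, seed=1,
                  fragment_lib=TOY_LIB)
        inflated = FitResult(res.best_free, res.best_fluxes,
                             ssr=10.0 * res.dof,
                             restart_results=res.restart_results,
                             n_starts=res.n_starts, free_ids=res.free_ids,
                             dof=res.dof, problem=res.problem)
        ok, _, p = chi2_goodness(inflated)
        assert not ok and p < 0.01
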