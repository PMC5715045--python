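"""EMU decomposition and labelling simulation vs the brute-force oracle."""

import networkx as nx
import numpy as np
import pytest

from cnmfa.emu import (EMU, EMUError, SubstrateLabeling, brute_force_mids,
                       decompose, simulate_mids)
from cnmfa.fitting import fragment_emu
from cnmfa.models import condition_setup
from cnmfa.network import free_flux_basis, parse_model

HEADER = "rxn_id,equation,atom_transition,class,lb,ub\n"


def _flux(model, measured, free=()):
    b = free_flux_basis(model, measured)
    return b.realize(np.asarray(free, dtype=float), check_bounds=False)


class TestDecompose:
    def test_chain_network(self, toy_models):
        net = decompose(toy_models["chain"], [EMU("C", (1, 2))])
        assert EMU("A", (1, 2)) in net.inputs
        assert len(net.terms) == 2  # B{1,2}, C{1,2}

    def test_condensation_convolution_node(self, toy_models):
        net = decompose(toy_models["condensation"], [EMU("C", (1, 2, 3, 4))])
        terms = net.terms[EMU("C", (1, 2, 3, 4))]
        srcs = {tuple(sorted(str(s) for s in t[2])) for t in terms}
        assert ("A{1,2}", "B{1,2}") in srcs

    def test_atom_out_of_range(self, toy_models):
        with pytest.raises(EMUError, match="beyond"):
            decompose(toy_models["chain"], [EMU("C", (1, 2, 3))])

    def test_default_model_reaches_all_central_intermediates(
            self, default_model, fragment_lib):
        targets = [fragment_emu(fragment_lib, aa, kind)
                   for (aa, kind) in fragment_lib]
        net = decompose(default_model, targets)
        emu_mets = {e.metabolite for e in net.terms}
        # independent oracle: metabolite-level backward reachability
        g = nx.DiGraph()
        for r in default_model.reactions:
            for a in r.reactants:
                for b in r.products:
                    g.add_edge(a, b)
                    if r.reversible:
                        g.add_edge(b, a)
        reachable = set()
        for t in targets:
            reachable |= nx.ancestors(g, t.metabolite) | {t.metabolite}
        central = {"G6P", "6PG", "KDPG", "F6P", "F16P", "DHAP", "G3P", "3PG",
                   "PEP", "PYR", "ACCOA", "CIT", "ICIT", "AKG", "SUCOA",
                   "SUC", "FUM", "MAL", "OAA", "GLOX", "RU5P", "R5P", "X5P",
                   "S7P", "E4P", "RU15P"}
        assert central <= emu_mets
        assert emu_mets <= reachable


class TestSimulate:
    def test_label_passes_through_chain(self, toy_models):
        m = toy_models["chain"]
        v = _flux(m, {"v1": 1.0})
        net = decompose(m, [EMU("C", (1, 2))])
        out = simulate_mids(net, v, [SubstrateLabeling("A", (1.0, 0.0))])
        assert np.allclose(out[EMU("C", (1, 2))].fractions, [0, 1, 0])

    def test_unlabelled_substrate_gives_all_m0(self, toy_models):
        m = toy_models["branch"]
        b = free_flux_basis(m, {"u": 1.0})
        v = b.realize([0.3])
        net = decompose(m, [EMU("X", (1, 2, 3))])
        out = simulate_mids(net, v, [SubstrateLabeling("S", (0, 0, 0))])
        assert out[EMU("X", (1, 2, 3))].fractions[0] == pytest.approx(1.0,
                                                                      abs=0)

    def test_flux_scale_invariance(self, toy_models):
        m = toy_models["branch"]
        b = free_flux_basis(m, {"u": 1.0})
        net = decompose(m, [EMU("X", (1, 2, 3))])
        lab = [SubstrateLabeling("S", (0.99, 0.3, 0.1))]
        out1 = simulate_mids(net, b.realize([0.3]), lab)
        out2 = simulate_mids(net, b.realize([0.3]).scaled(7.5), lab)
        for k in out1:
            assert np.allclose(out1[k].fractions, out2[k].fractions,
                               atol=1e-12)

    def test_singular_balance_names_the_emu(self):
        m = parse_model(HEADER +
                        "u,S -> A,a > a,measured,0,10\n"
                        "r,B -> A,a > a,dependent,0,10\n"
                        "c,A + B -> C,a + b > ab,free,0,10\n"
                        "o,C -> X,ab > ab,dependent,0,10",
                        {"sinks": ["X"]})
        # B is produced only from itself through C; force a positive flux
        # through the condensation so B{1} truly lacks influx
        b = free_flux_basis(m, {"u": 1.0})
        v = b.realize(np.zeros(b.n_free), check_bounds=False)
        v.values.update({"c": 1.0, "o": 1.0, "r": 1.0, "u": 1.0})
        v.array_cache = None
        net = decompose(m, [EMU("X", (1, 2))])
        with pytest.raises(EMUError, match="B"):
            simulate_mids(net, v, [SubstrateLabeling("S", (0.5,))])


class TestOracleEquivalence:
    """simulate_mids must agree with full positional-isotopomer enumeration
    on toy networks spanning branching, condensation, decarboxylation with
    refixation, symmetric scrambling and a reversible pair."""

    def _compare(self, model, flux, labelings, targets, atol=1e-8):
        net = decompose(model, targets)
        fast = simulate_mids(net, flux, labelings)
        slow = brute_force_mids(model, flux, labelings, targets)
        for t in targets:
            assert np.allclose(fast[t].fractions, slow[t].fractions,
                               atol=atol), f"mismatch at {t}"

    def test_branching_with_rearrangement(self, toy_models):
        m = toy_models["branch"]
        b = free_flux_basis(m, {"u": 1.0})
        self._compare(m, b.realize([0.3]),
                      [SubstrateLabeling("S", (0.99, 0.5, 0.0))],
                      [EMU("X", (1, 2, 3)), EMU("X", (2, 3))])

    def test_condensation(self, toy_models):
        m = toy_models["condensation"]
        b = free_flux_basis(m, {"ua": 1.0, "ub": 1.0})
        self._compare(m, b.realize([]),
                      [SubstrateLabeling("Sa", (0.99, 0.2)),
                       SubstrateLabeling("Sb", (0.1, 0.7))],
                      [EMU("C", (1, 2, 3, 4)), EMU("C", (2, 4))])

    def test_decarboxylation_and_refixation(self, toy_models):
        m = toy_models["decarboxylation"]
        b = free_flux_basis(m, {"u": 1.0})
        self._compare(m, b.realize(np.zeros(b.n_free), check_bounds=False),
                      [SubstrateLabeling("S", (0.99, 0.99, 0.0107)),
                       SubstrateLabeling("CO2", (0.01,))],
                      [EMU("D", (1, 2, 3))])

    def test_symmetric_scrambling(self, toy_models):
        m = toy_models["symmetric"]
        b = free_flux_basis(m, {"u": 1.0})
        lab = [SubstrateLabeling("S", (0.99, 0.6, 0.2, 0.05))]
        targets = [EMU("X", (1, 2, 3, 4)), EMU("X", (1, 2))]
        self._compare(m, b.realize([]), lab, targets)
        # the pool MID must be invariant under atom reversal
        net = decompose(m, targets + [EMU("X", (3, 4))])
        out = simulate_mids(net, b.realize([]), lab)
        assert np.allclose(out[EMU("X", (1, 2))].fractions,
                           out[EMU("X", (3, 4))].fractions, atol=1e-12)

    def test_reversible_pair_with_exchange(self, toy_models):
        m = toy_models["reversible"]
        b = free_flux_basis(m, {"u": 1.0})
        v = b.realize([] if b.n_free == 0 else np.zeros(b.n_free))
        v.exchange["x"] = 0.7
        self._compare(m, v, [SubstrateLabeling("S", (0.99, 0.4, 0.0))],
                      [EMU("X", (1, 2, 3)), EMU("A", (1,))])

    def test_single_input_no_reactions_identity(self, toy_models):
        m = toy_models["chain"]
        v = _flux(m, {"v1": 1.0})
        lab = [SubstrateLabeling("A", (0.3, 0.8))]
        out = brute_force_mids(m, v, lab, [EMU("A", (1, 2))])
        expected = np.convolve([0.7, 0.3], [0.2, 0.8])
        assert np.allclose(out[EMU("A", (1, 2))].fractions, expected)


def test_brute_force_refuses_large_networks(default_model):
    measured, over = condition_setup(default_model, "hetero_fructose")
    b = free_flux_basis(default_model, measured, over)
    v, _ = b.realize_with_violations(np.full(b.n_free, 0.05))
    with pytest.raises(EMUError, match="too large"):
        brute_force_mids(default_model, v,
                         [SubstrateLabeling("FRUx", (0.99,) + (0.0107,) * 5),
                          SubstrateLabeling("GLYCx", (0.0107,) * 3)],
                         [EMU("ALA", (1, 2, 3))])
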