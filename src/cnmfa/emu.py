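"""Elementary-metabolite-unit (EMU) labelling simulator.

Predicts mass isotopomer distributions (MIDs) of target fragments from a
flux vector and the positional 13C enrichment of the substrates.  An EMU is
a subset of a metabolite's carbon atoms; tracing target EMUs backward
through the atom transitions yields, per EMU size, a linear balance system
A.X = B.Y whose unknowns are the MIDs of same-size EMUs and whose right
hand side collects substrate EMUs and convolutions of smaller EMUs
(condensation reactions).  Systems are solved in ascending size, so the
cascade is closed.

A brute-force positional-isotopomer solver (fixed-point iteration over the
full 2^n isotopomer distributions) is included as an independent oracle for
small networks.

Reversible reactions contribute both directions with forward flux
max(v,0)+exch and backward flux max(-v,0)+exch.  Reactions producing a
rotationally symmetric metabolite (succinate, fumarate) contribute both
atom orientations with weight 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mid import MIDVector, convolve
from .network import FluxVector, MetabolicModel

__all__ = [
    "EMU",
    "SubstrateLabeling",
    "EMUNetwork",
    "decompose",
    "simulate_mids",
    "convolve",
    "brute_force_mids",
    "EMUError",
]

DEFAULT_CO2_13C = 0.01  # fixed CO2-pool enrichment (1% natural 13C)


class EMUError(RuntimeError):
    pass


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite together with a sorted tuple of 1-based carbon indices."""

    metabolite: str
    atoms: tuple

    def __post_init__(self):
        atoms = tuple(sorted(int(a) for a in self.atoms))
        if not atoms or any(a < 1 for a in atoms) or len(set(atoms)) != len(atoms):
            raise ValueError(f"invalid EMU atoms {self.atoms!r}")
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "_hash", hash((self.metabolite, atoms)))

    def __hash__(self):
        return self._hash

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.metabolite}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class SubstrateLabeling:
    """Per-carbon 13C enrichment of an input metabolite (0..1 each)."""

    metabolite: str
    positional_enrichment: tuple

    def __post_init__(self):
        enr = tuple(float(x) for x in self.positional_enrichment)
        if any(not 0.0 <= x <= 1.0 for x in enr):
            raise ValueError(f"enrichment outside [0,1]: {enr}")
        object.__setattr__(self, "positional_enrichment", enr)

    def emu_mid(self, atoms) -> np.ndarray:
        """MID of the EMU with the given atoms under independent positions."""
        out = np.array([1.0])
        for a in atoms:
            p = self.positional_enrichment[a - 1]
            out = np.convolve(out, [1.0 - p, p])
        return out


# ---------------------------------------------------------------------------
# Directed reaction instances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Directed:
    index: int
    rxn_index: int
    forward: bool
    reactants: tuple
    r_atoms: tuple
    products: tuple
    p_atoms: tuple


def _directed_instances(model: MetabolicModel):
    out = []
    for ri, r in enumerate(model.reactions):
        t = r.transition
        out.append(_Directed(len(out), ri, True, r.reactants, t.reactant_atoms,
                             r.products, t.product_atoms))
        if r.reversible:
            out.append(_Directed(len(out), ri, False, r.products,
                                 t.product_atoms, r.reactants, t.reactant_atoms))
    return out


def _directed_fluxes(model: MetabolicModel, instances, flux: FluxVector):
    w = np.zeros(len(instances))
    for d in instances:
        r = model.reactions[d.rxn_index]
        v = flux.values[r.id]
        e = flux.exchange.get(r.id, 0.0)
        if r.reversible:
            w[d.index] = (max(v, 0.0) if d.forward else max(-v, 0.0)) + e
        else:
            # negative irreversible fluxes can transiently occur for penalized
            # candidate points during optimization; clamp for simulation
            w[d.index] = max(v, 0.0) if d.forward else 0.0
    return w


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

class EMUNetwork:
    """Size-stratified EMU balance systems reachable backward from targets."""

    def __init__(self, model, targets, instances, terms, inputs):
        self.model = model
        self.targets = list(targets)
        self.instances = instances
        self.terms = terms      # EMU -> [(inst_index, coeff, (src EMUs...))]
        self.inputs = inputs    # set of input EMUs
        self._compiled = None
        self._input_cache = {}
        # vectorized directed-flux computation
        self._inst_rxn = np.array([d.rxn_index for d in instances], dtype=int)
        self._inst_fwd = np.array([d.forward for d in instances], dtype=bool)
        self._rxn_rev = np.array([r.reversible for r in model.reactions],
                                 dtype=bool)

    def directed_fluxes(self, flux: FluxVector) -> np.ndarray:
        """Forward/backward flux weight per directed reaction instance."""
        v = flux.as_array(self.model)
        if flux.exchange:
            e = np.array([flux.exchange.get(r.id, 0.0)
                          for r in self.model.reactions])
        else:
            e = None
        vi = v[self._inst_rxn]
        rev = self._rxn_rev[self._inst_rxn]
        w = np.where(self._inst_fwd, np.maximum(vi, 0.0),
                     np.maximum(-vi, 0.0))
        # irreversible backward instances never exist; irreversible forward
        # weights are already clamped at zero by the maximum above
        if e is not None:
            w = w + np.where(rev, e[self._inst_rxn], 0.0)
        return w

    @property
    def emus(self):
        return set(self.terms) | set(self.inputs)

    def sizes(self):
        return sorted({e.size for e in self.terms})

    # -- compilation to flat index arrays for fast repeated simulation -----
    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        levels = []
        emu_level = {}   # EMU -> (size, row)  for solved (unknown) EMUs
        for s in self.sizes():
            unknowns = sorted(e for e in self.terms if e.size == s)
            uidx = {e: i for i, e in enumerate(unknowns)}
            for e, i in uidx.items():
                emu_level[e] = (s, i)
            knowns = []
            kidx = {}
            diag = [[], [], []]     # row, inst, coeff
            off = [[], [], [], []]  # row, col, inst, coeff
            rhs = [[], [], [], []]  # row, kpos, inst, coeff
            for e in unknowns:
                row = uidx[e]
                for inst, coeff, sources in self.terms[e]:
                    diag[0].append(row)
                    diag[1].append(inst)
                    diag[2].append(coeff)
                    if len(sources) == 1 and sources[0] in uidx:
                        off[0].append(row)
                        off[1].append(uidx[sources[0]])
                        off[2].append(inst)
                        off[3].append(coeff)
                    else:
                        key = tuple(sorted(sources))
                        if key not in kidx:
                            kidx[key] = len(knowns)
                            knowns.append(key)
                        rhs[0].append(row)
                        rhs[1].append(kidx[key])
                        rhs[2].append(inst)
                        rhs[3].append(coeff)
            levels.append({
                "size": s,
                "unknowns": unknowns,
                "knowns": knowns,
                "diag": tuple(np.asarray(a) for a in diag),
                "off": tuple(np.asarray(a) for a in off),
                "rhs": tuple(np.asarray(a) for a in rhs),
            })
        self._compiled = (levels, emu_level)
        return self._compiled


def decompose(model: MetabolicModel, targets) -> EMUNetwork:
    """Minimal EMU network reachable backward from the target EMUs."""
    instances = _directed_instances(model)
    # producer map: met -> [(instance, product slot)]
    producers = {}
    for d in instances:
        for slot, met in enumerate(d.products):
            producers.setdefault(met, []).append((d, slot))

    for t in targets:
        if t.metabolite not in model.carbons:
            raise EMUError(f"target metabolite {t.metabolite} not in model")
        if t.atoms[-1] > model.carbons[t.metabolite]:
            raise EMUError(
                f"target {t}: atom index beyond the {model.carbons[t.metabolite]}"
                f" carbons of {t.metabolite}")

    co2_input = model.co2 is not None and not model.balance_co2
    inputs, terms = set(), {}
    stack = list(dict.fromkeys(targets))
    seen = set(stack)
    while stack:
        emu = stack.pop()
        met = emu.metabolite
        if met in model.substrates or (co2_input and met == model.co2):
            inputs.add(emu)
            continue
        plist = producers.get(met, [])
        if not plist:
            raise EMUError(f"EMU {emu} has no producing reaction")
        tlist = []
        for d, slot in plist:
            patoms = d.p_atoms[slot]
            orientations = [(patoms, 1.0)]
            if met in model.symmetric:
                orientations = [(patoms, 0.5), (patoms[::-1], 0.5)]
            for pa, coeff in orientations:
                by_reactant = {}
                for a in emu.atoms:
                    letter = pa[a - 1]
                    for ri, ratoms in enumerate(d.r_atoms):
                        pos = ratoms.find(letter)
                        if pos >= 0:
                            by_reactant.setdefault(ri, []).append(pos + 1)
                            break
                sources = tuple(EMU(d.reactants[ri], tuple(atoms))
                                for ri, atoms in sorted(by_reactant.items()))
                tlist.append((d.index, coeff, sources))
                for s in sources:
                    if s not in seen:
                        seen.add(s)
                        stack.append(s)
        terms[emu] = tlist
    return EMUNetwork(model, targets, instances, terms, inputs)


def _input_mid(emu: EMU, labeling_map, co2_name, co2_enrichment):
    met = emu.metabolite
    if met in labeling_map:
        return labeling_map[met].emu_mid(emu.atoms)
    if met == co2_name:
        p = co2_enrichment
        out = np.array([1.0])
        for _ in emu.atoms:
            out = np.convolve(out, [1.0 - p, p])
        return out
    raise EMUError(f"no labelling given for input metabolite {met}")


def simulate_mids(net: EMUNetwork, fluxes: FluxVector, labelings,
                  co2_enrichment: float = DEFAULT_CO2_13C,
                  as_arrays: bool = False) -> dict:
    """Solve the EMU cascade; returns {target EMU: MIDVector}.

    ``labelings`` is a list of SubstrateLabeling covering every substrate
    input; the CO2 pool defaults to 1% 13C unless a labelling for it is
    supplied or ``co2_enrichment`` is overridden.  ``as_arrays=True``
    returns plain ndarrays (fast path for repeated calls during fitting).
    """
    model = net.model
    labeling_map = {l.metabolite: l for l in labelings}
    w = net.directed_fluxes(fluxes)
    levels, emu_level = net._compile()

    # input-EMU MIDs are flux-independent: cache per labelling signature
    lab_key = (co2_enrichment,
               tuple(sorted((l.metabolite, l.positional_enrichment)
                            for l in labelings)))
    inputs_mid = net._input_cache.get(lab_key)
    if inputs_mid is None:
        inputs_mid = {e: _input_mid(e, labeling_map, model.co2,
                                    co2_enrichment) for e in net.inputs}
        net._input_cache[lab_key] = inputs_mid

    solved = {}   # size -> (unknown list, X matrix)
    mid_of = dict(inputs_mid)   # EMU -> ndarray (inputs and solved)
    dead = set()  # EMUs with zero influx (inactive branches); placeholder MID

    def known_mid(key):
        # key: tuple of source EMUs (inputs, lower-size solved, or both)
        out = None
        for e in key:
            y = mid_of.get(e)
            if y is None:
                y = _input_mid(e, labeling_map, model.co2, co2_enrichment)
                mid_of[e] = y
            out = y if out is None else np.convolve(out, y)
        return out

    for lev in levels:
        s = lev["size"]
        unknowns = lev["unknowns"]
        n = len(unknowns)
        A = np.zeros((n, n))
        dr, di, dc = lev["diag"]
        if dr.size:
            np.add.at(A, (dr, dr), w[di] * dc)
        orow, ocol, oi, oc = lev["off"]
        if orow.size:
            np.add.at(A, (orow, ocol), -(w[oi] * oc))
        B = np.zeros((n, s + 1))
        rrow, rk, rinst, rc = lev["rhs"]
        if rrow.size:
            rw = w[rinst] * rc
            # a known source containing a dead EMU may only be used with
            # zero flux weight; otherwise the balance is genuinely singular
            for kpos, key in enumerate(lev["knowns"]):
                if dead.intersection(key):
                    used = rw[rk == kpos]
                    if np.any(used > 1e-12):
                        culprit = next(iter(dead.intersection(key)))
                        raise EMUError(
                            f"singular EMU balance: no influx to {culprit}")
            Y = np.vstack([known_mid(k) for k in lev["knowns"]])
            contrib = rw[:, None] * Y[rk]
            np.add.at(B, rrow, contrib)
        influx = np.abs(np.diag(A))
        zero_rows = np.where(influx <= 1e-12)[0]
        if zero_rows.size:
            # EMUs of inactive pathway branches (all producing fluxes zero):
            # substitute a placeholder unlabelled MID; if such an EMU feeds
            # any same-size balance with positive weight, that is a genuine
            # singularity and is reported
            orow2, ocol2, oi2, oc2 = lev["off"]
            if orow2.size:
                live = (w[oi2] * oc2) > 1e-12
                hit = np.isin(ocol2, zero_rows) & live
                if np.any(hit):
                    bad = unknowns[int(ocol2[np.argmax(hit)])]
                    raise EMUError(f"singular EMU balance: no influx to {bad}")
            for i in zero_rows:
                A[i, :] = 0.0
                A[i, i] = 1.0
                B[i, :] = 0.0
                B[i, 0] = 1.0
                dead.add(unknowns[i])
        X = np.linalg.solve(A, B)
        X = np.clip(X, 0.0, None)
        X /= X.sum(axis=1, keepdims=True)
        for e, row in zip(unknowns, X):
            mid_of[e] = row
        solved[s] = (unknowns, X)

    if as_arrays:
        return {t: mid_of[t] for t in net.targets}
    return {t: MIDVector(mid_of[t], renormalize=True) for t in net.targets}


# ---------------------------------------------------------------------------
# Brute-force positional-isotopomer oracle
# ---------------------------------------------------------------------------

def brute_force_mids(model: MetabolicModel, fluxes: FluxVector, labelings,
                     targets, co2_enrichment: float = DEFAULT_CO2_13C,
                     max_total_carbons: int = 32, tol: float = 1e-13,
                     max_iter: int = 50000) -> dict:
    """Solve the full positional-isotopomer balance by fixed-point iteration.

    Exponential in carbon count; refuses networks whose balanced metabolites
    carry more than ``max_total_carbons`` carbons in total.  Serves as an
    independent oracle for simulate_mids on small networks.
    """
    labeling_map = {l.metabolite: l for l in labelings}
    co2_input = model.co2 is not None and not model.balance_co2
    inputs = set(model.substrates) | ({model.co2} if co2_input else set())

    solved_mets = [m for m in model.carbons if m not in inputs]
    total_carbons = sum(model.carbons[m] for m in solved_mets)
    if total_carbons > max_total_carbons:
        raise EMUError(
            f"network too large for brute force ({total_carbons} carbons "
            f"across {len(solved_mets)} balanced metabolites)")

    def input_dist(met):
        n = model.carbons[met]
        if met in labeling_map:
            enr = labeling_map[met].positional_enrichment
        elif met == model.co2:
            enr = [co2_enrichment] * n
        else:
            raise EMUError(f"no labelling for input metabolite {met}")
        d = np.array([1.0])
        for p in enr:  # bit k of the state corresponds to carbon k+1
            d = (np.outer(d, [1.0 - p, p])).ravel(order="F")
        # 'F' ravel puts the new atom in the high bit: state = sum_k b_k 2^k
        return d

    instances = _directed_instances(model)
    w = _directed_fluxes(model, instances, fluxes)

    # production term index maps
    term_specs = []  # (product met, weight, [reactant mets], product index map)
    for d in instances:
        if w[d.index] <= 0.0:
            continue
        rmets = list(d.reactants)
        rcarb = [model.carbons[m] for m in rmets]
        for slot, met in enumerate(d.products):
            if met in inputs:
                continue
            orientations = [(d.p_atoms[slot], 1.0)]
            if met in model.symmetric:
                orientations = [(d.p_atoms[slot], 0.5),
                                (d.p_atoms[slot][::-1], 0.5)]
            for pa, coeff in orientations:
                # joint reactant state index: bits of reactant 0 lowest
                offsets = np.cumsum([0] + rcarb[:-1])
                njoint = 1 << sum(rcarb)
                states = np.arange(njoint)
                pstate = np.zeros(njoint, dtype=np.int64)
                for a_pos, letter in enumerate(pa):
                    for ri, ratoms in enumerate(d.r_atoms):
                        pos = ratoms.find(letter)
                        if pos >= 0:
                            bit = offsets[ri] + pos
                            pstate |= ((states >> bit) & 1) << a_pos
                            break
                term_specs.append((met, w[d.index] * coeff, rmets, pstate,
                                   rcarb))

    dist = {m: input_dist(m) for m in inputs if model.carbons[m] > 0}
    for m in solved_mets:
        d0 = np.zeros(1 << model.carbons[m])
        d0[0] = 1.0
        dist[m] = d0

    influx = {m: 0.0 for m in solved_mets}
    for met, weight, *_ in term_specs:
        influx[met] += weight
    # zero-influx metabolites belong to inactive branches; they keep the
    # unlabelled placeholder distribution (mirrors simulate_mids pruning)
    live_mets = [m for m in solved_mets if influx[m] > 0]

    for _ in range(max_iter):
        acc = {m: np.zeros_like(dist[m]) for m in live_mets}
        for met, weight, rmets, pstate, rcarb in term_specs:
            joint = _joint(dist, rmets)
            acc[met] += weight * np.bincount(pstate, weights=joint,
                                             minlength=acc[met].size)
        delta = 0.0
        for m in live_mets:
            new = acc[m] / influx[m]
            delta = max(delta, float(np.max(np.abs(new - dist[m]))))
            dist[m] = new
        if delta < tol:
            break
    else:
        raise EMUError("brute-force iteration did not converge")

    out = {}
    for t in targets:
        d = dist[t.metabolite] if t.metabolite in dist \
            else input_dist(t.metabolite)
        n = model.carbons[t.metabolite]
        states = np.arange(1 << n)
        mask = 0
        for a in t.atoms:
            mask |= 1 << (a - 1)
        counts = np.array([bin(s & mask).count("1") for s in states])
        mid = np.bincount(counts, weights=d, minlength=t.size + 1)
        out[t] = MIDVector(mid, renormalize=True)
    return out


def _joint(dist, rmets):
    """Joint distribution over reactant states, reactant 0 in the low bits."""
    joint = np.array([1.0])
    for rm in rmets:
        joint = (joint[:, None] * dist[rm][None, :]).ravel(order="F")
    return joint
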