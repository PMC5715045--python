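"""Carbon-atom-mapped metabolic network model.

A model is an ordered list of reactions, each carrying stoichiometry and a
carbon atom transition written with one lowercase letter per carbon.  The
letters on the reactant side must be distinct and every one of them must
reappear exactly once on the product side; carbon leaving the network as
CO2 is written explicitly against the CO2 pool metabolite, so carbon is
conserved reaction by reaction.

Flux classes partition the flux space: ``measured`` fluxes (substrate
uptake) are supplied at analysis time and fix the scale, ``constrained``
fluxes are pinned in the model file (biomass precursor demands), and the
remaining unknowns split into independent *free* fluxes and *dependent*
fluxes determined by the steady-state balance S.v = 0 of the balanced
(intracellular) metabolites.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtomTransition",
    "Reaction",
    "MetabolicModel",
    "FluxVector",
    "FluxBasis",
    "ValidationReport",
    "ModelError",
    "InfeasibleFluxError",
    "parse_model",
    "serialize_model",
    "load_model",
    "validate_model",
    "free_flux_basis",
    "realize_fluxes",
]

FLUX_CLASSES = ("free", "dependent", "constrained", "measured")
_STEADY_TOL = 1e-9


class ModelError(ValueError):
    """Raised for malformed or inconsistent model definitions."""


class InfeasibleFluxError(RuntimeError):
    """A realized flux vector violates bounds of dependent fluxes."""

    def __init__(self, message, violations=None, total=0.0):
        super().__init__(message)
        self.violations = violations or []
        self.total_violation = float(total)


@dataclass(frozen=True)
class AtomTransition:
    """Per-substrate/per-product carbon letter strings, positional order."""

    reactant_atoms: tuple
    product_atoms: tuple

    def reversed(self) -> "AtomTransition":
        return AtomTransition(self.product_atoms, self.reactant_atoms)


@dataclass
class Reaction:
    id: str
    reactants: tuple
    products: tuple
    transition: AtomTransition
    reversible: bool = False
    flux_class: str = "dependent"
    lb: float = 0.0
    ub: float = 10.0

    def __post_init__(self):
        if self.flux_class not in FLUX_CLASSES:
            raise ModelError(
                f"reaction {self.id}: unknown flux class {self.flux_class!r}")
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.reversible and self.lb < 0:
            raise ModelError(
                f"reaction {self.id}: irreversible but lower bound {self.lb} < 0")
        self._check_atoms()

    # -- carbon accounting -------------------------------------------------
    def _check_atoms(self):
        t = self.transition
        if len(t.reactant_atoms) != len(self.reactants):
            raise ModelError(
                f"reaction {self.id}: {len(self.reactants)} reactants but "
                f"{len(t.reactant_atoms)} atom strings")
        if len(t.product_atoms) != len(self.products):
            raise ModelError(
                f"reaction {self.id}: {len(self.products)} products but "
                f"{len(t.product_atoms)} atom strings")
        seen = {}
        for met, atoms in zip(self.reactants, t.reactant_atoms):
            if not atoms or not atoms.islower():
                raise ModelError(
                    f"reaction {self.id}: bad atom string {atoms!r} for {met}")
            for ch in atoms:
                if ch in seen:
                    raise ModelError(
                        f"reaction {self.id}: carbon letter {ch!r} reused "
                        f"across substrates")
                seen[ch] = met
        used = {}
        for met, atoms in zip(self.products, t.product_atoms):
            for ch in atoms:
                if ch not in seen:
                    raise ModelError(
                        f"reaction {self.id}: product carbon {ch!r} does not "
                        f"occur in any reactant")
                if ch in used:
                    raise ModelError(
                        f"reaction {self.id}: product carbon {ch!r} used twice")
                used[ch] = met
        missing = sorted(set(seen) - set(used))
        if missing:
            raise ModelError(
                f"reaction {self.id}: unaccounted carbon "
                f"{', '.join(missing)} (map released carbon to the CO2 pool)")

    @property
    def stoichiometry(self) -> dict:
        """Metabolite -> signed coefficient (reactants negative)."""
        s = {}
        for met in self.reactants:
            s[met] = s.get(met, 0) - 1
        for met in self.products:
            s[met] = s.get(met, 0) + 1
        return s


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    def add(self, code: str, message: str):
        self.findings.append((code, message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def __len__(self):
        return len(self.findings)

    def __str__(self):  # pragma: no cover - cosmetic
        if self.ok:
            return "model admissible: no findings"
        return "\n".join(f"[{c}] {m}" for c, m in self.findings)


class MetabolicModel:
    """Ordered reactions plus metabolite roles and substrate labellings.

    Roles: *substrates* are external inputs (fixed labelling), *sinks* drain
    carbon out (biomass precursors, amino acids, PHB), the *co2* pool is by
    default an unbalanced input/output pool with fixed 13C enrichment, and
    every other metabolite is *balanced* (steady state, S.v = 0).
    """

    def __init__(self, reactions, substrates=None, sinks=None, co2="CO2",
                 symmetric=(), substrate_labelings=None, conditions=None,
                 balance_co2=False):
        self.reactions = list(reactions)
        ids = [r.id for r in self.reactions]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ModelError(f"duplicate reaction id(s): {sorted(dup)}")
        self._index = {r.id: i for i, r in enumerate(self.reactions)}
        self.carbons = self._infer_carbons()
        produced, consumed = self._producers_consumers()
        mets = set(self.carbons)
        self.co2 = co2 if co2 in mets else None
        if substrates is None:
            substrates = {m for m in mets
                          if m not in produced and m != self.co2}
        if sinks is None:
            sinks = {m for m in mets
                     if m not in consumed and m != self.co2}
        self.substrates = set(substrates)
        self.sinks = set(sinks)
        self.symmetric = set(symmetric)
        self.balance_co2 = bool(balance_co2)
        self.substrate_labelings = dict(substrate_labelings or {})
        self.conditions = dict(conditions or {})

    # -- construction helpers ---------------------------------------------
    def _infer_carbons(self):
        carbons = {}
        for r in self.reactions:
            for met, atoms in (list(zip(r.reactants, r.transition.reactant_atoms))
                               + list(zip(r.products, r.transition.product_atoms))):
                n = len(atoms)
                if met in carbons and carbons[met] != n:
                    raise ModelError(
                        f"metabolite {met}: inconsistent carbon count "
                        f"({carbons[met]} vs {n} in reaction {r.id})")
                carbons[met] = n
        return carbons

    def _producers_consumers(self):
        produced, consumed = set(), set()
        for r in self.reactions:
            produced.update(r.products)
            consumed.update(r.reactants)
            if r.reversible:
                produced.update(r.reactants)
                consumed.update(r.products)
        return produced, consumed

    # -- public API --------------------------------------------------------
    def __len__(self):
        return len(self.reactions)

    def __getitem__(self, rxn_id: str) -> Reaction:
        return self.reactions[self._index[rxn_id]]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self._index

    def index(self, rxn_id: str) -> int:
        return self._index[rxn_id]

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    @property
    def balanced(self):
        unbalanced = self.substrates | self.sinks
        if self.co2 is not None and not self.balance_co2:
            unbalanced.add(self.co2)
        return sorted(m for m in self.carbons if m not in unbalanced)

    def stoichiometric_matrix(self):
        """(S, metabolite order) restricted to balanced metabolites."""
        cached = getattr(self, "_S_cache", None)
        if cached is not None:
            return cached
        mets = self.balanced
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                if met in midx:
                    S[midx[met], j] += coeff
        self._S_cache = (S, mets)
        return self._S_cache

    def steady_state_residual(self, flux: "FluxVector") -> float:
        S, _ = self.stoichiometric_matrix()
        v = flux.as_array(self)
        scale = max(1.0, float(np.max(np.abs(v))) if v.size else 1.0)
        return float(np.max(np.abs(S @ v))) / scale if v.size else 0.0


@dataclass
class FluxVector:
    """Net fluxes per reaction (mmol/g DW/h) plus optional exchange fluxes
    for reversible reactions (forward = max(v,0)+exch, back = max(-v,0)+exch)."""

    values: dict
    exchange: dict = field(default_factory=dict)
    array_cache: np.ndarray | None = field(default=None, repr=False,
                                           compare=False)

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]

    def as_array(self, model: MetabolicModel) -> np.ndarray:
        if self.array_cache is not None:
            return self.array_cache
        return np.array([self.values[r.id] for r in model.reactions])

    def scaled(self, c: float) -> "FluxVector":
        return FluxVector({k: c * v for k, v in self.values.items()},
                          {k: c * v for k, v in self.exchange.items()})


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _parse_side(text: str):
    terms = [t.strip() for t in text.split("+")]
    if any(not t for t in terms):
        raise ModelError(f"empty term in equation side {text!r}")
    return tuple(terms)


def _parse_equation(eq: str):
    for arrow, rev in (("<->", True), ("<=>", True), ("->", False), (">", False)):
        if arrow in eq:
            lhs, rhs = eq.split(arrow, 1)
            return _parse_side(lhs), _parse_side(rhs), rev
    raise ModelError(f"equation {eq!r} has no arrow")


def _parse_transition(text: str):
    if ">" not in text:
        raise ModelError(f"atom transition {text!r} has no '>'")
    lhs, rhs = text.split(">", 1)
    return (tuple(a.strip() for a in lhs.split("+")),
            tuple(a.strip() for a in rhs.split("+")))


def parse_model(model_text: str, config: dict | None = None) -> MetabolicModel:
    """Parse a model table (CSV/TSV text) into a validated MetabolicModel.

    Expected columns: ``rxn_id, equation, atom_transition, class, lb, ub``.
    Lines starting with '#' are comments.  ``config`` optionally carries
    metabolite roles, symmetric metabolites, substrate labellings and named
    analysis conditions (see the packaged YAML for the schema).
    """
    sep = "\t" if "\t" in model_text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(model_text), comment="#", sep=sep,
                     skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["rxn_id", "equation", "atom_transition", "class", "lb", "ub"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelError(f"model table missing column(s): {missing}")
    df = df.rename(columns={"class": "flux_class"})

    reactions = []
    for row in df.itertuples(index=False):
        reactants, products, rev = _parse_equation(str(row.equation))
        r_atoms, p_atoms = _parse_transition(str(row.atom_transition))
        rxn = Reaction(
            id=str(row.rxn_id).strip(),
            reactants=reactants,
            products=products,
            transition=AtomTransition(r_atoms, p_atoms),
            reversible=rev,
            flux_class=str(row.flux_class).strip(),
            lb=float(row.lb),
            ub=float(row.ub),
        )
        reactions.append(rxn)

    cfg = dict(config or {})
    labelings = {m: np.asarray(v, dtype=float)
                 for m, v in (cfg.get("labelings") or {}).items()}
    return MetabolicModel(
        reactions,
        substrates=cfg.get("substrates"),
        sinks=cfg.get("sinks"),
        co2=cfg.get("co2", "CO2"),
        symmetric=cfg.get("symmetric", ()),
        substrate_labelings=labelings,
        conditions=cfg.get("conditions"),
        balance_co2=cfg.get("balance_co2", False),
    )


def serialize_model(model: MetabolicModel) -> str:
    """Inverse of parse_model for the reaction table (round-trip safe)."""
    lines = ["rxn_id,equation,atom_transition,class,lb,ub"]
    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        eq = f"{' + '.join(r.reactants)} {arrow} {' + '.join(r.products)}"
        tr = (f"{' + '.join(r.transition.reactant_atoms)} > "
              f"{' + '.join(r.transition.product_atoms)}")
        lines.append(f"{r.id},{eq},{tr},{r.flux_class},{r.lb:g},{r.ub:g}")
    return "\n".join(lines) + "\n"


def load_model(csv_path, yaml_path=None) -> MetabolicModel:
    """Load a model from a reaction CSV plus an optional YAML role/labelling
    companion file."""
    with open(csv_path, encoding="utf-8") as fh:
        text = fh.read()
    config = None
    if yaml_path is not None:
        with open(yaml_path, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    return parse_model(text, config)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> ValidationReport:
    """Network-level admissibility checks.

    Per-reaction carbon conservation is already enforced at construction;
    this reports structural findings: empty model, balanced metabolites
    that are never produced or never consumed (orphans / dead ends), and
    substrates that are also produced.
    """
    report = ValidationReport()
    if not model.reactions:
        report.add("empty", "no reactions")
        return report
    produced, consumed = model._producers_consumers()
    for met in model.balanced:
        if met not in produced:
            report.add("orphan", f"balanced metabolite {met} is never produced")
        if met not in consumed:
            report.add("dead-end",
                       f"balanced metabolite {met} is never consumed and is "
                       f"not declared a sink")
    for met in sorted(model.substrates):
        if met in produced:
            report.add("substrate-produced",
                       f"substrate {met} is produced by the network")
    for met in sorted(model.sinks):
        if met in {m for r in model.reactions for m in r.reactants}:
            report.add("sink-consumed", f"sink {met} is consumed")
    return report


# ---------------------------------------------------------------------------
# Flux-space parameterization
# ---------------------------------------------------------------------------

class FluxBasis:
    """Free-flux parameterization of the steady-state flux space.

    Fixed fluxes (measured + constrained) are substituted into S.v = 0; the
    remaining unknown fluxes are split into pivot (dependent) and non-pivot
    (free) columns by Gaussian elimination, preferring reactions marked
    ``free`` in the model file as the free coordinates.  Any assignment of
    the free fluxes then determines the dependent fluxes linearly:
    v_dep = T.v_free + c.
    """

    def __init__(self, model: MetabolicModel, measured: dict | None = None,
                 overrides: dict | None = None, tol: float = 1e-9):
        self.model = model
        measured = dict(measured or {})
        overrides = dict(overrides or {})
        bad = [k for k in overrides
               if k not in model or model[k].flux_class != "constrained"]
        if bad:
            raise ModelError(
                f"overrides for non-constrained reactions: {sorted(bad)}")
        fixed = {}
        for r in model.reactions:
            if r.flux_class == "constrained":
                if r.id in overrides:
                    fixed[r.id] = float(overrides[r.id])
                    continue
                if r.lb != r.ub:
                    raise ModelError(
                        f"constrained reaction {r.id} needs lb == ub "
                        f"(its fixed value)")
                fixed[r.id] = r.lb
            elif r.flux_class == "measured":
                if r.id not in measured:
                    raise ModelError(
                        f"measured reaction {r.id} has no supplied value")
                fixed[r.id] = float(measured[r.id])
        extra = set(measured) - set(fixed)
        if extra:
            raise ModelError(f"measured values for non-measured reactions: "
                             f"{sorted(extra)}")
        if not fixed:
            raise ModelError("no measured/constrained flux fixes the scale")
        self.fixed = fixed

        S, _ = model.stoichiometric_matrix()
        ids = model.reaction_ids
        unknown = [i for i, r in enumerate(model.reactions)
                   if r.id not in fixed]
        fixed_idx = [i for i, r in enumerate(model.reactions) if r.id in fixed]
        v_fix = np.array([fixed[ids[i]] for i in fixed_idx])
        b0 = -S[:, fixed_idx] @ v_fix if fixed_idx else np.zeros(S.shape[0])

        # column order: 'dependent'-marked first so 'free'-marked reactions
        # preferentially end up as the non-pivot (free) coordinates
        order = sorted(unknown,
                       key=lambda i: model.reactions[i].flux_class == "free")
        Su = S[:, order]
        pivots, nonpivots = _eliminate(Su, tol)
        self.dep_idx = [order[j] for j in pivots]
        self.free_idx = [order[j] for j in nonpivots]
        self.free_ids = [ids[i] for i in self.free_idx]
        self.dep_ids = [ids[i] for i in self.dep_idx]

        S_dep = S[:, self.dep_idx]
        S_free = S[:, self.free_idx]
        P = np.linalg.pinv(S_dep) if self.dep_idx else np.zeros((0, S.shape[0]))
        self.T = -P @ S_free
        self.c = P @ b0
        # consistency of the fixed part: b0 - S_free.v_free must lie in the
        # column space of S_dep for some v_free; check at v_free = 0
        resid = S_dep @ self.c - b0
        # rows not spanned may still be killed by free fluxes; verify with a
        # least-squares solve over all unknown columns
        full = np.linalg.lstsq(S[:, unknown], b0, rcond=None)
        if unknown and full[0].size:
            misfit = np.max(np.abs(S[:, unknown] @ full[0] - b0))
        else:
            misfit = np.max(np.abs(b0)) if b0.size else 0.0
        if misfit > 1e-6 * max(1.0, float(np.max(np.abs(v_fix))) if v_fix.size else 1.0):
            raise ModelError(
                f"fixed fluxes are infeasible: steady state unsatisfiable "
                f"(misfit {misfit:.3g})")
        del resid
        self.free_lb = np.array([model.reactions[i].lb for i in self.free_idx])
        self.free_ub = np.array([model.reactions[i].ub for i in self.free_idx])

    @property
    def n_free(self) -> int:
        return len(self.free_idx)

    def realize(self, free_values, check_bounds: bool = True) -> FluxVector:
        """Assemble the full flux vector for the given free-flux values."""
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free values, got {free_values.shape}")
        vec, violations, total = self._assemble(free_values)
        if check_bounds and violations:
            raise InfeasibleFluxError(
                "dependent flux bound violation: "
                + "; ".join(f"{i} = {v:.4g} not in [{lo:g}, {hi:g}]"
                            for i, v, lo, hi in violations),
                violations=violations, total=total)
        return vec

    def realize_with_violations(self, free_values):
        """Like realize, but returns (FluxVector, total bound violation)
        instead of raising; used as an optimization penalty."""
        free_values = np.asarray(free_values, dtype=float)
        vec, _, total = self._assemble(free_values)
        return vec, total

    def _assemble(self, free_values):
        ids = self.model.reaction_ids
        v = np.zeros(len(ids))
        for i, rid in enumerate(ids):
            if rid in self.fixed:
                v[i] = self.fixed[rid]
        v[self.free_idx] = free_values
        dep = self.T @ free_values + self.c
        v[self.dep_idx] = dep
        violations, total = [], 0.0
        for i, val in zip(self.dep_idx, dep):
            r = self.model.reactions[i]
            if val < r.lb - 1e-9 or val > r.ub + 1e-9:
                excess = max(r.lb - val, val - r.ub)
                violations.append((r.id, val, r.lb, r.ub))
                total += excess
        flux = FluxVector({rid: float(v[i]) for i, rid in enumerate(ids)},
                          array_cache=v)
        resid = self.model.steady_state_residual(flux)
        if resid > _STEADY_TOL:
            raise InfeasibleFluxError(
                f"steady-state residual {resid:.3g} exceeds tolerance")
        return flux, violations, total


def _eliminate(M, tol):
    """Gaussian elimination honouring the given column order; returns
    (pivot column positions, non-pivot positions)."""
    A = M.copy().astype(float)
    m, n = A.shape
    pivots, used_rows = [], set()
    scale = max(1.0, float(np.max(np.abs(A))) if A.size else 1.0)
    for j in range(n):
        rows = [i for i in range(m) if i not in used_rows]
        if not rows:
            break
        col = np.abs(A[rows, j])
        k = int(np.argmax(col))
        if col[k] <= tol * scale:
            continue
        pr = rows[k]
        used_rows.add(pr)
        pivots.append(j)
        piv = A[pr, j]
        for i in range(m):
            if i != pr and A[i, j] != 0.0:
                A[i, :] -= (A[i, j] / piv) * A[pr, :]
    nonpivots = [j for j in range(n) if j not in pivots]
    return pivots, nonpivots


def free_flux_basis(model: MetabolicModel, measured: dict | None = None,
                    overrides: dict | None = None) -> FluxBasis:
    """Parameterize the admissible flux space; see FluxBasis.

    ``measured`` supplies values for measured-class reactions;
    ``overrides`` optionally replaces the file-fixed values of
    constrained-class reactions (per-condition biomass demands).
    """
    return FluxBasis(model, measured, overrides)


def realize_fluxes(basis: FluxBasis, free_values) -> FluxVector:
    """Full flux vector from free-flux values (raises on bound violation)."""
    return basis.realize(free_values)
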