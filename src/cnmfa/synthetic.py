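"""Synthetic data with known ground truth for the three study conditions.

The generator emulates every input the pipeline consumes: substrate
labelling definitions, admissible ground-truth flux vectors, raw and
corrected GC-MS MID tables (forward-convolved with each fragment's
natural-abundance correction matrix, plus additive Gaussian noise on mole
fractions), and exponential-growth OD/substrate time series.

Conditions mirror the labelling design: heterotrophic growth on
[1-13C]fructose or [1,2-13C]glycerol (99 atom% tracer purity, non-tracer
positions at 1.07% natural 13C), and mixotrophic growth on
[1,2-13C]glycerol with a CO2 pool at 1% 13C.  Default growth parameters
and uptake rates are the measured values of the corresponding cultures
(mu = 0.254/0.173/0.23 1/h; uptake 0.189/0.023/0.055 g/L/OD/h).

All outputs are deterministic functions of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import build_correction_matrix, load_fragment_library
from .emu import SubstrateLabeling, decompose, simulate_mids
from .fitting import Measurement, MeasurementSet, fragment_emu
from .labelstats import GrowthSeries
from .models import CONDITIONS, condition_setup
from .network import FluxVector, MetabolicModel, free_flux_basis

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "make_labeling",
    "sample_flux_vector",
    "demo_truth",
    "simulate_dataset",
    "simulate_growth_series",
]

NATURAL_13C = 0.0107

# per-condition culture parameters (growth rate 1/h, uptake g/L/OD/h,
# initial substrate g/L, substrate molar mass g/mol)
_CONDITION_DEFAULTS = {
    "hetero_fructose": dict(mu=0.254, uptake_g=0.189, conc0=4.0, mw=180.16),
    "hetero_glycerol": dict(mu=0.173, uptake_g=0.023, conc0=10.0, mw=92.09),
    "mixo_glycerol_co2": dict(mu=0.23, uptake_g=0.055, conc0=10.0, mw=92.09),
}

# realistic demo ground-truth free fluxes (mmol/g DW/h): CBB (rbc) nearly
# silent on fructose, modest on heterotrophic glycerol, dominant under
# mixotrophy (glycerol-to-CO2 carbon ratio in the observed R range)
_DEMO_FREE = {
    "hetero_fructose": dict(pyk=1.5, rbc=0.05, ppc=0.4, pck=0.05, pyc=0.05,
                            mae=0.3, phaA=0.01),
    "hetero_glycerol": dict(pyk=0.25, rbc=0.15, ppc=0.08, pck=0.15, pyc=0.02,
                            mae=0.10, phaA=0.005),
    "mixo_glycerol_co2": dict(pyk=0.8, rbc=2.2, ppc=0.15, pck=0.2, pyc=0.05,
                              mae=0.15, phaA=0.02),
}


@dataclass
class ScenarioConfig:
    """Everything that determines one synthetic dataset."""

    condition: str
    seed: int = 0
    tracer_purity: float = 0.99
    co2_13c: float = 0.01
    natural_13c: float = NATURAL_13C
    noise_sd: float = 0.01          # mole-fraction SD per isotopologue
    mu: float | None = None         # 1/h; default per condition
    od0: float = 0.01
    n_points: int = 8
    od_noise_sd: float = 0.01       # lognormal sigma on OD
    conc_noise_sd: float = 0.02     # g/L additive on substrate
    uptake_g: float | None = None   # g/L/OD/h; default per condition

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; "
                             f"expected one of {CONDITIONS}")
        d = _CONDITION_DEFAULTS[self.condition]
        if self.mu is None:
            self.mu = d["mu"]
        if self.uptake_g is None:
            self.uptake_g = d["uptake_g"]

    @property
    def defaults(self):
        return _CONDITION_DEFAULTS[self.condition]


@dataclass
class GroundTruth:
    fluxes: FluxVector
    true_mids: dict              # (amino_acid, kind) -> np.ndarray
    scenario: ScenarioConfig = field(repr=False)


def make_labeling(condition: str, purity: float = 0.99,
                  natural: float = NATURAL_13C, co2: float = 0.01):
    """Substrate labelling vectors for a named condition.

    Tracer positions carry the 99 atom% purity; all other substrate carbons
    sit at natural 13C abundance; the CO2 pool is 1% 13C.  The inactive
    substrate of a condition is included at natural abundance so the model's
    idle uptake branch stays defined.
    """
    if condition == "hetero_fructose":
        fru = (purity,) + (natural,) * 5
        gly = (natural,) * 3
    elif condition in ("hetero_glycerol", "mixo_glycerol_co2"):
        fru = (natural,) * 6
        gly = (purity, purity, natural)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return [SubstrateLabeling("FRUx", fru), SubstrateLabeling("GLYCx", gly),
            SubstrateLabeling("CO2", (co2,))]


def sample_flux_vector(model: MetabolicModel, seed: int,
                       measured=None, overrides=None,
                       max_attempts: int = 5000) -> FluxVector:
    """Rejection-sample an admissible flux vector.

    Free fluxes are drawn uniformly within their bounds until every
    dependent flux is feasible; deterministic per seed.
    """
    basis = free_flux_basis(model, measured, overrides)
    rng = np.random.default_rng(seed)
    lb, ub = basis.free_lb, basis.free_ub
    for _ in range(max_attempts):
        x = rng.uniform(lb, ub)
        flux, violation = basis.realize_with_violations(x)
        if violation == 0.0:
            return flux
    raise RuntimeError(
        f"no admissible flux vector found in {max_attempts} attempts "
        f"(bounds too wide or model over-constrained)")


def demo_truth(model: MetabolicModel, condition: str,
               free_overrides: dict | None = None) -> FluxVector:
    """The packaged realistic ground-truth flux vector for a condition."""
    measured, overrides = condition_setup(model, condition)
    basis = free_flux_basis(model, measured, overrides)
    table = dict(_DEMO_FREE[condition])
    table.update(free_overrides or {})
    x = np.array([table.get(f, 0.05) for f in basis.free_ids])
    return basis.realize(x)


def simulate_dataset(model: MetabolicModel, truth: FluxVector,
                     scenario: ScenarioConfig, fragment_lib=None):
    """Generate one synthetic GC-MS dataset from a known flux vector.

    Returns (MeasurementSet of noisy corrected MIDs, raw MID DataFrame,
    GroundTruth).  The raw table is the forward convolution of the true
    MIDs with each fragment's correction matrix; the corrected table is the
    true MIDs plus additive Gaussian noise (clipped at zero, renormalized)
    with per-entry SD = noise_sd.
    """
    if fragment_lib is None:
        fragment_lib = load_fragment_library()
    labelings = make_labeling(scenario.condition, purity=scenario.tracer_purity,
                              natural=scenario.natural_13c,
                              co2=scenario.co2_13c)
    targets = {key: fragment_emu(fragment_lib, *key) for key in fragment_lib}
    net = decompose(model, list(targets.values()))
    mids = simulate_mids(net, truth, labelings,
                         co2_enrichment=scenario.co2_13c)
    rng = np.random.default_rng(scenario.seed)

    measurements, raw_rows, true_mids = [], [], {}
    for key in sorted(fragment_lib):
        spec = fragment_lib[key]
        true = np.asarray(mids[targets[key]])
        true_mids[key] = true
        cm = build_correction_matrix(spec, tracer_purity=scenario.tracer_purity)
        raw = cm.forward(true)
        row = {"condition": scenario.condition, "amino_acid": key[0],
               "fragment": key[1]}
        row.update({f"M{i}": raw[i] for i in range(raw.size)})
        raw_rows.append(row)
        noisy = true + rng.normal(0.0, scenario.noise_sd, size=true.size) \
            if scenario.noise_sd > 0 else true.copy()
        noisy = np.clip(noisy, 0.0, None)
        noisy = noisy / noisy.sum()
        measurements.append(Measurement(
            condition=scenario.condition, amino_acid=key[0],
            fragment_kind=key[1], mid=noisy,
            sd=np.full(true.size, scenario.noise_sd if scenario.noise_sd > 0
                       else 0.01),
            include=not spec.excluded,
            exclude_reason=spec.exclude_reason))
    raw_df = pd.DataFrame(raw_rows)
    return (MeasurementSet(measurements), raw_df,
            GroundTruth(truth, true_mids, scenario))


def simulate_growth_series(scenario: ScenarioConfig) -> GrowthSeries:
    """Exponential OD600 series with substrate depletion.

    OD(t) = OD0 * exp(mu t) with multiplicative lognormal noise; substrate
    c(t) = c0 - q * int OD dt with the configured biomass-specific uptake
    rate q (g/L/OD/h).  Sampling spans inoculation to OD ~ 1.2 (the
    study's sampling ceiling).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    mu, od0 = scenario.mu, scenario.od0
    d = scenario.defaults
    t_end = np.log(1.2 / od0) / mu
    # sample the second half of the run (OD ~0.1 to 1.2, the window where
    # growth is measurably exponential and the study drew its samples)
    times = np.linspace(0.5 * t_end, t_end, scenario.n_points)
    od_true = od0 * np.exp(mu * times)
    od = od_true * np.exp(rng.normal(0.0, scenario.od_noise_sd,
                                     size=times.size)) \
        if scenario.od_noise_sd > 0 else od_true
    integral = od0 * (np.exp(mu * times) - 1.0) / mu
    conc = d["conc0"] - scenario.uptake_g * integral
    if scenario.conc_noise_sd > 0:
        conc = conc + rng.normal(0.0, scenario.conc_noise_sd,
                                 size=times.size)
    return GrowthSeries(times=times, od600=od, substrate_conc=conc,
                        condition=scenario.condition)
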