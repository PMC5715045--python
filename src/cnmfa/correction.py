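"""Natural-abundance correction of GC-MS amino acid fragment spectra.

TBDMS-derivatized amino acids are measured as [M-57] ions (loss of
tert-butyl; all amino-acid carbons retained) and [M-85] ions (loss of
tert-butyl + CO; the C1 carboxyl carbon is lost).  The raw isotopologue
envelope of such an ion mixes the tracer signal with the natural isotope
abundance of every atom of the derivatized ion (C, H, N, O, Si, S) and with
the imperfect purity of the tracer.  This module builds the correction
matrix mapping a tracer-carbon MID to the observed envelope and inverts it
by non-negative least squares, recovering the tracer-only MID.

Isotope abundances follow the IUPAC 2013 compilation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

from .mid import MIDVector

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "NOMINAL_MASS",
    "FragmentSpec",
    "CorrectionMatrix",
    "parse_formula",
    "natural_envelope",
    "build_correction_matrix",
    "correct_mid",
    "load_fragment_library",
]

# mass-shift distributions (shift 0, +1, +2 ...) per element, IUPAC 2013
ISOTOPE_ABUNDANCES = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
    "S": np.array([0.9499, 0.0075, 0.0425]),
}

NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "Si": 28, "S": 32}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula) -> dict:
    """'C11H26NO2Si2' -> {'C': 11, 'H': 26, 'N': 1, 'O': 2, 'Si': 2}."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts, pos = {}, 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, n in counts.items():
        if el not in ISOTOPE_ABUNDANCES:
            raise ValueError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
    return counts


def nominal_mass(formula) -> int:
    counts = parse_formula(formula)
    return sum(NOMINAL_MASS[el] * n for el, n in counts.items())


def _element_power(dist: np.ndarray, n: int, depth: int) -> np.ndarray:
    """dist convolved with itself n times, truncated to depth+1 entries."""
    out = np.array([1.0])
    base = dist.copy()
    while n:
        if n & 1:
            out = np.convolve(out, base)[: depth + 1]
        n >>= 1
        if n:
            base = np.convolve(base, base)[: depth + 1]
    return out


def natural_envelope(formula, depth: int = 8) -> MIDVector:
    """Isotopologue envelope of a formula at natural abundance.

    Repeated convolution of the per-element isotope distributions,
    truncated at mass shift ``depth`` and renormalized.
    """
    counts = parse_formula(formula)
    out = np.array([1.0])
    for el, n in counts.items():
        out = np.convolve(out, _element_power(ISOTOPE_ABUNDANCES[el], n,
                                              depth))[: depth + 1]
    return MIDVector(out, renormalize=True)


@dataclass(frozen=True)
class FragmentSpec:
    """Identity of one detected amino acid fragment ion.

    ``backbone_carbons`` counts the amino-acid carbons retained in the ion
    (all of them for [M-57], all but the C1 carboxyl for [M-85]);
    ``formula`` is the full elemental composition of the derivatized ion,
    whose nominal monoisotopic mass must equal ``m0_mz``.
    """

    amino_acid: str
    fragment_kind: str           # "M-57" or "M-85"
    m0_mz: int
    backbone_carbons: int
    formula: str
    excluded: bool = False
    exclude_reason: str = ""
    metabolite: str = ""         # model metabolite carrying the backbone

    def __post_init__(self):
        if not self.metabolite:
            object.__setattr__(self, "metabolite", self.amino_acid.upper())
        if self.fragment_kind not in ("M-57", "M-85"):
            raise ValueError(f"unknown fragment kind {self.fragment_kind!r}")
        counts = parse_formula(self.formula)
        if counts.get("C", 0) < self.backbone_carbons:
            raise ValueError(
                f"{self.amino_acid} {self.fragment_kind}: formula has fewer "
                f"carbons than the {self.backbone_carbons} backbone carbons")
        mass = nominal_mass(counts)
        if mass != self.m0_mz:
            raise ValueError(
                f"{self.amino_acid} {self.fragment_kind}: formula mass {mass} "
                f"!= declared m0 {self.m0_mz}")

    @property
    def key(self):
        return (self.amino_acid, self.fragment_kind)


@dataclass
class CorrectionMatrix:
    """Maps a tracer-carbon MID (length backbone+1) to the observed
    isotopologue envelope."""

    fragment: FragmentSpec
    tracer_purity: float
    matrix: np.ndarray  # (n_rows, backbone_carbons + 1)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def forward(self, mid) -> np.ndarray:
        """Predicted raw envelope for a tracer MID (columns convolution)."""
        mid = np.asarray(mid, dtype=float)
        if mid.size != self.matrix.shape[1]:
            raise ValueError(
                f"MID length {mid.size} != {self.matrix.shape[1]}")
        return self.matrix @ mid


def build_correction_matrix(frag: FragmentSpec, tracer_purity: float = 0.99,
                            depth: int = 8,
                            natural_13c: float | None = None
                            ) -> CorrectionMatrix:
    """Correction matrix for one fragment.

    Column j (j tracer-derived backbone carbons) is the envelope of the
    formula minus the backbone carbons, convolved with the tracer purity
    smear Binomial(j, purity) and with the natural-abundance distribution
    Binomial(nb - j, 1.07%) of the remaining unlabelled backbone carbons.
    Column 0 therefore equals the natural envelope of the whole ion, and a
    natural-abundance-only spectrum corrects to M0 = 1.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError("tracer purity must be in (0, 1]")
    if natural_13c is None:
        natural_13c = float(ISOTOPE_ABUNDANCES["C"][1])
    counts = parse_formula(frag.formula)
    nb = frag.backbone_carbons
    rest = dict(counts)
    rest["C"] = rest.get("C", 0) - nb
    env_rest = np.asarray(natural_envelope(rest, depth=depth))
    n_rows = nb + depth + 1
    M = np.zeros((n_rows, nb + 1))
    for j in range(nb + 1):
        smear = binom.pmf(np.arange(j + 1), j, tracer_purity)
        nat = binom.pmf(np.arange(nb - j + 1), nb - j, natural_13c)
        col = np.convolve(np.convolve(env_rest, smear), nat)[:n_rows]
        M[: col.size, j] = col
    return CorrectionMatrix(frag, tracer_purity, M)


def correct_mid(raw, matrix: CorrectionMatrix):
    """Recover the tracer-only MID from a raw isotopologue envelope.

    Non-negative least squares against the correction matrix, renormalized
    to unit sum.  Accepts envelopes shorter than the theoretical depth
    (truncated scans) by solving on the overlapping rows only.

    Returns
    -------
    (MIDVector, float)
        The corrected MID and the relative residual of the reconstruction.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw envelope must be a 1-D vector")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero raw envelope")
    raw = raw / total
    n = min(raw.size, matrix.n_rows)
    A = matrix.matrix[:n, :]
    sol, rnorm = nnls(A, raw[:n])
    if sol.sum() <= 0:
        raise ValueError("correction produced an all-zero MID")
    return MIDVector(sol, renormalize=True), float(rnorm)


def load_fragment_library(path=None) -> dict:
    """Packaged table of TBDMS amino acid fragments; {(aa, kind): FragmentSpec}.

    The default exclusion flags mirror the measurement-quality policy of the
    study design: Tyr and Lys excluded for low signal-to-noise, Pro for
    co-elution.
    """
    if path is None:
        src = resources.files("cnmfa.data").joinpath("fragments.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    out = {}
    for row in df.itertuples(index=False):
        spec = FragmentSpec(
            amino_acid=row.amino_acid,
            fragment_kind=row.kind,
            m0_mz=int(row.m0_mz),
            backbone_carbons=int(row.backbone_carbons),
            formula=row.formula,
            excluded=bool(row.excluded),
            exclude_reason=str(row.exclude_reason)
            if isinstance(row.exclude_reason, str) else "",
        )
        out[spec.key] = spec
    return out
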