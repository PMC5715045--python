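"""Mass isotopomer distribution (MID) container.

An MID is the vector of fractional abundances (M0, M1, ..., Mn) of the
isotopologues of an analyte that differ in the number of heavy atoms.  MIDs
are the universal currency of this package: the labelling simulator emits
them, the natural-abundance correction produces them, and the flux-fitting
objective compares them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MIDVector", "convolve"]

_SUM_TOL = 1e-9


class MIDVector:
    """A normalized mass isotopomer distribution M0..Mn.

    Parameters
    ----------
    fractions : array-like
        Non-negative isotopologue fractions.  Must sum to 1 within 1e-9
        unless ``renormalize=True``.
    renormalize : bool
        Rescale the vector to unit sum (used after noise addition or
        truncation).

    Raises
    ------
    ValueError
        If any fraction is negative, outside [0, 1], or the vector does not
        sum to one (when not renormalizing).
    """

    __slots__ = ("fractions",)

    def __init__(self, fractions, renormalize: bool = False):
        arr = np.asarray(fractions, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("MID must be a non-empty 1-D vector")
        if np.any(arr < -1e-12):
            raise ValueError(f"MID has negative fractions: {arr}")
        arr = np.clip(arr, 0.0, None)
        total = arr.sum()
        if renormalize:
            if total <= 0:
                raise ValueError("cannot renormalize an all-zero MID")
            arr = arr / total
        elif abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"MID fractions sum to {total!r}, not 1")
        if np.any(arr > 1.0 + 1e-12):
            raise ValueError("MID fraction exceeds 1")
        self.fractions = arr

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return int(self.fractions.size)

    def __getitem__(self, i):
        return self.fractions[i]

    def __iter__(self):
        return iter(self.fractions)

    def __array__(self, dtype=None, copy=None):
        if dtype is not None:
            return self.fractions.astype(dtype)
        return self.fractions

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{x:.4g}" for x in self.fractions)
        return f"MIDVector([{body}])"

    def __eq__(self, other) -> bool:
        if not isinstance(other, MIDVector):
            return NotImplemented
        return (len(self) == len(other)
                and bool(np.all(self.fractions == other.fractions)))

    @property
    def n_carbons(self) -> int:
        """Number of (tracer) carbon positions, i.e. len - 1."""
        return len(self) - 1

    def isclose(self, other, atol: float = 1e-8) -> bool:
        other = np.asarray(other, dtype=float)
        return (self.fractions.size == other.size
                and bool(np.allclose(self.fractions, other, atol=atol)))


def convolve(a, b) -> MIDVector:
    """Cauchy-product convolution of two MIDs.

    This is the condensation rule: when two molecular fragments combine,
    the isotopologue distribution of the product is the convolution of the
    distributions of the parts.  Length of the result is
    ``len(a) + len(b) - 1`` and it sums to one.
    """
    out = np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return MIDVector(out, renormalize=True)
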