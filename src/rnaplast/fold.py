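"""Thermodynamic folding and plasticity metrics.

Wraps the ViennaRNA nearest-neighbor (Turner-style) energy model to obtain,
for a single sequence, the minimum free energy (MFE) structure and its free
energy, the partition-function base-pair probability matrix, per-residue
positional entropy (PE), span-averaged PE (APE), and the clear-to-red color
normalization used to paint PE onto structure drawings.

Positional entropy of residue i is the Shannon entropy of its pairing-state
distribution under the thermodynamic ensemble: each possible partner j with
probability p_ij, plus the unpaired state with probability
q_i = 1 - sum_j p_ij.  The default log base is 2, matching the convention of
the folding engine's own entropy output (from which published PE color maps
are derived); the base is exposed for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

import RNA

from .sequences import RnaSequence
from .structure import SecondaryStructure

#: Color-normalization cap: the highest per-residue PE observed across the
#: study's structures, used as the "fully red" end of the scale.
DEFAULT_PE_CAP = 2.6

DEFAULT_TEMPERATURE = 37.0

_ROW_SUM_TOL = 1e-6


class FoldError(ValueError):
    """Raised for invalid folding inputs or inconsistent probability data."""


@dataclass
class PairProbabilityMatrix:
    """Symmetric base-pair probability matrix plus unpaired probabilities.

    ``p[i, j]`` (0-based internally) is the probability that residues i+1 and
    j+1 pair in the Boltzmann ensemble; ``q[i]`` is the probability that
    residue i+1 is unpaired.
    """

    p: np.ndarray
    q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise FoldError("pair probability matrix must be square")
        if not np.allclose(self.p, self.p.T, atol=1e-12):
            raise FoldError("pair probability matrix must be symmetric")
        if (self.p < -1e-12).any() or (self.p > 1 + 1e-9).any():
            raise FoldError("pair probabilities must lie in [0, 1]")
        row_sums = self.p.sum(axis=1)
        if (row_sums > 1 + _ROW_SUM_TOL).any():
            bad = int(np.argmax(row_sums)) + 1
            raise FoldError(
                f"pairing probabilities at position {bad} sum to "
                f"{row_sums[bad - 1]:.8f} > 1"
            )
        if self.q is None:
            self.q = np.clip(1.0 - row_sums, 0.0, 1.0)
        else:
            self.q = np.asarray(self.q, dtype=float)
            if self.q.shape != (n,):
                raise FoldError("unpaired probability vector has wrong length")
            if not np.allclose(self.q, 1.0 - row_sums, atol=_ROW_SUM_TOL * 10):
                raise FoldError("q inconsistent with 1 - row sums of p")

    @property
    def n(self) -> int:
        return self.p.shape[0]


@dataclass
class FoldResult:
    """MFE structure, free energy and pairing probabilities for one sequence."""

    sequence: RnaSequence
    mfe_structure: SecondaryStructure
    delta_g: float  # kcal/mol, <= 0
    bpp: PairProbabilityMatrix
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.mfe_structure.length != self.sequence.length:
            raise FoldError("structure length does not match sequence length")
        if self.delta_g > 1e-9:
            raise FoldError(f"MFE free energy must be <= 0, got {self.delta_g}")


@dataclass
class EntropyProfile:
    """Per-residue positional entropy values with a color-normalization cap."""

    values: np.ndarray
    cap: float = DEFAULT_PE_CAP
    base: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FoldError("entropy profile must be one-dimensional")
        if (self.values < -1e-9).any():
            raise FoldError("positional entropy values must be nonnegative")
        self.values = np.maximum(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.values)


def fold(seq: RnaSequence, temperature: float = DEFAULT_TEMPERATURE) -> FoldResult:
    """Fold one sequence: MFE structure, free energy and pair probabilities.

    Uses the nearest-neighbor partition function at ``temperature`` (deg C).
    A sequence with no favorable pairs returns the open structure with
    delta_g = 0.
    """
    md = RNA.md()
    md.temperature = float(temperature)
    fc = RNA.fold_compound(seq.residues, md)
    structure, mfe = fc.mfe()
    # rescale Boltzmann factors around the MFE for numerical stability of pf
    fc.exp_params_rescale(mfe)
    fc.pf()
    n = seq.length
    upper = np.asarray(fc.bpp(), dtype=float)[1:, 1:]
    p = upper + upper.T
    return FoldResult(
        sequence=seq,
        mfe_structure=SecondaryStructure.from_dotbracket(structure),
        delta_g=round(float(mfe), 2),
        bpp=PairProbabilityMatrix(p),
        temperature=float(temperature),
    )


def entropy_from_bpp(bpp: PairProbabilityMatrix, base: float = 2.0) -> np.ndarray:
    """Per-residue Shannon entropy of the pairing-state distribution.

    S_i = -[ sum_j p_ij log p_ij + q_i log q_i ] / log(base), with
    0 log 0 := 0.
    """
    if base <= 0 or base == 1:
        raise FoldError("entropy log base must be positive and != 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(bpp.p > 0, bpp.p * np.log(bpp.p), 0.0)
        qlogq = np.where(bpp.q > 0, bpp.q * np.log(bpp.q), 0.0)
    s = -(plogp.sum(axis=1) + qlogq) / math.log(base)
    return np.maximum(s, 0.0)


def positional_entropy(
    result: FoldResult, base: float = 2.0, cap: float = DEFAULT_PE_CAP
) -> EntropyProfile:
    """Positional entropy profile of a fold's thermodynamic ensemble.

    A residue scores exactly 0 when it has a single certain state (always
    unpaired, or always paired to the same partner).
    """
    return EntropyProfile(values=entropy_from_bpp(result.bpp, base=base), cap=cap, base=base)


def average_positional_entropy(
    profile: EntropyProfile, span: tuple[int, int] | None = None
) -> float:
    """Arithmetic mean PE over a 1-based inclusive span (default: whole profile)."""
    n = len(profile)
    if span is None:
        span = (1, n)
    start, end = span
    if not (1 <= start <= end <= n):
        raise FoldError(f"span {span} out of range for profile of length {n}")
    return float(profile.values[start - 1 : end].mean())


def sliding_window_ape(profile: EntropyProfile, window: int) -> np.ndarray:
    """Mean PE over every sliding window of the given length.

    Returns an array of length n - window + 1.  Raises if the window exceeds
    the profile length.
    """
    n = len(profile)
    if window < 1 or window > n:
        raise FoldError(f"window {window} invalid for profile of length {n}")
    c = np.concatenate([[0.0], np.cumsum(profile.values)])
    return (c[window:] - c[:-window]) / window


def pe_color_values(profile: EntropyProfile, cap: float | None = None) -> np.ndarray:
    """Normalize PE to [0, 1] for a clear-to-red color scale: min(S, cap)/cap."""
    if cap is None:
        cap = profile.cap
    if cap <= 0:
        raise FoldError("color cap must be positive")
    return np.minimum(profile.values, cap) / cap
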