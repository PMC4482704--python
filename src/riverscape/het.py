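"""Substrate-based macroinvertebrate abundance (habitat evaluation tool).

Macroinvertebrate abundance in a reach is predicted from empirical
substrate-specific densities (individuals/m² observed on each substrate
type) weighted by the reach's substrate composition and scaled by reach
area. The raw prediction can be corrected for water quality through
species-specific dose–response curves (a factor in [0, 1] per parameter,
combined by the limiting-factor minimum by default), compared with observed
communities via the Renkonen percentage-similarity index, and standardized
against the abundance predicted for natural reference substrate
compositions — sampled from per-class reference ranges (e.g. 5–20% gravel)
— to yield a relative abundance with an uncertainty range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SubstrateComposition", "SubstratePreference", "DoseResponse",
    "ReferenceRange", "HETResult", "predict_abundance", "apply_water_quality",
    "renkonen", "relative_abundance",
]

#: The substrate classes distinguished in the field protocol this model
#: follows (mineral grain-size classes plus biotic/organic substrates).
CANONICAL_SUBSTRATES = (
    "silt", "sand", "fine_gravel", "coarse_gravel", "stones",
    "macrophytes", "moss", "wood", "cpom", "fpom",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SubstrateComposition:
    """Areal fractions per substrate class; fractions sum to 1."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        fr = dict(self.fractions)
        if any(v < 0 for v in fr.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total:g}, expected 1")
        # exact renormalization keeps the simplex invariant tight
        object.__setattr__(self, "fractions", {k: v / total for k, v in fr.items()})

    def __getitem__(self, cls: str) -> float:
        return self.fractions.get(cls, 0.0)


@dataclass(frozen=True)
class SubstratePreference:
    """Per-species density (individuals/m²) on each substrate class."""

    species: str
    densities: Mapping[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class DoseResponse:
    """Piecewise-linear factor in [0,1] vs a water-quality parameter.

    Linear between breakpoints, constant beyond the first and last.
    """

    parameter: str
    values: Sequence[float]
    factors: Sequence[float]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        f = np.asarray(self.factors, dtype=float)
        if v.size != f.size or v.size == 0:
            raise ValueError("values and factors must be nonempty and equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("breakpoint abscissae must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("factors must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "factors", f)

    def factor(self, x: float) -> float:
        return float(np.interp(x, self.values, self.factors))


@dataclass(frozen=True)
class ReferenceRange:
    """Per-class (min, max) fractions describing natural substrate cover."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for cls, (lo, hi) in self.ranges.items():
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"invalid range for {cls}: ({lo}, {hi})")


@dataclass(frozen=True)
class HETResult:
    abundance: float
    corrected: float
    relative_median: float
    relative_low: float
    relative_high: float


def predict_abundance(pref: SubstratePreference, comp: SubstrateComposition,
                      reach_area: float) -> float:
    """Predicted individuals in the reach: Σ density_k · fraction_k · area."""
    if reach_area <= 0:
        raise ValueError("reach area must be positive")
    unknown = set(comp.fractions) - set(pref.densities)
    if unknown:
        raise ValueError(f"no density for substrate class(es): {sorted(unknown)}")
    return reach_area * sum(pref.densities[k] * f for k, f in comp.fractions.items())


def apply_water_quality(abundance: float,
                        dose_responses: Sequence[DoseResponse],
                        wq: Mapping[str, float],
                        mode: str = "min") -> float:
    """Scale an abundance by water-quality dose–response factors.

    ``mode="min"`` applies the limiting-factor principle (default);
    ``mode="product"`` multiplies the per-parameter factors.
    """
    if mode not in {"min", "product"}:
        raise ValueError("mode must be 'min' or 'product'")
    curves = {dr.parameter: dr for dr in dose_responses}
    missing = set(wq) - set(curves)
    if missing:
        raise ValueError(f"no dose-response curve for parameter(s): {sorted(missing)}")
    factors = [curves[p].factor(x) for p, x in wq.items()]
    if not factors:
        return abundance
    combined = min(factors) if mode == "min" else float(np.prod(factors))
    return abundance * combined


def renkonen(p: Sequence[float], q: Sequence[float]) -> float:
    """Renkonen percentage similarity of two abundance vectors, in [0, 100].

    Both vectors are normalized to percentages; the index is the sum of the
    element-wise minima, 100 for identical relative compositions and 0 for
    disjoint ones.
    """
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError("vectors must cover the same species set")
    if np.any(pa < 0) or np.any(qa < 0):
        raise ValueError("abundances must be non-negative")
    if pa.sum() == 0 or qa.sum() == 0:
        raise ValueError("each vector needs at least one positive entry")
    return float(np.minimum(100 * pa / pa.sum(), 100 * qa / qa.sum()).sum())


def sample_reference_compositions(ref: ReferenceRange, n_samples: int,
                                  rng: np.random.Generator,
                                  rejection: bool = False,
                                  max_tries: int = 1000) -> list[SubstrateComposition]:
    """Draw reference compositions uniformly within per-class ranges.

    Draws are independent uniforms within each class range, renormalized to
    the simplex. With ``rejection=True`` draws whose renormalized fractions
    leave any class range are discarded and redrawn.
    """
    classes = list(ref.ranges)
    lo = np.array([ref.ranges[c][0] for c in classes])
    hi = np.array([ref.ranges[c][1] for c in classes])
    if lo.sum() > 1 + _SUM_TOL or hi.sum() < 1 - _SUM_TOL:
        raise ValueError("infeasible reference ranges: no composition sums to 1")
    out: list[SubstrateComposition] = []
    tries = 0
    while len(out) < n_samples:
        tries += 1
        if tries > max_tries * n_samples:
            raise ValueError("rejection sampling failed to find valid compositions")
        draw = rng.uniform(lo, hi)
        total = draw.sum()
        if total == 0:
            continue
        frac = draw / total
        if rejection and (np.any(frac < lo - _SUM_TOL) or np.any(frac > hi + _SUM_TOL)):
            continue
        out.append(SubstrateComposition(dict(zip(classes, frac))))
    return out


def relative_abundance(pref: SubstratePreference,
                       present: SubstrateComposition,
                       ref: ReferenceRange,
                       reach_area: float = 1.0,
                       n_samples: int = 1000,
                       seed: int | np.random.Generator = 0,
                       rejection: bool = False) -> tuple[float, float, float]:
    """Present-state abundance as a percentage of the natural reference.

    Reference compositions are Monte Carlo samples within the per-class
    natural ranges; for each, the predicted abundance is computed and the
    present-state abundance expressed as a percentage of it. Returns
    ``(median, low, high)`` over the samples (min–max range). Reproducible
    for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present_ab = predict_abundance(pref, present, reach_area)
    refs = sample_reference_compositions(ref, n_samples, rng, rejection=rejection)
    ratios = []
    for comp in refs:
        ref_ab = predict_abundance(pref, comp, reach_area)
        if ref_ab <= 0:
            continue
        ratios.append(100.0 * present_ab / ref_ab)
    if not ratios:
        raise ValueError("reference abundance is zero for every sample")
    arr = np.asarray(ratios)
    return float(np.median(arr)), float(arr.min()), float(arr.max())
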