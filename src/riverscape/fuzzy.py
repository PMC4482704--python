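"""Mamdani fuzzy-inference habitat suitability for fish.

Expert knowledge of hydraulic habitat preferences is encoded as trapezoidal
fuzzy sets over flow velocity and water depth, and a rule base of the form

    IF velocity IS low AND depth IS deep THEN suitability IS high

Inference uses the classical Mamdani operator set: AND = minimum,
implication = minimum (clipping the consequent set), aggregation across
rules = maximum, and centroid defuzzification on [0, 1] sampled at 0.001.
Evaluating the system on every wet cell of a 2D hydraulic grid and summing
suitability × cell area gives the Weighted Usable Area (WUA) of the reach;
dividing by the bankfull wetted area standardizes it to a percentage so
reaches and species can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MembershipFunction", "FuzzySystem", "Rule", "HydraulicGrid",
    "WUAResult", "infer_suitability", "wua", "standardize_wua",
]

_RESOLUTION = 0.001


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoidal fuzzy set with breakpoints z1 ≤ z2 ≤ z3 ≤ z4.

    z2 = z3 gives a triangle; z1 = z2 (or z3 = z4) a crisp shoulder, where
    the boundary point itself has degree 1 (left/right-closed plateau).
    """

    z1: float
    z2: float
    z3: float
    z4: float

    def __post_init__(self):
        if not self.z1 <= self.z2 <= self.z3 <= self.z4:
            raise ValueError("breakpoints must satisfy z1 <= z2 <= z3 <= z4")

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        deg = np.zeros_like(x)
        plateau = (x >= self.z2) & (x <= self.z3)
        deg[plateau] = 1.0
        if self.z2 > self.z1:
            up = (x >= self.z1) & (x < self.z2)
            deg[up] = (x[up] - self.z1) / (self.z2 - self.z1)
        if self.z4 > self.z3:
            down = (x > self.z3) & (x <= self.z4)
            deg[down] = (self.z4 - x[down]) / (self.z4 - self.z3)
        return deg if deg.ndim else float(deg)

    def to_dict(self) -> list[float]:
        return [self.z1, self.z2, self.z3, self.z4]


@dataclass(frozen=True)
class Rule:
    """Antecedent classes per input variable (joined by AND) → output class."""

    antecedent: Mapping[str, str]
    consequent: str


@dataclass(frozen=True)
class FuzzySystem:
    """Fuzzy rule system mapping hydraulic variables to suitability in [0,1].

    ``variables`` maps each input variable name (by default "velocity" in
    m/s and "depth" in m) to its named membership classes; ``output``
    holds the named fuzzy sets on the suitability domain [0, 1].
    """

    variables: Mapping[str, Mapping[str, MembershipFunction]]
    output: Mapping[str, MembershipFunction]
    rules: Sequence[Rule]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("rule base is empty")
        for rule in self.rules:
            for var, cls in rule.antecedent.items():
                if var not in self.variables or cls not in self.variables[var]:
                    raise ValueError(f"rule references unknown class {var}/{cls}")
            if rule.consequent not in self.output:
                raise ValueError(f"rule references unknown output class {rule.consequent}")

    def to_dict(self) -> dict:
        return {
            "variables": {v: {c: mf.to_dict() for c, mf in classes.items()}
                          for v, classes in self.variables.items()},
            "output": {c: mf.to_dict() for c, mf in self.output.items()},
            "rules": [{"if": dict(r.antecedent), "then": r.consequent}
                      for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzySystem":
        return cls(
            variables={v: {c: MembershipFunction(*bp) for c, bp in classes.items()}
                       for v, classes in d["variables"].items()},
            output={c: MembershipFunction(*bp) for c, bp in d["output"].items()},
            rules=[Rule(antecedent=r["if"], consequent=r["then"]) for r in d["rules"]],
        )


def infer_suitability(sys: FuzzySystem, velocity: float, depth: float,
                      **extra: float) -> tuple[float, bool]:
    """Mamdani inference for one (velocity, depth) sample.

    Returns ``(suitability, undefined)``: when no rule fires the suitability
    is 0 and the ``undefined`` flag is set (a conservative fallback for WUA).
    Extra input variables configured on the system are passed by keyword.
    """
    values = {"velocity": velocity, "depth": depth, **extra}
    grid = np.arange(0.0, 1.0 + _RESOLUTION / 2, _RESOLUTION)
    aggregated = np.zeros_like(grid)
    fired = False
    for rule in sys.rules:
        act = 1.0
        for var, cls in rule.antecedent.items():
            if var not in values:
                raise ValueError(f"no value supplied for input variable {var!r}")
            act = min(act, sys.variables[var][cls](values[var]))
        if act <= 0:
            continue
        fired = True
        clipped = np.minimum(sys.output[rule.consequent](grid), act)
        aggregated = np.maximum(aggregated, clipped)
    total = aggregated.sum()
    if not fired or total <= 0:
        return 0.0, True
    return float((aggregated * grid).sum() / total), False


@dataclass(frozen=True)
class HydraulicGrid:
    """Per-cell depth and velocity at one discharge, on a uniform grid.

    Dry cells carry depth 0 and ``wet`` False; ``cell_area`` is the uniform
    cell area in m² (0.25 m² for a 0.5 m raster).
    """

    depth: np.ndarray
    velocity: np.ndarray
    cell_area: float
    wet: np.ndarray = None  # derived if omitted

    def __post_init__(self):
        depth = np.asarray(self.depth, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if depth.shape != vel.shape or depth.ndim != 2:
            raise ValueError("depth and velocity must be 2D arrays of equal shape")
        if self.cell_area <= 0:
            raise ValueError("cell area must be positive")
        wet = self.wet
        if wet is None:
            wet = depth > 0
        wet = np.asarray(wet, dtype=bool)
        depth = np.where(wet, depth, 0.0)
        vel = np.where(wet, vel, 0.0)
        if np.any(depth < 0) or np.any(vel < 0):
            raise ValueError("depth and velocity must be non-negative")
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "velocity", vel)
        object.__setattr__(self, "wet", wet)

    @property
    def wetted_area(self) -> float:
        return float(self.wet.sum()) * self.cell_area


def wua(grid: HydraulicGrid, sys: FuzzySystem) -> float:
    """Weighted Usable Area in m²: Σ over wet cells of suitability × area."""
    total = 0.0
    rows, cols = np.nonzero(grid.wet)
    for r, c in zip(rows, cols):
        s, _ = infer_suitability(sys, grid.velocity[r, c], grid.depth[r, c])
        total += s * grid.cell_area
    return total


@dataclass(frozen=True)
class WUAResult:
    """Monthly WUA series standardized by the bankfull wetted area."""

    monthly_wua: np.ndarray          # m², 12 values
    relative: np.ndarray             # % of bankfull wetted area
    median: float
    minimum: float
    value_range: tuple[float, float]

    @property
    def range_width(self) -> float:
        return self.value_range[1] - self.value_range[0]


def standardize_wua(monthly_wua: Sequence[float],
                    bankfull_wetted_area: float) -> WUAResult:
    """Express 12 monthly WUA values as shares of the bankfull wetted area.

    The bankfull wetted area is the maximum attainable WUA (suitability 1
    everywhere at bankfull), so the share is a percentage with 100% as the
    best case; the median, range and minimum of the 12 monthly shares are
    reported, the minimum being a potential seasonal bottleneck.
    """
    if bankfull_wetted_area <= 0:
        raise ValueError("bankfull wetted area must be positive")
    m = np.asarray(monthly_wua, dtype=float)
    if m.size != 12:
        raise ValueError("need 12 monthly values")
    rel = 100.0 * m / bankfull_wetted_area
    return WUAResult(
        monthly_wua=m,
        relative=rel,
        median=float(np.median(rel)),
        minimum=float(rel.min()),
        value_range=(float(rel.min()), float(rel.max())),
    )
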