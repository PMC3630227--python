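"""Core state types and rate laws of the plasmid copy-number-control model.

A non-conjugative plasmid is described by three heritable traits:

* ``alpha`` — *selfishness*: the basal replication-initiation rate of a
  plasmid copy in the absence of any inhibition (cis-acting).
* ``kappa`` — *policing*: the rate at which a plasmid copy synthesises a
  short-lived trans-acting replication inhibitor.
* ``beta`` — *obedience*: the binding affinity of the plasmid's own
  replication target to that inhibitor (cis-acting sensitivity).

The host cell grows in biomass at a rate set by the chromosomal baseline,
a saturating gene-dosage benefit of plasmid carriage, and linear
per-copy maintenance (plus, optionally, policing-production) costs.  Both
the deterministic single-cell layer and the stochastic multicellular
engine are built on the two rate laws defined here: :func:`growth_rate`
and :func:`replication_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PlasmidGenotype",
    "TraitBounds",
    "CellParams",
    "EvolutionParams",
    "HostCell",
    "growth_rate",
    "benefit",
    "optimal_copy_number",
    "inhibitor_concentration",
    "inhibition_response",
    "replication_rate",
    "TRAIT_NAMES",
]

TRAIT_NAMES = ("alpha", "kappa", "beta")

InhibitionForm = Literal["hyperbolic", "exponential"]


@dataclass(frozen=True)
class PlasmidGenotype:
    """One heritable plasmid replication profile (alpha, kappa, beta)."""

    alpha: float
    kappa: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.kappa < 0 or self.beta < 0:
            raise ValueError(
                f"plasmid traits must be non-negative, got "
                f"alpha={self.alpha}, kappa={self.kappa}, beta={self.beta}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.kappa, self.beta], dtype=float)

    @staticmethod
    def from_array(a) -> "PlasmidGenotype":
        return PlasmidGenotype(float(a[0]), float(a[1]), float(a[2]))

    def swapped(self) -> "PlasmidGenotype":
        """Exchange policing and obedience (homogeneity symmetry partner)."""
        return PlasmidGenotype(self.alpha, self.beta, self.kappa)


@dataclass(frozen=True)
class TraitBounds:
    """Physiological upper limits of the three plasmid traits.

    Traits live in ``[0, max]``; the caps stand in for physico-chemical
    limits on initiator activity, inhibitor synthesis and binding affinity.
    """

    alpha_max: float = 0.1
    kappa_max: float = 0.05
    beta_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha_max, self.kappa_max, self.beta_max) <= 0:
            raise ValueError("trait bounds must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_max, self.kappa_max, self.beta_max])

    def validate(self, g: PlasmidGenotype) -> None:
        for name, cap in zip(TRAIT_NAMES, self.as_array()):
            v = getattr(g, name)
            if not 0.0 <= v <= cap:
                raise ValueError(f"trait {name}={v} outside [0, {name}_max={cap}]")

    def clip(self, traits: np.ndarray) -> np.ndarray:
        return np.clip(traits, 0.0, self.as_array())


@dataclass(frozen=True)
class CellParams:
    """Host-cell growth-law constants and simulation geometry.

    Parameters
    ----------
    g0 : basal (chromosomal) growth rate, per unit biomass per unit time.
    B : ceiling of the saturating plasmid benefit to growth.
    steepness : shape constant of the benefit curve, per plasmid copy.
    c : general maintenance cost per plasmid copy per unit time.
    c_inh : policing cost per unit of inhibitor synthesised (0 = baseline).
    M0 : newborn biomass; the cell divides when biomass reaches ``2*M0``.
    tau : mean lifetime of the replication inhibitor (short vs the cycle).
    dt : time step of the discrete-time stochastic update.
    """

    g0: float = 0.01
    B: float = 0.05
    steepness: float = 0.1
    c: float = 0.001
    c_inh: float = 0.0
    M0: float = 1.0
    tau: float = 2.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValueError(f"g0 must be positive, got {self.g0}")
        for name in ("B", "c", "c_inh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        for name in ("M0", "tau", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def division_mass(self) -> float:
        return 2.0 * self.M0

    def plasmid_free_division_time(self) -> float:
        """Closed-form cycle length of a plasmid-free cell: ln2/g0."""
        return math.log(2.0) / self.g0


@dataclass(frozen=True)
class EvolutionParams:
    """Mutation process acting on plasmid replication traits.

    Each replication event mutates the copied genotype with probability
    ``mu``; exactly one trait (uniform among ``free`` traits) is perturbed
    by an additive uniform step of half-width ``step`` times that trait's
    bound, then clipped into bounds.
    """

    mu: float = 0.005
    step: float = 0.05
    bounds: TraitBounds = field(default_factory=TraitBounds)
    free: tuple[str, ...] = TRAIT_NAMES
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.step <= 0:
            raise ValueError("mutation step must be positive")
        for name in self.free:
            if name not in TRAIT_NAMES:
                raise ValueError(f"unknown trait {name!r} in free set")

    @property
    def free_indices(self) -> np.ndarray:
        return np.array([TRAIT_NAMES.index(n) for n in self.free], dtype=np.int64)


@dataclass
class HostCell:
    """A single bacterium: biomass plus its multiset of plasmid genotypes."""

    biomass: float
    plasmids: list[PlasmidGenotype] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.plasmids)

    @property
    def alive(self) -> bool:
        return self.biomass >= 0.0

    def total_kappa(self) -> float:
        return float(sum(p.kappa for p in self.plasmids))

    def traits_array(self) -> np.ndarray:
        if not self.plasmids:
            return np.empty((0, 3))
        return np.stack([p.as_array() for p in self.plasmids])


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def benefit(n, p: CellParams):
    """Saturating gene-dosage benefit B*(1 - exp(-steepness*n)).

    Monotone increasing and bounded by ``p.B``; its marginal value
    ``B*steepness*exp(-steepness*n)`` decreases with copy number.
    """
    return p.B * (-np.expm1(-p.steepness * np.asarray(n, dtype=float)))


def growth_rate(n, total_kappa, p: CellParams):
    """Per-biomass growth rate g(n) of a host carrying ``n`` plasmid copies.

    ``g = g0 + B(1 - e^(-steepness*n)) - c*n - c_inh*total_kappa``

    ``total_kappa`` is the summed inhibitor-production rate of the cell's
    plasmids; it only enters through the (optional) policing cost term.
    Accepts scalars or arrays in ``n``/``total_kappa``.
    """
    n = np.asarray(n, dtype=float)
    tk = np.asarray(total_kappa, dtype=float)
    if np.any(n < 0):
        raise ValueError("copy number n must be non-negative")
    if np.any(tk < 0):
        raise ValueError("total_kappa must be non-negative")
    g = p.g0 + benefit(n, p) - p.c * n - p.c_inh * tk
    return g if g.ndim else float(g)


def optimal_copy_number(p: CellParams, kappa: float = 0.0) -> float:
    """Copy number maximising the growth rate (marginal benefit = marginal cost).

    With the exponential benefit form the first-order condition
    ``B*s*exp(-s*n) = c + c_inh*kappa`` gives
    ``n_opt = ln(B*s/(c + c_inh*kappa))/s``.  When the per-copy cost exceeds
    the marginal benefit already at n=0 the plasmid is a pure parasite and
    the optimum is 0.  ``kappa`` is the per-copy policing rate, so a
    homogeneous cell's total policing cost scales with n.
    """
    c_eff = p.c + p.c_inh * kappa
    if c_eff < 0:
        raise ValueError("effective per-copy cost must be non-negative")
    if c_eff == 0.0:
        return math.inf if p.B > 0 else 0.0
    marginal0 = p.B * p.steepness
    if marginal0 <= c_eff:
        return 0.0  # pure parasite: any copy is a net burden
    return math.log(marginal0 / c_eff) / p.steepness


def inhibitor_concentration(plasmids, biomass: float, tau: float) -> float:
    """Quasi-steady-state inhibitor concentration I = tau * sum(kappa) / M.

    The inhibitor decays fast relative to the cell cycle, so its
    concentration tracks the current total synthesis rate, diluted by the
    cell's biomass.  ``plasmids`` may be an iterable of
    :class:`PlasmidGenotype`, a :class:`HostCell`, or a precomputed
    kappa-sum (float).
    """
    if biomass <= 0:
        raise ValueError(f"biomass must be positive (dead cell?), got {biomass}")
    if isinstance(plasmids, HostCell):
        ksum = plasmids.total_kappa()
    elif isinstance(plasmids, (int, float, np.floating)):
        ksum = float(plasmids)
    else:
        ksum = float(sum(pl.kappa for pl in plasmids))
    if ksum < 0:
        raise ValueError("total inhibitor production must be non-negative")
    return tau * ksum / biomass


def inhibition_response(x, form: InhibitionForm = "hyperbolic"):
    """Decreasing inhibition response h(x) with h(0)=1.

    ``hyperbolic``: 1/(1+x) — quasi-equilibrium inhibitor/target binding,
    the conventional copy-number-control form.  ``exponential``: exp(-x).
    """
    x = np.asarray(x, dtype=float)
    if form == "hyperbolic":
        out = 1.0 / (1.0 + x)
    elif form == "exponential":
        out = np.exp(-x)
    else:
        raise ValueError(f"unknown inhibition response form {form!r}")
    return out if out.ndim else float(out)


def replication_rate(pl: PlasmidGenotype, I: float,
                     form: InhibitionForm = "hyperbolic") -> float:
    """Actual per-plasmid replication rate r = alpha * h(beta * I).

    The plasmid's obedience ``beta`` weights its response to the shared
    inhibitor pool; a fully disobedient plasmid (beta=0) replicates at its
    basal rate regardless of policing.
    """
    if I < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    return pl.alpha * inhibition_response(pl.beta * I, form)
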