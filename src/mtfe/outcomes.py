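"""Structural endpoints of a solved model: apparent stiffness, failure load
via a strain-based criterion, BMC-normalized forms, and strain histograms.

Failure load uses a Pistoia-type rule: the linear solution is scaled until
a set fraction of the nodes (default 10%) reaches a critical compressive
third principal strain (default −14,420 µε = −0.01442).  Because the model
is linear, the scale factor λ applies exactly and Fu = λ·|axial reaction|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .fe_solver import BoundaryConditions, FESolution
from .image_io import BMCReport

__all__ = [
    "FailureCriterion",
    "OutcomeSet",
    "apparent_stiffness",
    "failure_load",
    "normalize_outcomes",
    "strain_histogram",
]


@dataclass(frozen=True)
class FailureCriterion:
    """Node-fraction / critical-strain failure rule."""

    node_fraction: float = 0.10
    critical_e3: float = -0.01442

    def __post_init__(self):
        if not 0 < self.node_fraction <= 1:
            raise ValueError("node_fraction must lie in (0, 1]")
        if not self.critical_e3 < 0:
            raise ValueError("critical_e3 must be negative (compression)")


@dataclass(frozen=True)
class OutcomeSet:
    """The four structural endpoints plus the BMC used to normalize."""

    stiffness: float  # N/mm
    failure_load: float  # N
    total_bmc: float  # mg
    stiffness_norm: float  # N/mm/mg
    failure_load_norm: float  # N/mg

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _axial_reaction(sol: FESolution, bc: BoundaryConditions) -> float:
    return float(sol.reactions[bc.fixed_nodes, 2].sum())


def apparent_stiffness(sol: FESolution, bc: BoundaryConditions) -> float:
    """S = |Σ axial reactions at the fixed (distal) surface| / applied
    displacement, in N/mm."""
    if bc.applied_displacement == 0:
        raise ValueError("applied displacement is zero; stiffness undefined")
    return abs(_axial_reaction(sol, bc)) / bc.applied_displacement


def failure_load(
    sol: FESolution, bc: BoundaryConditions,
    crit: FailureCriterion = FailureCriterion(),
    exclude_bc_nodes: bool = False,
) -> float:
    """Scale the linear solution until ``node_fraction`` of the nodes reach
    the critical compressive strain.

    Rank rule: with nodal e3 sorted ascending (most compressive first), the
    r-th node with r = max(1, floor(fraction·N)) sets the scale
    λ = critical_e3 / e3_(r); Fu = λ·|axial reaction|.  All nodes are
    counted by default; ``exclude_bc_nodes`` drops the fixed and driven
    surface nodes from the count.
    """
    e3_field = sol.nodal_e3
    if exclude_bc_nodes:
        keep = np.ones(len(e3_field), dtype=bool)
        keep[bc.fixed_nodes] = False
        keep[bc.driven_nodes] = False
        e3_field = e3_field[keep]
        if len(e3_field) == 0:
            raise ValueError("no nodes left after excluding BC surfaces")
    e3 = np.sort(e3_field)  # ascending: most compressive first
    n = len(e3)
    r = max(1, int(np.floor(crit.node_fraction * n)))
    eps_star = float(e3[r - 1])
    if eps_star >= 0:
        raise ValueError(
            f"fewer than {crit.node_fraction:.0%} of nodes are in compression "
            f"(rank-{r} e3 = {eps_star:g}); failure load undefined"
        )
    lam = crit.critical_e3 / eps_star
    return lam * abs(_axial_reaction(sol, bc))


def normalize_outcomes(S: float, Fu: float, bmc: BMCReport) -> OutcomeSet:
    """Divide stiffness and failure load by total BMC (mg)."""
    if not bmc.total_bmc > 0:
        raise ValueError("total BMC must be positive to normalize")
    return OutcomeSet(
        stiffness=float(S),
        failure_load=float(Fu),
        total_bmc=float(bmc.total_bmc),
        stiffness_norm=float(S) / bmc.total_bmc,
        failure_load_norm=float(Fu) / bmc.total_bmc,
    )


def strain_histogram(sol: FESolution, n_bins: int = 100, range=None):
    """Frequency tables of nodal first and third principal strains.

    Returns a dict with ``edges`` (n_bins+1,) and per-channel counts
    (each summing to the node count).  ``range`` defaults to the combined
    min/max of e1 and e3.
    """
    e1, e3 = sol.nodal_e1, sol.nodal_e3
    if range is None:
        lo = float(min(e1.min(), e3.min()))
        hi = float(max(e1.max(), e3.max()))
        if hi <= lo:
            hi = lo + 1e-12
        range = (lo, hi)
    c1, edges = np.histogram(e1, bins=n_bins, range=range)
    c3, _ = np.histogram(np.clip(e3, range[0], range[1]), bins=n_bins, range=range)
    # np.histogram drops out-of-range values; clip both so counts conserve
    c1, _ = np.histogram(np.clip(e1, range[0], range[1]), bins=n_bins, range=range)
    return {"edges": edges, "e1_counts": c1, "e3_counts": c3}
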