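"""Forward sensitivities of the cascade states.

The flux space is parameterized by null-space coordinates u with
v = v0 + N u (N an orthonormal basis of the stoichiometric null space over
balanced metabolites); pool sizes of the metabolites present in the pruned
network are the remaining parameters.  Implicit differentiation of the
isotope balance C dx/dt = g(x, v) gives, for each parameter theta,

    d/dt (dx/dtheta) = J_x(x) dx/dtheta + df/dtheta,

with df/du_j obtained by evaluating the flux-linear right-hand side at the
basis column N[:, j], and df/dC_m = -f(x)/C_m on the rows of metabolite m.
All sensitivity blocks start at zero.  The augmented system keeps the
block-cascade structure of the base system, so the same integrators (serial
or parallel) apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import MetabolicModel, ModelError, free_flux_dimension
from .ode_assembly import CascadeSystem

__all__ = ["Parameterization", "build_parameterization", "extend_with_sensitivities", "AugmentedCascade"]


@dataclass
class Parameterization:
    """Free-flux basis and free pool-size list of one assembled system."""

    free_flux_basis: np.ndarray  # (n_reactions, n_free)
    free_pools: list[str]  # metabolites of the pruned network

    @property
    def n_free_fluxes(self) -> int:
        return self.free_flux_basis.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.n_free_fluxes + len(self.free_pools)

    @property
    def names(self) -> list[str]:
        return [f"u{j}" for j in range(self.n_free_fluxes)] + [
            f"pool:{m}" for m in self.free_pools
        ]


def build_parameterization(
    model: MetabolicModel, pruned_metabolites: list[str] | None = None
) -> Parameterization:
    """Null-space flux basis plus the pool sizes that the pruned network
    actually touches (metabolites outside the traced network do not enter
    the measured MIDs and carry no identifiable pool sensitivity)."""
    dim, basis = free_flux_dimension(model)
    if dim == 0:
        raise ModelError("fluxes fully determined: zero-dimensional null space")
    if pruned_metabolites is None:
        pruned_metabolites = model.balanced_metabolites()
    return Parameterization(free_flux_basis=basis, free_pools=sorted(pruned_metabolites))


class AugmentedCascade:
    """Base cascade plus one sensitivity block per parameter.

    State layout: ``[x, s_1, ..., s_P]`` with every block of length
    ``base.dim``.  Block i of the augmented system stacks block i of the
    base state with block i of every sensitivity, which preserves the
    parent-before-child dependency structure.
    """

    def __init__(self, base: CascadeSystem, params: Parameterization):
        self.base = base
        self.params = params
        self.n_blocks = base.n_blocks
        self.n = base.dim
        self.dim = base.dim * (1 + params.n_parameters)
        # flux-direction forcings: structural terms bound to basis columns
        self._flux_dirs = [
            base.numeric_for(params.free_flux_basis[:, j])
            for j in range(params.n_free_fluxes)
        ]
        self._pool_masks = []
        for m in params.free_pools:
            rows = base.met_rows.get(m, np.array([], dtype=int))
            mask = np.zeros(base.dim)
            mask[rows] = 1.0
            self._pool_masks.append((m, mask, base.model.pool_sizes[m]))

    # -- integrator surface (mirrors CascadeSystem) -------------------------
    def initial_state(self) -> np.ndarray:
        x = np.zeros(self.dim)
        x[: self.n] = self.base.initial_state()
        return x  # sensitivity blocks start at zero

    def block_parents(self, i: int) -> list[int]:
        return self.base.block_parents(i)

    def block_indices(self, i: int) -> np.ndarray:
        sl = self.base.block_slices[i]
        own = np.arange(sl.start, sl.stop)
        return np.concatenate(
            [own + p * self.n for p in range(1 + self.params.n_parameters)]
        )

    def block_rhs(self, i: int, X: np.ndarray) -> np.ndarray:
        x = X[: self.n]
        f = self.base.block_rhs(i, x)
        sl = self.base.block_slices[i]
        parts = [f]
        P = self.params.n_parameters
        nf = self.params.n_free_fluxes
        for p in range(P):
            s = X[(1 + p) * self.n : (2 + p) * self.n]
            d = self.base._numeric.block_rhs_dir(i, x, s)
            if p < nf:
                d = d + self._flux_dirs[p].block_rhs(i, x)
            else:
                _, mask, pool = self._pool_masks[p - nf]
                d = d - mask[sl] * f / pool
            parts.append(d)
        return np.concatenate(parts)

    def rhs(self, X: np.ndarray, t: float = 0.0) -> np.ndarray:
        out = np.empty(self.dim)
        for i in range(self.n_blocks):
            out[self.block_indices(i)] = self.block_rhs(i, X)
        return out

    # -- labeling -----------------------------------------------------------
    def row_labels(self) -> list[dict]:
        base_labels = self.base.row_labels()
        out = []
        names = ["state"] + self.params.names
        for pname in names:
            for lab in base_labels:
                out.append({**lab, "parameter": pname})
        return out

    def sensitivity_block(self, X: np.ndarray, param_index: int) -> np.ndarray:
        return X[(1 + param_index) * self.n : (2 + param_index) * self.n]


def extend_with_sensitivities(
    system: CascadeSystem, params: Parameterization | None = None
) -> AugmentedCascade:
    """Augment an assembled cascade with forward sensitivity equations."""
    if params is None:
        params = build_parameterization(
            system.model, pruned_metabolites=sorted(system.met_rows)
        )
    return AugmentedCascade(system, params)
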