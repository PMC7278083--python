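"""Per-SCC isotope balance ODEs in tensor and vector form.

For every retained mass isotopomer x = m_w of an EMU of metabolite P with
pool size C_P, the balance reads

    C_P dx/dt = sum_prod v_p * (production into x)  -  (sum_cons v_c) * x

where production terms enumerate the weight compositions of the producing
EMU reactions (a convolution of reactant mass isotopomer distributions,
substrate MIDs entering as constants) and the consumption sum runs over all
reactions consuming P.  Two interchangeable right-hand-side backends are
assembled from the same structural terms:

* ``tensor`` — explicit sparse 0/1 transition-tensor entries, one scalar
  product per nonzero entry (analogous to cumomer-style tensor updates);
* ``vector`` — a sparse linear matrix for all single-molecule transitions
  plus explicit MID convolutions for multi-molecule transitions (the
  EMU-block style).  This is the default; it is the faster of the two.

Both are exact; they differ only in summation organization, which the test
suite exploits as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import reduce
from itertools import product as iterproduct

import numpy as np
import scipy.sparse as sp

from .emu_decomposition import EMU, EMUReaction, EMUReactionNetwork
from .misotope_graph import MassIsotopomerNode, SCCPartition
from .network_model import MetabolicModel, ModelError

__all__ = [
    "convolve_mid",
    "build_transition_tensor",
    "build_eliminating_matrix",
    "assemble",
    "rhs",
    "CascadeSystem",
]


def convolve_mid(a, b):
    """MID convolution: c_w = sum_{u+v=w} a_u b_v."""
    return np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def build_transition_tensor(reaction: EMUReaction) -> dict[tuple, int]:
    """Sparse 0/1 transition tensor of one EMU reaction.

    Keys are index tuples (w_1, ..., w_n, w_P) over the mass isotopomer
    weights of the n reactant EMUs and the product EMU; the entry is 1
    exactly when the reactant mass isotopomers join to make the product
    mass isotopomer (weights add).  For fixed reactant indices at most one
    product index is set.
    """
    entries: dict[tuple, int] = {}
    ranges = [range(e.size + 1) for e in reaction.reactant_emus]
    for weights in iterproduct(*ranges):
        entries[(*weights, sum(weights))] = 1
    return entries


def build_eliminating_matrix(scc_members, reaction) -> np.ndarray:
    """Diagonal eliminating matrix of one reaction over one SCC block:
    -1 on the diagonal where the reaction consumes that mass isotopomer's
    metabolite, 0 elsewhere."""
    consumed = set(reaction.reactant_instances)
    diag = [-1.0 if n.emu.metabolite in consumed else 0.0 for n in scc_members]
    return np.diag(diag)


# ---------------------------------------------------------------------------
# Structural terms
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    """One reactant slot of a production term: a dynamic EMU gathered from
    the state, or a constant substrate MID."""

    const: np.ndarray | None  # substrate MID, or None for dynamic
    size: int
    gather_pos: np.ndarray | None = None  # weights with retained nodes
    gather_idx: np.ndarray | None = None  # their global state indices


@dataclass
class _ConvTerm:
    """Multi-reactant production term: flux * conv(slot vectors),
    scattered onto the retained product mass isotopomers."""

    r_idx: int
    base: float  # symmetry-alternative weight
    slots: list[_Slot]
    # per product block: [(product weight, local row)]
    scatter: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def gather(self, x: np.ndarray) -> list[np.ndarray]:
        vecs = []
        for s in self.slots:
            if s.const is not None:
                vecs.append(s.const)
            else:
                v = np.zeros(s.size + 1)
                v[s.gather_pos] = x[s.gather_idx]
                vecs.append(v)
        return vecs

    def gather_dir(self, x: np.ndarray, sdir: np.ndarray, k: int) -> list[np.ndarray]:
        """Slot vectors with dynamic slot k gathered from ``sdir`` instead
        of ``x`` (product rule for the Jacobian action)."""
        vecs = self.gather(x)
        s = self.slots[k]
        v = np.zeros(s.size + 1)
        v[s.gather_pos] = sdir[s.gather_idx]
        vecs[k] = v
        return vecs


@dataclass
class _TensorEntry:
    r_idx: int
    coef: float  # symmetry weight times constant input factors
    dyn_idx: tuple[int, ...]  # global state indices of dynamic factors
    row: int  # local row within the block


class CascadeSystem:
    """Assembled right-hand side of the SCC cascade.

    Exposes a blockwise evaluation surface (``block_rhs``) used by the
    serial and parallel integrators — the full ``rhs`` is the fixed-order
    concatenation of the per-block evaluations, so a scheduler that honors
    the block dependencies reproduces the serial result bit for bit.
    """

    def __init__(
        self,
        partition: SCCPartition,
        network: EMUReactionNetwork,
        model: MetabolicModel,
        backend: str = "vector",
    ):
        if backend not in ("vector", "tensor"):
            raise ValueError(f"unknown backend {backend!r}")
        self.partition = partition
        self.network = network
        self.model = model
        self.backend = backend

        self.nodes: list[MassIsotopomerNode] = [
            n for scc in partition.sccs for n in scc.members
        ]
        self.node_index = {n: i for i, n in enumerate(self.nodes)}
        self.dim = len(self.nodes)
        self.block_slices: list[slice] = []
        start = 0
        for scc in partition.sccs:
            self.block_slices.append(slice(start, start + scc.size))
            start += scc.size
        self.n_blocks = len(partition.sccs)

        # pool sizes per state row
        pools = []
        for n in self.nodes:
            met = n.emu.metabolite
            if met not in model.pool_sizes:
                raise ModelError(f"missing pool size for metabolite {met}")
            pools.append(model.pool_sizes[met])
        self.pool = np.array(pools)
        self.inv_pool = 1.0 / self.pool
        self.flux_vector = np.array([r.flux_value for r in model.reactions])
        self._r_index = {r.id: j for j, r in enumerate(model.reactions)}

        # rows of each metabolite (for pool-size sensitivities)
        self.met_rows: dict[str, np.ndarray] = {}
        for i, n in enumerate(self.nodes):
            self.met_rows.setdefault(n.emu.metabolite, [])
            self.met_rows[n.emu.metabolite].append(i)
        self.met_rows = {m: np.array(ix) for m, ix in self.met_rows.items()}

        self._build_structure()
        self._numeric = self.numeric_for(self.flux_vector)

    # -- structure ---------------------------------------------------------
    def _gather_slot(self, emu: EMU) -> _Slot:
        if emu in set(self.network.input_emus):
            return _Slot(const=np.array(self.network.input_mid(emu)), size=emu.size)
        pos, idx = [], []
        for w in range(emu.size + 1):
            gi = self.node_index.get(MassIsotopomerNode(emu, w))
            if gi is not None:
                pos.append(w)
                idx.append(gi)
        return _Slot(const=None, size=emu.size, gather_pos=np.array(pos, dtype=int),
                     gather_idx=np.array(idx, dtype=int))

    def _build_structure(self) -> None:
        node_block = {}
        for bi, sl in enumerate(self.block_slices):
            for li, n in enumerate(self.nodes[sl]):
                node_block[n] = (bi, li)

        # linear terms (row, col, r_idx, coef); constant terms (row, r_idx, coef)
        lin: list[tuple[int, int, int, float]] = []
        const: list[tuple[int, int, float]] = []
        conv_terms: list[_ConvTerm] = []

        # consumption: every reaction consuming the metabolite eliminates
        # each of its mass isotopomers, once per reactant instance
        for i, n in enumerate(self.nodes):
            met = n.emu.metabolite
            for rx in self.model.consumed_by(met):
                count = rx.reactant_instances.count(met)
                lin.append((i, i, self._r_index[rx.id], -float(count)))

        inputs = set(self.network.input_emus)
        for er in self.network.reactions:
            r_idx = self._r_index[er.reaction_id]
            retained = {
                w: self.node_index[MassIsotopomerNode(er.product_emu, w)]
                for w in range(er.product_emu.size + 1)
                if MassIsotopomerNode(er.product_emu, w) in self.node_index
            }
            if not retained:
                continue
            if len(er.reactant_emus) == 1:
                remu = er.reactant_emus[0]
                if remu in inputs:
                    mid = self.network.input_mid(remu)
                    for w, row in retained.items():
                        const.append((row, r_idx, er.weight * mid[w]))
                else:
                    for w, row in retained.items():
                        src = self.node_index.get(MassIsotopomerNode(remu, w))
                        if src is not None:
                            lin.append((row, src, r_idx, er.weight))
                continue
            slots = [self._gather_slot(e) for e in er.reactant_emus]
            if all(s.const is not None for s in slots):
                c = reduce(np.convolve, [s.const for s in slots])
                for w, row in retained.items():
                    const.append((row, r_idx, er.weight * c[w]))
                continue
            term = _ConvTerm(r_idx=r_idx, base=er.weight, slots=slots)
            for w, row in retained.items():
                bi, li = node_block[self.nodes[row]]
                term.scatter.setdefault(bi, []).append((w, li))
            conv_terms.append(term)

        self._lin = lin
        self._const = const
        self._conv = conv_terms
        self._dyn_slots = [
            [k for k, s in enumerate(t.slots) if s.const is None] for t in conv_terms
        ]

        if self.backend == "tensor":
            self._build_tensor_entries(node_block)

    def _build_tensor_entries(self, node_block) -> None:
        """Expand every term into explicit transition-tensor entries."""
        entries: list[list[_TensorEntry]] = [[] for _ in range(self.n_blocks)]
        for row, col, r_idx, coef in self._lin:
            bi, li = node_block[self.nodes[row]]
            entries[bi].append(_TensorEntry(r_idx, coef, (col,), li))
        for row, r_idx, coef in self._const:
            bi, li = node_block[self.nodes[row]]
            entries[bi].append(_TensorEntry(r_idx, coef, (), li))
        for term in self._conv:
            ranges = [range(s.size + 1) for s in term.slots]
            scatter = {}
            for bi, pairs in term.scatter.items():
                for w, li in pairs:
                    scatter[w] = (bi, li)
            for weights in iterproduct(*ranges):
                w = sum(weights)
                if w not in scatter:
                    continue
                coef = term.base
                dyn = []
                dead = False
                for s, wk in zip(term.slots, weights):
                    if s.const is not None:
                        coef *= s.const[wk]
                    else:
                        hit = np.nonzero(s.gather_pos == wk)[0]
                        if hit.size == 0:
                            dead = True  # pruned reactant node: term vanishes
                            break
                        dyn.append(int(s.gather_idx[hit[0]]))
                if dead or coef == 0.0:
                    continue
                bi, li = scatter[w]
                entries[bi].append(_TensorEntry(term.r_idx, coef, tuple(dyn), li))
        self._tensor_entries = entries

    # -- numeric assembly --------------------------------------------------
    def numeric_for(self, flux: np.ndarray) -> "_Numeric":
        """Bind the structural terms to a flux vector.  The right-hand side
        is linear in the fluxes, so binding to a null-space basis column
        yields the flux-direction forcing used by the sensitivities."""
        return _Numeric(self, np.asarray(flux, dtype=float))

    # -- evaluation (model fluxes) ------------------------------------------
    def initial_state(self) -> np.ndarray:
        """Naturally unlabeled start: every EMU entirely at weight 0."""
        x = np.zeros(self.dim)
        for i, n in enumerate(self.nodes):
            if n.weight == 0:
                x[i] = 1.0
        return x

    def block_parents(self, i: int) -> list[int]:
        return self.partition.parents_of(i)

    def block_indices(self, i: int) -> np.ndarray:
        sl = self.block_slices[i]
        return np.arange(sl.start, sl.stop)

    def row_labels(self) -> list[dict]:
        return [
            {
                "metabolite": n.emu.metabolite,
                "emu_atoms": "".join(map(str, n.emu.atoms)),
                "weight": n.weight,
            }
            for n in self.nodes
        ]

    def emu_rows(self) -> dict[EMU, tuple[np.ndarray, np.ndarray]]:
        """Per non-input EMU: (weights, global row indices) retained in the
        state (complete EMUs have size+1 rows)."""
        out: dict[EMU, tuple[list, list]] = {}
        for i, n in enumerate(self.nodes):
            out.setdefault(n.emu, ([], []))
            out[n.emu][0].append(n.weight)
            out[n.emu][1].append(i)
        return {e: (np.array(w), np.array(ix)) for e, (w, ix) in out.items()}

    def block_rhs(self, i: int, x: np.ndarray) -> np.ndarray:
        return self._numeric.block_rhs(i, x)

    def rhs(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Full derivative: fixed-order concatenation of block evaluations."""
        out = np.empty(self.dim)
        for i in range(self.n_blocks):
            out[self.block_slices[i]] = self._numeric.block_rhs(i, x)
        return out

    def rhs_dir(self, x: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Action of the state Jacobian at ``x`` on direction ``s``."""
        out = np.empty(self.dim)
        for i in range(self.n_blocks):
            out[self.block_slices[i]] = self._numeric.block_rhs_dir(i, x, s)
        return out

    def internal_matrix(self, i: int) -> np.ndarray:
        """Dense square internal matrix M_i of block i: single-molecule
        transitions within the block plus all consumption, scaled by the
        inverse pool sizes.  Its spectrum governs the block's stiffness."""
        sl = self.block_slices[i]
        n_i = sl.stop - sl.start
        M = np.zeros((n_i, n_i))
        for row, col, r_idx, coef in self._lin:
            if sl.start <= row < sl.stop and sl.start <= col < sl.stop:
                M[row - sl.start, col - sl.start] += self.flux_vector[r_idx] * coef
        return M * self.inv_pool[sl][:, None]

    # -- serialization ------------------------------------------------------
    def bundle(self) -> dict:
        """JSON-serializable description of the assembled system."""
        return {
            "backend": self.backend,
            "nodes": [str(n) for n in self.nodes],
            "blocks": [
                {
                    "weight": scc.weight,
                    "topo_index": scc.topo_index,
                    "members": [str(n) for n in scc.members],
                }
                for scc in self.partition.sccs
            ],
            "linear": [
                [row, col, self.model.reactions[r_idx].id, coef]
                for row, col, r_idx, coef in self._lin
            ],
            "constant": [
                [row, self.model.reactions[r_idx].id, coef]
                for row, r_idx, coef in self._const
            ],
            "convolutions": [
                {
                    "reaction": self.model.reactions[t.r_idx].id,
                    "weight": t.base,
                    "arity": len(t.slots),
                }
                for t in self._conv
            ],
            "pool_sizes": dict(zip([str(n) for n in self.nodes], self.pool.tolist())),
        }

    def save_bundle(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.bundle(), fh, indent=1)


class _Numeric:
    """Structural terms bound to a concrete flux vector."""

    def __init__(self, system: CascadeSystem, flux: np.ndarray):
        self.system = system
        self.flux = flux
        n = system.dim
        rows = np.array([t[0] for t in system._lin], dtype=int)
        cols = np.array([t[1] for t in system._lin], dtype=int)
        data = np.array([flux[t[2]] * t[3] for t in system._lin])
        A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        b = np.zeros(n)
        for row, r_idx, coef in system._const:
            b[row] += flux[r_idx] * coef
        self._A_blocks = [A[sl] for sl in system.block_slices]
        self._b_blocks = [b[sl] for sl in system.block_slices]
        self._conv_coef = [flux[t.r_idx] * t.base for t in system._conv]
        # conv terms touching each block
        self._conv_by_block: list[list[int]] = [[] for _ in range(system.n_blocks)]
        for ti, term in enumerate(system._conv):
            for bi in term.scatter:
                self._conv_by_block[bi].append(ti)

    def block_rhs(self, i: int, x: np.ndarray) -> np.ndarray:
        sys_ = self.system
        if sys_.backend == "tensor":
            return self._block_rhs_tensor(i, x)
        out = self._A_blocks[i] @ x + self._b_blocks[i]
        for ti in self._conv_by_block[i]:
            term = sys_._conv[ti]
            c = reduce(np.convolve, term.gather(x))
            coef = self._conv_coef[ti]
            for w, li in term.scatter[i]:
                out[li] += coef * c[w]
        return out * sys_.inv_pool[sys_.block_slices[i]]

    def _block_rhs_tensor(self, i: int, x: np.ndarray) -> np.ndarray:
        sys_ = self.system
        sl = sys_.block_slices[i]
        out = np.zeros(sl.stop - sl.start)
        for e in sys_._tensor_entries[i]:
            val = self.flux[e.r_idx] * e.coef
            for gi in e.dyn_idx:
                val *= x[gi]
            out[e.row] += val
        return out * sys_.inv_pool[sl]

    def block_rhs_dir(self, i: int, x: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Jacobian action restricted to block i (product rule over the
        dynamic factors of every term)."""
        sys_ = self.system
        if sys_.backend == "tensor":
            sl = sys_.block_slices[i]
            out = np.zeros(sl.stop - sl.start)
            for e in sys_._tensor_entries[i]:
                base = self.flux[e.r_idx] * e.coef
                for k in range(len(e.dyn_idx)):
                    val = base
                    for l, gi in enumerate(e.dyn_idx):
                        val *= s[gi] if l == k else x[gi]
                    out[e.row] += val
            return out * sys_.inv_pool[sl]
        out = self._A_blocks[i] @ s
        for ti in self._conv_by_block[i]:
            term = sys_._conv[ti]
            coef = self._conv_coef[ti]
            for k in sys_._dyn_slots[ti]:
                c = reduce(np.convolve, term.gather_dir(x, s, k))
                for w, li in term.scatter[i]:
                    out[li] += coef * c[w]
        return out * sys_.inv_pool[sys_.block_slices[i]]

    def rhs(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(self.system.dim)
        for i in range(self.system.n_blocks):
            out[self.system.block_slices[i]] = self.block_rhs(i, x)
        return out


def assemble(
    partition: SCCPartition,
    network: EMUReactionNetwork,
    model: MetabolicModel,
    backend: str = "vector",
) -> CascadeSystem:
    """Build the per-SCC right-hand-side evaluator for the given backend."""
    return CascadeSystem(partition, network, model, backend=backend)


def rhs(system: CascadeSystem, state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Derivative of the full cascade state at time ``t``."""
    return system.rhs(state, t)
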