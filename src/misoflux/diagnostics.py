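"""Stability, stiffness and correctness diagnostics.

Contains the spectral/stiffness analysis of the per-SCC internal matrices,
an algebraic stationary-state solver (the t -> infinity oracle), a
brute-force positional-isotopomer reference integrator that bypasses the
EMU/SCC machinery entirely, and conservation reporting along trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate

from .emu_decomposition import EMU, EMUReactionNetwork
from .network_model import MetabolicModel, ModelError
from .ode_assembly import CascadeSystem

__all__ = [
    "StiffnessResult",
    "stiffness_ratio",
    "spectral_check",
    "stationary_solution",
    "IsotopomerOracle",
    "isotopomer_oracle",
    "conservation_report",
]


# ---------------------------------------------------------------------------
# Spectra and stiffness
# ---------------------------------------------------------------------------

@dataclass
class StiffnessResult:
    eigenvalues: np.ndarray
    ratio: float
    defined: bool


def stiffness_ratio(M: np.ndarray) -> StiffnessResult:
    """max|Re lambda| / min|Re lambda| of a square matrix; flagged as
    undefined when the minimal real part is (numerically) zero."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("stiffness ratio needs a square matrix")
    eig = np.linalg.eigvals(M)
    re = np.abs(eig.real)
    lo = re.min()
    if lo <= 1e-14 * max(1.0, re.max()):
        return StiffnessResult(eig, np.inf, defined=False)
    return StiffnessResult(eig, float(re.max() / lo), defined=True)


@dataclass
class SpectralReport:
    per_block: list[StiffnessResult]
    nonnegative_blocks: list[int]  # blocks with any Re lambda >= 0
    max_ratio: float

    @property
    def stable(self) -> bool:
        return not self.nonnegative_blocks


def spectral_check(system: CascadeSystem, tol: float = 1e-12) -> SpectralReport:
    """Eigenvalues of every SCC internal matrix M_i; for flux-balanced
    models with outflow all real parts should be strictly negative
    (imaginary parts are reported, never assumed zero)."""
    results = []
    flagged = []
    max_ratio = 1.0
    for i in range(system.n_blocks):
        res = stiffness_ratio(system.internal_matrix(i))
        results.append(res)
        if np.any(res.eigenvalues.real >= -tol):
            flagged.append(i)
        if res.defined:
            max_ratio = max(max_ratio, res.ratio)
    return SpectralReport(results, flagged, max_ratio)


# ---------------------------------------------------------------------------
# Stationary (t -> infinity) EMU solution
# ---------------------------------------------------------------------------

def stationary_solution(network: EMUReactionNetwork) -> dict[EMU, np.ndarray]:
    """Algebraic steady state of the EMU balances, solved size by size.

    At isotopic steady state the balance of every non-input EMU reads
    (sum of consuming fluxes) * MID = sum over producing EMU reactions of
    flux * convolution of reactant MIDs.  Multi-reactant terms only involve
    strictly smaller EMUs, so ascending over EMU sizes leaves one linear
    solve per size, coupling same-size EMUs through unimolecular reactions.
    """
    model = network.model
    mids: dict[EMU, np.ndarray] = {}
    for emu in network.input_emus:
        mids[emu] = np.array(network.input_mid(emu))
    by_size: dict[int, list[EMU]] = {}
    for emu in network.non_input_emus():
        by_size.setdefault(emu.size, []).append(emu)
    for size in sorted(by_size):
        emus = sorted(by_size[size])
        index = {e: i for i, e in enumerate(emus)}
        k = len(emus)
        A = np.zeros((k, k))
        B = np.zeros((k, size + 1))
        for e in emus:
            i = index[e]
            cons = sum(
                rx.flux_value * rx.reactant_instances.count(e.metabolite)
                for rx in model.consumed_by(e.metabolite)
            )
            A[i, i] += cons
            for er in network.producers_of(e):
                v = model.reaction(er.reaction_id).flux_value * er.weight
                if len(er.reactant_emus) == 1 and er.reactant_emus[0] in index:
                    A[i, index[er.reactant_emus[0]]] -= v
                else:
                    conv = np.array([1.0])
                    for remu in er.reactant_emus:
                        conv = np.convolve(conv, mids[remu])
                    B[i] += v * conv
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ModelError(
                f"singular stationary balance for size-{size} EMU block "
                f"({', '.join(map(str, emus))})"
            ) from exc
        for e in emus:
            mids[e] = X[index[e]]
    return mids


# ---------------------------------------------------------------------------
# Brute-force positional isotopomer oracle
# ---------------------------------------------------------------------------

class IsotopomerOracle:
    """Reference integrator over every positional isotopomer.

    Tracks all 2^n isotopomer fractions of every balanced metabolite
    directly from the atom maps — no EMU tracing, no SCC machinery — and
    marginalizes to the MID of any requested EMU.  Guarded to small
    networks (total isotopomer count <= 10_000).
    """

    GUARD = 10_000

    def __init__(self, model: MetabolicModel):
        model.validate()
        self.model = model
        self.mets = model.balanced_metabolites()
        counts = [2 ** model.carbon_counts[m] for m in self.mets]
        if sum(counts) > self.GUARD:
            raise ModelError(
                f"isotopomer count {sum(counts)} exceeds oracle guard {self.GUARD}"
            )
        self.offsets = {}
        off = 0
        for m, c in zip(self.mets, counts):
            self.offsets[m] = off
            off += c
        self.dim = off
        self._compile()

    def _substrate_dist(self, met: str) -> np.ndarray:
        n = self.model.carbon_counts[met]
        x = np.zeros(2**n)
        for pattern, frac in self.model.substrate_labeling[met].items():
            x[int(pattern, 2)] += frac
        return x

    def _compile(self) -> None:
        """Precompute production routes: per (reaction, alternative,
        product instance of a balanced metabolite), the list of reactant
        factors (metabolite or substrate distribution, plus the map from
        product atom positions to reactant atom positions)."""
        self.routes = []
        balanced = set(self.mets)
        for rx in self.model.reactions:
            for tr in rx.transitions:
                weight = rx.flux_value / len(rx.transitions)
                if weight == 0.0:
                    continue
                for pi, pmet in enumerate(rx.product_instances):
                    if pmet not in balanced:
                        continue
                    n = self.model.carbon_counts[pmet]
                    factors = []  # (reactant met, [(prod_pos, reac_pos)])
                    per_reactant: dict[int, list[tuple[int, int]]] = {}
                    for a in range(1, n + 1):
                        ri, pos = tr.atom_origin(pi, a)
                        per_reactant.setdefault(ri, []).append((a, pos))
                    for ri, pairs in sorted(per_reactant.items()):
                        factors.append((rx.reactant_instances[ri], pairs))
                    self.routes.append((pmet, weight, factors))
        self.consumption = {
            m: sum(
                rx.flux_value * rx.reactant_instances.count(m)
                for rx in self.model.consumed_by(m)
            )
            for m in self.mets
        }

    def _marginal(self, dist: np.ndarray, n: int, positions: list[int]) -> np.ndarray:
        """Marginal distribution over the given 1-based atom positions."""
        out = np.zeros(2 ** len(positions))
        for q in range(dist.size):
            if dist[q] == 0.0:
                continue
            bits = 0
            for j, p in enumerate(positions):
                if q >> (n - p) & 1:
                    bits |= 1 << (len(positions) - 1 - j)
            out[bits] += dist[q]
        return out

    def _met_dist(self, x: np.ndarray, met: str) -> np.ndarray:
        if met in self.offsets:
            off = self.offsets[met]
            return x[off : off + 2 ** self.model.carbon_counts[met]]
        if self.model.is_substrate(met):
            return self._substrate_dist(met)
        raise ModelError(f"metabolite {met} is neither balanced nor a substrate")

    def rhs(self, t, x):
        dx = np.zeros_like(x)
        model = self.model
        for pmet, weight, factors in self.routes:
            n = model.carbon_counts[pmet]
            margs = []
            for rmet, pairs in factors:
                rn = model.carbon_counts[rmet]
                positions = [pos for _, pos in pairs]
                margs.append((pairs, self._marginal(self._met_dist(x, rmet), rn, positions)))
            off = self.offsets[pmet]
            for p in range(2**n):
                prob = weight
                for pairs, marg in margs:
                    bits = 0
                    for j, (prod_pos, _) in enumerate(pairs):
                        if p >> (n - prod_pos) & 1:
                            bits |= 1 << (len(pairs) - 1 - j)
                    prob *= marg[bits]
                    if prob == 0.0:
                        break
                dx[off + p] += prob
        for m in self.mets:
            off = self.offsets[m]
            c = 2 ** model.carbon_counts[m]
            dx[off : off + c] -= self.consumption[m] * x[off : off + c]
            dx[off : off + c] /= model.pool_sizes[m]
        return dx

    def initial_state(self) -> np.ndarray:
        x = np.zeros(self.dim)
        for m in self.mets:
            x[self.offsets[m]] = 1.0  # index 0 = all-12C pattern
        return x

    def integrate(self, times, rtol=1e-11, atol=1e-13):
        sol = scipy.integrate.solve_ivp(
            self.rhs,
            (0.0, float(max(times))),
            self.initial_state(),
            method="DOP853",
            t_eval=np.asarray(times, dtype=float),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"oracle integration failed: {sol.message}")
        return sol.y.T  # (n_times, dim)

    def mid(self, states: np.ndarray, emu: EMU) -> np.ndarray:
        """MIDs (n_times, size+1) of an EMU from isotopomer states."""
        met = emu.metabolite
        n = self.model.carbon_counts[met]
        if met in self.offsets:
            off = self.offsets[met]
            dist = states[:, off : off + 2**n]
        else:
            d = self._substrate_dist(met)
            dist = np.tile(d, (states.shape[0], 1))
        out = np.zeros((states.shape[0], emu.size + 1))
        for q in range(2**n):
            w = sum((q >> (n - a)) & 1 for a in emu.atoms)
            out[:, w] += dist[:, q]
        return out


def isotopomer_oracle(
    model: MetabolicModel, times, targets: list[EMU]
) -> dict[EMU, np.ndarray]:
    """MIDs of the target EMUs at the given times, computed by the
    brute-force positional-isotopomer reference."""
    oracle = IsotopomerOracle(model)
    states = oracle.integrate(times)
    return {emu: oracle.mid(states, emu) for emu in targets}


# ---------------------------------------------------------------------------
# Conservation reporting
# ---------------------------------------------------------------------------

@dataclass
class ConservationReport:
    mid_sum_deviation: dict[str, float]  # per EMU: max |sum_w m_w - 1|
    sens_sum_deviation: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def max_mid(self) -> float:
        return max(self.mid_sum_deviation.values(), default=0.0)

    @property
    def max_sens(self) -> float:
        return max(self.sens_sum_deviation.values(), default=0.0)

    def worst_emu(self) -> str | None:
        if not self.mid_sum_deviation:
            return None
        return max(self.mid_sum_deviation, key=self.mid_sum_deviation.get)


def conservation_report(trajectory) -> ConservationReport:
    """Max over time of |sum_w m_w - 1| per complete EMU, and of
    |sum_w dm_w/dtheta| per (EMU, parameter) when sensitivities are
    present."""
    system = trajectory.system
    base = getattr(system, "base", system)
    states = trajectory.states
    mid_dev: dict[str, float] = {}
    sens_dev: dict[tuple[str, str], float] = {}
    for emu, (weights, rows) in base.emu_rows().items():
        if len(weights) != emu.size + 1:
            continue  # incomplete EMU after pruning: no closed sum
        sums = states[:, rows].sum(axis=1)
        mid_dev[str(emu)] = float(np.abs(sums - 1.0).max())
        if hasattr(system, "params"):
            n = base.dim
            for p, name in enumerate(system.params.names):
                block = states[:, (1 + p) * n : (2 + p) * n]
                ssum = block[:, rows].sum(axis=1)
                sens_dev[(str(emu), name)] = float(np.abs(ssum).max())
    return ConservationReport(mid_dev, sens_dev)
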