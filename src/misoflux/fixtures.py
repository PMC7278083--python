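"""Packaged toy network and synthetic model generators.

The toy network is the classic 8-reaction demonstration model (metabolites
A..F plus three sinks, two carbon-reversing steps and two condensations).
The generators produce seeded random atom-mapped networks that admit a
strictly positive balanced flux vector, plus flux and pool-size samplers,
so the whole test surface is reproducible without any external model
download.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .network_model import (
    AtomTransition,
    MetabolicModel,
    ModelError,
    Reaction,
    SimulationSettings,
    stoichiometric_matrix,
    free_flux_dimension,
)

__all__ = [
    "toy_model",
    "TOY_FLUXES",
    "TOY_POOLS",
    "GeneratorSpec",
    "sample_flux_distribution",
    "sample_pool_sizes",
    "random_network",
]


# Default experiment attached to the toy network: a consistent balanced
# flux set and pool sizes giving turnover times C/v of about 1-10 s,
# commensurate with the 10 s labeling window of the default settings.
TOY_FLUXES = {
    "V_1": 100.0,
    "V_2": 50.0,
    "V_3": 30.0,
    "V_4": 10.0,
    "V_5": 10.0,
    "V_6": 20.0,
    "V_7": 30.0,
    "V_8": 10.0,
}
TOY_POOLS = {"B": 100.0, "C": 80.0, "D": 60.0, "E": 40.0, "F": 50.0}


def _rxn(rid, reactants, products, rmaps, pmaps):
    return Reaction(
        id=rid,
        reactants=[(m, 1.0) for m in reactants],
        products=[(m, 1.0) for m in products],
        transitions=[AtomTransition(tuple(rmaps), tuple(pmaps))],
    )


def toy_model(
    fluxes: dict[str, float] | None = None,
    pool_sizes: dict[str, float] | None = None,
    labeled_fraction: float = 1.0,
) -> MetabolicModel:
    """The 8-reaction toy network with its default labeling experiment.

    Substrate A enters fully (or partially, ``labeled_fraction``)
    13C-labeled; the whole-molecule MID of F is measured.
    """
    reactions = [
        _rxn("V_1", ["A"], ["B"], ["AB"], ["BA"]),
        _rxn("V_2", ["B"], ["C"], ["AB"], ["AB"]),
        _rxn("V_3", ["B", "C"], ["D"], ["AB", "CD"], ["ABCD"]),
        _rxn("V_4", ["C"], ["E"], ["AB"], ["BA"]),
        _rxn("V_5", ["C", "E"], ["F"], ["AB", "CD"], ["ABCD"]),
        _rxn("V_6", ["B"], ["B_OUT"], ["AB"], ["AB"]),
        _rxn("V_7", ["D"], ["D_OUT"], ["ABCD"], ["ABCD"]),
        _rxn("V_8", ["F"], ["F_OUT"], ["ABCD"], ["ABCD"]),
    ]
    carbon_counts = {
        "A": 2, "B": 2, "C": 2, "D": 4, "E": 2, "F": 4,
        "B_OUT": 2, "D_OUT": 4, "F_OUT": 4,
    }
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ModelError("labeled_fraction must lie in [0, 1]")
    labeling = {"A": {"11": labeled_fraction}}
    if labeled_fraction < 1.0:
        labeling["A"]["00"] = 1.0 - labeled_fraction
    model = MetabolicModel(
        reactions=reactions,
        carbon_counts=carbon_counts,
        pool_sizes=dict(pool_sizes or TOY_POOLS),
        substrate_labeling=labeling,
        measured_targets=[("F", (1, 2, 3, 4))],
        settings=SimulationSettings(),
    )
    for rid, v in (fluxes or TOY_FLUXES).items():
        model.reaction(rid).flux_value = v
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _interior_point(model: MetabolicModel) -> np.ndarray:
    """A strictly positive balanced flux vector (max-min-component LP)."""
    dim, N = free_flux_dimension(model)
    if dim == 0:
        raise ModelError("empty feasible region: fluxes fully determined")
    # maximize t subject to N u >= t, t <= 1  (variables: u, t)
    n_r = N.shape[0]
    c = np.zeros(dim + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-N, np.ones((n_r, 1))])
    b_ub = np.zeros(n_r)
    bounds = [(None, None)] * dim + [(None, 1.0)]
    res = scipy.optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    if not res.success or res.x[-1] <= 1e-9:
        raise ModelError("empty feasible region: no strictly positive balanced flux")
    return N @ res.x[:-1]


def _uptake_reactions(model: MetabolicModel) -> list[str]:
    return [
        r.id
        for r in model.reactions
        if any(model.is_substrate(m) for m in r.reactant_instances)
    ]


def sample_flux_distribution(
    model: MetabolicModel, seed: int, n_burn: int = 200, uptake: float = 10.0
) -> dict[str, float]:
    """One strictly positive balanced flux vector, sampled by hit-and-run
    in the null-space polytope {v = N u, v > 0} and scaled so the total
    substrate uptake equals ``uptake`` (when the model has substrates)."""
    rng = np.random.default_rng(seed)
    _, N = free_flux_dimension(model)
    v = _interior_point(model)
    for _ in range(n_burn):
        d = N @ rng.standard_normal(N.shape[1])
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        d /= nrm
        # keep v + a*d > 0: bounds from each component
        with np.errstate(divide="ignore"):
            ratios = -v / d
        lo = np.max(ratios[d > 0]) if np.any(d > 0) else -np.inf
        hi = np.min(ratios[d < 0]) if np.any(d < 0) else np.inf
        if not (lo < 0.0 < hi) or not np.isfinite([lo, hi]).all():
            continue
        a = rng.uniform(0.9 * lo, 0.9 * hi)
        v = v + a * d
    up = _uptake_reactions(model)
    if up:
        idx = {r.id: j for j, r in enumerate(model.reactions)}
        total = sum(v[idx[r]] for r in up)
        v = v * (uptake / total)
    return {r.id: float(v[j]) for j, r in enumerate(model.reactions)}


def sample_pool_sizes(
    model: MetabolicModel, seed: int, low: float = 1e-6, high: float = 1e-3
) -> dict[str, float]:
    """Log-uniform pool sizes for the balanced metabolites, defaulting to
    the physiological micromolar-to-millimolar range (units: mol per liter
    in the same volume basis as the fluxes)."""
    rng = np.random.default_rng(seed)
    mets = model.balanced_metabolites()
    draws = 10 ** rng.uniform(np.log10(low), np.log10(high), size=len(mets))
    return {m: float(d) for m, d in zip(mets, draws)}


# ---------------------------------------------------------------------------
# Random network generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Conditions for one synthetic atom-mapped network."""

    n_metabolites: int = 6
    max_carbons: int = 4
    bimolecular_fraction: float = 0.3
    seed: int = 0
    pool_range: tuple[float, float] = (1e-6, 1e-3)
    flux_scale: float = 10.0
    retry_limit: int = 50

    def validate(self) -> None:
        if self.n_metabolites < 2 or self.max_carbons < 1:
            raise ModelError("generator spec too small")
        if not 0.0 <= self.bimolecular_fraction <= 1.0:
            raise ModelError("bimolecular_fraction must lie in [0, 1]")


def _random_transition(rng, r_counts: list[int], p_counts: list[int]) -> AtomTransition:
    letters = list(string.ascii_uppercase + string.ascii_lowercase)
    total = sum(r_counts)
    rmaps = []
    pos = 0
    for c in r_counts:
        rmaps.append("".join(letters[pos : pos + c]))
        pos += c
    perm = rng.permutation(total)
    shuffled = [letters[i] for i in perm]
    pmaps = []
    pos = 0
    for c in p_counts:
        pmaps.append("".join(shuffled[pos : pos + c]))
        pos += c
    return AtomTransition(tuple(rmaps), tuple(pmaps))


def _try_generate(spec: GeneratorSpec, rng) -> MetabolicModel:
    carbon_counts: dict[str, int] = {}
    reactions: list[Reaction] = []
    sub = "S0"
    carbon_counts[sub] = int(rng.integers(2, spec.max_carbons + 1))
    available = [sub]
    n_internal = spec.n_metabolites
    rix = 0
    for k in range(n_internal):
        met = f"M{k}"
        bimolecular = (
            len(available) >= 2 and rng.random() < spec.bimolecular_fraction
        )
        if bimolecular:
            picks = list(rng.choice(len(available), size=2, replace=False))
            rmets = [available[p] for p in picks]
        else:
            rmets = [available[int(rng.integers(len(available)))]]
        total = sum(carbon_counts[m] for m in rmets)
        if total > spec.max_carbons and len(rmets) == 2:
            # split into the new metabolite plus a byproduct
            nc = int(rng.integers(1, min(spec.max_carbons, total - 1) + 1))
            by = f"Y{k}"
            carbon_counts[met] = nc
            carbon_counts[by] = total - nc
            pmets = [met, by]
        else:
            carbon_counts[met] = total
            pmets = [met]
        rix += 1
        reactions.append(
            Reaction(
                id=f"R{rix}",
                reactants=[(m, 1.0) for m in rmets],
                products=[(m, 1.0) for m in pmets],
                transitions=[
                    _random_transition(
                        rng,
                        [carbon_counts[m] for m in rmets],
                        [carbon_counts[m] for m in pmets],
                    )
                ],
            )
        )
        available.extend(pmets)
    # sink for every internal metabolite not yet consumed
    consumed = {m for r in reactions for m in r.reactant_instances}
    for m in sorted(set(available) - {sub}):
        if m not in consumed:
            rix += 1
            out = f"{m}_OUT"
            carbon_counts[out] = carbon_counts[m]
            n = carbon_counts[m]
            letters = string.ascii_uppercase[:n]
            reactions.append(
                Reaction(
                    id=f"R{rix}",
                    reactants=[(m, 1.0)],
                    products=[(out, 1.0)],
                    transitions=[AtomTransition((letters,), (letters,))],
                )
            )
    model = MetabolicModel(
        reactions=reactions,
        carbon_counts=carbon_counts,
        substrate_labeling={sub: {"1" * carbon_counts[sub]: 1.0}},
    )
    # measured target: the deepest internal metabolite (whole molecule)
    target = f"M{n_internal - 1}"
    model.measured_targets = [(target, tuple(range(1, carbon_counts[target] + 1)))]
    return model


def random_network(spec: GeneratorSpec) -> MetabolicModel:
    """A seeded random atom-mapped network with at least one labeled input
    and one measured metabolite, admitting strictly positive balanced
    fluxes (rejection with a retry limit)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _ in range(spec.retry_limit):
        try:
            model = _try_generate(spec, rng)
            model.validate()
            fluxes = sample_flux_distribution(
                model, int(rng.integers(2**31)), uptake=spec.flux_scale
            )
            for rid, v in fluxes.items():
                model.reaction(rid).flux_value = v
            lo, hi = spec.pool_range
            model.pool_sizes = sample_pool_sizes(
                model, int(rng.integers(2**31)), low=lo, high=hi
            )
            model.validate()
            return model
        except (ModelError, ValueError) as exc:  # infeasible draw: retry
            last_err = exc
    raise ModelError(f"generation retry limit exceeded: {last_err}")
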