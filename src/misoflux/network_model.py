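"""Atom-mapped metabolic models and simulation parameters.

A model is a set of irreversible reactions with carbon-atom transitions
written in the positional-letter convention (``#AB + #CD -> #ABCD``): each
letter names one carbon atom, letters are unique within one side of a
reaction, and the multiset of letters is conserved across the arrow.
Reversible exchange is expressed as two irreversible reactions.

Models are read from a 3-column TSV (``reaction``, ``stoichiometry``,
``transition``) plus a YAML/JSON parameter document carrying flux values,
pool sizes, substrate labeling, measured targets and integration settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import yaml

__all__ = [
    "AtomTransition",
    "Reaction",
    "MetabolicModel",
    "SimulationSettings",
    "ModelError",
    "parse_model",
    "parse_model_text",
    "write_model_text",
    "write_params_text",
    "load_supplementary_model",
    "stoichiometric_matrix",
    "free_flux_dimension",
    "validate_flux_balance",
]


class ModelError(ValueError):
    """Raised for any structural or parse problem in a model document."""


@dataclass(frozen=True)
class AtomTransition:
    """Carbon transition of one reaction, one symmetry alternative.

    ``reactant_maps``/``product_maps`` hold one position-ordered letter
    string per reactant/product instance; letter k of a product string
    names the reactant atom that carbon position k+1 descends from.
    """

    reactant_maps: tuple[str, ...]
    product_maps: tuple[str, ...]

    def validate(self, reaction_id: str = "?") -> None:
        for side in (self.reactant_maps, self.product_maps):
            letters = "".join(side)
            if len(set(letters)) != len(letters):
                raise ModelError(
                    f"reaction {reaction_id}: duplicate atom letter within one side"
                )
        r = sorted("".join(self.reactant_maps))
        p = sorted("".join(self.product_maps))
        if r != p:
            raise ModelError(
                f"atom conservation violation in reaction {reaction_id}: "
                f"reactant atoms {''.join(r)!r} != product atoms {''.join(p)!r}"
            )

    def atom_origin(self, product_index: int, position: int) -> tuple[int, int]:
        """Map (product instance, 1-based carbon position) to its
        (reactant instance, 1-based position) of origin."""
        letter = self.product_maps[product_index][position - 1]
        for ri, rmap in enumerate(self.reactant_maps):
            j = rmap.find(letter)
            if j >= 0:
                return ri, j + 1
        raise ModelError(f"atom letter {letter!r} has no reactant origin")


@dataclass
class Reaction:
    """One irreversible reaction with >=1 atom-transition alternatives.

    Multiple transitions encode symmetric-molecule alternatives; each
    carries an equal fractional weight 1/n of the flux.
    """

    id: str
    reactants: list[tuple[str, float]]
    products: list[tuple[str, float]]
    transitions: list[AtomTransition]
    flux_value: float = 0.0

    @property
    def reactant_instances(self) -> list[str]:
        return [m for m, _ in self.reactants]

    @property
    def product_instances(self) -> list[str]:
        return [m for m, _ in self.products]

    def validate(self) -> None:
        if not self.transitions:
            raise ModelError(f"reaction {self.id}: no carbon transition")
        for m, c in self.reactants + self.products:
            if c <= 0:
                raise ModelError(f"reaction {self.id}: non-positive coefficient for {m}")
        for tr in self.transitions:
            if len(tr.reactant_maps) != len(self.reactants) or len(
                tr.product_maps
            ) != len(self.products):
                raise ModelError(
                    f"reaction {self.id}: transition arity does not match stoichiometry"
                )
            tr.validate(self.id)


@dataclass
class SimulationSettings:
    """Integration settings (defaults mirror the packaged parameter table)."""

    t_end: float = 10.0
    step: float = 0.005
    lam: int = 10
    tol_scaling: float = 1e-9
    tol_addition: float = 1e-7

    def validate(self) -> None:
        if min(self.t_end, self.step, self.tol_scaling, self.tol_addition) <= 0:
            raise ModelError("all simulation settings must be positive")
        if self.lam < 1:
            raise ModelError("lambda must be >= 1")
        if self.step > self.t_end:
            raise ModelError("step must not exceed t_end")


@dataclass
class MetabolicModel:
    """Atom-mapped network plus the parameters of one labeling experiment.

    ``substrate_labeling`` maps an input metabolite to a distribution over
    positional isotopomer patterns (e.g. ``"11"`` = fully labeled 2-carbon
    molecule).  ``measured_targets`` lists (metabolite, 1-based atom tuple)
    pairs whose mass isotopomer distribution is observed.
    """

    reactions: list[Reaction]
    carbon_counts: dict[str, int]
    pool_sizes: dict[str, float] = field(default_factory=dict)
    substrate_labeling: dict[str, dict[str, float]] = field(default_factory=dict)
    measured_targets: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    # -- classification ---------------------------------------------------
    @property
    def metabolites(self) -> list[str]:
        return sorted(self.carbon_counts)

    def produced_by(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if met in r.product_instances]

    def consumed_by(self, met: str) -> list[Reaction]:
        return [r for r in self.reactions if met in r.reactant_instances]

    def is_substrate(self, met: str) -> bool:
        return met in self.substrate_labeling

    def balanced_metabolites(self) -> list[str]:
        """Intracellular (flux-balanced) metabolites: produced and consumed
        by the network and not a labeled substrate."""
        return sorted(
            m
            for m in self.carbon_counts
            if not self.is_substrate(m)
            and self.produced_by(m)
            and self.consumed_by(m)
        )

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        self.settings.validate()
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate reaction id")
        for r in self.reactions:
            r.validate()
            for m, _ in r.reactants + r.products:
                if m not in self.carbon_counts:
                    raise ModelError(f"reaction {r.id}: undeclared metabolite {m}")
            for tr in r.transitions:
                for (m, _), s in zip(r.reactants, tr.reactant_maps):
                    if len(s) != self.carbon_counts[m]:
                        raise ModelError(
                            f"reaction {r.id}: map {s!r} does not match "
                            f"carbon count {self.carbon_counts[m]} of {m}"
                        )
                for (m, _), s in zip(r.products, tr.product_maps):
                    if len(s) != self.carbon_counts[m]:
                        raise ModelError(
                            f"reaction {r.id}: map {s!r} does not match "
                            f"carbon count {self.carbon_counts[m]} of {m}"
                        )
        for m in self.balanced_metabolites():
            if m in self.pool_sizes and self.pool_sizes[m] <= 0:
                raise ModelError(f"non-positive pool size for {m}")
        for met, dist in self.substrate_labeling.items():
            if met not in self.carbon_counts:
                raise ModelError(f"labeling given for undeclared metabolite {met}")
            n = self.carbon_counts[met]
            total = 0.0
            for pat, frac in dist.items():
                if len(pat) != n or set(pat) - {"0", "1"}:
                    raise ModelError(f"bad isotopomer pattern {pat!r} for {met}")
                total += frac
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ModelError(f"labeling of {met} sums to {total}, not 1")
        for met, atoms in self.measured_targets:
            if met not in self.carbon_counts:
                raise ModelError(f"measured target on undeclared metabolite {met}")
            if any(a < 1 or a > self.carbon_counts[met] for a in atoms):
                raise ModelError(f"measured atoms {atoms} out of range for {met}")


# ---------------------------------------------------------------------------
# TSV / parameter parsing
# ---------------------------------------------------------------------------

_ARROWS = ("->", "- >", "=>", "→")


def _split_arrow(text: str, lineno: int) -> tuple[str, str]:
    for arrow in _ARROWS:
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            return lhs.strip(), rhs.strip()
    raise ModelError(f"line {lineno}: no arrow in {text!r}")


def _parse_side(side: str) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 2 and parts[0].replace(".", "", 1).isdigit():
            coeff, met = float(parts[0]), parts[1]
        else:
            coeff, met = 1.0, term
        # expand integer coefficients into per-instance entries so that the
        # transition strings align one map per molecule instance
        if coeff == int(coeff) and coeff > 1:
            out.extend((met, 1.0) for _ in range(int(coeff)))
        else:
            out.append((met, coeff))
    return out


def _parse_maps(side: str) -> tuple[str, ...]:
    return tuple(t.strip().lstrip("#") for t in side.split("+") if t.strip())


def parse_model_text(model_text: str, params_text: str | None = None) -> MetabolicModel:
    """Parse the TSV model dialect (and optional YAML/JSON parameters)."""
    reactions: list[Reaction] = []
    carbon_counts: dict[str, int] = {}
    lines = model_text.splitlines()
    start = 0
    if lines and lines[0].strip().lower().startswith("reaction"):
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.strip()
        if not line or line.startswith("#!"):
            continue
        cols = [c.strip() for c in raw.split("\t")]
        if len(cols) < 3:
            raise ModelError(f"line {lineno}: expected 3 tab-separated columns")
        rid, stoich, transition = cols[0], cols[1], cols[2]
        lhs, rhs = _split_arrow(stoich, lineno)
        reactants = _parse_side(lhs)
        products = _parse_side(rhs)
        transitions = []
        for alt in transition.split("|"):
            tl, tr = _split_arrow(alt, lineno)
            transitions.append(AtomTransition(_parse_maps(tl), _parse_maps(tr)))
        rx = Reaction(rid, reactants, products, transitions)
        for (m, _), s in zip(reactants, transitions[0].reactant_maps):
            _record_carbons(carbon_counts, m, len(s), lineno)
        for (m, _), s in zip(products, transitions[0].product_maps):
            _record_carbons(carbon_counts, m, len(s), lineno)
        reactions.append(rx)
    model = MetabolicModel(reactions=reactions, carbon_counts=carbon_counts)
    if params_text is not None:
        _apply_params(model, params_text)
    model.validate()
    return model


def _record_carbons(counts: dict[str, int], met: str, n: int, lineno: int) -> None:
    if met in counts and counts[met] != n:
        raise ModelError(
            f"line {lineno}: metabolite {met} previously had {counts[met]} carbons, now {n}"
        )
    counts[met] = n


def _apply_params(model: MetabolicModel, params_text: str) -> None:
    doc = yaml.safe_load(params_text) or {}
    known = {r.id for r in model.reactions}
    for rid, v in (doc.get("fluxes") or {}).items():
        if rid not in known:
            raise ModelError(f"flux given for unknown reaction {rid}")
        model.reaction(rid).flux_value = float(v)
    model.pool_sizes = {m: float(v) for m, v in (doc.get("pool_sizes") or {}).items()}
    model.substrate_labeling = {
        m: {str(p): float(f) for p, f in dist.items()}
        for m, dist in (doc.get("labeling") or {}).items()
    }
    targets: list[tuple[str, tuple[int, ...]]] = []
    for entry in doc.get("measured") or []:
        if isinstance(entry, str):
            targets.append((entry, tuple(range(1, model.carbon_counts[entry] + 1))))
        else:
            targets.append((entry["metabolite"], tuple(entry["atoms"])))
    model.measured_targets = targets
    s = doc.get("settings") or {}
    model.settings = SimulationSettings(
        t_end=float(s.get("t_end", 10.0)),
        step=float(s.get("step", 0.005)),
        lam=int(s.get("lambda", 10)),
        tol_scaling=float(s.get("tol_scaling", 1e-9)),
        tol_addition=float(s.get("tol_addition", 1e-7)),
    )


def parse_model(model_path: str | Path, params_path: str | Path | None = None) -> MetabolicModel:
    """Read a model TSV and optional parameter YAML/JSON from disk."""
    text = Path(model_path).read_text(encoding="utf-8")
    params = Path(params_path).read_text(encoding="utf-8") if params_path else None
    return parse_model_text(text, params)


def load_supplementary_model(model_path: str | Path, params_path: str | Path | None = None) -> MetabolicModel:
    """Load an externally supplied network written in the same TSV dialect.

    Intended for non-desk-scale networks (genome-scale or organism-specific
    reconstructions) distributed separately from this package.
    """
    return parse_model(model_path, params_path)


def write_model_text(model: MetabolicModel) -> str:
    """Serialize a model back to the TSV dialect (round-trip inverse of
    :func:`parse_model_text`)."""
    rows = ["reaction\tstoichiometry\ttransition"]
    for r in model.reactions:
        def side(entries):
            return " + ".join(
                (f"{c:g} {m}" if c != 1.0 else m) for m, c in entries
            )
        trs = " | ".join(
            " + ".join(f"#{s}" for s in tr.reactant_maps)
            + " -> "
            + " + ".join(f"#{s}" for s in tr.product_maps)
            for tr in r.transitions
        )
        rows.append(f"{r.id}\t{side(r.reactants)} -> {side(r.products)}\t{trs}")
    return "\n".join(rows) + "\n"


def write_params_text(model: MetabolicModel, fmt: str = "yaml") -> str:
    doc = {
        "fluxes": {r.id: r.flux_value for r in model.reactions},
        "pool_sizes": dict(model.pool_sizes),
        "labeling": {m: dict(d) for m, d in model.substrate_labeling.items()},
        "measured": [
            {"metabolite": m, "atoms": list(atoms)} for m, atoms in model.measured_targets
        ],
        "settings": {
            "t_end": model.settings.t_end,
            "step": model.settings.step,
            "lambda": model.settings.lam,
            "tol_scaling": model.settings.tol_scaling,
            "tol_addition": model.settings.tol_addition,
        },
    }
    if fmt == "json":
        return json.dumps(doc, indent=1)
    return yaml.safe_dump(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# Stoichiometry and free fluxes
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel, metabolites: list[str] | None = None):
    """S over the given metabolites (default: balanced set), columns in
    reaction order. Returns (S, metabolites, reaction ids)."""
    mets = metabolites if metabolites is not None else model.balanced_metabolites()
    index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for m, c in r.reactants:
            if m in index:
                S[index[m], j] -= c
        for m, c in r.products:
            if m in index:
                S[index[m], j] += c
    return S, mets, [r.id for r in model.reactions]


def free_flux_dimension(model: MetabolicModel) -> tuple[int, np.ndarray]:
    """Dimension of the flux null space over balanced metabolites, with an
    orthonormal basis (columns) for sensitivity parameterization."""
    S, _, _ = stoichiometric_matrix(model)
    if S.size == 0:
        basis = np.eye(len(model.reactions))
        return len(model.reactions), basis
    basis = scipy.linalg.null_space(S)
    return basis.shape[1], basis


@dataclass
class BalanceReport:
    residuals: dict[str, float]
    flagged: list[str]
    message: str = ""

    @property
    def ok(self) -> bool:
        return not self.flagged and not self.message


def validate_flux_balance(model: MetabolicModel, tol: float = 1e-6) -> BalanceReport:
    """Net production of every balanced metabolite under the model's fluxes."""
    v = np.array([r.flux_value for r in model.reactions])
    if not np.any(v):
        return BalanceReport({}, [], message="no fluxes")
    S, mets, _ = stoichiometric_matrix(model)
    resid = S @ v
    residuals = {m: float(resid[i]) for i, m in enumerate(mets)}
    flagged = [m for m in mets if abs(residuals[m]) > tol]
    return BalanceReport(residuals, flagged)
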