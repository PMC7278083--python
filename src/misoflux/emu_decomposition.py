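"""Backward tracing of elementary metabolite units (EMUs).

An EMU is a specific subset of a metabolite's carbon atoms whose labeling
state is tracked as a unit.  Starting from the measured EMUs, every
producing reaction is followed backwards through its atom map; the atoms of
the product EMU partition into contiguous contributions from one or more
reactant molecule instances, each of which becomes a (smaller or equal)
reactant EMU.  The closure of this process is the minimal EMU reaction
network sufficient to simulate the measured mass isotopomer distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network_model import MetabolicModel, ModelError

__all__ = ["EMU", "EMUReaction", "EMUReactionNetwork", "trace_emus", "emus_by_size", "to_dot"]


@dataclass(frozen=True, order=True)
class EMU:
    metabolite: str
    atoms: tuple[int, ...]  # 1-based, sorted

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if not self.atoms:
            raise ValueError("EMU must have at least one atom")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.metabolite}_{''.join(map(str, self.atoms))}"


@dataclass(frozen=True)
class EMUReaction:
    """One EMU-level reaction: reactant EMUs convolve into the product EMU.

    ``weight`` is the fractional share of the flux (1/n for n symmetric
    atom-transition alternatives).
    """

    reaction_id: str
    weight: float
    reactant_emus: tuple[EMU, ...]
    product_emu: EMU

    def __post_init__(self):
        if sum(e.size for e in self.reactant_emus) != self.product_emu.size:
            raise ValueError(
                f"EMU size mismatch in {self.reaction_id}: "
                f"{self.reactant_emus} -> {self.product_emu}"
            )


@dataclass
class EMUReactionNetwork:
    emus: list[EMU]
    reactions: list[EMUReaction]
    input_emus: list[EMU]
    model: MetabolicModel = None

    def producers_of(self, emu: EMU) -> list[EMUReaction]:
        return [r for r in self.reactions if r.product_emu == emu]

    def non_input_emus(self) -> list[EMU]:
        inputs = set(self.input_emus)
        return [e for e in self.emus if e not in inputs]

    def input_mid(self, emu: EMU) -> list[float]:
        """MID of an input EMU, marginalized from the substrate isotopomer
        fractions; constant over time (step labeling at t=0)."""
        dist = self.model.substrate_labeling[emu.metabolite]
        mid = [0.0] * (emu.size + 1)
        for pattern, frac in dist.items():
            w = sum(int(pattern[a - 1]) for a in emu.atoms)
            mid[w] += frac
        return mid


def _trace_reaction(model: MetabolicModel, emu: EMU) -> list[EMUReaction]:
    """All EMU reactions producing ``emu``, one per (reaction, transition
    alternative, product instance)."""
    out = []
    for rx in model.produced_by(emu.metabolite):
        alt_weight = 1.0 / len(rx.transitions)
        for tr in rx.transitions:
            for pi, pmet in enumerate(rx.product_instances):
                if pmet != emu.metabolite:
                    continue
                by_reactant: dict[int, list[int]] = {}
                for a in emu.atoms:
                    ri, pos = tr.atom_origin(pi, a)
                    by_reactant.setdefault(ri, []).append(pos)
                reactant_emus = tuple(
                    EMU(rx.reactant_instances[ri], tuple(sorted(pos_list)))
                    for ri, pos_list in sorted(by_reactant.items())
                )
                out.append(EMUReaction(rx.id, alt_weight, reactant_emus, emu))
    return out


def trace_emus(model: MetabolicModel, targets: list[EMU]) -> EMUReactionNetwork:
    """Backward closure of the target EMUs through the atom-mapped network."""
    for t in targets:
        if t.metabolite not in model.carbon_counts:
            raise ModelError(f"target on unknown metabolite {t.metabolite}")
    emus: set[EMU] = set()
    reactions: list[EMUReaction] = []
    seen_rx: set[EMUReaction] = set()
    inputs: set[EMU] = set()
    stack = list(dict.fromkeys(targets))
    while stack:
        emu = stack.pop()
        if emu in emus:
            continue
        emus.add(emu)
        if model.is_substrate(emu.metabolite):
            inputs.add(emu)
            continue
        produced = _trace_reaction(model, emu)
        if not produced:
            raise ModelError(
                f"unreachable EMU {emu}: no producing reaction and no labeling"
            )
        for er in produced:
            if er not in seen_rx:
                seen_rx.add(er)
                reactions.append(er)
            stack.extend(er.reactant_emus)
    order = sorted(emus)
    reactions.sort(key=lambda r: (r.product_emu, r.reaction_id, r.reactant_emus))
    return EMUReactionNetwork(
        emus=order,
        reactions=reactions,
        input_emus=sorted(inputs),
        model=model,
    )


def emus_by_size(network: EMUReactionNetwork) -> dict[int, list[EMU]]:
    """Partition the network's EMUs by atom count, deterministically ordered."""
    out: dict[int, list[EMU]] = {}
    for emu in sorted(network.emus):
        out.setdefault(emu.size, []).append(emu)
    return dict(sorted(out.items()))


def to_dot(network: EMUReactionNetwork) -> str:
    """DOT rendering of the EMU reaction network for inspection."""
    lines = ["digraph emu_network {"]
    for emu in network.emus:
        shape = "box" if emu in set(network.input_emus) else "ellipse"
        lines.append(f'  "{emu}" [shape={shape}];')
    for er in network.reactions:
        for remu in er.reactant_emus:
            lines.append(
                f'  "{remu}" -> "{er.product_emu}" [label="{er.reaction_id}"];'
            )
    lines.append("}")
    return "\n".join(lines)
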