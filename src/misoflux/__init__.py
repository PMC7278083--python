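"""misoflux: parallel instationary 13C-fluxomics simulation on
mass-isotopomer strongly connected components.

Pipeline: parse an atom-mapped model -> trace EMUs backward from the
measured targets -> build and prune the mass isotopomer network ->
decompose into weight-homogeneous SCCs -> assemble per-SCC isotope ODEs
(with optional forward sensitivities) -> integrate with constant-step RK4
or adaptive Cash-Karp under a dependency-cascade parallel contract.
"""

from .network_model import (
    AtomTransition,
    MetabolicModel,
    ModelError,
    Reaction,
    SimulationSettings,
    free_flux_dimension,
    load_supplementary_model,
    parse_model,
    parse_model_text,
    validate_flux_balance,
    write_model_text,
    write_params_text,
)
from .emu_decomposition import EMU, EMUReaction, EMUReactionNetwork, emus_by_size, trace_emus
from .misotope_graph import (
    MassIsotopomerNode,
    SCCPartition,
    aggregate_lambda,
    build_graph,
    decompose,
    measured_nodes,
    prune_to_measured,
    tarjan_scc,
    topological_sort,
)
from .ode_assembly import (
    CascadeSystem,
    assemble,
    build_eliminating_matrix,
    build_transition_tensor,
    convolve_mid,
    rhs,
)
from .sensitivity import (
    AugmentedCascade,
    Parameterization,
    build_parameterization,
    extend_with_sensitivities,
)
from .integrate import (
    StepController,
    Trajectory,
    cash_karp_step,
    integrate_adaptive,
    integrate_constant,
    pilot_controller,
    rk4_step,
    run_parallel,
)
from .diagnostics import (
    IsotopomerOracle,
    conservation_report,
    isotopomer_oracle,
    spectral_check,
    stationary_solution,
    stiffness_ratio,
)
from .fixtures import (
    GeneratorSpec,
    random_network,
    sample_flux_distribution,
    sample_pool_sizes,
    toy_model,
)

__version__ = "0.1.0"


def simulate_measured(model, lam=None, backend="vector", mode="constant", workers=None,
                      sensitivities=False):
    """Convenience wrapper: decompose the model's measured targets and
    integrate with its settings.  Returns (system, trajectory)."""
    targets = [EMU(m, atoms) for m, atoms in model.measured_targets]
    network = trace_emus(model, targets)
    lam = model.settings.lam if lam is None else lam
    _, partition = decompose(network, targets, lam=lam)
    system = assemble(partition, network, model, backend=backend)
    if sensitivities:
        system = extend_with_sensitivities(system)
    if mode == "constant":
        traj = integrate_constant(
            system, model.settings.step, model.settings.t_end, workers=workers
        )
    else:
        controller = StepController(
            tol_scaling=model.settings.tol_scaling,
            tol_addition=model.settings.tol_addition,
            pilot=pilot_controller(partition, system),
        )
        traj = integrate_adaptive(
            system, controller, model.settings.t_end,
            h0=model.settings.step, workers=workers,
        )
    return system, traj
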