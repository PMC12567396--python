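import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermafem import (
    InterfaceSpec,
    assemble_system,
    build_mesh,
    simulate,
    step,
    study_default_config,
)
from dermafem.fem import ConcentrationState, initial_state
from dermafem.oracles import analytic_slab_solution, equilibrium_state

from conftest import FAST_DT, make_slab_config


def _finite_interfaces(config, transfer, indices=(1, 2)):
    """Replace equilibrium interfaces by finite ones with large K (penalty)."""
    interfaces = tuple(
        dataclasses.replace(itf, mode="finite", transfer=transfer)
        if itf.index in indices else itf
        for itf in config.interfaces
    )
    return dataclasses.replace(config, interfaces=interfaces)


# --------------------------------------------------------------------------
# assembly

def test_finite_interface_coupling_block_symmetric_at_unit_partition():
    config = make_slab_config()
    config = _finite_interfaces(config, transfer=2.0, indices=(1, 2, 3))
    mesh = build_mesh(config)
    system = assemble_system(mesh, config)
    area = config.geometry.area
    a, b = mesh.interface_pairs[0]
    block = system.transport[np.ix_([a, b], [a, b])].toarray()
    # stiffness contributes D/h on the diagonal; remove it to isolate coupling
    h = np.diff(mesh.node_positions[0])[0]
    d_over_h = area * config.layers[0].diffusivity / h
    block -= np.diag([d_over_h, d_over_h])
    expected = 2.0 * area * np.array([[1.0, -1.0], [-1.0, 1.0]])
    assert block == pytest.approx(expected, rel=1e-12)


def test_coupling_columns_sum_to_zero_for_random_partitions():
    """Interface coupling conserves mass: outflux of one layer is influx of
    the next, so every column of the transport operator sums to zero."""
    rng = np.random.default_rng(7)
    base = make_slab_config(n_elements=2)
    for _ in range(100):
        p = rng.uniform(1e-3, 10.0, size=3)
        k = rng.uniform(1e-3, 10.0, size=3)
        interfaces = tuple(
            InterfaceSpec(i + 1, p[i], "finite", k[i]) for i in range(3)
        )
        config = dataclasses.replace(base, interfaces=interfaces)
        system = assemble_system(build_mesh(config), config)
        colsums = np.asarray(system.transport.sum(axis=0)).ravel()
        assert np.max(np.abs(colsums)) < 1e-10 * abs(system.transport).max()


def test_unit_partition_elimination_reproduces_continuous_mesh():
    """With P = 1 equilibrium interfaces, merging duplicated DOFs must give
    exactly the operators of a single conforming uniform mesh."""
    config = make_slab_config(D=0.3, n_elements=2)
    system = assemble_system(build_mesh(config), config)
    _, smt, sat = system.reduced_operators()
    n_el, h, area, D = 8, 1.0 / 8, config.geometry.area, 0.3
    n = n_el + 1
    mass = np.zeros((n, n))
    stiff = np.zeros((n, n))
    for e in range(n_el):
        mass[e:e + 2, e:e + 2] += area * h / 6 * np.array([[2, 1], [1, 2]])
        stiff[e:e + 2, e:e + 2] += area * D / h * np.array([[1, -1], [-1, 1]])
    assert smt.toarray() == pytest.approx(mass, abs=1e-14)
    assert sat.toarray() == pytest.approx(stiff, abs=1e-12)


def test_mass_matrix_row_sums_give_layer_volumes(study):
    config, _ = study
    system = assemble_system(build_mesh(config), config)
    for weights, layer in zip(system.layer_mass_weights, config.layers):
        assert weights.sum() == pytest.approx(
            config.geometry.area * layer.thickness, rel=1e-12
        )


def test_assemble_rejects_mesh_config_mismatch(study):
    config, _ = study
    other = make_slab_config()
    with pytest.raises(ValueError, match="does not match|layers"):
        assemble_system(build_mesh(other), config)


# --------------------------------------------------------------------------
# stepping

def test_equilibrium_state_is_stationary(study):
    config, _ = study
    mesh = build_mesh(config)
    system = assemble_system(mesh, config)
    eq = equilibrium_state(config, 5.0)
    values = np.concatenate([
        np.full(len(nodes), eq.concentrations[lay.name])
        for nodes, lay in zip(mesh.node_positions, config.layers)
    ])
    new = step(system, ConcentrationState(0.0, values), dt=0.01)
    assert new.values == pytest.approx(values, rel=1e-12)


def test_single_giant_step_lands_on_equilibrium(study):
    """Backward Euler is A-stable: one dt = 1e6 h step from the initial
    condition must land within 0.1% of the closed-form equilibrium."""
    config, _ = study
    mesh = build_mesh(config)
    system = assemble_system(mesh, config)
    state = step(system, initial_state(system), dt=1e6)
    eq = equilibrium_state(config, 5.0)
    for sl, lay in zip(mesh.layer_slices, config.layers):
        assert state.values[sl] == pytest.approx(
            eq.concentrations[lay.name], rel=1e-3
        )


def test_zero_or_negative_dt_rejected(study):
    config, _ = study
    system = assemble_system(build_mesh(config), config)
    state = initial_state(system)
    with pytest.raises(ValueError, match="dt"):
        step(system, state, 0.0)
    with pytest.raises(ValueError, match="dt"):
        simulate(config, [1.0], dt=-0.1)


def test_simulate_validates_output_times(study):
    config, _ = study
    with pytest.raises(ValueError, match="empty"):
        simulate(config, [], dt=0.1)
    with pytest.raises(ValueError, match="increasing"):
        simulate(config, [2.0, 1.0], dt=0.1)


# --------------------------------------------------------------------------
# trajectories

def test_time_zero_state_is_initial_condition(study):
    config, _ = study
    res = simulate(config, [0.0, 1.0], dt=0.5)
    mesh = res.mesh
    assert np.all(res.states[0].values[mesh.layer_slices[0]] == 5.0)
    for sl in mesh.layer_slices[1:]:
        assert np.all(res.states[0].values[sl] == 0.0)
    assert res.layer_masses[0] == pytest.approx([5.0, 0, 0, 0], abs=1e-12)


def test_total_mass_conserved_over_study_run(study_result):
    totals = study_result.layer_masses.sum(axis=1)
    assert np.max(np.abs(totals - 5.0)) < 1e-8 * 5.0


def test_receiver_mass_is_non_decreasing(study_result):
    rc = study_result.layer_mass("RC")
    assert np.all(np.diff(rc) >= -1e-10)


def test_states_have_no_significant_undershoot(study_result):
    min_val = min(s.values.min() for s in study_result.states)
    assert min_val >= -1e-9 * 5.0


def test_interface_jumps_approach_partition_ratios(study):
    """In the long-time limit the downstream/upstream concentration ratio at
    each interface equals P_i."""
    config, _ = study
    res = simulate(config, [1e4], dt=50.0)
    values = res.states[-1].values
    for itf in config.interfaces:
        a, b = res.mesh.interface_pairs[itf.index - 1]
        assert values[b] / values[a] == pytest.approx(itf.partition, rel=1e-6)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    d_sc=st.floats(1e-5, 1e-3),
    p1=st.floats(0.1, 10.0),
    p2=st.floats(0.1, 10.0),
    p3=st.floats(0.05, 5.0),
    k3=st.floats(0.005, 1.0),
)
def test_conservation_holds_across_parameter_space(d_sc, p1, p2, p3, k3):
    """No-flux walls conserve total drug mass for any valid parameter set."""
    from dermafem import apply_parameters

    config, _ = study_default_config(n_elements=(2, 10, 14, 3))
    config = apply_parameters(
        config, {"D_SC": d_sc, "P_1": p1, "P_2": p2, "P_3": p3, "K_3": k3}
    )
    res = simulate(config, [5.0, 25.0, 51.5], dt=0.5)
    totals = res.layer_masses.sum(axis=1)
    assert np.max(np.abs(totals - 5.0)) < 1e-8 * 5.0


# --------------------------------------------------------------------------
# convergence and equivalence

def spatial_convergence_orders():
    """L2 errors against the analytic slab series under 4x/8x/16x refinement;
    dt is scaled with h^2 so the first-order temporal error stays subdominant."""
    config = make_slab_config(D=0.05, n_elements=2)
    t_eval = 0.2
    errors = []
    for r in (4, 8, 16):
        res = simulate(config, [t_eval], dt=2.56e-3 / r**2, refinement=r)
        x = res.mesh.coordinates
        exact = analytic_slab_solution(
            0.05, 1.0, lambda s: 1.0 if s < 0.25 else 0.0, t_eval, x
        )
        err = res.states[-1].values - exact
        errors.append(np.sqrt(np.trapezoid(err**2, x)))
    return [np.log2(errors[i] / errors[i + 1]) for i in range(2)]


def test_spatial_convergence_is_second_order():
    orders = spatial_convergence_orders()
    for order in orders:
        assert 1.8 <= order <= 2.2, orders


def test_temporal_convergence_is_first_order(study):
    """Halving dt halves the change in receiver mass at 51.5 h."""
    config, _ = study
    masses = [
        simulate(config, [51.5], dt=dt).layer_mass("RC")[-1]
        for dt in (0.4, 0.2, 0.1)
    ]
    ratio = (masses[0] - masses[1]) / (masses[1] - masses[2])
    assert 1.7 <= ratio <= 2.3, (masses, ratio)


def penalty_vs_elimination_max_relative_gap(config, schedule, transfer, dt=FAST_DT):
    exact = simulate(config, schedule, dt=dt)
    penal = simulate(_finite_interfaces(config, transfer), schedule, dt=dt)
    rc_e, rc_p = exact.layer_mass("RC"), penal.layer_mass("RC")
    return float(np.max(np.abs(rc_p - rc_e) / rc_e.max()))


def test_penalty_interfaces_match_exact_elimination(study, study_schedule):
    config, _ = study
    gap4 = penalty_vs_elimination_max_relative_gap(config, study_schedule, 1e4)
    gap5 = penalty_vs_elimination_max_relative_gap(config, study_schedule, 1e5)
    assert gap4 < 1e-3
    assert gap5 < 1e-4


def test_receiver_mass_insensitive_to_well_mixed_diffusivity():
    """A x10 change of the artificial donor/receptor diffusivity moves the
    receiver mass by < 0.1%: the compartments really are well mixed."""
    masses = []
    for wm in (1e4, 1e5):
        config, _ = study_default_config(well_mixed_diffusivity=wm)
        masses.append(simulate(config, [51.5], dt=0.02).layer_mass("RC")[-1])
    assert abs(masses[1] / masses[0] - 1) < 1e-3


def test_lumped_mass_conserves_and_tracks_consistent(study, study_schedule):
    config, _ = study
    lump = simulate(config, study_schedule, dt=0.05, lumped=True)
    cons = simulate(config, study_schedule, dt=0.05, lumped=False)
    assert np.max(np.abs(lump.layer_masses.sum(axis=1) - 5.0)) < 1e-8 * 5.0
    assert lump.layer_mass("RC")[-1] == pytest.approx(
        cons.layer_mass("RC")[-1], rel=1e-2
    )
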