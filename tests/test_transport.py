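"""Transport solver: conservation, bounds, monotonicity, oracle agreement."""

import numpy as np
import pytest

from cugel.geometry import DeformedGeometry
from cugel.transport import (TransportConfig, mass_balance_residual,
                             penetration_depth, solve, wellmixed_limit,
                             write_profile_csv, write_timeseries_csv)
from cugel.units import ReleaseSpec

VOLUME = 7.5e-6  # m3
EIGHT_H = 28_800.0


def covered_2mm(thickness=2.0e-3, exposed=0.0, ph="7"):
    length = 21.220659e-3
    return DeformedGeometry(
        gel_thickness=thickness, gel_length=length * (1 - exposed),
        exposed_fraction=exposed, ph=ph,
        sleeve_radius=1.5e-3, sleeve_length=length)


def material_with(D, ph="7", kp=0.0):
    from cugel.geometry import AdsorptionParams, GelMaterial
    from cugel.swelling import DimensionalChange
    ads = AdsorptionParams(capacity=100.0, partition=kp) if kp else None
    return GelMaterial(
        "test", {ph: D, "4": D},
        {"4": DimensionalChange(0.0, 0.0), ph: DimensionalChange(0.0, 0.0)},
        adsorption=ads, adsorption_ph=frozenset([ph]) if kp else frozenset())


@pytest.fixture(scope="module")
def fast_cfg():
    return TransportConfig(n_cells=60, dt=30.0, t_end=EIGHT_H)


class TestWellMixedLimit:
    def test_reference_bound(self, release):
        assert wellmixed_limit(release, EIGHT_H, VOLUME) == pytest.approx(
            3.50e-5, rel=2e-3)

    def test_in_vitro_volume(self, release):
        assert wellmixed_limit(release, EIGHT_H, 10e-6) == pytest.approx(
            2.62e-5, rel=2e-3)

    def test_zero_duration(self, release):
        assert wellmixed_limit(release, 0.0, VOLUME) == 0.0


class TestLimitsAndBounds:
    def test_fast_diffusion_reaches_equilibrium_limit(self, release, fast_cfg):
        """At D = 1e-6 m2/s the gel is no barrier: the coupled system is
        well mixed over fluid + gel, so the fluid holds the exact closed
        form J*A*t/(V + V_gel) (partition coefficient 1)."""
        deformed = covered_2mm()
        states = solve(release, deformed, material_with(1e-6), VOLUME,
                       fast_cfg)
        a, b = deformed.sleeve_radius, deformed.sleeve_radius + deformed.gel_thickness
        v_gel = np.pi * (b ** 2 - a ** 2) * deformed.covered_length
        exact = release.injected(EIGHT_H) / ((VOLUME + v_gel) * 1e3)
        assert states[-1].fluid_molar == pytest.approx(exact, rel=1e-3)

    def test_fast_diffusion_thin_gel_reaches_wellmixed_bound(self, release,
                                                             fast_cfg):
        """When the coating volume is negligible next to the compartment,
        the D -> infinity value is J*A*t/V itself within 1%."""
        states = solve(release, covered_2mm(thickness=0.2e-3),
                       material_with(1e-6), VOLUME, fast_cfg)
        limit = wellmixed_limit(release, EIGHT_H, VOLUME)
        assert states[-1].fluid_molar == pytest.approx(limit, rel=0.01)
        assert states[-1].fluid_molar <= limit * (1 + 1e-9)

    def test_bound_holds_at_all_times_and_D(self, release, fast_cfg):
        for D in (1e-12, 1e-10, 1e-8):
            states = solve(release, covered_2mm(), material_with(D), VOLUME,
                           fast_cfg)
            for s in states[1:]:
                assert s.fluid_molar <= wellmixed_limit(
                    release, s.time, VOLUME) * (1 + 1e-9)

    def test_confinement_at_low_D(self, release, fast_cfg):
        """Tight gel (D = 1e-12): penetration ~0.34 mm of a 2-mm coating, so
        ions pile up at the copper surface and the fluid stays clean."""
        states = solve(release, covered_2mm(), material_with(1e-12), VOLUME,
                       fast_cfg)
        final = states[-1]
        assert final.fluid_molar < 1e-6
        assert final.radial_profile[0] >= 1e3 * final.fluid_concentration

    def test_linearity_in_flux(self, fast_cfg):
        half = ReleaseSpec(daily_release=25.0, copper_area=2.0e-4)
        full = ReleaseSpec(daily_release=50.0, copper_area=2.0e-4)
        c_half = solve(half, covered_2mm(), material_with(3e-10), VOLUME,
                       fast_cfg)[-1].fluid_molar
        c_full = solve(full, covered_2mm(), material_with(3e-10), VOLUME,
                       fast_cfg)[-1].fluid_molar
        assert c_full == pytest.approx(2 * c_half, rel=1e-9)


class TestConservation:
    @pytest.mark.parametrize("n_cells,kp,exposed", [
        (10, 0.0, 0.0), (100, 0.0, 0.0), (100, 9.0, 0.0), (100, 0.0, 0.286),
    ])
    def test_residual_below_tolerance(self, release, n_cells, kp, exposed):
        """Conservation is exact by construction (telescoping fluxes),
        independent of grid resolution, adsorption or exposure."""
        cfg = TransportConfig(n_cells=n_cells, dt=60.0, t_end=EIGHT_H)
        states = solve(release, covered_2mm(exposed=exposed),
                       material_with(3e-10, kp=kp), VOLUME, cfg)
        for s in states:
            assert mass_balance_residual(s, VOLUME) < 1e-6

    def test_initial_state_residual_zero(self, release, fast_cfg):
        states = solve(release, covered_2mm(), material_with(3e-10), VOLUME,
                       fast_cfg)
        assert mass_balance_residual(states[0], VOLUME) == 0.0

    def test_ledger_identity(self, release, fast_cfg):
        s = solve(release, covered_2mm(), material_with(3e-10, kp=4.0),
                  VOLUME, fast_cfg)[-1]
        held = s.gel_moles + s.fluid_concentration * VOLUME + s.adsorbed
        assert held == pytest.approx(s.injected, rel=1e-9)
        assert s.adsorbed == pytest.approx(4.0 * s.gel_moles, rel=1e-12)


class TestMonotonicity:
    def test_fluid_concentration_nondecreasing_in_time(self, release, fast_cfg):
        states = solve(release, covered_2mm(), material_with(3e-10), VOLUME,
                       fast_cfg)
        conc = [s.fluid_molar for s in states]
        assert all(b >= a - 1e-15 for a, b in zip(conc, conc[1:]))

    def test_antitone_in_thickness(self, release, fast_cfg):
        conc = [solve(release, covered_2mm(thickness=t), material_with(3e-10),
                      VOLUME, fast_cfg)[-1].fluid_molar
                for t in (1.0e-3, 1.5e-3, 2.0e-3, 2.5e-3)]
        assert all(b < a for a, b in zip(conc, conc[1:]))

    def test_monotone_in_D(self, release, fast_cfg):
        conc = [solve(release, covered_2mm(), material_with(D), VOLUME,
                      fast_cfg)[-1].fluid_molar
                for D in (1e-11, 1e-10, 1e-9, 1e-8)]
        assert all(b > a for a, b in zip(conc, conc[1:]))

    def test_adsorption_retards_release(self, release, fast_cfg):
        free = solve(release, covered_2mm(), material_with(3e-10), VOLUME,
                     fast_cfg)[-1].fluid_molar
        retarded = solve(release, covered_2mm(), material_with(3e-10, kp=9.0),
                         VOLUME, fast_cfg)[-1].fluid_molar
        assert retarded < free


class TestNumerics:
    def test_refinement_changes_little(self, release):
        """Halving dt and doubling n_cells moves the 8-h value < 0.5%."""
        coarse = TransportConfig(n_cells=100, dt=10.0, t_end=EIGHT_H)
        fine = TransportConfig(n_cells=200, dt=5.0, t_end=EIGHT_H)
        c0 = solve(release, covered_2mm(), material_with(4.5e-10), VOLUME,
                   coarse)[-1].fluid_molar
        c1 = solve(release, covered_2mm(), material_with(4.5e-10), VOLUME,
                   fine)[-1].fluid_molar
        assert abs(c1 - c0) / c0 < 0.005

    def test_schemes_agree(self, release):
        be = TransportConfig(n_cells=100, dt=10.0, t_end=EIGHT_H,
                             scheme="backward_euler")
        cn = TransportConfig(n_cells=100, dt=10.0, t_end=EIGHT_H,
                             scheme="crank_nicolson")
        c_be = solve(release, covered_2mm(), material_with(4.5e-10), VOLUME,
                     be)[-1].fluid_molar
        c_cn = solve(release, covered_2mm(), material_with(4.5e-10), VOLUME,
                     cn)[-1].fluid_molar
        assert c_be == pytest.approx(c_cn, rel=0.01)

    def test_matches_dense_reference(self, release):
        """20-cell backward Euler agrees with an independently assembled
        dense linear-algebra reference to 1e-10."""
        n, dt, t_end = 20, 300.0, EIGHT_H
        ratio = 1.03
        cfg = TransportConfig(n_cells=n, dt=dt, t_end=t_end, grid_ratio=ratio)
        deformed = covered_2mm()
        D = 3e-10
        states = solve(release, deformed, material_with(D), VOLUME, cfg)

        # --- independent dense reference -----------------------------------
        a, L = deformed.sleeve_radius, deformed.covered_length
        b = a + deformed.gel_thickness
        w0 = (b - a) * (ratio - 1.0) / (ratio ** n - 1.0)
        faces = [a]
        for i in range(n):
            faces.append(faces[-1] + w0 * ratio ** i)
        faces[-1] = b
        faces = np.array(faces)
        centers = 0.5 * (faces[:-1] + faces[1:])
        vols = np.pi * (faces[1:] ** 2 - faces[:-1] ** 2) * L

        N = n + 1
        A = np.zeros((N, N))
        for i in range(n - 1):
            g = D * 2 * np.pi * faces[i + 1] * L / (centers[i + 1] - centers[i])
            A[i, i] += g; A[i, i + 1] -= g
            A[i + 1, i + 1] += g; A[i + 1, i] -= g
        g_out = D * 2 * np.pi * b * L / (b - centers[-1])
        A[n - 1, n - 1] += g_out; A[n - 1, n] -= g_out
        A[n, n] += g_out; A[n, n - 1] -= g_out
        Mass = np.diag(np.concatenate((vols, [VOLUME])))
        src = np.zeros(N)
        src[0] = release.flux * release.copper_area

        steps = int(round(t_end / dt))
        lhs = Mass + dt * A
        c = np.zeros(N)
        for _ in range(steps):
            c = np.linalg.solve(lhs, Mass @ c + dt * src)

        np.testing.assert_allclose(states[-1].radial_profile, c[:n],
                                   rtol=1e-10)
        assert states[-1].fluid_concentration == pytest.approx(
            c[n], rel=1e-10)

    def test_degenerate_thin_gel_is_wellmixed(self, release, fast_cfg):
        states = solve(release, covered_2mm(thickness=1e-8), material_with(1e-12),
                       VOLUME, fast_cfg)
        limit = wellmixed_limit(release, EIGHT_H, VOLUME)
        assert states[-1].fluid_molar == pytest.approx(limit, rel=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TransportConfig(n_cells=5)
        with pytest.raises(ValueError):
            TransportConfig(dt=100.0, t_end=10.0)
        with pytest.raises(ValueError):
            TransportConfig(scheme="explicit")


class TestPenetrationDepth:
    def test_closed_form(self):
        assert penetration_depth(1e-12, EIGHT_H) == pytest.approx(3.4e-4,
                                                                  rel=0.01)
        assert penetration_depth(1e-10, EIGHT_H) == pytest.approx(3.4e-3,
                                                                  rel=0.01)

    def test_zero_time(self):
        assert penetration_depth(1e-10, 0.0) == 0.0

    def test_scaling(self):
        assert penetration_depth(4e-12, 100.0) == pytest.approx(
            2 * penetration_depth(1e-12, 100.0), rel=1e-12)


def test_csv_outputs(tmp_path, release, fast_cfg):
    import pandas as pd
    states = solve(release, covered_2mm(), material_with(3e-10), VOLUME,
                   fast_cfg)
    ts = tmp_path / "ts.csv"
    write_timeseries_csv(states, VOLUME, ts)
    df = pd.read_csv(ts)
    assert list(df.columns) == ["time_s", "fluid_conc_M", "gel_moles",
                                "adsorbed_moles", "injected_moles", "residual"]
    assert len(df) == len(states)
    prof = tmp_path / "prof.csv"
    write_profile_csv(states[-1], prof)
    dfp = pd.read_csv(prof)
    assert list(dfp.columns) == ["r_m", "conc_M"]
    assert len(dfp) == fast_cfg.n_cells
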