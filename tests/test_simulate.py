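"""Method-of-lines simulator: fixed points, dispersion, conservation, speed."""

import numpy as np
import pytest

from pbdna import ModelParams, simulate
from pbdna.benchmark import benchmark_params, benchmark_setup, exact_on_window
from pbdna.simulate import SimState, core_position, measure_speed, run, step


class TestStep:
    def test_zero_state_is_fixed_point(self, unit_params):
        x = simulate.make_grid(10.0, 64)
        st = SimState(x=x, R=np.zeros(64), V=np.zeros(64))
        out = step(st, unit_params, dt=0.01)
        assert np.all(out.R == 0) and np.all(out.V == 0)
        assert out.time == pytest.approx(0.01)

    def test_cfl_auto_shrink(self, unit_params):
        x = simulate.make_grid(10.0, 64)
        st = SimState(x=x, R=np.sin(np.pi * x / 10), V=np.zeros(64))
        out = step(st, unit_params, dt=10.0)  # way above the CFL bound
        assert out.time - st.time <= st.stable_dt(unit_params) * (1 + 1e-12)

    def test_blowup_halts_with_report(self):
        p = ModelParams(a1=-1.0, a2=0.0, eta=1.0, zeta=0.0)  # ill-posed: growth
        x = simulate.make_grid(5.0, 128)
        st = SimState(x=x, R=1e3 * np.sin(np.pi * x * 12.8), V=np.zeros(128))
        with pytest.raises(FloatingPointError, match="blew up"):
            s = st
            for _ in range(2000):
                s = step(s, p, dt=0.05)

    def test_linear_plane_wave_phase_speed(self):
        """a2 = zeta = 0: a right-moving wave advects at sqrt(a1) (within
        0.5% at 64 points per wavelength)."""
        p = ModelParams(a1=4.0, a2=0.0, eta=1.0, zeta=0.0)
        c = 2.0
        L, m = 2 * np.pi, 2  # two wavelengths
        n = 64 * m
        k = 2 * np.pi * m / L
        x = -L / 2 + L * np.arange(n) / n
        st = SimState(x=x, R=np.sin(k * x), V=-c * k * np.cos(k * x))
        T = 0.7
        end, _ = run(st, p, T=T, record_every=10**9, track_core=False)
        # phase of the m-th Fourier mode moves by -k c T
        phase0 = np.angle(np.fft.fft(st.R)[m])
        phase1 = np.angle(np.fft.fft(end.R)[m])
        dphi = np.angle(np.exp(1j * (phase1 - phase0)))
        c_meas = -dphi / (k * end.time)
        assert abs(c_meas - c) / c < 0.005


class TestConservation:
    def test_energy_drift_short_run(self):
        fp = benchmark_params()
        _, st = benchmark_setup(1024)
        E0 = st.energy(fp.params)
        _, traj = run(st, fp.params, T=2.0, record_every=25)
        drift = max(abs(e - E0) for e in traj.energies) / abs(E0)
        assert drift < 1e-5

    def test_time_reversal(self):
        """Forward then backward with negated V returns the initial state."""
        fp = benchmark_params()
        _, st = benchmark_setup(256)
        dt = st.stable_dt(fp.params) / 16
        s = st
        for _ in range(50):
            s = step(s, fp.params, dt)
        s = SimState(x=s.x, R=s.R, V=-s.V, time=0.0, cfl=s.cfl)
        for _ in range(50):
            s = step(s, fp.params, dt)
        assert np.max(np.abs(s.R - st.R)) < 1e-8
        assert np.max(np.abs(s.V + st.V)) < 1e-8


class TestTravelingFidelity:
    def test_convergence_second_order(self):
        """L2/Linf error vs the translated closed form drops ~4x per 2x
        spatial refinement (order ~ 2; time error is O(dt^4), negligible)."""
        fp = benchmark_params()
        errs = []
        for n in (256, 512, 1024):
            cf, st = benchmark_setup(n)
            end, _ = run(st, fp.params, T=2.0, record_every=10**9, track_core=False)
            sel, Re = exact_on_window(cf, st.x, end.time, window=10.0)
            errs.append(np.max(np.abs(end.R[sel] - Re)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 1.8) and np.all(orders < 2.2)

    def test_shape_persistence_T5(self):
        fp = benchmark_params()
        cf, st = benchmark_setup(1024)
        end, _ = run(st, fp.params, T=5.0, record_every=10**9, track_core=False)
        sel, Re = exact_on_window(cf, st.x, end.time, window=10.0)
        assert np.max(np.abs(end.R[sel] - Re)) < 1e-2

    def test_initial_velocity_matches_time_derivative(self):
        """V(x, 0) = -omega r'(xi) agrees with the centered FD in t of the
        evaluator to O(dt^2)."""
        cf, st = benchmark_setup(512)
        f = cf.R_func()
        dt = 1e-4
        sel = np.abs(st.x) < 20
        fd = (np.asarray(f(st.x[sel] + 0j, dt)).real
              - np.asarray(f(st.x[sel] + 0j, -dt)).real) / (2 * dt)
        # periodize zeroed V outside the core window; compare inside
        assert np.max(np.abs(st.V[sel] - fd)) < 1e-6

    def test_cmax_formula(self):
        fp = benchmark_params()
        _, st = benchmark_setup(1024)
        rx = simulate.d1(st.R, st.dx)
        expect = np.sqrt(fp.params.a1 + 3 * fp.params.a2 * np.max(rx**2))
        assert st.c_max(fp.params) == pytest.approx(expect, rel=1e-12)


class TestSpeed:
    def test_translating_gaussian(self):
        x = simulate.make_grid(20.0, 512)
        traj = simulate.Trajectory()
        p = ModelParams(a1=1, a2=1, eta=1, zeta=1)
        for tv in np.linspace(0, 4, 9):
            R = np.exp(-((np.mod(x - 0.7 * tv + 20, 40) - 20) ** 2))
            st = SimState(x=x, R=R, V=np.zeros_like(R), time=tv)
            traj.record(st, p)
        assert measure_speed(traj) == pytest.approx(0.7, abs=1e-3)

    def test_stationary_profile(self):
        x = simulate.make_grid(20.0, 512)
        traj = simulate.Trajectory()
        p = ModelParams(a1=1, a2=1, eta=1, zeta=1)
        R = np.exp(-(x**2))
        for tv in (0.0, 1.0, 2.0):
            traj.record(SimState(x=x, R=R, V=0 * R, time=tv), p)
        assert measure_speed(traj) == pytest.approx(0.0, abs=1e-12)

    def test_flat_field_reports_no_core(self):
        x = simulate.make_grid(10.0, 256)
        with pytest.raises(ValueError, match="flat"):
            core_position(x, np.ones_like(x))

    def test_benchmark_speed_matches_branch_omega(self):
        """End-to-end: measured core speed within 1% of the branch omega."""
        import sympy as sp

        fp = benchmark_params()
        cf, st = benchmark_setup(1024)
        _, traj = run(st, fp.params, T=5.0, record_every=20)
        om = complex(sp.N(cf.omega)).real
        assert abs(measure_speed(traj) - om) / om < 0.01


class TestInitialization:
    def test_zero_profile(self, unit_params):
        from pbdna.unified import SolutionBranch, build_ansatz
        # a degenerate closed form R == 0 initializes the zero state
        import sympy as sp
        from pbdna.params import SYM
        from pbdna.unified import A0, A1, A2, CINT, W, AuxiliaryODE, LAM, assemble_R, integrate_auxiliary

        br = SolutionBranch(
            family="solitary",
            assignment={A0: sp.S.One, A1: sp.S.Zero, A2: sp.S.Zero,
                        W: sp.S.One, CINT: sp.S.Zero},
            ansatz=build_ansatz("solitary"), sign=1, variant=None,
        )
        lam = integrate_auxiliary(AuxiliaryODE(1, 1 + LAM**2), c1=0)[0]
        cf = assemble_R(br, lam, subs={SYM.eta: 1.0})
        st = simulate.init_from_closed_form(cf, simulate.make_grid(5.0, 64))
        assert np.all(st.R == 0) and np.all(st.V == 0)

    def test_singular_profile_refused(self):
        """A profile with a pole inside the domain cannot be simulated."""
        from pbdna.families import FamilyParams, closed_form

        fp = FamilyParams(
            "soliton", ModelParams(a1=10.0, a2=1.0, eta=1.0, zeta=1.0),
            {"B1": 2.0, "B2": 1.0}, sign=1, variant="E1",
        )
        cf = closed_form(fp)  # E1 branch has a pole at xi = -c1
        with pytest.raises(ValueError, match="singular"):
            simulate.init_from_closed_form(cf, simulate.make_grid(30.0, 256))
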