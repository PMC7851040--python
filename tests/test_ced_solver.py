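import numpy as np
import pytest

import cedsim as cs
from cedsim.ced_solver import FlowField, orientation_set
from cedsim.imaging_io import ScalarVolume, TensorVolume

from conftest import isotropic_tensor


def spherical_case(n, k=4.22e-16, vox=None, R_mm=22.0):
    vox = vox if vox is not None else 48.0 / n
    aff = np.diag([vox, vox, vox, 1.0])
    c = (n - 1) / 2.0 * vox
    aff[:3, 3] = (-c, -c, -c)
    ii = np.indices((n, n, n)).astype(float)
    xyz = np.stack([ii[a] * vox - c for a in range(3)], axis=-1)
    r = np.linalg.norm(xyz, axis=-1)
    mask = r <= R_mm
    data = np.zeros((n, n, n, 6))
    data[..., 0] = data[..., 2] = data[..., 5] = k
    return TensorVolume(data, aff, mask), mask, r, vox


def zero_flow(shape, aff):
    mask = np.ones(shape, bool)
    flux = tuple(np.zeros(tuple(s + 1 if a == ax else s
                                for a, s in enumerate(shape)))
                 for ax in range(3))
    p = ScalarVolume(np.zeros(shape), aff, mask)
    return FlowField(pressure=p, velocity=np.zeros(shape + (3,)),
                     face_flux=flux, boundary_outflow=0.0,
                     source=np.zeros(shape))


class TestPressureSolver:
    def test_radial_darcy_oracle_converges_under_refinement(self):
        errs = []
        for n in (21, 33):
            K, mask, r, vox = spherical_case(n)
            cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
            cfg = cs.SimulationConfig()
            p, flow = cs.solve_pressure(K, cath, cfg, mask)
            k = 4.22e-16
            rm = r * 1e-3
            Rb = (22.0 + vox / 2) * 1e-3
            sel = mask & (r > 3 * vox) & (r < 22.0 - 2 * vox)
            pe = cath.flow_rate * cfg.mu / (4 * np.pi * k) \
                * (1 / rm[sel] - 1 / Rb)
            errs.append(np.sqrt(np.mean((p.data[sel] - pe) ** 2))
                        / np.sqrt(np.mean(pe ** 2)))
        assert errs[0] < 0.10
        assert errs[1] < errs[0]

    def test_fluid_mass_conservation_to_1e6(self):
        K, mask, _, _ = spherical_case(17)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        _, flow = cs.solve_pressure(K, cath, cs.SimulationConfig(), mask)
        assert abs(flow.boundary_outflow - cath.flow_rate) \
            / cath.flow_rate < 1e-6

    def test_doubling_q_doubles_pressure(self):
        K, mask, _, _ = spherical_case(13)
        cfg = cs.SimulationConfig()
        p1, _ = cs.solve_pressure(K, cs.CatheterSpec(tip_mm=(0, 0, 0)),
                                  cfg, mask)
        p2, _ = cs.solve_pressure(
            K, cs.CatheterSpec(tip_mm=(0, 0, 0),
                               flow_rate=2 * cs.CatheterSpec(
                                   tip_mm=(0, 0, 0)).flow_rate),
            cfg, mask)
        np.testing.assert_allclose(p2.data, 2 * p1.data, rtol=1e-8,
                                   atol=1e-12)

    def test_anisotropic_solution_matches_coordinate_stretch_oracle(self):
        # K = diag(k_par, k_perp, k_perp) on an ellipsoidal domain matched
        # to the anisotropy: stretching x by sqrt(k_perp/k_par) maps the
        # problem onto the radial one, so with rho = sqrt(x^T K^-1 x),
        # p = Q mu / (4 pi sqrt(det K)) (1/rho - 1/rho_R) exactly, and the
        # isobars are ellipsoids elongated along the high-permeability axis
        n = 27
        k_par, k_perp = 4e-15, 1e-15
        stretch = np.sqrt(k_par / k_perp)      # = 2
        vox = 48.0 / n
        aff = np.diag([vox, vox, vox, 1.0])
        c = (n - 1) / 2.0 * vox
        aff[:3, 3] = (-c, -c, -c)
        ii = np.indices((n, n, n)).astype(float)
        xyz = np.stack([ii[a] * vox - c for a in range(3)], axis=-1)
        R_mm = 11.0
        r_ell = np.sqrt((xyz[..., 0] / stretch) ** 2 + xyz[..., 1] ** 2
                        + xyz[..., 2] ** 2)
        mask = r_ell <= R_mm
        data = np.zeros((n, n, n, 6))
        data[..., 0] = k_par
        data[..., 2] = data[..., 5] = k_perp
        K = TensorVolume(data, aff, mask)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        cfg = cs.SimulationConfig()
        p, _ = cs.solve_pressure(K, cath, cfg, mask)

        m = 1e-3
        rho = np.sqrt((xyz[..., 0] * m) ** 2 / k_par
                      + ((xyz[..., 1] * m) ** 2 + (xyz[..., 2] * m) ** 2)
                      / k_perp)
        rho_R = (R_mm + vox / 2) * m / np.sqrt(k_perp)
        pe = cath.flow_rate * cfg.mu \
            / (4 * np.pi * np.sqrt(k_par * k_perp ** 2)) \
            * (1 / np.where(rho > 0, rho, np.inf) - 1 / rho_R)
        sel = mask & (r_ell > 3 * vox) & (r_ell < R_mm - 2 * vox)
        err = np.sqrt(np.mean((p.data[sel] - pe[sel]) ** 2)) \
            / np.sqrt(np.mean(pe[sel] ** 2))
        assert err < 0.10
        # isobars elongated along x: farther x point at equal pressure
        cc = n // 2
        assert p.data[cc + 6, cc, cc] > p.data[cc, cc + 4, cc]

    def test_axis_permutation_symmetry(self):
        # permuting the grid axes together with the tensor permutes p
        n = 15
        K, mask, _, _ = spherical_case(n)
        K.data[..., 0] = 4e-15  # anisotropic along x
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        cfg = cs.SimulationConfig()
        p1, _ = cs.solve_pressure(K, cath, cfg, mask)
        # swap x <-> y: xx <-> yy, xz <-> yz
        perm = K.data.transpose(1, 0, 2, 3)[..., [2, 1, 0, 4, 3, 5]]
        K2 = TensorVolume(perm.copy(), K.affine, mask.transpose(1, 0, 2).copy())
        p2, _ = cs.solve_pressure(K2, cath, cfg, mask.transpose(1, 0, 2))
        np.testing.assert_allclose(p2.data, p1.data.transpose(1, 0, 2),
                                   rtol=1e-7, atol=1e-9)

    def test_empty_mask_and_non_spd_rejected(self):
        K, mask, _, _ = spherical_case(9)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        with pytest.raises(ValueError, match="empty brain mask"):
            cs.solve_pressure(K, cath, cs.SimulationConfig(),
                              np.zeros_like(mask))
        K.data[..., 0] = -1e-16
        with pytest.raises(ValueError, match="not SPD"):
            cs.solve_pressure(K, cath, cs.SimulationConfig(), mask)


class TestTransportOracles:
    aff = np.diag([2.0, 2.0, 2.0, 1.0])

    def test_pure_decay_matches_exponential(self):
        n = 8
        flow = zero_flow((n, n, n), self.aff)
        D = isotropic_tensor((n, n, n), 0.0)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0), flow_rate=1e-30)
        cfg = cs.SimulationConfig(dt=2.0)  # 180 s, lambda = 0.01 / min
        res = cs.solve_transport(flow, D, cath, cfg,
                                 c_init=np.full((n, n, n), cath.c0))
        ratio = res.final_concentration.data / cath.c0
        np.testing.assert_allclose(ratio, np.exp(-0.03), rtol=1e-12)
        assert np.exp(-0.03) == pytest.approx(0.97045, abs=5e-6)

    def test_impulse_diffusion_spreads_with_variance_2dt(self):
        n, Dval, T = 12, 1e-9, 100.0
        flow = zero_flow((n, n, n), self.aff)
        D = isotropic_tensor((n, n, n), Dval)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0), flow_rate=1e-30)
        cfg = cs.SimulationConfig(dt=2.0, loss_rate=0.0, total_time=T)
        ci = np.zeros((n, n, n)); ci[n // 2, n // 2, n // 2] = 1.0
        res = cs.solve_transport(flow, D, cath, cfg, c_init=ci)
        c = res.final_concentration.data
        h = 2e-3
        for axis in range(3):
            x = (np.arange(n) - n // 2) * h
            marg = c.sum(axis=tuple(a for a in range(3) if a != axis))
            var = (marg * x ** 2).sum() / marg.sum()
            assert var == pytest.approx(2 * Dval * T, rel=1e-3)
        assert c.sum() == pytest.approx(ci.sum(), rel=1e-10)

    def test_uniform_advection_translates_centroid(self):
        n, v, T = 12, 1e-6, 1000.0
        h = 2e-3
        flux = [np.zeros((n + 1, n, n)), np.zeros((n, n + 1, n)),
                np.zeros((n, n, n + 1))]
        flux[0][1:-1] = v * h * h
        flow = zero_flow((n, n, n), self.aff)
        flow = FlowField(pressure=flow.pressure, velocity=flow.velocity,
                         face_flux=tuple(flux), boundary_outflow=0.0,
                         source=np.zeros((n, n, n)))
        D = isotropic_tensor((n, n, n), 0.0)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0), flow_rate=1e-30)
        cfg = cs.SimulationConfig(dt=2.0, loss_rate=0.0, total_time=T)
        ci = np.zeros((n, n, n)); ci[3, n // 2, n // 2] = 1.0
        res = cs.solve_transport(flow, D, cath, cfg, c_init=ci)
        c = res.final_concentration.data
        centroid = (c.sum(axis=(1, 2)) * np.arange(n) * h).sum() / c.sum()
        assert abs(centroid - 3 * h - v * T) < h  # within one cell


class TestMassBudgetAndBounds:
    def run_slab(self, loss_rate, shape=(14, 14, 14), dt=2.0):
        ph = cs.generate_phantom(cs.PhantomSpec(shape=shape))
        inputs = cs.CaseInputs(tensor=ph.tensor, fa=ph.fa, noddi=ph.noddi,
                               mask=ph.mask)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        cfg = cs.SimulationConfig(dt=dt, loss_rate=loss_rate)
        return cs.run_case(inputs, cath, cfg, mode="noddi"), cath, cfg

    def test_lossless_mass_equals_injection(self):
        res, cath, cfg = self.run_slab(loss_rate=1e-30)
        mb = res.mass_budget
        expected = cath.flow_rate * cath.c0 * cfg.total_time
        assert mb["mass"].iloc[-1] == pytest.approx(expected, rel=1e-3)
        assert mb["fluid_injected"].sum() == pytest.approx(9e-9, rel=1e-12)

    def test_budget_closes_each_step(self):
        res, cath, cfg = self.run_slab(loss_rate=cs.SimulationConfig().loss_rate)
        mb = res.mass_budget
        prev = np.concatenate([[0.0], mb["mass"].values[:-1]])
        residual = (mb["mass"] - prev - mb["injected"] + mb["decayed"]
                    - mb["clipped"])
        step_scale = np.maximum(mb["injected"].values, 1e-30)
        assert (np.abs(residual.values) / step_scale < 1e-3).all()

    def test_concentration_bounded_by_inlet(self):
        res, cath, _ = self.run_slab(loss_rate=cs.SimulationConfig().loss_rate)
        for vol in res.concentrations.values():
            assert vol.data.min() >= 0.0
            assert vol.data.max() <= cath.c0 * (1 + 1e-12)

    def test_cfl_substepping_engages_for_large_dt(self):
        res, _, _ = self.run_slab(loss_rate=1e-4, dt=180.0)
        assert res.provenance["nsub"] > 1


class TestGridConvergence:
    def test_infusion_volume_error_contracts_under_refinement(self):
        # three-grid sequence on the standard phantom: the change in the
        # 180 s threshold volume must shrink as the grid is refined (the
        # threshold volume is quantized in whole voxels, so the asymptotic
        # band itself is only reached beyond desk-scale grids)
        vols = []
        for nvox, voxmm in ((16, 2.0), (24, 1.0), (48, 0.5)):
            ph = cs.generate_phantom(cs.PhantomSpec(shape=(nvox,) * 3,
                                                    voxel_size=voxmm))
            inputs = cs.CaseInputs(tensor=ph.tensor, fa=ph.fa,
                                   noddi=ph.noddi, mask=ph.mask)
            cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
            res = cs.run_case(inputs, cath, cs.SimulationConfig(dt=4.0),
                              mode="noddi")
            reg = cs.infusion_region(res.final_concentration, cath.c0)
            vols.append(reg.volume_mm3)
        change_coarse = abs(vols[1] - vols[0]) / vols[1]
        change_fine = abs(vols[2] - vols[1]) / vols[2]
        assert change_fine < change_coarse
        assert change_fine < 0.10


class TestRunCase:
    def test_matched_constants_make_models_equivalent(self):
        # with the baseline constants set to the law values at the phantom's
        # VF_ECS, the DTI-NODDI model reduces to the DTI baseline
        ph = cs.generate_phantom(cs.PhantomSpec(shape=(12, 12, 12)))
        vf = ph.spec.vf_ecs
        const = cs.TissueConstants(k_par_dti=cs.k_parallel(vf),
                                   k_perp_dti=cs.k_perpendicular(vf))
        inputs = cs.CaseInputs(tensor=ph.tensor, fa=ph.fa, noddi=ph.noddi,
                               mask=ph.mask, constants=const)
        cath = cs.CatheterSpec(tip_mm=(0, 0, 0))
        cfg = cs.SimulationConfig(dt=6.0)
        r1 = cs.run_case(inputs, cath, cfg, mode="dti")
        r2 = cs.run_case(inputs, cath, cfg, mode="noddi")
        np.testing.assert_allclose(r2.pressure.data, r1.pressure.data,
                                   rtol=1e-8, atol=1e-6)
        np.testing.assert_allclose(r2.final_concentration.data,
                                   r1.final_concentration.data,
                                   rtol=1e-8, atol=1e-12)

    def test_csf_contact_and_tip_warnings(self):
        # 3^3 all-WM grid with one CSF voxel next to the source: the plume
        # must reach it within 180 s and trigger the warning
        shape = (3, 3, 3)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -2.0
        fa = np.full(shape, 0.7); fa[2, 1, 1] = 0.05
        vfw = np.full(shape, 0.05); vfw[2, 1, 1] = 0.995
        vf_ecs = np.full(shape, 0.3); vf_ecs[2, 1, 1] = 1.0 - 1e-4
        mask = np.ones(shape, bool)
        mk = lambda d: ScalarVolume(d, aff, mask)
        noddi = cs.NoddiMaps(mk(1 - vf_ecs), mk(vf_ecs - vfw), mk(vfw))
        dirs = np.broadcast_to([1.0, 0, 0], shape + (3,)).copy()
        from cedsim.phantom import _tensor_from_directions
        tens = _tensor_from_directions(dirs, fa)
        inputs = cs.CaseInputs(
            tensor=cs.TensorVolume.from_matrices(tens, aff, mask),
            fa=mk(fa), noddi=noddi, mask=mask)
        cfg = cs.SimulationConfig(dt=10.0)
        with pytest.warns(UserWarning, match="CSF"):
            cs.run_case(inputs, cs.CatheterSpec(tip_mm=(0, 0, 0)), cfg,
                        mode="noddi")
        with pytest.warns(UserWarning) as rec:
            cs.run_case(inputs, cs.CatheterSpec(tip_mm=(2.0, 0.0, 0.0)), cfg,
                        mode="noddi")
        assert any("tip is not inside" in str(w.message) for w in rec)

    def test_provenance_records_mode_and_constants(self):
        ph = cs.generate_phantom(cs.PhantomSpec(shape=(10, 10, 10)))
        inputs = cs.CaseInputs(tensor=ph.tensor, fa=ph.fa, noddi=ph.noddi,
                               mask=ph.mask)
        res = cs.run_case(inputs, cs.CatheterSpec(tip_mm=(0, 0, 0)),
                          cs.SimulationConfig(dt=10.0), mode="dti")
        assert res.provenance["mode"] == "dti"
        assert res.provenance["constants"]["k_par_dti"] == 6.75e-15
        assert res.provenance["catheter"]["flow_rate"] == pytest.approx(5e-11)


class TestOrientationSuite:
    def test_nine_distinct_unit_vectors(self):
        dirs = orientation_set()
        assert dirs.shape == (9, 3)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0,
                                   atol=1e-12)
        assert len({tuple(np.round(d, 9)) for d in dirs}) == 9

    def test_catheters_1_and_3_antiparallel_along_x(self):
        dirs = orientation_set()
        np.testing.assert_allclose(dirs[0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(dirs[2], [-1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(dirs[0] + dirs[2], 0.0, atol=1e-12)

    def test_bisector_components_are_inverse_sqrt3(self):
        dirs = orientation_set()
        for d in dirs[5:]:
            np.testing.assert_allclose(np.abs(d), 1 / np.sqrt(3), atol=1e-12)
        assert (dirs[5:, 2] > 0).all()

    def test_suite_returns_paired_results(self):
        ph = cs.generate_phantom(cs.PhantomSpec(shape=(8, 8, 8)))
        inputs = cs.CaseInputs(tensor=ph.tensor, fa=ph.fa, noddi=ph.noddi,
                               mask=ph.mask)
        cfg = cs.SimulationConfig(dt=30.0, total_time=60.0)
        pairs = cs.nine_orientation_suite(inputs, (0, 0, 0), cfg)
        assert len(pairs) == 9
        for r_dti, r_noddi in pairs:
            assert r_dti.provenance["mode"] == "dti"
            assert r_noddi.provenance["mode"] == "noddi"


class TestCatheterSpec:
    def test_orientation_normalized_and_validation(self):
        c = cs.CatheterSpec(tip_mm=(0, 0, 0), orientation=(2, 0, 0))
        np.testing.assert_allclose(c.orientation, [1, 0, 0])
        with pytest.raises(ValueError, match="nonzero"):
            cs.CatheterSpec(tip_mm=(0, 0, 0), orientation=(0, 0, 0))
        with pytest.raises(ValueError, match="flow rate"):
            cs.CatheterSpec(tip_mm=(0, 0, 0), flow_rate=-1.0)

    def test_defaults_are_protocol_values(self):
        c = cs.CatheterSpec(tip_mm=(0, 0, 0))
        assert c.flow_rate == pytest.approx(5e-11)
        assert c.c0 == pytest.approx(500.0)
        assert c.diameter == pytest.approx(1e-3)
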