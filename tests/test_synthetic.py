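"""Generator contracts: planted patterns, envelopes, cohorts, conditions, nuisance."""

import numpy as np
import pytest

import qppdyn as q


class TestPatternLibrary:
    def test_single_pattern_is_near_uniform_with_bounded_phase_span(self):
        (p,) = q.make_pattern_library(100, 1, seed=0)
        assert np.all(p.magnitude_map > 0)
        # near-uniform: smooth variation around the mean, not a sparse map
        rel = p.magnitude_map / p.magnitude_map.mean()
        assert rel.max() - rel.min() < 0.8
        assert p.phase_map.max() - p.phase_map.min() <= np.pi + 1e-9

    def test_magnitude_maps_near_orthogonal(self):
        pats = q.make_pattern_library(100, 3, seed=0)
        M = np.stack([p.magnitude_map for p in pats])
        gram = M @ M.T
        off = gram[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) <= 0.2)
        assert np.allclose(np.diag(gram), 1.0)  # unit-norm maps

    def test_block_patterns_are_anti_phase(self):
        pats = q.make_pattern_library(200, 3, seed=1)
        for p in pats[1:]:
            on = p.magnitude_map > 0
            phases = p.phase_map[on]
            # two blocks offset by ~pi
            spread = np.abs(np.angle(np.exp(1j * (phases[:, None] - phases[None, :]))))
            assert spread.max() > 2.0

    def test_deterministic(self):
        a = q.make_pattern_library(100, 3, seed=7)
        b = q.make_pattern_library(100, 3, seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.magnitude_map, pb.magnitude_map)
            np.testing.assert_array_equal(pa.phase_map, pb.phase_map)

    def test_too_many_patterns_rejected(self):
        with pytest.raises(ValueError):
            q.make_pattern_library(2, 3)


class TestEnvelopes:
    def test_kinds(self):
        assert np.allclose(q.EnvelopeSpec("constant", 2.0).render(5), 2.0)
        ramp = q.EnvelopeSpec("linear_ramp", 0.0, 1.0).render(5)
        np.testing.assert_allclose(ramp, [0, 0.25, 0.5, 0.75, 1.0])
        pw = q.EnvelopeSpec("piecewise", breakpoints=(2,), levels=(1.0, 3.0)).render(4)
        np.testing.assert_allclose(pw, [1, 1, 3, 3])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            q.EnvelopeSpec("constant", -1.0)
        with pytest.raises(ValueError):
            q.EnvelopeSpec("piecewise", breakpoints=(3, 2), levels=(1, 1, 1))
        with pytest.raises(ValueError):
            q.EnvelopeSpec("piecewise", breakpoints=(2,), levels=(1.0,))


class TestSimulateSubject:
    def test_noise_free_single_pattern_is_pure_sinusoid(self):
        pats = q.make_pattern_library(50, 1, seed=0)
        # carrier 0.03 Hz falls exactly on DFT bin 6 for T=200, tr=1
        ds, _ = q.simulate_subject(
            pats, [q.EnvelopeSpec("constant", 1.0)], 200, 1.0, noise_sd=0.0, seed=0
        )
        spec = np.abs(np.fft.rfft(ds.data, axis=0))
        peak_bins = spec.argmax(axis=0)
        # every location peaks at the carrier bin and has no other energy
        f_bin = round(pats[0].carrier_freq * 200 * 1.0)
        assert np.all(peak_bins == f_bin)
        other = spec.copy()
        other[f_bin] = 0.0
        assert other.max() < 1e-8 * spec.max()

    def test_crossing_envelopes_switch_true_dominant_once(self, pattern_library):
        specs = [
            q.EnvelopeSpec("linear_ramp", 0.0, 2.0),
            q.EnvelopeSpec("linear_ramp", 2.0, 0.0),
            q.EnvelopeSpec("constant", 0.0),
        ]
        _, gt = q.simulate_subject(pattern_library, specs, 100, 1.0, 0.0, seed=0)
        switches = np.sum(np.diff(gt.true_dominant) != 0)
        assert switches == 1
        assert gt.true_dominant[0] == 2 and gt.true_dominant[-1] == 1

    def test_snr_parameter_realized_within_15_percent(self, pattern_library):
        specs = [q.EnvelopeSpec("constant", 1.0) for _ in range(3)]
        ds, gt = q.simulate_subject(
            pattern_library, specs, 600, 0.72, snr=1.0, seed=1
        )
        clean, _ = q.simulate_subject(
            pattern_library, specs, 600, 0.72, noise_sd=0.0, seed=1
        )
        noise = ds.data - clean.data
        ratio = clean.data.var() / noise.var()
        assert 0.85 <= ratio <= 1.15

    def test_true_dominant_matches_envelope_argmax_with_low_index_ties(self):
        pats = q.make_pattern_library(30, 2, seed=0)
        specs = [q.EnvelopeSpec("constant", 1.0), q.EnvelopeSpec("constant", 1.0)]
        _, gt = q.simulate_subject(pats, specs, 10, 1.0, 0.0, seed=0)
        assert np.all(gt.true_dominant == 1)

    def test_parameter_errors(self, pattern_library):
        specs = [q.EnvelopeSpec("constant", 1.0) for _ in range(3)]
        with pytest.raises(ValueError):
            q.simulate_subject(pattern_library, specs, 0, 1.0)
        with pytest.raises(ValueError):
            q.simulate_subject(pattern_library, specs, 100, -1.0)
        with pytest.raises(ValueError):
            q.simulate_subject(pattern_library, specs[:2], 100, 1.0)


class TestCohort:
    def test_deterministic_and_groups_recorded(self):
        a = q.simulate_cohort(2, seed=9, n_timepoints=50, n_locations=30)
        b = q.simulate_cohort(2, seed=9, n_timepoints=50, n_locations=30)
        for (da, ga), (db, gb) in zip(a, b):
            np.testing.assert_array_equal(da.data, db.data)
            assert ga.group_id == gb.group_id
        assert {g.group_id for _, g in a} == {"ramp", "constant"}

    def test_identical_group_specs_give_symmetric_groups(self):
        specs = q.default_group_specs(3)
        same = [dict(specs[0]), dict(specs[0])]
        same[1] = {"group_id": "copy", "envelope_specs": specs[0]["envelope_specs"]}
        cohort = q.simulate_cohort(
            5, group_specs=same, seed=4, n_timepoints=80, n_locations=30
        )
        # inter-group separation of true envelope features ~ 0 (negative control)
        feats = {}
        for _, g in cohort:
            feats.setdefault(g.group_id, []).append(
                np.concatenate([g.envelopes.mean(0), g.envelopes.std(0)])
            )
        means = {k: np.mean(v, axis=0) for k, v in feats.items()}
        gap = np.linalg.norm(means["ramp"] - means["copy"])
        within = np.mean([np.std(v, axis=0).mean() for v in feats.values()])
        assert gap < 3 * within

    def test_empty_group_specs_rejected(self):
        with pytest.raises(ValueError):
            q.simulate_cohort(2, group_specs=[], seed=0)


class TestConditions:
    def test_degenerate_weights_give_pure_incidence(self):
        specs = [
            {"condition_id": "a", "weights": (1.0, 0.0, 0.0)},
            {"condition_id": "b", "weights": (0.0, 1.0, 0.0)},
        ]
        sims = q.simulate_conditions(1, specs, [200, 200], seed=0, noise_sd=0.0)
        inc_a = sims[0][1].true_incidence()
        inc_b = sims[1][1].true_incidence()
        assert inc_a[0] == 1.0 and inc_b[0] == 0.0 and inc_b[1] == 1.0

    def test_realized_fractions_track_weights(self):
        specs = [{"condition_id": "c", "weights": (0.6, 0.3, 0.1)}]
        sims = q.simulate_conditions(3, specs, [1000], seed=1, noise_sd=0.0)
        for _, gt in sims:
            np.testing.assert_allclose(
                gt.true_incidence(), [0.6, 0.3, 0.1], atol=0.05
            )

    def test_durations_honored_exactly(self):
        specs = [{"condition_id": c, "weights": (0.5, 0.3, 0.2)} for c in "abc"]
        sims = q.simulate_conditions(1, specs, [300, 600, 450], seed=0, noise_sd=0.0)
        assert [d.n_timepoints for d, _ in sims] == [300, 600, 450]

    def test_mismatched_spec_lengths_rejected(self):
        specs = [{"condition_id": "a", "weights": (1.0, 0.0, 0.0)}]
        with pytest.raises(ValueError):
            q.simulate_conditions(1, specs, [100, 100], seed=0)


class TestNuisance:
    def test_null_specs_are_identity(self, small_subject):
        ds, _ = small_subject
        out, trace = q.add_nuisance(ds, None, None, None, seed=0)
        np.testing.assert_array_equal(out.data, ds.data)
        assert np.all(trace.params == 0)

    def test_linear_drift_recovered_then_removed(self, small_subject):
        ds, _ = small_subject
        slope = 0.05  # a.u. per second
        out, _ = q.add_nuisance(ds, drift_spec={"order": 1, "coeffs": [slope]}, seed=0)
        t = np.arange(ds.n_timepoints) * ds.tr
        fit = np.polyfit(t, out.data - ds.data, 1)[0]
        np.testing.assert_allclose(fit, slope, atol=1e-10)
        # after the projection filter, the drift is gone
        filtered = q.preprocess_dataset(out, standardize=False)
        fit_after = np.polyfit(t, filtered.data, 1)[0]
        assert np.abs(fit_after).max() < 1e-3 * slope / ds.tr + 1e-4

    def test_respiration_in_passband_warns(self, small_subject):
        ds, _ = small_subject
        with pytest.warns(UserWarning, match="passband"):
            q.add_nuisance(
                ds,
                respiration_spec={
                    "freq_hz": 0.05,
                    "amplitude": 1.0,
                    "passband": (0.01, 0.1),
                },
                seed=0,
            )

    def test_deterministic(self, small_subject):
        ds, _ = small_subject
        kw = dict(
            motion_spec={"amplitude_mm": 0.1, "coupling": 0.5},
            drift_spec={"order": 2, "coeffs": [0.1, 0.01]},
            respiration_spec={"freq_hz": 0.4, "amplitude": 0.2},
        )
        a, ta = q.add_nuisance(ds, seed=42, **kw)
        b, tb = q.add_nuisance(ds, seed=42, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ta.params, tb.params)


def test_noise_free_planted_subspace_equals_top_k_principal_subspace():
    """With orthogonal maps and no noise, the planted span is the top-K subspace."""
    T, tr = 400, 1.0
    carriers = (8 / (T * tr), 13 / (T * tr), 21 / (T * tr))  # DFT-grid, distinct
    pats = q.make_pattern_library(80, 3, seed=2, carrier_freqs=carriers)
    specs = [q.EnvelopeSpec("constant", a) for a in (1.0, 0.9, 0.8)]
    ds, _ = q.simulate_subject(pats, specs, T, tr, noise_sd=0.0, seed=0)
    analytic = q.analytic_signal(ds)
    # eigendecomposition oracle of the complex covariance
    C = analytic.data.conj().T @ analytic.data
    w, V = np.linalg.eigh(C)
    top = V[:, ::-1][:, :3]
    # spatial factors of the analytic data are the conjugated complex maps
    # (X(t, v) = sum_k phasor_k(t) * [m_k(v) e^{i phi_k(v)}] enters as a plain
    # transpose, so right singular vectors carry e^{-i phi})
    planted = np.stack([np.conj(p.complex_map) for p in pats], axis=1)
    Qp, _ = np.linalg.qr(planted)
    # subspace projectors agree
    P_top = top @ top.conj().T
    P_pl = Qp @ Qp.conj().T
    assert np.abs(P_top - P_pl).max() < 1e-6
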