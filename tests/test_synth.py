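"""Phantom and spike-train generators: determinism and ground truth."""

import numpy as np
import pytest

from somatomap.ephys import standard_protocol
from somatomap.synth import (
    Blob,
    CohortParams,
    FieldPhantomParams,
    GroupEffect,
    StackPhantomParams,
    generate_cohort,
    generate_fiber_response,
    generate_terminal_stack,
    make_fiber,
)

HALF_MAX_RADIUS = np.sqrt(2 * np.log(2))  # of a Gaussian, in SD units


def centred_blob_params(**kwargs):
    return StackPhantomParams(
        shape=(9, 9, 9),
        voxel_size_um=(2.0, 1.0, 1.0),
        blobs=(Blob(centre_um=(8.0, 4.0, 4.0), spread_um=(3.0, 2.0, 2.0)),),
        background_sd=0.0,
        background_mean=0.0,
        hot_pixel_rate=0.0,
        **kwargs,
    )


class TestTerminalStack:
    def test_centred_blob_truth_centre_is_grid_centre(self):
        _, truth = generate_terminal_stack(centred_blob_params())
        np.testing.assert_allclose(truth.centre_voxel, [4.0, 4.0, 4.0], atol=1e-9)
        np.testing.assert_allclose(truth.centre_um, [8.0, 4.0, 4.0], atol=1e-9)

    def test_same_seed_bitwise_identical(self):
        params = StackPhantomParams(seed=11)
        g1, _ = generate_terminal_stack(params)
        g2, _ = generate_terminal_stack(params)
        np.testing.assert_array_equal(g1.tracer, g2.tracer)
        np.testing.assert_array_equal(g1.autofluorescence, g2.autofluorescence)

    def test_different_seed_differs(self):
        g1, _ = generate_terminal_stack(StackPhantomParams(seed=1))
        g2, _ = generate_terminal_stack(StackPhantomParams(seed=2))
        assert not np.array_equal(g1.tracer, g2.tracer)

    def test_wider_blob_has_larger_support_matching_gaussian_formula(self):
        results = {}
        for spread in (5.0, 10.0):
            params = StackPhantomParams(
                shape=(40, 80, 80),
                blobs=(
                    Blob(centre_um=(40.0, 40.0, 40.0), spread_um=(spread,) * 3),
                ),
                background_sd=0.0,
                hot_pixel_rate=0.0,
            )
            _, truth = generate_terminal_stack(params)
            # independent analytic support: voxels within the half-maximum
            # ellipsoid of the Gaussian
            vox = np.asarray(params.voxel_size_um)
            axes = [np.arange(n) * v for n, v in zip(params.shape, vox)]
            zz, yy, xx = np.meshgrid(*axes, indexing="ij")
            r2 = sum(
                ((g - 40.0) / spread) ** 2 for g in (zz, yy, xx)
            )
            expected = int((r2 < 2 * np.log(2)).sum())
            assert truth.count == expected
            results[spread] = truth
        for ax in range(3):
            assert results[10.0].extent_um[ax] > results[5.0].extent_um[ax]

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_terminal_stack(
                StackPhantomParams(shape=(2, 10, 10))
            )

    def test_hot_pixel_rate_validation(self):
        with pytest.raises(ValueError, match="hot-pixel"):
            StackPhantomParams(hot_pixel_rate=1.5)


SMALL_FIELD = FieldPhantomParams(
    shape=(32, 192, 96),
    field_semi_um=(40.0, 16.0),
    thickness_max_um=20.0,
    dv_extent_um=28.0,
)


class TestCohort:
    def test_identity_effects_give_seed_matched_identical_truths(self):
        params = CohortParams(
            base=SMALL_FIELD, mutant=GroupEffect(), n_per_group=3, seed=5
        )
        specimens = list(generate_cohort(params, render=False))
        control = [s for s in specimens if s.group == "control"]
        mutant = [s for s in specimens if s.group == "mutant"]
        for c, m in zip(control, mutant):
            assert c.truth.count == m.truth.count
            assert c.truth.centre_um == m.truth.centre_um

    def test_rc_multiplier_recovered_from_truths(self):
        params = CohortParams(
            base=SMALL_FIELD,
            mutant=GroupEffect(span_rc=1.30),
            n_per_group=12,
            seed=7,
        )
        rc = {"control": [], "mutant": []}
        for s in generate_cohort(params, render=False):
            rc[s.group].append(s.truth.extent_um[1])
        ratio = np.mean(rc["mutant"]) / np.mean(rc["control"])
        assert ratio == pytest.approx(1.30, rel=0.05)

    def test_default_displacement_recovered_as_planar_distance(self):
        params = CohortParams(base=SMALL_FIELD, n_per_group=10, seed=3)
        foci = {"control": [], "mutant": []}
        for s in generate_cohort(params, render=False):
            foci[s.group].append((s.truth.centre_um[2], s.truth.centre_um[0]))
        dists = [
            np.hypot(m[0] - c[0], m[1] - c[1])
            for c, m in zip(foci["control"], foci["mutant"])
        ]
        assert np.mean(dists) == pytest.approx(18.8, abs=0.5)

    def test_effect_multipliers_converge_on_truths(self):
        # cohort effect sizes converge to configured multipliers
        params = CohortParams(base=SMALL_FIELD, n_per_group=25, seed=1)
        ext = {"control": [], "mutant": []}
        dens = {"control": [], "mutant": []}
        for s in generate_cohort(params, render=False):
            ext[s.group].append(s.truth.extent_um)
            dens[s.group].append(s.truth.count / s.truth.projection_area_um2["DV"])
        mean_ext = {g: np.mean(v, axis=0) for g, v in ext.items()}
        ratios = mean_ext["mutant"] / mean_ext["control"]
        assert ratios[2] == pytest.approx(1.14, rel=0.05)  # ML
        assert ratios[1] == pytest.approx(1.30, rel=0.05)  # RC
        assert ratios[0] == pytest.approx(1.00, rel=0.05)  # DV
        dens_ratio = np.mean(dens["mutant"]) / np.mean(dens["control"])
        assert dens_ratio == pytest.approx(0.78, rel=0.05)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="two specimens"):
            CohortParams(n_per_group=1)

    def test_render_is_deterministic(self):
        params = CohortParams(base=SMALL_FIELD, n_per_group=2, seed=9)
        first = next(generate_cohort(params, render=True))
        again = next(generate_cohort(params, render=True))
        np.testing.assert_array_equal(first.grid.tracer, again.grid.tracer)


class TestFiberResponses:
    def test_mechano_insensitive_fibre_is_silent(self, protocol):
        train = generate_fiber_response(
            make_fiber("mechano-insensitive", seed=0), protocol
        )
        assert len(train) == 0

    def test_ram_fires_nothing_during_holds(self, protocol):
        train = generate_fiber_response(make_fiber("RAM", seed=0), protocol)
        assert len(train) > 0
        for epoch in protocol.of_kind("hold"):
            inside = (train.times >= epoch.start_s) & (train.times < epoch.end_s)
            assert inside.sum() == 0

    def test_tap_unit_fires_at_most_one_spike_only_to_tap(self, protocol):
        train = generate_fiber_response(make_fiber("tap-unit", seed=0), protocol)
        assert len(train) == 1
        tap = protocol.of_kind("manual-tap")[0]
        assert tap.start_s <= train.times[0] < tap.end_s

    def test_sam_sustains_firing_through_hold(self, protocol):
        train = generate_fiber_response(make_fiber("SAM", seed=0), protocol)
        hold = protocol.of_kind("hold")[0]
        inside = (train.times >= hold.start_s) & (train.times < hold.end_s)
        assert inside.sum() >= 1

    def test_ramp_spike_count_scales_linearly_with_dynamic_gain(self, protocol):
        # dynamic-phase counts only; vibration and tap responses do not
        # depend on the dynamic gain. Short refractory keeps thinning
        # losses negligible at the rates involved.
        import dataclasses

        ramps = protocol.of_kind("ramp")
        counts = {}
        for gain in (60.0, 120.0):
            totals = []
            for seed in range(50):
                model = dataclasses.replace(
                    make_fiber("RAM", seed=seed),
                    dynamic_gain=gain, refractory_ms=0.1, seed=seed,
                )
                train = generate_fiber_response(model, protocol)
                totals.append(sum(
                    int(np.sum((train.times >= e.start_s) & (train.times < e.end_s)))
                    for e in ramps
                ))
            counts[gain] = np.mean(totals)
        assert counts[120.0] / counts[60.0] == pytest.approx(2.0, rel=0.1)

    def test_refractory_period_enforced(self, protocol):
        train = generate_fiber_response(make_fiber("SAM", seed=4), protocol)
        assert np.all(np.diff(train.times) >= 1e-3 - 1e-12)

    def test_same_seed_identical_train(self, protocol):
        a = generate_fiber_response(make_fiber("RAM", seed=3), protocol)
        b = generate_fiber_response(make_fiber("RAM", seed=3), protocol)
        np.testing.assert_array_equal(a.times, b.times)
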