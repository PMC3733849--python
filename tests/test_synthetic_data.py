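"""Generator contracts: determinism, effect directions, truth bookkeeping."""

import numpy as np
import pytest

from strokedti.image_io import ImageGrid, default_gradient_table
from strokedti.synthetic_data import (
    PhantomSpec,
    make_phantom,
    simulate_behavior,
    simulate_cohort,
    simulate_dwi,
    simulate_ihc_field,
)
from strokedti.tensor_fit import eigensystem, fit_volume, md_map


class TestPhantom:
    def test_intact_baseline_multipliers(self):
        spec = PhantomSpec(condition="intact")
        _, _, truth = make_phantom(spec)
        lm, _, _ = make_phantom(spec)
        ca23 = truth.values[lm.region_mask("hippocampus_CA23_ipsi")]
        np.testing.assert_allclose(ca23, spec.region_md["hippocampus_CA23_ipsi"])
        assert "infarct" not in lm.legend

    def test_mcao_effect_is_ipsilateral_only(self):
        spec = PhantomSpec(condition="MCAO", ca23_multiplier=0.9)
        lm, _, truth = make_phantom(spec)
        ipsi = truth.values[lm.region_mask("hippocampus_CA23_ipsi")]
        contra = truth.values[lm.region_mask("hippocampus_CA23_contra")]
        np.testing.assert_allclose(ipsi, 0.9 * spec.region_md["hippocampus_CA23_ipsi"])
        np.testing.assert_allclose(contra, spec.region_md["hippocampus_CA23_contra"])

    def test_effect_direction_contract(self):
        """Infarct MD above cortex baseline; stroke CA2/3 below sham;
        knockout stroke equals sham."""
        sham = make_phantom(PhantomSpec(condition="sham"))
        mcao = make_phantom(PhantomSpec(condition="MCAO"))
        ko = make_phantom(PhantomSpec(condition="KO_MCAO"))

        def region_md(out, region):
            lm, _, truth = out
            return truth.values[lm.region_mask(region)].mean()

        assert region_md(mcao, "infarct") > region_md(mcao, "cortex")
        assert region_md(mcao, "hippocampus_CA23_ipsi") < region_md(
            sham, "hippocampus_CA23_ipsi"
        )
        assert region_md(ko, "hippocampus_CA23_ipsi") == pytest.approx(
            region_md(sham, "hippocampus_CA23_ipsi")
        )

    def test_every_region_at_least_20_voxels(self):
        lm, _, _ = make_phantom(PhantomSpec(condition="MCAO"))
        for name, lid in lm.legend.items():
            assert (lm.labels == lid).sum() >= 20, name

    def test_deterministic_given_spec(self):
        a = make_phantom(PhantomSpec(condition="MCAO", seed=3))
        b = make_phantom(PhantomSpec(condition="MCAO", seed=3))
        assert np.array_equal(a[0].labels, b[0].labels)
        np.testing.assert_array_equal(a[1].d, b[1].d)

    def test_anisotropic_region_keeps_md(self):
        spec = PhantomSpec(region_fa={"cortex": 0.3})
        lm, tv, truth = make_phantom(spec)
        sel = lm.region_mask("cortex")
        md = tv.d[sel][:, :3].mean(axis=1)
        np.testing.assert_allclose(md, spec.region_md["cortex"], rtol=1e-12)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PhantomSpec(condition="lesion")
        with pytest.raises(ValueError):
            PhantomSpec(snr=-1)


class TestSimulateDwi:
    def test_noiseless_roundtrip_through_fit(self, small_phantom):
        spec, labels, truth_tv, truth_md = small_phantom
        stack = simulate_dwi(truth_tv, spec.table, snr=None)
        fit, _ = fit_volume(stack, mask=labels.labels > 0)
        md = md_map(eigensystem(fit))
        sel = labels.labels > 0
        np.testing.assert_allclose(md.values[sel], truth_md.values[sel], rtol=1e-9)

    def test_isotropic_directions_equal_noiseless_intensity(self, table):
        from conftest import uniform_isotropic_volume

        tv = uniform_isotropic_volume((4, 4, 1), d=3e-4)
        stack = simulate_dwi(tv, table, snr=None)
        dw = stack.signal[2, 2, 0, table.bvals > 0]
        np.testing.assert_allclose(dw, dw[0], rtol=1e-12)
        assert stack.signal[2, 2, 0, 0] == pytest.approx(1000.0)

    def test_b0_rician_bias_matches_closed_form(self, table):
        """Mean b=0 intensity is biased upward by the Rician floor; the
        exact mean is sigma·sqrt(pi/2)·L_{1/2}(-S²/2sigma²)."""
        from scipy.special import hyp1f1
        from conftest import uniform_isotropic_volume

        snr = 3.0  # low SNR so the bias is visible
        s0 = 100.0
        sigma = s0 / snr
        tv = uniform_isotropic_volume((200, 200, 1), d=3e-4, s0=s0)
        stack = simulate_dwi(tv, table, s0=s0, snr=snr, seed=9)
        b0 = stack.signal[..., 0]
        # E|S+n| for complex Gaussian n: sigma*sqrt(pi/2)*1F1(-1/2;1;-S^2/(2 sigma^2))
        expect = sigma * np.sqrt(np.pi / 2) * hyp1f1(-0.5, 1.0, -(s0**2) / (2 * sigma**2))
        assert expect > s0  # upward bias
        assert b0.mean() == pytest.approx(expect, rel=0.01)

    def test_seeded_noise_reproducible(self, table):
        from conftest import uniform_isotropic_volume

        tv = uniform_isotropic_volume((5, 5, 1))
        s1 = simulate_dwi(tv, table, snr=30, seed=4).signal
        s2 = simulate_dwi(tv, table, snr=30, seed=4).signal
        s3 = simulate_dwi(tv, table, snr=30, seed=5).signal
        assert np.array_equal(s1, s2)
        assert not np.array_equal(s1, s3)


class TestCohort:
    def test_paper_scale_design(self):
        subs = simulate_cohort(
            {"MCAO": 6, "intact": 7},
            template=PhantomSpec(grid=ImageGrid((48, 48, 1))),
            base_seed=8,
        )
        assert len(subs) == 13
        assert sum(s.condition == "MCAO" for s in subs) == 6
        assert len({s.subject_id for s in subs}) == 13

    def test_zero_cv_no_noise_subjects_identical(self):
        subs = simulate_cohort(
            {"sham": 3},
            template=PhantomSpec(grid=ImageGrid((48, 48, 1)), snr=None),
            base_seed=8,
            between_subject_cv=0.0,
        )
        assert np.array_equal(subs[0].stack.signal, subs[1].stack.signal)
        assert np.array_equal(subs[1].stack.signal, subs[2].stack.signal)

    def test_distinct_base_seeds_change_noise_not_structure(self):
        kw = dict(template=PhantomSpec(grid=ImageGrid((48, 48, 1))), between_subject_cv=0.0)
        a = simulate_cohort({"sham": 2}, base_seed=1, **kw)
        b = simulate_cohort({"sham": 2}, base_seed=2, **kw)
        assert not np.array_equal(a[0].stack.signal, b[0].stack.signal)
        assert np.array_equal(a[0].labels.labels, b[0].labels.labels)
        np.testing.assert_array_equal(a[0].truth_md.values, b[0].truth_md.values)

    def test_full_determinism_same_seed(self):
        kw = dict(template=PhantomSpec(grid=ImageGrid((48, 48, 1))))
        a = simulate_cohort({"MCAO": 2}, base_seed=77, **kw)
        b = simulate_cohort({"MCAO": 2}, base_seed=77, **kw)
        assert np.array_equal(a[0].stack.signal, b[0].stack.signal)
        np.testing.assert_array_equal(a[1].truth_md.values, b[1].truth_md.values)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            simulate_cohort({"MCAO": 0})
        with pytest.raises(ValueError):
            simulate_cohort({"nonsense": 2})


class TestIhcField:
    def test_zero_density_blank_truth(self):
        f, truth = simulate_ihc_field(density_per_marker={"GFAP": 0.0}, seed=1)
        assert truth["GFAP"] == 0.0

    def test_single_blob_footprint(self):
        """One disk of known radius: truth equals its pixel footprint."""
        f, truth = simulate_ihc_field(
            density_per_marker={"GFAP": 1.0 / 0.36},  # ≈1 expected blob
            blob_radius_um=(6.0, 0.0),
            seed=3,
        )
        mask_px = truth["GFAP"] / 100.0 * 400 * 400
        n_blobs = round(mask_px / (np.pi * (6.0 / 1.5) ** 2))
        if n_blobs == 1:  # blob fully inside and non-overlapping
            assert mask_px == pytest.approx(np.pi * 4.0**2, rel=0.15)

    def test_field_below_min_area_rejected(self):
        with pytest.raises(ValueError, match="0.28"):
            simulate_ihc_field(field_shape=(100, 100), pixel_size_um=1.0)

    def test_determinism(self):
        f1, t1 = simulate_ihc_field(seed=6)
        f2, t2 = simulate_ihc_field(seed=6)
        assert t1 == t2
        assert np.array_equal(f1.channels["GFAP"], f2.channels["GFAP"])

    def test_saturated_density_flagged(self):
        with pytest.raises(ValueError, match="95%"):
            simulate_ihc_field(density_per_marker={"GFAP": 30000.0}, seed=0)


class TestBehavior:
    def test_zero_noise_equals_group_means(self):
        t = simulate_behavior(
            {"sham": (60.0, 20.0)}, {"sham": 4}, noise_sd=(0.0, 0.0), seed=0
        )
        assert (t.freezing_percent == 60.0).all()
        assert (t.neuro_score == 20).all()

    def test_ranges_enforced(self):
        with pytest.raises(ValueError, match="freezing"):
            simulate_behavior({"g": (110.0, 10.0)}, {"g": 3})
        with pytest.raises(ValueError, match="neuro"):
            simulate_behavior({"g": (50.0, 25.0)}, {"g": 3})
        t = simulate_behavior({"g": (2.0, 1.0)}, {"g": 200}, noise_sd=(20.0, 4.0), seed=1)
        assert t.freezing_percent.between(0, 100).all()
        assert t.neuro_score.between(0, 21).all()

    def test_detection_rate_matches_power_oracle(self):
        """Simulated detection rate of a 1.5-pooled-SD freezing deficit
        (n = 6 vs 6, two-sided pooled t at 0.05) agrees with the
        noncentral-t closed form."""
        from scipy import stats as sps
        from strokedti.group_stats import student_t

        sd, delta, n = 8.0, 1.5 * 8.0, 6
        n_rep = 400
        hits = 0
        for rep in range(n_rep):
            t = simulate_behavior(
                {"sham": (60.0, 20.0), "MCAO": (60.0 - delta, 14.0)},
                {"sham": n, "MCAO": n},
                noise_sd=(sd, 1.5),
                seed=10_000 + rep,
            )
            g = {k: s.freezing_percent.to_numpy() for k, s in t.groupby("group")}
            hits += student_t(g["sham"], g["MCAO"]).significant
        rate = hits / n_rep
        ncp = 1.5 * np.sqrt(n * n / (2 * n))
        power = sps.nct.sf(sps.t.isf(0.025, 2 * n - 2), 2 * n - 2, ncp)
        assert rate == pytest.approx(power, abs=4 * np.sqrt(power * (1 - power) / n_rep))
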