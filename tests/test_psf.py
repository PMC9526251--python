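"""Bead detection, exclusion rules and Gaussian FWHM fitting."""

import numpy as np
import pytest

from microqc import AcquisitionMeta, ChannelMeta, Modality
from microqc.psf import (
    Exclusion,
    analyze_psf_stack,
    central_zone_filter,
    detect_beads,
    fit_psf,
    summarize_psf,
    BeadRecord,
    PsfResult,
)
from microqc.resolution import theoretical_resolution
from microqc.synth import make_bead_stack


@pytest.fixture
def clean_stack():
    return make_bead_stack(seed=11)


class TestDetectBeads:
    def test_well_separated_beads_all_kept(self, clean_stack, wf_meta):
        stack, truth = clean_stack
        beads = detect_beads(stack, wf_meta, prominence=2000)
        kept = [b for b in beads if b.kept]
        assert len(kept) == len(truth["positions_zyx_px"])
        found = sorted((b.y, b.x) for b in kept)
        expected = sorted((round(p[1]), round(p[2])) for p in truth["positions_zyx_px"])
        for (fy, fx), (ey, ex) in zip(found, expected):
            assert abs(fy - ey) <= 1 and abs(fx - ex) <= 1

    def test_close_pair_both_marked_too_close(self, wf_meta):
        spec = theoretical_resolution(wf_meta, wf_meta.channels[0])
        stack, _ = make_bead_stack(
            seed=0,
            positions=[(20, 96.0, 80.0), (20, 96.0, 100.0)],  # 1 µm apart
        )
        beads = detect_beads(stack, wf_meta, prominence=2000, min_spacing=2.0)
        assert [b.exclusion for b in beads] == [Exclusion.TOO_CLOSE] * 2

    def test_edge_bead_marked(self, wf_meta):
        stack, _ = make_bead_stack(seed=0, positions=[(20, 5.0, 5.0), (20, 96.0, 96.0)])
        beads = detect_beads(stack, wf_meta, prominence=2000)
        by_pos = {(b.y, b.x): b.exclusion for b in beads}
        assert by_pos[(5, 5)] is Exclusion.EDGE
        assert by_pos[(96, 96)] is Exclusion.KEPT

    def test_saturated_bead_marked_when_discarding(self, wf_meta):
        stack, _ = make_bead_stack(seed=0, positions=[(20, 96.0, 96.0)], amplitude=1e6)
        assert stack.max() == wf_meta.max_value
        (bead,) = detect_beads(stack, wf_meta, prominence=2000, discard_saturated=True)
        assert bead.exclusion is Exclusion.SATURATED
        (bead,) = detect_beads(stack, wf_meta, prominence=2000, discard_saturated=False)
        assert bead.kept

    def test_no_beads_kept_warns_not_raises(self, wf_meta):
        stack, _ = make_bead_stack(seed=0, positions=[(20, 3.0, 3.0)])
        with pytest.warns(UserWarning, match="no beads kept"):
            beads = detect_beads(stack, wf_meta, prominence=2000)
        assert not any(b.kept for b in beads)

    def test_too_few_planes_rejected(self, wf_meta):
        with pytest.raises(ValueError, match="z-planes"):
            detect_beads(np.zeros((2, 64, 64)), wf_meta, prominence=10)


class TestCentralZoneFilter:
    def _bead(self, x, y):
        return BeadRecord(x=x, y=y, z_max=0, roi_xy=5, roi_z=5)

    def test_center_kept_corner_flagged(self):
        beads = [self._bead(64, 64), self._bead(2, 2)]
        central_zone_filter(beads, (128, 128), fraction=0.30)
        assert beads[0].kept
        assert beads[1].exclusion is Exclusion.CENTRAL_ZONE_OUT

    def test_full_fraction_keeps_everything(self):
        beads = [self._bead(0, 0), self._bead(127, 127)]
        central_zone_filter(beads, (128, 128), fraction=1.0)
        assert all(b.kept for b in beads)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            central_zone_filter([], (64, 64), fraction=0.0)


class TestFitPsf:
    def test_noiseless_fwhm_recovery_within_half_percent(self, clean_stack, wf_meta):
        stack, truth = clean_stack
        beads = [b for b in detect_beads(stack, wf_meta, prominence=2000) if b.kept]
        for bead in beads:
            res = fit_psf(stack, bead, wf_meta)
            assert res.valid
            assert res.fwhm_x == pytest.approx(truth["fwhm_xy_um"], rel=0.005)
            assert res.fwhm_y == pytest.approx(truth["fwhm_xy_um"], rel=0.005)
            assert res.fwhm_z == pytest.approx(truth["fwhm_z_um"], rel=0.005)
            assert res.r2_x > 0.999 and res.r2_y > 0.999 and res.r2_z > 0.999

    def test_lar_is_one_for_symmetric_bead(self):
        res = PsfResult(fwhm_x=0.19, fwhm_y=0.19, fwhm_z=0.7)
        assert res.lar == 1.0

    def test_lar_min_over_max(self):
        res = PsfResult(fwhm_x=0.20, fwhm_y=0.16, fwhm_z=0.7)
        assert res.lar == pytest.approx(0.8)

    def test_snr_normalized_to_12bit(self, wf_meta):
        # a 40000-count voxel in a 16-bit image is 40000/16 in 12-bit units
        stack, _ = make_bead_stack(seed=0, positions=[(20, 96.0, 96.0)], amplitude=39900, background=100)
        (bead,) = [b for b in detect_beads(stack, wf_meta, prominence=2000) if b.kept]
        res = fit_psf(stack, bead, wf_meta)
        assert res.snr == pytest.approx(np.sqrt(stack.max() / 16.0), rel=1e-6)

    def test_sbr_reflects_signal_over_background(self, wf_meta):
        stack, _ = make_bead_stack(seed=0, positions=[(20, 96.0, 96.0)], amplitude=5000, background=500)
        (bead,) = [b for b in detect_beads(stack, wf_meta, prominence=1000) if b.kept]
        res = fit_psf(stack, bead, wf_meta)
        assert res.sbr > 3

    def test_excluded_bead_rejected(self, clean_stack, wf_meta):
        stack, _ = clean_stack
        bead = BeadRecord(x=5, y=5, z_max=20, roi_xy=5, roi_z=5, exclusion=Exclusion.EDGE)
        with pytest.raises(ValueError, match="excluded"):
            fit_psf(stack, bead, wf_meta)


class TestSummarize:
    def _spec(self, meta):
        return theoretical_resolution(meta, meta.channels[0])

    def test_identical_beads_zero_sd(self, clean_stack, wf_meta):
        stack, _ = clean_stack
        beads = [b for b in detect_beads(stack, wf_meta, prominence=2000) if b.kept]
        results = [fit_psf(stack, b, wf_meta) for b in beads]
        summary = summarize_psf(results, self._spec(wf_meta))
        for ax in "xyz":
            assert summary.sd_fwhm[ax] == pytest.approx(0.0, abs=1e-4)

    def test_r2_filter_drops_bead_per_axis(self, wf_meta):
        results = [
            PsfResult(fwhm_x=0.19, fwhm_y=0.19, fwhm_z=0.7, r2_x=0.99, r2_y=0.99, r2_z=0.99)
            for _ in range(4)
        ]
        results.append(
            PsfResult(fwhm_x=0.19, fwhm_y=0.19, fwhm_z=5.0, r2_x=0.99, r2_y=0.99, r2_z=0.90)
        )
        summary = summarize_psf(results, self._spec(wf_meta))
        assert summary.n_used["z"] == 4
        assert summary.n_used["x"] == 5
        assert summary.mean_fwhm["z"] == pytest.approx(0.7)

    def test_all_filtered_raises_naming_filter(self, wf_meta):
        results = [PsfResult(fwhm_x=0.19, fwhm_y=0.19, fwhm_z=0.7, r2_x=0.5, r2_y=0.5, r2_z=0.5)]
        with pytest.raises(ValueError, match="R²"):
            summarize_psf(results, self._spec(wf_meta))

    def test_few_beads_warns_in_summary(self, wf_meta):
        results = [
            PsfResult(fwhm_x=0.19, fwhm_y=0.19, fwhm_z=0.7, r2_x=1.0, r2_y=1.0, r2_z=1.0)
        ]
        summary = summarize_psf(results, self._spec(wf_meta))
        assert any("at least 5" in w for w in summary.warnings)


class TestEndToEnd:
    def test_noisy_parameter_recovery(self, wf_meta):
        """Seeded shot+read noise at SBR>3: median FWHM error <5% xy, <8% z."""
        stack, truth = make_bead_stack(
            seed=42,
            shape=(41, 448, 448),
            n_beads=20,
            amplitude=3000,
            background=200,
            shot_noise=True,
            read_sigma=10.0,
        )
        results, summary = analyze_psf_stack(stack, wf_meta, prominence=800)
        assert summary.n_beads == 20
        assert summary.mean_sbr > 3
        err_x = [abs(r.fwhm_x - truth["fwhm_xy_um"]) / truth["fwhm_xy_um"] for r in results]
        err_z = [abs(r.fwhm_z - truth["fwhm_z_um"]) / truth["fwhm_z_um"] for r in results]
        assert np.median(err_x) < 0.05
        assert np.median(err_z) < 0.08

    def test_processing_is_deterministic(self, wf_meta):
        stack, _ = make_bead_stack(seed=7, shot_noise=True, read_sigma=5.0)
        r1, s1 = analyze_psf_stack(stack, wf_meta, prominence=2000)
        r2, s2 = analyze_psf_stack(stack, wf_meta, prominence=2000)
        assert s1.mean_fwhm == s2.mean_fwhm
        for a, b in zip(r1, r2):
            assert (a.fwhm_x, a.fwhm_y, a.fwhm_z, a.sbr, a.snr) == (
                b.fwhm_x, b.fwhm_y, b.fwhm_z, b.sbr, b.snr
            )

    def test_coarse_sampling_biases_fwhm_upward(self, gfp_channel):
        """Lateral FWHM at pixels beyond ~1.16x Nyquist reads high vs fine sampling."""
        from microqc.core import AcquisitionMeta, Modality

        fwhm = 0.19125
        means = []
        for pixel in (0.04, 0.12):  # fine vs well past the 1-AU Nyquist bound
            meta = AcquisitionMeta(
                Modality.WF, 1.4, 1.515, pixel, z_step=0.1, channels=(gfp_channel,)
            )
            stack, _ = make_bead_stack(
                seed=3,
                shape=(41, 160, 160),
                pixel_size_xy=pixel,
                n_beads=4,
                shot_noise=True,
                read_sigma=5.0,
                amplitude=8000,
            )
            _, summary = analyze_psf_stack(stack, meta, prominence=2000)
            means.append((summary.mean_fwhm["x"] + summary.mean_fwhm["y"]) / 2)
        assert means[1] > means[0]
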