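"""Perfusion metrics inside the disc and the scan-level QC rule."""

import numpy as np
import pandas as pd
import pytest

from omagperf.metrics import (
    compute_flux,
    compute_normalized_flux,
    compute_perfusion_metrics,
    compute_vessel_area_density,
    qc_filter,
)


@pytest.fixture
def disc():
    d = np.zeros((20, 20), bool)
    d[4:16, 4:16] = True
    return d


class TestFlux:
    def test_extremes(self, disc):
        assert compute_flux(np.zeros((20, 20)), disc) == 0.0
        assert compute_flux(np.full((20, 20), 255.0), disc) == pytest.approx(1.0)

    def test_half_and_half(self, disc):
        F = np.zeros((20, 20))
        F[:10] = 255.0
        assert compute_flux(F, disc) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng, disc):
        F = rng.random((20, 20)) * 255
        total, n = 0.0, 0
        for i in range(20):
            for j in range(20):
                if disc[i, j]:
                    total += F[i, j] / 255.0
                    n += 1
        assert compute_flux(F, disc) == pytest.approx(total / n, rel=1e-12)

    def test_monotone_in_every_pixel(self, rng, disc):
        F = rng.random((20, 20)) * 200
        bumped = F.copy()
        bumped[8, 8] += 50
        assert compute_flux(bumped, disc) > compute_flux(F, disc)

    def test_empty_disc_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_flux(np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestDensity:
    def test_extremes(self, disc):
        assert compute_vessel_area_density(np.ones((20, 20), bool), disc) == 1.0
        assert compute_vessel_area_density(np.zeros((20, 20), bool), disc) == 0.0

    def test_matches_counting_oracle(self, rng, disc):
        vessel = rng.random((20, 20)) > 0.6
        expected = sum(1 for i in range(20) for j in range(20)
                       if vessel[i, j] and disc[i, j]) / disc.sum()
        assert compute_vessel_area_density(vessel, disc) == pytest.approx(expected)


class TestNormalizedFlux:
    def test_saturated_vessels(self, disc):
        vessel = disc.copy()
        assert compute_normalized_flux(np.full((20, 20), 255.0), vessel, disc) == pytest.approx(1.0)

    def test_two_level_identity_example(self, disc):
        # vessels at 200, background at 50, density 1/2:
        # nf = 200/255 and flux = 0.5*(200/255) + 0.5*(50/255)
        vessel = np.zeros((20, 20), bool)
        vessel[4:16, 4:10] = True
        F = np.where(vessel, 200.0, 50.0)
        nf = compute_normalized_flux(F, vessel, disc)
        flux = compute_flux(F, disc)
        assert nf == pytest.approx(200 / 255, abs=1e-12)
        assert flux == pytest.approx(0.5 * 200 / 255 + 0.5 * 50 / 255, abs=1e-12)

    def test_undefined_without_vessels_is_nan_flagged(self, disc):
        with pytest.warns(UserWarning, match="undefined"):
            nf = compute_normalized_flux(np.zeros((20, 20)), np.zeros((20, 20), bool), disc)
        assert np.isnan(nf)
        pm = compute_perfusion_metrics(np.zeros((20, 20)), np.zeros((20, 20), bool), disc)
        assert not pm.normalized_flux_defined

    def test_disc_sum_identity_on_random_maps(self, disc):
        # flux = d*nf + (1-d)*mean(non-vessel normalized flow), exactly
        rng = np.random.default_rng(99)
        for _ in range(20):
            F = rng.random((20, 20)) * 255
            vessel = rng.random((20, 20)) > rng.uniform(0.2, 0.8)
            if not (vessel & disc).any() or not (~vessel & disc).any():
                continue
            flux = compute_flux(F, disc)
            d = compute_vessel_area_density(vessel, disc)
            nf = compute_normalized_flux(F, vessel, disc)
            bbar = (F[~vessel & disc] / 255).mean()
            assert flux == pytest.approx(d * nf + (1 - d) * bbar, abs=1e-12)


class TestQC:
    def make(self, strengths, motions=None, groups=None):
        n = len(strengths)
        return pd.DataFrame({
            "signal_strength": strengths,
            "motion_flag": motions if motions is not None else [False] * n,
            "group": groups if groups is not None else ["normal"] * n,
        })

    def test_cutoff_boundary(self):
        inc, exc, _ = qc_filter(self.make([5, 6]))
        assert list(exc["signal_strength"]) == [5]
        assert list(inc["signal_strength"]) == [6]

    def test_study_accounting(self):
        # enrolled 30/33/33 with 2/3/2 flagged scans -> analysed 28/30/31
        rows = []
        for g, n_enrolled, n_flagged in [("normal", 30, 2), ("POAG", 33, 3), ("NTG", 33, 2)]:
            for i in range(n_enrolled):
                rows.append({"group": g, "signal_strength": 4 if i < n_flagged else 8,
                             "motion_flag": False})
        _, _, counts = qc_filter(pd.DataFrame(rows))
        assert counts.loc["normal", "included"] == 28
        assert counts.loc["POAG", "included"] == 30
        assert counts.loc["NTG", "included"] == 31

    def test_motion_flag_excludes(self):
        inc, exc, _ = qc_filter(self.make([9, 9], motions=[True, False]))
        assert len(inc) == 1 and len(exc) == 1

    def test_no_flags_keeps_everything(self):
        inc, exc, _ = qc_filter(self.make([7, 8, 10]))
        assert len(inc) == 3 and exc.empty

    def test_missing_strength_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            inc, exc, _ = qc_filter(self.make([np.nan, 8]))
        assert len(exc) == 1

    def test_out_of_range_strength_rejected(self):
        with pytest.raises(ValueError, match="0, 10"):
            qc_filter(self.make([11]))
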