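import numpy as np
import pytest

from fodfbias.errors import CardinalityError, DivisionGuardError, GridMismatchError
from fodfbias.odf_core import DirectionSet, FODFField, angles_for_set, fodf_to_pmf
from fodfbias.reweight import (
    CohortFODF,
    StdField,
    assemble_cohort,
    change_histogram,
    cross_subject_std,
    reweight_cohort,
    reweight_fodf,
)


def _dirs(n_half, seed=0):
    half = np.random.default_rng(seed).normal(size=(n_half, 3))
    half /= np.linalg.norm(half, axis=1, keepdims=True)
    return DirectionSet(np.concatenate([half, -half]))


def _cohort(stack, roi=None, ds=None):
    s, *grid, n = stack.shape
    if ds is None:
        ds = _dirs(n // 2)
    if roi is None:
        roi = np.ones(grid, dtype=bool)
    return CohortFODF(
        stack=stack,
        subject_ids=[f"s{i}" for i in range(s)],
        roi_mask=roi,
        affine=np.eye(4),
        directions=ds,
    )


class TestCrossSubjectStd:
    def test_identical_subjects_give_zero_sigma(self):
        base = np.random.default_rng(0).random((2, 2, 2, 8))
        cohort = _cohort(np.stack([base] * 4))
        sf = cross_subject_std(cohort)
        assert np.allclose(sf.sigma, 0.0)

    def test_two_subject_closed_form(self):
        stack = np.zeros((2, 1, 1, 1, 8))
        stack[0, 0, 0, 0, 3] = 1.0
        stack[1, 0, 0, 0, 3] = 3.0
        sf = cross_subject_std(_cohort(stack))
        assert sf.sigma[0, 0, 0, 3] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_voxelwise_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(1)
        stack = rng.random((5, 3, 2, 2, 10))
        roi = rng.random((3, 2, 2)) > 0.3
        sf = cross_subject_std(_cohort(stack, roi=roi))
        for idx in np.ndindex(3, 2, 2):
            for d in range(10):
                if roi[idx]:
                    expected = np.std(stack[(slice(None),) + idx + (d,)], ddof=1)
                    assert sf.sigma[idx + (d,)] == pytest.approx(expected, abs=1e-12)
                else:
                    assert np.isnan(sf.sigma[idx + (d,)])

    def test_roi_pooled_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        stack = rng.random((4, 2, 2, 1, 6))
        roi = np.array([[[True], [False]], [[True], [True]]])
        sf = cross_subject_std(_cohort(stack, roi=roi), mode="roi_pooled")
        pooled = stack[:, roi, :].reshape(-1, 6)
        for d in range(6):
            expected = np.std(pooled[:, d], ddof=1)
            assert np.allclose(sf.sigma[roi, d], expected, atol=1e-12)

    def test_single_subject_rejected(self):
        stack = np.ones((1, 1, 1, 1, 4))
        with pytest.raises(CardinalityError):
            _cohort(stack)  # assembly also enforces >= 2 via cross_subject_std
            cross_subject_std(
                CohortFODF(
                    stack=stack, subject_ids=["a"], roi_mask=np.ones((1, 1, 1), bool),
                    affine=np.eye(4), directions=_dirs(2),
                )
            )


class TestReweightFodf:
    def _field_and_sigma(self, dens, sigma_vals, roi=None):
        n = dens.shape[-1]
        ds = _dirs(n // 2)
        f = FODFField(densities=dens, affine=np.eye(4), directions=ds)
        if roi is None:
            roi = np.ones(dens.shape[:3], dtype=bool)
        sig = np.full(dens.shape, np.nan)
        sig[roi] = sigma_vals
        return f, StdField(sigma=sig, roi_mask=roi)

    def test_uniform_sigma_rescales_but_preserves_pmf(self):
        dens = np.random.default_rng(3).random((2, 1, 1, 8))
        f, sf = self._field_and_sigma(dens, 0.5)
        out = reweight_fodf(f, sf, epsilon=0.1)
        assert np.allclose(out.densities, dens / 0.6)
        assert np.allclose(
            fodf_to_pmf(out, (0, 0, 0)), fodf_to_pmf(f, (0, 0, 0)), atol=1e-9
        )

    def test_low_sigma_direction_boosted_tenfold(self):
        dens = np.ones((1, 1, 1, 8))
        sigma_vals = np.ones(8)
        sigma_vals[2] = 0.1
        f, sf = self._field_and_sigma(dens, sigma_vals)
        out = reweight_fodf(f, sf, epsilon=0.0)
        rel = out.densities[0, 0, 0] / out.densities[0, 0, 0, 0]
        assert rel[2] == pytest.approx(10.0, abs=1e-12)

    def test_outside_roi_passes_through_unchanged(self):
        dens = np.random.default_rng(4).random((2, 1, 1, 6))
        roi = np.array([[[True]], [[False]]])
        f, sf = self._field_and_sigma(dens, 0.5, roi=roi)
        out = reweight_fodf(f, sf, epsilon=0.0)
        assert np.array_equal(out.densities[1], dens[1])
        assert not np.array_equal(out.densities[0], dens[0])

    def test_zero_sigma_with_zero_epsilon_names_offending_voxel(self):
        dens = np.ones((2, 1, 1, 4))
        sigma_vals = np.zeros(4)
        f, sf = self._field_and_sigma(dens, sigma_vals)
        with pytest.raises(DivisionGuardError, match=r"\(0, 0, 0\)"):
            reweight_fodf(f, sf, epsilon=0.0)

    def test_lowering_one_sigma_never_decreases_that_pmf_value(self):
        rng = np.random.default_rng(5)
        dens = rng.random((1, 1, 1, 10)) + 0.1
        sigma_vals = rng.random(10) + 0.5
        f, sf_hi = self._field_and_sigma(dens, sigma_vals)
        for d in range(10):
            lowered = sigma_vals.copy()
            lowered[d] *= 0.25
            _, sf_lo = self._field_and_sigma(dens, lowered)
            hi = fodf_to_pmf(reweight_fodf(f, sf_hi, epsilon=0.0), (0, 0, 0))
            lo = fodf_to_pmf(reweight_fodf(f, sf_lo, epsilon=0.0), (0, 0, 0))
            assert lo[d] >= hi[d] - 1e-12

    def test_grid_mismatch_rejected(self):
        f, _ = self._field_and_sigma(np.ones((2, 1, 1, 4)), 1.0)
        _, sf = self._field_and_sigma(np.ones((1, 1, 1, 4)), 1.0)
        with pytest.raises(GridMismatchError):
            reweight_fodf(f, sf)


def _loop_change_histogram(before, after, phi, defined, roi, n_bins=20):
    """Independent per-subject implementation of the change-histogram recipe."""
    edges = np.linspace(-90, 90, n_bins + 1)
    inc_all, dec_all = [], []
    for s in range(before.shape[0]):
        diffs, phis = [], []
        for idx in np.ndindex(before.shape[1:4]):
            if not roi[idx]:
                continue
            b = np.clip(before[(s,) + idx], 0, None).astype(float)
            a = np.clip(after[(s,) + idx], 0, None).astype(float)
            if b.sum() <= 0 or a.sum() <= 0:
                continue
            b, a = b / b.sum(), a / a.sum()
            for d in range(before.shape[4]):
                if not defined[d]:
                    continue
                diffs.append(a[d] - b[d])
                phis.append(phi[d])
        diffs = np.array(diffs)
        phis = np.array(phis)
        pos, neg = diffs[diffs > 0], diffs[diffs < 0]
        inc = np.zeros(n_bins)
        dec = np.zeros(n_bins)
        if pos.size:
            sel = diffs > np.median(pos)
            inc = np.histogram(phis[sel], bins=edges)[0]
        if neg.size:
            sel = diffs < np.median(neg)
            dec = np.histogram(phis[sel], bins=edges)[0]
        inc_all.append(inc)
        dec_all.append(dec)
    return np.mean(inc_all, axis=0), np.mean(dec_all, axis=0)


class TestChangeHistogram:
    def test_identical_fields_flagged_all_zero(self):
        ds = _dirs(4)
        stack = np.random.default_rng(6).random((3, 2, 1, 1, 8))
        cohort = _cohort(stack, ds=ds)
        h = change_histogram(cohort, cohort, angles_for_set(ds), cohort.roi_mask)
        assert h.increase_flagged and h.decrease_flagged
        assert np.all(h.increase_counts == 0) and np.all(h.decrease_counts == 0)

    def test_toy_increase_at_ml_decrease_at_ap(self):
        # four directions: +-x (phi = -+90) and +-y (phi = 0)
        ds = DirectionSet(
            np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
        )
        ang = angles_for_set(ds)
        before = np.array([0.2, 0.3, 0.2, 0.3]).reshape(1, 1, 1, 1, 4)
        after = np.array([0.3, 0.2, 0.3, 0.2]).reshape(1, 1, 1, 1, 4)
        roi = np.ones((1, 1, 1), dtype=bool)
        h = change_histogram(before, after, ang, roi)
        # all increase mass in the two outermost bins, all decrease mass in
        # the two bins straddling 0 degrees (medians split each 2-item pool,
        # leaving the strictly-above/below halves empty only for exact ties,
        # so here every entry is tied at the median and nothing is strict)
        assert h.increase_counts.sum() == 0  # both increases tie at the median
        # break the tie: make one increase larger
        after2 = np.array([0.35, 0.2, 0.25, 0.2]).reshape(1, 1, 1, 1, 4)
        h2 = change_histogram(before, after2, ang, roi)
        inc_bins = np.nonzero(h2.increase_counts)[0]
        dec_bins = np.nonzero(h2.decrease_counts)[0]
        assert set(inc_bins) <= {0, 19}
        assert set(dec_bins) <= {9, 10}

    def test_matches_verbatim_loop_oracle_on_random_cohort(self):
        rng = np.random.default_rng(7)
        ds = _dirs(15)
        ang = angles_for_set(ds)
        before = rng.random((4, 3, 2, 2, 30))
        after = before + rng.normal(0, 0.2, size=before.shape)
        roi = rng.random((3, 2, 2)) > 0.25
        h = change_histogram(before, after, ang, roi)
        inc, dec = _loop_change_histogram(before, after, ang.phi, ang.defined, roi)
        assert np.allclose(h.increase_counts, inc, atol=1e-9)
        assert np.allclose(h.decrease_counts, dec, atol=1e-9)

    def test_undefined_directions_excluded_and_counted(self):
        ds = DirectionSet(
            np.array([[1, 0, 0], [0, 0, 1], [-1, 0, 0], [0, 0, -1]], dtype=float)
        )
        ang = angles_for_set(ds)
        rng = np.random.default_rng(8)
        before = rng.random((2, 2, 1, 1, 4))
        after = rng.random((2, 2, 1, 1, 4))
        roi = np.ones((2, 1, 1), dtype=bool)
        h = change_histogram(before, after, ang, roi)
        # 2 undefined directions x 2 voxels x 2 subjects
        assert h.n_excluded_undefined == 8


class TestCohortAssembly:
    def test_mismatched_affines_rejected(self):
        ds = _dirs(3)
        f1 = FODFField(np.ones((2, 2, 2, 6)), np.eye(4), ds)
        aff = np.eye(4)
        aff[0, 3] = 5.0
        f2 = FODFField(np.ones((2, 2, 2, 6)), aff, ds)
        with pytest.raises(GridMismatchError):
            assemble_cohort([f1, f2], np.ones((2, 2, 2), bool))

    def test_reweight_cohort_matches_single_subject_path(self):
        rng = np.random.default_rng(9)
        stack = rng.random((3, 2, 2, 1, 8))
        cohort = _cohort(stack)
        rew, sigma = reweight_cohort(cohort, epsilon=0.05)
        for s in range(3):
            single = reweight_fodf(cohort.subject_field(s), sigma, epsilon=0.05)
            assert np.allclose(rew.stack[s], single.densities, atol=1e-12)
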