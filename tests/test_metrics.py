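import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from roigan import (
    PairedSample,
    dice,
    evaluate,
    hausdorff,
    histogram_compare,
    ms_ssim,
    paired_t_test,
    psnr,
    ssim,
)
from roigan.metrics import K1, K2, MS_SSIM_WEIGHTS


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def psnr_oracle(x, r, mask=None):
    sel = mask.astype(bool) if mask is not None else np.ones_like(x, bool)
    mse = np.mean((x[sel] - r[sel]) ** 2)
    return 10 * np.log10(max(x.max(), r.max()) ** 2 / mse)


def ssim_oracle(x, r):
    c1, c2 = (K1 * 1.0) ** 2, (K2 * 1.0) ** 2
    mx, mr = x.mean(), r.mean()
    vx, vr = x.var(), r.var()
    cov = ((x - mx) * (r - mr)).mean()
    return ((2 * mx * mr + c1) * (2 * cov + c2)
            / ((mx ** 2 + mr ** 2 + c1) * (vx + vr + c2)))


def ms_ssim_oracle(x, r, scales):
    """Step-by-step reimplementation: cs at each dyadic scale, luminance at
    the coarsest, 2x2 average-pool downsampling, renormalized weights."""
    c1, c2 = (K1 * 1.0) ** 2, (K2 * 1.0) ** 2
    w = np.array(MS_SSIM_WEIGHTS[:scales])
    w = w / w.sum()
    val = 1.0
    for j in range(scales):
        mx, mr = x.mean(), r.mean()
        cov = ((x - mx) * (r - mr)).mean()
        cs = (2 * cov + c2) / (x.var() + r.var() + c2)
        if j == scales - 1:
            lum = (2 * mx * mr + c1) / (mx ** 2 + mr ** 2 + c1)
            val *= max(lum * cs, 0.0) ** w[j]
        else:
            val *= max(cs, 0.0) ** w[j]
            x = x.reshape(x.shape[0] // 2, 2, x.shape[1] // 2, 2).mean((1, 3))
            r = r.reshape(r.shape[0] // 2, 2, r.shape[1] // 2, 2).mean((1, 3))
    return val


def hausdorff_oracle(a, b):
    pa = np.argwhere(a)
    pb = np.argwhere(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(1).max(), d.min(0).max())


# ---------------------------------------------------------------------------


class TestPsnr:
    def test_uniform_error_closed_form(self):
        x = np.zeros((8, 8))
        x[0, 0] = 1.0  # peak 1
        r = x + 0.1
        r[0, 0] = 1.0
        mse = np.mean((x - r) ** 2)
        assert psnr(x, r) == pytest.approx(10 * np.log10(1 / mse), rel=1e-12)
        # exact 20 dB when every pixel differs by 0.1 and the peak is 1
        x = np.ones((8, 8))
        assert psnr(x, x - 0.1) == pytest.approx(20.0, rel=1e-12)

    def test_identical_images_give_infinity(self, rng):
        x = rng.random((8, 8))
        assert psnr(x, x.copy()) == float("inf")

    def test_matches_direct_formula(self, rng):
        for _ in range(60):
            x = rng.random((16, 16))
            r = rng.random((16, 16))
            assert psnr(x, r) == pytest.approx(psnr_oracle(x, r), rel=1e-9)
            mask = rng.random((16, 16)) > 0.5
            if mask.any():
                assert psnr(x, r, mask) == pytest.approx(
                    psnr_oracle(x, r, mask), rel=1e-9)


class TestSsim:
    def test_identity_gives_one(self, rng):
        x = rng.random((12, 12))
        assert ssim(x, x.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_constant_zero_vs_constant_one(self):
        x = np.zeros((8, 8))
        r = np.ones((8, 8))
        c1 = 0.01 ** 2
        assert ssim(x, r) == pytest.approx(c1 / (1 + c1), rel=1e-9)

    def test_matches_direct_formula_and_symmetry(self, rng):
        for _ in range(60):
            x = rng.random((16, 16))
            r = rng.random((16, 16))
            assert ssim(x, r) == pytest.approx(ssim_oracle(x, r), rel=1e-9)
            assert ssim(x, r) == pytest.approx(ssim(r, x), rel=1e-12)

    def test_windowed_mode_agrees_with_skimage(self, rng):
        from skimage.metrics import structural_similarity

        x = rng.random((32, 32))
        r = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        ref = structural_similarity(x, r, data_range=1.0,
                                    gaussian_weights=True, K1=K1, K2=K2)
        assert ssim(x, r, windowed=True) == pytest.approx(ref, rel=1e-12)


class TestMsSsim:
    def test_identity_gives_one(self, rng):
        x = rng.random((32, 32))
        assert ms_ssim(x, x.copy(), scales=2) == pytest.approx(1.0, abs=1e-9)

    def test_single_scale_reduces_to_ssim(self, rng):
        x = rng.random((16, 16))
        r = rng.random((16, 16))
        assert ms_ssim(x, r, scales=1) == pytest.approx(ssim(x, r), rel=1e-12)

    def test_three_scales_match_independent_reimplementation(self, rng):
        for _ in range(50):
            x = rng.random((64, 64))
            r = np.clip(x + rng.normal(0, 0.2, x.shape), 0, 1)
            assert ms_ssim(x, r, scales=3) == pytest.approx(
                ms_ssim_oracle(x, r, 3), rel=1e-6)

    def test_too_small_image_suggests_fewer_scales(self):
        with pytest.raises(ValueError, match="scales"):
            ms_ssim(np.zeros((16, 16)), np.ones((16, 16)), scales=5)


class TestDice:
    def test_identical_disjoint_and_half_overlap(self):
        a = np.zeros((6, 6), dtype=int)
        a[1:3, 1:3] = 1
        assert dice(a, a.copy()) == 1.0
        b = np.zeros((6, 6), dtype=int)
        b[4:6, 4:6] = 1
        assert dice(a, b) == 0.0
        c = np.zeros((6, 6), dtype=int)
        c[1:3, 2:4] = 1  # |a|=|c|=4, overlap 2
        assert dice(a, c) == 0.5

    def test_two_empty_masks_count_as_agreement_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert dice(np.zeros((4, 4), int), np.zeros((4, 4), int)) == 1.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = (rng.random((10, 10)) > 0.6).astype(int)
            b = (rng.random((10, 10)) > 0.6).astype(int)
            if a.sum() + b.sum() == 0:
                continue
            assert dice(a, b) == dice(b, a)


class TestHausdorff:
    def test_identical_masks_and_pythagorean_pair(self):
        m = np.zeros((8, 8), int)
        m[2:4, 2:4] = 1
        assert hausdorff(m, m.copy()) == 0.0
        a = np.zeros((8, 8), int)
        b = np.zeros((8, 8), int)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(a, b) == 5.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.zeros((4, 4), int), np.ones((4, 4), int))

    def test_matches_brute_force_double_loop_exactly(self, rng):
        for _ in range(50):
            a = (rng.random((12, 12)) > 0.7).astype(int)
            b = (rng.random((12, 12)) > 0.7).astype(int)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert hausdorff(a, b) == hausdorff_oracle(a, b)
            assert hausdorff(a, b) == hausdorff(b, a)


class TestPairedT:
    def test_identical_samples_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_symmetric_differences_give_t_zero_p_one(self):
        res = paired_t_test([1.0, 0.0], [0.0, 1.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        assert not res.significant

    def test_matches_textbook_formula_at_n30(self, rng):
        a = rng.normal(0.5, 1.0, 30)
        b = a + rng.normal(0.3, 0.5, 30)
        d = a - b
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_direct = 2 * tdist.sf(abs(t_direct), len(d) - 1)
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(t_direct, rel=1e-9)
        assert res.p == pytest.approx(p_direct, rel=1e-9)
        assert res.significant == (p_direct < 0.05)


class TestHistogram:
    def test_identical_images_distance_zero(self, rng):
        x = rng.random((16, 16))
        _, _, d = histogram_compare(x, x.copy())
        assert d == 0.0

    def test_disjoint_supports_distance_one(self):
        _, _, d = histogram_compare(np.zeros((8, 8)), np.ones((8, 8)))
        assert d == 1.0

    def test_matches_direct_bin_counting(self, rng):
        for _ in range(50):
            x = rng.random((16, 16))
            y = rng.random((16, 16))
            pa, pb, d = histogram_compare(x, y, n_bins=32)
            ca = np.histogram(x, bins=32, range=(0, 1))[0] / x.size
            cb = np.histogram(y, bins=32, range=(0, 1))[0] / y.size
            np.testing.assert_array_equal(pa, ca)
            np.testing.assert_array_equal(pb, cb)
            assert d == 0.5 * np.abs(ca - cb).sum()
            assert d == histogram_compare(y, x, n_bins=32)[2]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            histogram_compare(np.zeros((4, 4)), np.zeros((4, 4)), n_bins=1)


class TestMonotonicity:
    def test_psnr_and_ssim_decrease_with_noise_amplitude(self, phantoms16):
        rng = np.random.default_rng(0)
        amplitudes = [0.01, 0.05, 0.1, 0.2]
        mean_psnr, mean_ssim = [], []
        for amp in amplitudes:
            ps, ss = [], []
            for s in phantoms16:
                for _ in range(3):
                    noisy = np.clip(s.image + rng.normal(0, amp,
                                                         s.image.shape), 0, 1)
                    ps.append(psnr(s.image, noisy))
                    ss.append(ssim(s.image, noisy))
            mean_psnr.append(np.mean(ps))
            mean_ssim.append(np.mean(ss))
        assert all(np.diff(mean_psnr) < 0)
        assert all(np.diff(mean_ssim) < 0)

    def test_dice_and_hausdorff_move_oppositely_under_erosion(self, phantoms16):
        mask = phantoms16[0].mask
        dices, hds = [], []
        for it in range(0, 4):
            eroded = (binary_erosion(mask, iterations=it).astype(int)
                      if it else mask)
            if eroded.sum() == 0:
                break
            dices.append(dice(mask, eroded))
            hds.append(hausdorff(mask, eroded))
        assert all(np.diff(dices) <= 0)
        assert all(np.diff(hds) >= 0)


class TestEvaluate:
    def test_perfect_synthesis_report(self, phantoms16):
        pairs = [(s, s) for s in phantoms16[:4]]
        with pytest.warns(UserWarning, match="PSNR"):
            rep = evaluate(pairs, region="tumor")
        assert rep.psnr_inf_count == 4
        assert rep.aggregates["ssim"][0] == pytest.approx(1.0)
        assert rep.aggregates["dice"][0] == 1.0
        assert rep.aggregates["hausdorff"][0] == 0.0
        assert "psnr" not in rep.aggregates  # all infinite, all excluded

    def test_aggregates_match_hand_computed_mean_sd(self, phantoms16, rng):
        pairs = []
        for s in phantoms16[:6]:
            noisy = np.clip(s.image + rng.normal(0, 0.05, s.image.shape), 0, 1)
            pairs.append((s, PairedSample(image=noisy, mask=s.mask,
                                          sample_id=s.sample_id + "_n")))
        rep = evaluate(pairs, region="whole")
        col = rep.per_sample["ssim"].to_numpy()
        assert rep.aggregates["ssim"][0] == pytest.approx(col.mean())
        assert rep.aggregates["ssim"][1] == pytest.approx(col.std(ddof=1))
        direct = [ssim(o.image, n.image) for o, n in pairs]
        np.testing.assert_allclose(col, direct, rtol=1e-12)

    def test_tumor_region_restricts_statistics_to_mask(self, phantoms16, rng):
        s = phantoms16[0]
        recon = np.clip(s.image + rng.normal(0, 0.05, s.image.shape), 0, 1)
        pair = (s, PairedSample(image=recon, mask=s.mask, sample_id="x"))
        rep = evaluate([pair], region="tumor")
        expected = psnr_oracle(s.image, recon, s.mask)
        assert rep.per_sample["psnr"][0] == pytest.approx(expected, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no sample"):
            evaluate([], region="whole")
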