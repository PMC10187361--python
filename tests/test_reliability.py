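import numpy as np
import pytest

from ccshape.imaging_io import CCMask, ValidationError
from ccshape.reliability import (
    ReliabilityMatrix,
    UndefinedICCError,
    dice,
    icc2,
    reliability_study,
)
from ccshape.segmentation import mean_iou


def brute_force_icc21(values):
    """Independent oracle: ICC(2,1) from an explicit two-way ANOVA with
    nested Python loops (no shared code with the implementation)."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum((values[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestDice:
    def _mask(self, pixels):
        lab = np.zeros((16, 16), dtype=np.uint8)
        for r, c in pixels:
            lab[r, c] = 1
        return CCMask(lab)

    def test_identity_and_disjoint(self):
        a = self._mask([(1, 1), (1, 2), (2, 1)])
        b = self._mask([(9, 9)])
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_counting_example(self):
        a = self._mask([(0, 0), (0, 1), (0, 2), (0, 3)])
        b = self._mask([(0, 0), (0, 1)])
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_both_empty_is_one(self):
        e = CCMask(np.zeros((4, 4), dtype=np.uint8))
        assert dice(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice(CCMask(np.zeros((4, 4), dtype=np.uint8)),
                 CCMask(np.zeros((5, 5), dtype=np.uint8)))

    def test_dice_iou_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = CCMask((rng.random((32, 32)) > 0.6).astype(np.uint8))
            b = CCMask((rng.random((32, 32)) > 0.6).astype(np.uint8))
            iou = mean_iou(a, b)
            assert dice(a, b) == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestICC2:
    def test_perfect_agreement(self):
        mat = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
        assert icc2(mat) == pytest.approx(1.0)

    def test_small_matrix_matches_brute_force_anova(self):
        mat = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc2(mat) == pytest.approx(brute_force_icc21(mat), abs=1e-10)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, 6))
            mat = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * rng.random()
            assert icc2(mat) == pytest.approx(brute_force_icc21(mat), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        mat = rng.normal(size=(12, 4)) + 2 * rng.normal(size=(12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "rater": np.tile(np.arange(4), 12),
            "value": mat.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value")
        # absolute-agreement single-measurement row (labelled ICC2 or
        # ICC(A,1) depending on pingouin version)
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_val = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc2(mat) == pytest.approx(ref_val, abs=1e-8)

    def test_null_noise_is_near_zero(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(200, 10))
        assert abs(icc2(mat)) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(20, 5)) + 3 * rng.normal(size=(20, 1))
        base = icc2(mat)
        assert icc2(mat + 7.5) == pytest.approx(base, abs=1e-10)
        assert icc2(mat * 3.2) == pytest.approx(base, abs=1e-10)

    def test_variance_components_recovery(self):
        rng = np.random.default_rng(11)
        sb, sw = 2.0, 1.0
        subj = rng.normal(0, sb, (100, 1))
        mat = subj + rng.normal(0, sw, (100, 10))
        expected = sb**2 / (sb**2 + sw**2)
        assert icc2(mat) == pytest.approx(expected, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ReliabilityMatrix(np.ones((1, 5)))
        with pytest.raises(UndefinedICCError):
            icc2(np.ones((4, 4)))


class TestReliabilityStudy:
    def test_identical_sessions_are_perfectly_reliable(self, normal_phantom):
        mask = normal_phantom.mask
        other = CCMask(np.roll(mask.labels, 3, axis=0), mask.pixel_spacing)
        sessions = {"s1": [mask, mask], "s2": [other, other]}
        report = reliability_study(sessions, truth_masks={"s1": mask, "s2": other})
        vals = report["icc2"].dropna()
        assert (vals > 0.999).all()
        assert report.attrs["mean_dice"] == pytest.approx(1.0)

    def test_unequal_session_counts_rejected(self, normal_phantom):
        m = normal_phantom.mask
        with pytest.raises(ValidationError):
            reliability_study({"a": [m, m], "b": [m]})
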