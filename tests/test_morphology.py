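"""DMEAN outlier rejection and PCC/NRMSE waveform scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invisible_ecg import (
    BeatLabel,
    InsufficientDataError,
    UndefinedStatisticError,
    dmean_classify,
    nrmse,
    pcc,
)
from invisible_ecg.preprocessing import BeatTemplateSet


def make_tset(templates):
    templates = np.asarray(templates, dtype=float)
    return BeatTemplateSet(
        templates=templates,
        window_ms=(200.0, 400.0),
        fs=1000.0,
        r_indices=np.arange(templates.shape[0]) * 1000 + 500,
        dropped_r_indices=np.array([], dtype=int),
    )


def brute_force_dmean(templates, tp_threshold=70.0):
    """Independent step-by-step evaluation of the DMEAN rule with loops."""
    templates = [list(map(float, row)) for row in templates]
    n = len(templates)
    length = len(templates[0])
    mu = [sum(t[j] for t in templates) / n for j in range(length)]
    d = [[t[j] - mu[j] for j in range(length)] for t in templates]
    pooled = [abs(v) for row in d for v in row]
    mu_d = sum(pooled) / len(pooled)
    var = sum((v - mu_d) ** 2 for v in pooled) / (len(pooled) - 1)
    sigma_d = var**0.5
    bound = mu_d + 0.5 * sigma_d
    keep = []
    for row in d:
        n_ok = sum(1 for v in row if abs(v) <= bound)
        tp = 100.0 * n_ok / length
        keep.append(tp > tp_threshold)
    return keep


class TestDmean:
    def test_identical_templates_all_kept(self):
        tset = dmean_classify(make_tset(np.tile(np.sin(np.linspace(0, 6, 50)), (5, 1))))
        assert np.allclose(tset.tp_percent, 100.0)
        assert all(lb == BeatLabel.NORMAL for lb in tset.labels)

    def test_gross_outlier_rejected(self, rng):
        base = np.sin(np.linspace(0, 6, 100))
        templates = np.tile(base, (20, 1)) + rng.normal(0, 0.01, (20, 100))
        bad = templates[19].copy()
        bad[:60] += 10 * templates.std()  # 60% of samples far off
        templates[19] = bad
        tset = dmean_classify(make_tset(templates))
        assert tset.labels[19] == BeatLabel.OUTLIER
        assert tset.tp_percent[19] <= 40.0
        assert sum(lb == BeatLabel.OUTLIER for lb in tset.labels) == 1

    def test_zero_threshold_keeps_everything(self, rng):
        templates = rng.normal(0, 1, (10, 40))
        tset = dmean_classify(make_tset(templates), tp_threshold=0.0)
        assert all(lb == BeatLabel.NORMAL for lb in tset.labels)

    def test_too_few_templates_raise(self):
        with pytest.raises(InsufficientDataError):
            dmean_classify(make_tset(np.zeros((2, 10))))

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_beats = int(rng.integers(3, 31))
            n_samp = int(rng.integers(10, 201))
            templates = rng.normal(0, 1, (n_beats, n_samp))
            if rng.random() < 0.5:  # sprinkle in outliers
                k = int(rng.integers(0, n_beats))
                templates[k] += rng.normal(0, 5, n_samp)
            tset = dmean_classify(make_tset(templates))
            expected = brute_force_dmean(templates)
            got = [lb == BeatLabel.NORMAL for lb in tset.labels]
            assert got == expected

    def test_raising_threshold_never_grows_kept_set(self, rng):
        templates = rng.normal(0, 1, (15, 60))
        kept_sets = []
        for thr in (0.0, 30.0, 60.0, 90.0, 100.0):
            tset = dmean_classify(make_tset(templates), tp_threshold=thr)
            kept_sets.append({i for i, lb in enumerate(tset.labels)
                              if lb == BeatLabel.NORMAL})
        for lo, hi in zip(kept_sets[1:], kept_sets[:-1]):
            assert lo <= hi


class TestPcc:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(0, 1, 50)
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_matches_explicit_loop_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 6.0, 9.0]
        xb, yb = sum(x) / 4, sum(y) / 4
        num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
        den = (sum((xi - xb) ** 2 for xi in x) ** 0.5) * (
            sum((yi - yb) ** 2 for yi in y) ** 0.5
        )
        assert pcc(x, y) == pytest.approx(num / den)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_affine_invariance_and_sign_flip(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        base = pcc(x, y)
        assert pcc(x, a * y + b) == pytest.approx(base, abs=1e-9)
        assert pcc(x, -a * y + b) == pytest.approx(-base, abs=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pcc(np.ones(10), np.arange(10.0))


class TestNrmse:
    def test_identity_is_zero(self, rng):
        x = rng.normal(0, 1, 30)
        assert nrmse(x, x) == 0.0

    def test_constant_offset_closed_form(self, rng):
        ref = rng.normal(0, 1, 100)
        c = 0.37
        expected = 100.0 * c / np.ptp(ref)
        assert nrmse(ref, ref + c) == pytest.approx(expected)

    def test_matches_explicit_loop_oracle(self, rng):
        ref = rng.normal(0, 1, 64)
        exp = rng.normal(0, 1, 64)
        mse = sum((r - e) ** 2 for r, e in zip(ref, exp)) / 64
        expected = 100.0 * mse**0.5 / (max(ref) - min(ref))
        assert nrmse(ref, exp) == pytest.approx(expected)

    def test_flat_reference_raises(self):
        with pytest.raises(UndefinedStatisticError):
            nrmse(np.ones(10), np.arange(10.0))
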