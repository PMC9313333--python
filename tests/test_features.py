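"""Feature computations against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdhrv.emd import decompose
from emdhrv.errors import DataError
from emdhrv.features import (
    FEATURE_NAMES,
    EntropyParams,
    band_power,
    energy,
    energy_features,
    extract_all,
    gpnnx_threshold,
    hopkins_label,
    imf_time_features,
    perm_entropy,
    pnnx,
    rmssd,
    sample_entropy,
    sdnn,
    surrogate_correlation,
)
from emdhrv.preprocess import remove_outliers, resample_tachogram
from emdhrv.records import RRSeries

from conftest import make_two_tone


# ------------------------------------------------------------------- oracles

def perm_entropy_oracle(x, m, tau):
    """Exhaustive enumeration over all ordinal patterns."""
    counts = {}
    n_vec = len(x) - (m - 1) * tau
    for i in range(n_vec):
        window = [x[i + j * tau] for j in range(m)]
        pattern = tuple(np.argsort(window, kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def sample_entropy_oracle(x, m, r_coeff):
    """O(N^2) template counting, Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, float)
    r = r_coeff * np.std(x, ddof=1)
    n_templates = len(x) - m

    def count(length):
        c = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    return -math.log(a / b) if a and b else math.nan


# --------------------------------------------------------------- time domain

class TestTimeDomain:
    def test_sdnn_hand_value(self):
        assert sdnn([800.0, 800.0, 800.0]) == 0.0
        assert sdnn([800.0, 820.0]) == pytest.approx(math.sqrt(200.0))

    @given(st.lists(st.floats(300, 2000), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_sdnn_matches_two_pass_oracle(self, rr):
        mean = sum(rr) / len(rr)
        oracle = math.sqrt(sum((v - mean) ** 2 for v in rr) / (len(rr) - 1))
        assert sdnn(rr) == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_rmssd_hand_value(self):
        assert rmssd([800.0, 840.0, 800.0]) == pytest.approx(40.0)
        assert rmssd(np.full(20, 750.0)) == 0.0

    @given(st.lists(st.floats(300, 2000), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_rmssd_matches_direct_sum_oracle(self, rr):
        diffs = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
        oracle = math.sqrt(sum(d * d for d in diffs) / len(diffs))
        assert rmssd(rr) == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_pnnx_hand_count_strict_inequality(self):
        rr = [800.0, 840.0, 850.0, 900.0]  # diffs 40, 10, 50
        assert pnnx(rr, 30) == pytest.approx(200.0 / 3.0)
        assert pnnx(rr, 50) == 0.0  # strictly greater than
        assert pnnx(np.full(10, 800.0), 30) == 0.0

    @given(st.lists(st.floats(300, 2000), min_size=2, max_size=60),
           st.floats(0, 60), st.floats(0, 60))
    @settings(max_examples=50, deadline=None)
    def test_pnnx_monotone_nonincreasing_in_threshold(self, rr, x1, x2):
        lo, hi = min(x1, x2), max(x1, x2)
        assert pnnx(rr, lo) >= pnnx(rr, hi)


class TestGpnnx:
    @staticmethod
    def _records_from_medians(medians, rng):
        """Rest records whose median absolute successive difference equals
        the requested value (alternating up/down steps, no drift)."""
        records = []
        for med in medians:
            steps = np.tile([1.0, -1.0], 100) * med
            rr = 800.0 + np.concatenate([[0.0], np.cumsum(steps)])
            records.append(RRSeries("s", "rest", rr))
        return records

    def test_normal_distribution_uses_mean(self):
        rng = np.random.default_rng(8)
        medians = rng.normal(25.0, 3.0, size=60)
        records = self._records_from_medians(medians, rng)
        x = gpnnx_threshold(records)
        observed = [np.median(np.abs(np.diff(r.rr_ms))) for r in records]
        assert x == pytest.approx(np.mean(observed), rel=1e-9)

    def test_skewed_distribution_uses_median(self):
        rng = np.random.default_rng(9)
        medians = np.exp(rng.normal(3.0, 0.9, size=60))  # heavy right skew
        records = self._records_from_medians(medians, rng)
        x = gpnnx_threshold(records)
        observed = [np.median(np.abs(np.diff(r.rr_ms))) for r in records]
        assert x == pytest.approx(np.median(observed), rel=1e-9)
        assert x < np.mean(observed)

    def test_too_few_records_rejected(self):
        with pytest.raises(DataError):
            gpnnx_threshold([RRSeries("s", "rest", [800, 810, 790])] * 2)


# ----------------------------------------------------------------- entropies

class TestPermEntropy:
    def test_monotone_ramp_has_zero_entropy(self):
        assert perm_entropy(np.arange(200.0), m=3, tau=1) == 0.0

    def test_upper_bound_ln_m_factorial(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        for m in (3, 4):
            assert perm_entropy(x, m=m, tau=1) <= math.log(math.factorial(m)) + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(31)
        assert perm_entropy(x, m=3, tau=1) == pytest.approx(
            perm_entropy_oracle(x, 3, 1), rel=1e-12)

    def test_delay_two_matches_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        assert perm_entropy(x, m=3, tau=2) == pytest.approx(
            perm_entropy_oracle(x, 3, 2), rel=1e-12)

    def test_length_requirement_enforced(self):
        with pytest.raises(DataError, match="120"):
            perm_entropy(np.arange(100.0), m=4, tau=1)


class TestSampleEntropy:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_template_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        assert sample_entropy(x, m=2, r_coeff=0.2) == pytest.approx(
            sample_entropy_oracle(x, 2, 0.2), rel=1e-12)

    def test_strongly_periodic_signal_gives_zero(self):
        x = np.tile([0.0, 10.0], 40)  # every m-match extends to m+1
        assert sample_entropy(x, m=2, r_coeff=0.2) == 0.0

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(6)
        n = 400
        noise = rng.standard_normal(n)
        sine = np.sin(2 * np.pi * 0.25 * np.arange(n) / 8.0)
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_constant_series_rejected(self):
        with pytest.raises(DataError):
            sample_entropy(np.full(50, 3.0))


# ------------------------------------------------------------------ energies

class TestEnergy:
    def test_zero_signal(self):
        assert energy(np.zeros(100)) == 0.0

    def test_unit_sine_closed_form(self):
        k = 4000
        x = np.sin(2 * np.pi * 5 * np.arange(k) / k)  # whole periods
        assert energy(x) == pytest.approx(k / 2, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_parseval_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(512)
        spectral = np.sum(np.abs(np.fft.fft(x)) ** 2) / x.size
        assert energy(x) == pytest.approx(spectral, rel=1e-9)


class TestEnergyFeatures:
    def test_degenerate_slow_modes(self, two_tone):
        tach, fast, _ = two_tone
        imfset = decompose(tach)
        imfset.imfs[1] = np.zeros_like(imfset.imfs[1])
        imfset.imfs[2] = np.zeros_like(imfset.imfs[2])
        feats = energy_features(imfset)
        assert feats["Energy_IMF23/IMF1"] == 0.0
        assert feats["Energy_IMF1/IMF123"] == 1.0
        assert feats["Energy_IMF23/IMF123"] == 0.0

    def test_normalized_pair_sums_to_one(self, two_tone):
        tach, _, _ = two_tone
        feats = energy_features(decompose(tach))
        assert feats["Energy_IMF1/IMF123"] + feats["Energy_IMF23/IMF123"] == \
            pytest.approx(1.0, abs=1e-12)

    def test_ratio_follows_squared_amplitude_ratio(self):
        tach, fast, slow = make_two_tone(a_fast=30.0, a_slow=60.0)
        feats = energy_features(decompose(tach))
        assert feats["Energy_IMF23/IMF1"] == pytest.approx((60.0 / 30.0) ** 2,
                                                           rel=0.15)

    def test_energy_additivity_across_modes(self, two_tone):
        tach, _, _ = two_tone
        imfset = decompose(tach)
        total = sum(energy(m) for m in imfset.imfs) + energy(imfset.residual)
        centred = tach.x - tach.x.mean()
        assert total == pytest.approx(energy(centred), rel=0.10)


class TestImfTimeFeatures:
    def test_matches_sdnn_rmssd_oracles(self, two_tone):
        tach, _, _ = two_tone
        imfset = decompose(tach)
        feats = imf_time_features(imfset)
        for k in (1, 2, 3):
            mode = imfset.imfs[k - 1]
            assert feats[f"SDNN_IMF{k}"] == pytest.approx(sdnn(mode + 1000.0))
            assert feats[f"RMSSD_IMF{k}"] == pytest.approx(
                rmssd(mode - mode.min() + 500.0))

    def test_fast_modes_have_larger_rmssd_to_sdnn_ratio(self, two_tone):
        tach, _, _ = two_tone
        feats = imf_time_features(decompose(tach))
        ratio1 = feats["RMSSD_IMF1"] / feats["SDNN_IMF1"]
        ratio3 = feats["RMSSD_IMF3"] / feats["SDNN_IMF3"]
        assert ratio1 > ratio3


class TestBandPower:
    def test_pure_hf_tone(self):
        tach, _, _ = make_two_tone(a_fast=30.0, a_slow=0.0)
        bp = band_power(tach)
        assert bp.hf_power / (bp.hf_power + bp.lf_power) > 0.95

    def test_pure_lf_tone(self):
        tach, _, _ = make_two_tone(a_fast=0.0, a_slow=30.0, f_slow=0.10)
        bp = band_power(tach)
        assert bp.lf_power > bp.hf_power

    def test_two_tone_ratio_follows_squared_amplitudes(self):
        tach, _, _ = make_two_tone(a_fast=20.0, a_slow=40.0, f_slow=0.10)
        bp = band_power(tach)
        assert bp.lf_hf_ratio == pytest.approx(4.0, rel=0.10)


# ------------------------------------------------------------ full extraction

@pytest.fixture(scope="module")
def record_and_imfs(default_cohort):
    series = default_cohort.get(default_cohort.subjects()[0], "rest")
    cleaned, _ = remove_outliers(series)
    tach = resample_tachogram(cleaned)
    return cleaned, decompose(tach)


class TestExtractAll:
    def test_exactly_26_canonical_names(self, record_and_imfs):
        rr, imfset = record_and_imfs
        vector = extract_all(rr, imfset)
        assert list(vector) == FEATURE_NAMES
        assert len(vector) == 26

    def test_determinism(self, record_and_imfs):
        rr, imfset = record_and_imfs
        a = extract_all(rr, imfset)
        b = extract_all(rr, imfset)
        assert a == b

    def test_compositional_consistency(self, record_and_imfs):
        rr, imfset = record_and_imfs
        vector = extract_all(rr, imfset, gpnnx_x=25.0)
        assert vector["SDNN"] == pytest.approx(sdnn(rr.rr_ms))
        assert vector["RMSSD"] == pytest.approx(rmssd(rr.rr_ms))
        assert vector["pNN30"] == pytest.approx(pnnx(rr.rr_ms, 30.0))
        assert vector["G-pNNx"] == pytest.approx(pnnx(rr.rr_ms, 25.0))
        assert vector["HR"] == pytest.approx(60000.0 / np.mean(rr.rr_ms))

    def test_pnn_family_bounded_and_energies_nonnegative(self, record_and_imfs):
        rr, imfset = record_and_imfs
        vector = extract_all(rr, imfset)
        for name in ("pNN30", "pNN50", "G-pNNx"):
            assert 0.0 <= vector[name] <= 100.0
        for name in ("Energy", "Energy_IMF1", "Energy_(IMF2+IMF3)"):
            assert vector[name] >= 0.0


class TestSurrogateCorrelation:
    def test_hopkins_labels(self):
        assert hopkins_label(0.75) == "very large"
        assert hopkins_label(1.0) == "nearly perfect"
        assert hopkins_label(-0.05) == "trivial"
        assert hopkins_label(float("nan")) == "undefined"

    def test_self_correlation_is_nearly_perfect(self, default_table):
        table = default_table.copy()
        table["hf_power"] = table["Energy_IMF1"]
        r, labels = surrogate_correlation(table)
        assert r.loc["Energy_IMF1", "hf_power"] == pytest.approx(1.0)
        assert labels.loc["Energy_IMF1", "hf_power"] == "nearly perfect"

    def test_zero_variance_column_gives_sentinel(self, default_table):
        table = default_table.copy()
        table["lf_power"] = 1.0
        r, labels = surrogate_correlation(table)
        assert math.isnan(r.loc["Energy_IMF1", "lf_power"])
        assert labels.loc["Energy_IMF1", "lf_power"] == "undefined"

    def test_energy_surrogates_track_band_powers(self, default_table):
        r, _ = surrogate_correlation(default_table)
        assert r.loc["Energy_IMF1", "hf_power"] > 0.7
        assert r.loc["Energy_(IMF2+IMF3)", "lf_power"] > 0.5
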