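"""Gel densitometry to copy numbers: unit operations and full pipeline."""

import math

import pytest

from xlscout.simulate import gen_gel_signals
from xlscout.stoichiometry import (DEFAULT_ROUTES, GelBandMeasurement,
                                   calibrate_comigrated,
                                   comigrated_band_molar, integrate,
                                   molar_signal, partition_composite,
                                   read_band_table, total_lhci_copies)


class TestMolarSignal:
    def test_homogeneity(self):
        assert molar_signal(2 * 50.0, 2 * 100) == molar_signal(50.0, 100)

    def test_equal_signals_equal_carbons(self):
        assert molar_signal(7.0, 900) == molar_signal(7.0, 900)

    def test_invalid_carbons(self):
        with pytest.raises(ValueError):
            molar_signal(1.0, 0)

    def test_constructed_ratios(self):
        # copies {2,1,1} with distinct carbon counts
        copies = [2.0, 1.0, 1.0]
        carbons = [800, 950, 1100]
        signals = [c * k for c, k in zip(copies, carbons)]
        molar = [molar_signal(s, k) for s, k in zip(signals, carbons)]
        assert molar == pytest.approx(copies)


class TestCalibration:
    def test_identity_scale(self):
        assert calibrate_comigrated(2.17, 2.17) == pytest.approx(1.0)

    def test_proportionality(self):
        assert calibrate_comigrated(4.34, 2.17) == pytest.approx(0.5)

    def test_zero_band_rejected(self):
        with pytest.raises(ValueError):
            calibrate_comigrated(0.0, 2.17)

    def test_recovers_inverse_gain(self):
        copies = {"X": 1.3, "Y": 1.0}
        carbons = {"X": 700, "Y": 900}
        g = 3.7
        signal = g * sum(copies[s] * carbons[s] for s in copies)
        band_molar = comigrated_band_molar(signal, copies, carbons)
        scale = calibrate_comigrated(band_molar, sum(copies.values()))
        assert scale == pytest.approx(1 / g)


class TestPartition:
    @pytest.mark.parametrize("total,fracs,expected", [
        (3.0, (1 / 3, 1 / 3, 1 / 3), (1.0, 1.0, 1.0)),
        (3.0, (0.5, 0.25, 0.25), (1.5, 0.75, 0.75)),
    ])
    def test_known_partitions(self, total, fracs, expected):
        assert partition_composite(total, fracs) == pytest.approx(expected)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            partition_composite(3.0, (0.5, 0.25))


def _run_pipeline(copies, carbons, seed=0, noise_cv=0.0, n_replicates=3):
    bands = gen_gel_signals(copies, carbons, noise_cv=noise_cv, seed=seed,
                            n_replicates=n_replicates)
    return integrate(bands, carbons)


class TestIntegrate:
    def test_noiseless_exact_recovery(self, gel_universe):
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        copies["LHCA1"] = 2.0
        copies["PSAD"] = 1.17
        result = _run_pipeline(copies, carbons, seed=1)
        by = {a.subunit: a for a in result}
        for s in subs:
            assert by[s].mean == pytest.approx(copies[s], abs=1e-9)
        assert total_lhci_copies(result) == 10
        assert by["LHCA1"].copies == 2

    def test_comigrated_prediction(self, gel_universe):
        """Resolved PSAD (1.17) + PSAF (1.00) predict the 2.17 band."""
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        copies["PSAD"] = 1.17
        result = _run_pipeline(copies, carbons, seed=2)
        by = {a.subunit: a.mean for a in result}
        assert by["PSAD"] + by["PSAF"] == pytest.approx(2.17, abs=1e-9)

    def test_reference_is_identically_one(self, gel_universe):
        subs, carbons = gel_universe
        copies = {s: float(1 + (i % 3)) for i, s in enumerate(subs)}
        copies["PSAF"] = 1.0
        result = _run_pipeline(copies, carbons, seed=3, noise_cv=0.05)
        by = {a.subunit: a for a in result}
        assert by["PSAF"].mean == pytest.approx(1.0, abs=1e-12)

    def test_gain_invariance(self, gel_universe):
        """Scaling one gel system's signals must not change the result."""
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        copies["LHCA1"] = 2.0
        bands = gen_gel_signals(copies, carbons, noise_cv=0.0, seed=4)
        scaled = [
            GelBandMeasurement(b.gel_system, b.band_label, b.members,
                               b.signal * (7.5 if b.gel_system == "HMT6" else 1.0),
                               b.replicate)
            for b in bands
        ]
        a = {x.subunit: x.mean for x in integrate(bands, carbons)}
        b = {x.subunit: x.mean for x in integrate(scaled, carbons)}
        for s in a:
            assert a[s] == pytest.approx(b[s], abs=1e-9)

    def test_identical_replicates_zero_se(self, gel_universe):
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        result = _run_pipeline(copies, carbons, seed=5)
        # noiseless replicates differ only by gain, which calibration absorbs
        assert all(a.se == pytest.approx(0.0, abs=1e-9) for a in result)

    def test_missing_route_named(self, gel_universe):
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        bands = gen_gel_signals(copies, carbons, seed=6)
        trimmed = [b for b in bands
                   if not (b.gel_system == "HMT6"
                           and b.members == frozenset({"LHCA9"}))]
        with pytest.raises(ValueError, match="LHCA9"):
            integrate(trimmed, carbons)

    def test_random_copy_vectors_recovered(self, gel_universe):
        import numpy as np
        subs, carbons = gel_universe
        rng = np.random.default_rng(77)
        for _ in range(5):
            copies = {s: float(rng.uniform(0.5, 3.0)) for s in subs}
            result = _run_pipeline(copies, carbons, seed=int(rng.integers(1e6)))
            by = {a.subunit: a.mean for a in result}
            ref = copies["PSAF"]
            for s in subs:
                assert by[s] == pytest.approx(copies[s] / ref, abs=1e-9)

    def test_ambiguity_warning(self, gel_universe):
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        copies["LHCA6"] = 1.5
        warned = []
        bands = gen_gel_signals(copies, carbons, seed=8)
        integrate(bands, carbons,
                  warn_ambiguous=lambda s, v: warned.append(s))
        assert "LHCA6" in warned


class TestBandTable:
    def test_round_trip(self, tmp_path, gel_universe):
        subs, carbons = gel_universe
        copies = {s: 1.0 for s in subs}
        bands = gen_gel_signals(copies, carbons, seed=9)
        p = tmp_path / "bands.tsv"
        import pandas as pd
        pd.DataFrame([{
            "gel_system": b.gel_system, "band_label": b.band_label,
            "members": ";".join(sorted(b.members)), "signal": b.signal,
            "replicate": b.replicate} for b in bands
        ]).to_csv(p, sep="\t", index=False)
        back = read_band_table(p)
        assert len(back) == len(bands)
        got = {a.subunit: a.mean for a in integrate(back, carbons)}
        assert got["LHCA5"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gel_system\tband_label\nHMT55\tX\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_band_table(p)
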