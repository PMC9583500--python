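"""Barcode assignment and subpopulation tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csss.barcoding import assign_barcodes, barcode_to_string, tabulate_subpopulations
from csss.sa import fit_surprisal
from csss.thresholds import compute_thresholds
from csss.synth import generate

from conftest import four_subpop_spec, match_processes
from test_thresholds import make_dec


def barcodes_from(lam, lower, upper, labels=None):
    from csss.thresholds import ThresholdSet

    dec = make_dec(np.asarray(lam, dtype=float))
    if labels is not None:
        dec.sample_labels = np.asarray(labels, dtype=object)
    thr = ThresholdSet(np.asarray(lower, float), np.asarray(upper, float),
                       "quantile", {}, ["quantile"] * len(lower),
                       np.zeros(len(lower)))
    return dec, thr


class TestAssign:
    def test_inside_interval_is_all_zero(self):
        dec, thr = barcodes_from([[0.1, -0.2]] * 4, [-1, -1], [1, 1])
        bars = assign_barcodes(dec, thr)
        assert np.all(bars.codes == 0)
        assert bars.strings()[0] == "00"

    def test_signed_and_binary_modes(self):
        dec, thr = barcodes_from([[2.0, -2.0], [0.0, 0.0], [-2.0, 2.0]],
                                 [-1, -1], [1, 1])
        signed = assign_barcodes(dec, thr, mode="signed")
        binary = assign_barcodes(dec, thr, mode="binary")
        np.testing.assert_array_equal(signed.codes, [[1, -1], [0, 0], [-1, 1]])
        np.testing.assert_array_equal(binary.codes, np.abs(signed.codes))

    def test_k_mismatch_raises(self):
        dec, thr = barcodes_from([[0.0, 0.0]] * 3, [-1], [1])
        with pytest.raises(ValueError, match="processes"):
            assign_barcodes(dec, thr)

    def test_single_active_process_cell(self, planted):
        """A cell carrying only one planted process gets a one-hot barcode."""
        spec, mat, truth = planted
        dec = fit_surprisal(mat, max_processes=2)
        match, signs, _ = match_processes(dec.G, spec.processes)
        thr = compute_thresholds(dec, method="knee")
        bars = assign_barcodes(dec, thr)
        p2_only = truth["barcode"].to_numpy() == "0+"
        fitted_col = int(np.where(match == 1)[0][0])
        expected = np.zeros(2, dtype=int)
        expected[fitted_col] = int(signs[fitted_col])
        got = bars.codes[p2_only]
        assert (got == expected).all(axis=1).mean() > 0.99

    def test_confusion_diagonal_mass(self, planted):
        """Recovered vs planted barcodes agree for >= 90% of cells."""
        spec, mat, truth = planted
        dec = fit_surprisal(mat, max_processes=2)
        match, signs, _ = match_processes(dec.G, spec.processes)
        thr = compute_thresholds(dec, method="knee")
        bars = assign_barcodes(dec, thr)
        translated = np.zeros_like(bars.codes)
        for f, (p, s) in enumerate(zip(match, signs)):
            translated[:, p] = bars.codes[:, f] * int(s)
        rec = np.array([barcode_to_string(c) for c in translated])
        assert (rec == truth["barcode"].to_numpy()).mean() >= 0.90

    def test_idempotent_and_permutation_invariant(self, rng):
        lam = rng.normal(size=(500, 2))
        dec, thr = barcodes_from(lam, [-1.5, -1.5], [1.5, 1.5])
        b1 = assign_barcodes(dec, thr)
        b2 = assign_barcodes(dec, thr)
        np.testing.assert_array_equal(b1.codes, b2.codes)
        perm = rng.permutation(500)
        dec2, _ = barcodes_from(lam[perm], [-1.5, -1.5], [1.5, 1.5])
        b3 = assign_barcodes(dec2, thr)
        np.testing.assert_array_equal(b1.codes[perm], b3.codes)

    def test_tightening_thresholds_grows_zero_barcode(self, rng):
        lam = rng.normal(size=(1_000, 2))
        dec, thr_wide = barcodes_from(lam, [-1.0, -1.0], [1.0, 1.0])
        _, thr_tight = barcodes_from(lam, [-2.0, -2.0], [2.0, 2.0])
        frac_wide = (assign_barcodes(dec, thr_wide).codes == 0).all(axis=1).mean()
        frac_tight = (assign_barcodes(dec, thr_tight).codes == 0).all(axis=1).mean()
        assert frac_tight >= frac_wide


class TestTabulate:
    def _bars(self, strings, labels):
        code_map = {"+": 1, "-": -1, "0": 0}
        codes = np.array([[code_map[ch] for ch in s] for s in strings], dtype=np.int8)
        from csss.barcoding import BarcodeAssignment

        return BarcodeAssignment(codes, "signed", [f"c{j}" for j in range(len(strings))],
                                 np.asarray(labels, dtype=object))

    def test_two_barcode_fractions(self):
        bars = self._bars(["+0"] * 6 + ["0-"] * 4, ["s"] * 10)
        tab = tabulate_subpopulations(bars)
        assert tab.loc["+0", "frac_s"] == 0.6
        assert tab.loc["0-", "frac_s"] == 0.4
        assert tab.loc["+0", "label"] == "a" and tab.loc["0-", "label"] == "b"

    def test_rare_barcode_kept_but_not_dominant(self):
        strings = ["+0"] * 995 + ["0+"] * 5
        tab = tabulate_subpopulations(self._bars(strings, ["s"] * 1000),
                                      abundance_floor=0.01)
        assert "0+" in tab.index
        assert not tab.loc["0+", "dominant"]
        assert tab.loc["+0", "dominant"]

    def test_zero_barcode_never_dominant_and_labelled_0(self):
        strings = ["00"] * 900 + ["+0"] * 100
        tab = tabulate_subpopulations(self._bars(strings, ["s"] * 1000))
        assert tab.loc["00", "label"] == "0"
        assert not tab.loc["00", "dominant"]

    def test_counts_conserved_per_condition(self, rng):
        n = 600
        labels = rng.choice(["control", "RT"], size=n)
        codes = rng.choice(["00", "+0", "0-", "++"], size=n)
        tab = tabulate_subpopulations(self._bars(codes, labels))
        for cond in ("control", "RT"):
            assert tab[f"count_{cond}"].sum() == int(np.sum(labels == cond))
            assert abs(tab[f"frac_{cond}"].sum() - 1.0) < 1e-9

    def test_any_condition_scope_flags_emergent(self):
        strings = ["+0"] * 100 + ["00"] * 900 + ["0+"] * 20 + ["00"] * 980
        labels = ["control"] * 1000 + ["RT"] * 1000
        tab = tabulate_subpopulations(self._bars(strings, labels),
                                      abundance_floor=0.01, floor_scope="any_condition")
        assert tab.loc["0+", "dominant"]  # 2% of RT though absent from control

    def test_eight_planted_dominant_rows(self):
        from csss.synth import paper_shaped_spec

        spec = paper_shaped_spec(n_cells=4000, seed=5)
        mat, truth = generate(spec)
        dec = fit_surprisal(mat, max_processes=4)
        thr = compute_thresholds(dec, method="knee")
        tab = tabulate_subpopulations(assign_barcodes(dec, thr))
        assert int(tab["dominant"].sum()) == 8

    @given(floor=st.floats(0.0, 0.5))
    @settings(max_examples=20, deadline=None)
    def test_fraction_sum_invariant(self, floor):
        rng = np.random.default_rng(3)
        codes = rng.choice(["00", "+0", "0-"], size=200)
        if floor >= 1.0:
            return
        tab = tabulate_subpopulations(self._bars(codes, ["s"] * 200),
                                      abundance_floor=min(floor, 0.99))
        assert abs(tab["frac_s"].sum() - 1.0) < 1e-9
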