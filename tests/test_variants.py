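"""Variant classification, union re-interrogation, retention arithmetic,
VAF regression, PDX-specific reporting, drivers and passage stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from pdxfidelity.variants import (
    CLASS_LABELS,
    VariantObservation,
    build_paired_table,
    classify_observation,
    driver_conservation,
    passage_stability,
    pdx_specific_report,
    retention_from_counts,
    retention_summary,
    vaf_concordance,
)


def _calls(keys):
    return pd.DataFrame(keys, columns=["chrom", "pos", "ref", "alt"])


def _pileup(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads"]
    )


class TestClassify:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (100, 20, "detected"),
            (10, 3, "low_coverage"),
            (200, 4, "low_VAF"),
            (5, 0, "undetected_low_coverage"),
            (50, 0, "undetected"),
            (20, 1, "detected"),  # inclusive thresholds: 20x, 5%
            (19, 1, "low_coverage"),
            (100, 5, "detected"),  # VAF exactly 5%
        ],
    )
    def test_examples(self, depth, alt, expected):
        assert classify_observation(depth=depth, alt_reads=alt) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_observation(depth=-1, alt_reads=0)
        with pytest.raises(ValueError):
            VariantObservation("chr1", 5, "A", "T", "s", depth=10, alt_reads=12)

    @given(depth=st.integers(0, 500), alt=st.integers(0, 500))
    @settings(max_examples=200, derandomize=True)
    def test_labels_partition_all_cases(self, depth, alt):
        if alt > depth:
            alt = depth
        label = classify_observation(depth=depth, alt_reads=alt)
        assert label in CLASS_LABELS
        # the label is a function of (alt>0, depth>=20, vaf>=0.05) alone
        again = classify_observation(depth=depth, alt_reads=alt)
        assert label == again


class TestPairedTable:
    def test_identical_call_sets_no_recovery_no_specific(self):
        keys = [("chr1", 100, "A", "T"), ("chr1", 200, "C", "G")]
        pile = _pileup([k + (100, 30) for k in keys])
        table = build_paired_table(_calls(keys), _calls(keys), pile, pile)
        assert (table["provenance"] == "both").all()
        assert not table["recovered_in_pdx"].any()
        m = retention_summary(table)
        assert (m.pct_detected, m.pct_recovered, m.pct_shared) == (100.0, 0.0, 100.0)

    def test_tumor_only_variant_recovered_in_pdx(self):
        keys = [("chr1", 100, "A", "T")]
        t_pile = _pileup([("chr1", 100, "A", "T", 100, 30)])
        p_pile = _pileup([("chr1", 100, "A", "T", 30, 3)])
        table = build_paired_table(_calls(keys), _calls([]), t_pile, p_pile)
        row = table.iloc[0]
        assert row["provenance"] == "tumor_only"
        assert row["pdx_label"] == "detected"  # 3/30 = 10% at 30x
        assert row["recovered_in_pdx"]

    def test_missing_pileup_position_names_it(self):
        keys = [("chr1", 100, "A", "T")]
        t_pile = _pileup([("chr1", 100, "A", "T", 100, 30)])
        with pytest.raises(ValueError, match="chr1:100"):
            build_paired_table(_calls(keys), _calls([]), t_pile, _pileup([]))

    def test_recovered_count_matches_ground_truth_recount(self, simulated_pair):
        """Brute-force oracle: recovered = tumor-called keys absent from
        the PDX call set but with >= 1 PDX alt read."""
        obs, truth, table = simulated_pair
        cfg_dt, cfg_vt = 20, 0.05
        t_called = set()
        p_called = set()
        for r in obs.itertuples(index=False):
            key = (r.chrom, r.pos, r.ref, r.alt)
            for called, d, a in ((t_called, r.tumor_depth, r.tumor_alt),
                                 (p_called, r.pdx_depth, r.pdx_alt)):
                if a > 0 and d >= cfg_dt and a / d >= cfg_vt:
                    called.add(key)
        expected = sum(
            1
            for r in obs.itertuples(index=False)
            if (r.chrom, r.pos, r.ref, r.alt) in t_called
            and (r.chrom, r.pos, r.ref, r.alt) not in p_called
            and r.pdx_alt > 0
        )
        m = retention_summary(table)
        assert m.recovered == expected
        assert m.total == len(t_called)


class TestRetentionArithmetic:
    @pytest.mark.parametrize(
        "total,detected,recovered,expected",
        [
            (2414, 1929, 231, (79.9, 9.6, 89.5)),
            (220, 119, 19, (54.1, 8.6, 62.7)),
            (100, 100, 0, (100.0, 0.0, 100.0)),
        ],
    )
    def test_half_up_percentages(self, total, detected, recovered, expected):
        m = retention_from_counts(total, detected, recovered)
        assert (m.pct_detected, m.pct_recovered, m.pct_shared) == expected

    def test_truncated_mode_for_passages(self):
        assert retention_from_counts(104, 90, 0, rounding="truncated").pct_detected == 86

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            retention_from_counts(0, 0, 0)

    def test_detected_plus_recovered_equals_shared_before_rounding(self):
        m = retention_from_counts(2414, 1929, 231)
        assert m.shared_fraction == pytest.approx((1929 + 231) / 2414)

    @given(
        dt=st.integers(5, 40),
        vt=st.floats(0.01, 0.2),
    )
    @settings(
        max_examples=25, deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_lowering_thresholds_never_decreases_shared(self, dt, vt, simulated_pair):
        """Monotonicity: stricter thresholds can only shrink detection,
        and anything detected is also counted as shared."""
        obs, _, _ = simulated_pair
        from pdxfidelity.simulate import observations_to_calls, observations_to_pileup
        from pdxfidelity.simulate import SimulationConfig

        def shared_fraction(dthr, vthr):
            cfg = SimulationConfig(depth_threshold=dthr, vaf_threshold=vthr)
            t = build_paired_table(
                observations_to_calls(obs, "tumor", cfg),
                observations_to_calls(obs, "pdx", cfg),
                observations_to_pileup(obs, "tumor", "t"),
                observations_to_pileup(obs, "pdx", "x"),
                depth_threshold=dthr,
                vaf_threshold=vthr,
            )
            try:
                return retention_summary(t).shared_fraction
            except ValueError:
                return 1.0
        assert shared_fraction(dt, vt) <= shared_fraction(max(dt - 5, 1), vt) + 1e-12


class TestVafConcordance:
    def test_identical_vafs_give_unit_r2_and_slope(self):
        keys = [("chr1", i, "A", "T") for i in range(10)]
        pile = _pileup([k + (100, 10 + 5 * i) for i, k in enumerate(keys)])
        table = build_paired_table(_calls(keys), _calls(keys), pile, pile)
        r2, slope, intercept, n = vaf_concordance(table)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert n == 10

    def test_exact_line_slope_two(self):
        keys = [("chr1", i, "A", "T") for i in (1, 2, 3)]
        t_pile = _pileup([k + (100, v) for k, v in zip(keys, (10, 20, 30))])
        p_pile = _pileup([k + (100, v) for k, v in zip(keys, (20, 40, 60))])
        table = build_paired_table(_calls(keys), _calls(keys), t_pile, p_pile)
        r2, slope, intercept, _ = vaf_concordance(table)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_least_squares_oracle(self, simulated_pair):
        """Normal-equation OLS written out by hand."""
        _, _, table = simulated_pair
        r2, slope, intercept, n = vaf_concordance(table)
        use = table[
            (table["tumor_alt"] > 0) & (table["pdx_alt"] > 0)
            & (table["tumor_depth"] >= 20) & (table["pdx_depth"] >= 20)
        ]
        x = use["tumor_vaf"].to_numpy()
        y = use["pdx_vaf"].to_numpy()
        assert n == len(x) >= 3
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        b = sxy / sxx
        a = y.mean() - b * x.mean()
        resid = y - (a + b * x)
        r2_oracle = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(b, abs=1e-10)
        assert intercept == pytest.approx(a, abs=1e-10)
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_too_few_points_rejected(self):
        keys = [("chr1", 1, "A", "T")]
        pile = _pileup([keys[0] + (100, 30)])
        table = build_paired_table(_calls(keys), _calls(keys), pile, pile)
        with pytest.raises(ValueError, match="usable points"):
            vaf_concordance(table)


class TestPdxSpecific:
    def _pdx_only_table(self, n, pdx_vals=None, tumor_depths=None):
        keys = [("chr1", i + 1, "A", "T") for i in range(n)]
        pdx_vals = pdx_vals or [(100, 30)] * n
        tumor_depths = tumor_depths or [100] * n
        t_pile = _pileup([k + (d, 0) for k, d in zip(keys, tumor_depths)])
        p_pile = _pileup([k + v for k, v in zip(keys, pdx_vals)])
        return build_paired_table(_calls([]), _calls(keys), t_pile, p_pile), keys

    def test_expressed_fraction(self):
        table, keys = self._pdx_only_table(149)
        rna = _pileup([k + (50, 5 if i < 76 else 0) for i, k in enumerate(keys)])
        rep = pdx_specific_report(table, rna_pileup=rna)
        assert rep["n_pdx_only"] == 149
        assert rep["n_expressed"] == 76
        assert rep["pct_expressed"] == 51.0

    def test_low_vaf_and_low_coverage_fractions(self):
        pdx_vals = [(100, 4)] * 37 + [(100, 30)] * 153  # 37 at 4% VAF
        tumor_depths = [10] * 4 + [100] * 186  # 4 with <20x in tumor
        table, _ = self._pdx_only_table(190, pdx_vals, tumor_depths)
        rep = pdx_specific_report(table)
        assert rep["n_low_vaf"] == 37
        assert rep["pct_low_vaf"] == 19.5
        assert rep["n_low_tumor_coverage"] == 4
        assert rep["pct_low_tumor_coverage"] == 2.1

    def test_empty_pdx_only_set(self):
        keys = [("chr1", 1, "A", "T")]
        pile = _pileup([keys[0] + (100, 30)])
        table = build_paired_table(_calls(keys), _calls(keys), pile, pile)
        rep = pdx_specific_report(table, rna_pileup=_pileup([]))
        assert rep["n_pdx_only"] == 0
        assert rep["n_expressed"] == 0


class TestDriverConservation:
    BED = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [1000, 1000],
         "name": ["TP53", "NOTCH1"]}
    )

    def test_all_shared_is_conserved(self):
        keys = [("chr1", 100, "A", "T"), ("chr2", 50, "C", "G")]
        pile = _pileup([k + (100, 30) for k in keys])
        table = build_paired_table(_calls(keys), _calls(keys), pile, pile)
        res = driver_conservation(table, self.BED)
        assert res["conserved"]
        assert res["per_gene"].set_index("gene").loc["TP53", "n_shared"] == 1

    def test_tumor_only_driver_flags_non_conserved(self):
        keys = [("chr1", 100, "A", "T")]
        t_pile = _pileup([("chr1", 100, "A", "T", 100, 30)])
        p_pile = _pileup([("chr1", 100, "A", "T", 100, 0)])  # lost in PDX
        table = build_paired_table(_calls(keys), _calls([]), t_pile, p_pile)
        res = driver_conservation(table, self.BED)
        assert not res["conserved"]
        assert len(res["lost_driver_mutations"]) == 1

    def test_injected_driver_loss_in_simulation_flagged(self, simulated_pair):
        """Force one tumor-called variant to zero PDX reads; exactly that
        gene pair must be non-conserved."""
        _, _, table = simulated_pair
        t_rows = table[table["called_in_tumor"]]
        victim = t_rows.iloc[0]
        table = table.copy()
        table.loc[victim.name, ["pdx_alt", "pdx_vaf"]] = 0, 0.0
        table.loc[victim.name, ["called_in_pdx", "recovered_in_pdx"]] = False, False
        bed = pd.DataFrame(
            {"chrom": [victim["chrom"]], "start": [victim["pos"] - 1],
             "end": [victim["pos"] + 1], "name": ["VICTIM"]}
        )
        res = driver_conservation(table, bed)
        assert not res["conserved"]
        assert res["lost_driver_mutations"]["pos"].tolist() == [victim["pos"]]


class TestPassageStability:
    def _chain(self):
        keys = [("chr1", i + 1, "A", "T") for i in range(10)]
        primary = _calls(keys)
        pile_full = _pileup([k + (100, 30) for k in keys])
        # P0 loses the last 2 variants entirely
        p0_pile = _pileup(
            [k + ((100, 30) if i < 8 else (100, 0)) for i, k in enumerate(keys)]
        )
        p2_pile = _pileup(
            [k + ((100, 30) if i < 7 else (100, 0)) for i, k in enumerate(keys)]
        )
        p0_calls = _calls(keys[:8])
        p2_calls = {"p2a": _calls(keys[:7]), "p2b": _calls(keys[:7])}
        pileups = {"primary": pile_full, "p0": p0_pile, "p2a": p2_pile, "p2b": p2_pile}
        return primary, p0_calls, p2_calls, pileups

    def test_known_dropouts_recovered_exactly(self):
        primary, p0_calls, p2_calls, pileups = self._chain()
        res = passage_stability(primary, p0_calls, p2_calls, pileups)
        assert res["n_primary"] == 10
        assert res["n_detected_p0"] == 8
        assert res["pct_detected_p0"] == 80
        assert res["p2"]["p2a"]["n_confirmed"] == 7
        assert res["p2"]["p2a"]["pct_confirmed"] == 87  # trunc(7/8)

    def test_identical_samples_give_full_retention(self):
        keys = [("chr1", i + 1, "A", "T") for i in range(5)]
        pile = _pileup([k + (100, 30) for k in keys])
        res = passage_stability(
            _calls(keys), _calls(keys), {"p2a": _calls(keys)},
            {"primary": pile, "p0": pile, "p2a": pile},
        )
        assert res["pct_detected_p0"] == 100
        assert res["p2"]["p2a"]["pct_confirmed"] == 100
        assert len(res["p2_private"]) == 0

    def test_p2_private_variants_listed_with_shared_flag(self):
        keys = [("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")]
        zero = (100, 0)
        hot = (100, 20)
        pileups = {
            "primary": _pileup([keys[0] + hot, keys[1] + zero]),
            "p0": _pileup([keys[0] + hot, keys[1] + zero]),
            "p2a": _pileup([keys[0] + hot, keys[1] + hot]),
            "p2b": _pileup([keys[0] + hot, keys[1] + hot]),
        }
        res = passage_stability(
            _calls([keys[0]]), _calls([keys[0]]),
            {"p2a": _calls(keys), "p2b": _calls(keys)}, pileups,
        )
        private = res["p2_private"]
        assert private["pos"].tolist() == [2]
        assert private["shared_all_p2"].all()

    def test_empty_p2_list_rejected(self):
        primary, p0_calls, _, pileups = self._chain()
        with pytest.raises(ValueError, match="empty P2"):
            passage_stability(primary, p0_calls, {}, pileups)
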