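import dataclasses

import numpy as np
import pandas as pd
import pytest

import darcsign as ds
from darcsign.somatic_filters import RULES, evaluate_record
from darcsign.types import VariantRecord

EMPTY_MODEL = ds.ErrorModel(rates={}, panel_size=1)


def snv(vaf=0.10, depth=200, normal_depth=180, normal_alt=0, end_dist=30.0,
        context=None, repeat=False, alt_reads=None, pos=100):
    alt = alt_reads if alt_reads is not None else int(round(vaf * depth))
    context = context or ("ATCG" * 5 + "C" + "CGAT" * 5)
    return VariantRecord(
        chrom="1", pos=pos, ref="C", alt="T",
        tumour_depth=depth, tumour_alt=alt,
        normal_depth=normal_depth, normal_alt=normal_alt,
        mean_end_distance=end_dist, context=context, repeat_adjacent=repeat,
    )


def brute_force_verdict(r: VariantRecord, model: ds.ErrorModel,
                        c: ds.FilterConfig) -> set:
    """Literal rule-by-rule evaluation, independent of the implementation."""
    failed = set()
    t_vaf = r.tumour_alt / r.tumour_depth
    n_vaf = r.normal_alt / r.normal_depth if r.normal_depth else 0.0
    if t_vaf <= c.min_vaf:
        failed.add("vaf")
    if r.tumour_alt < c.min_alt_reads:
        failed.add("alt_reads")
    if r.tumour_depth <= c.min_depth or r.normal_depth <= c.min_depth:
        failed.add("depth")
    if t_vaf < c.tumour_vs_normal_ratio * n_vaf:
        failed.add("tn_ratio")
    window = r.context
    if r.is_snv:
        mid = len(window) // 2
        window = window[:mid] + window[mid + 1:]
    from collections import Counter
    dominant = max(Counter(window.upper()).values()) / len(window) > c.context_dominance
    mult = c.repeat_error_multiplier if (r.repeat_adjacent or dominant) else c.error_multiplier
    if r.is_snv:
        rate = model.rate(r.chrom, r.pos, r.alt)
    else:
        longer = r.alt if len(r.alt) > len(r.ref) else r.ref
        rate = model.rate(r.chrom, r.pos, longer[min(len(r.ref), len(r.alt))])
    if t_vaf < mult * rate:
        failed.add("error_rate")
    if r.mean_end_distance < c.min_end_distance:
        failed.add("end_distance")
    return failed


class TestErrorModel:
    def test_mean_vaf_across_samples(self):
        pileups = pd.DataFrame(
            {
                "sample": ["s1", "s2"],
                "chrom": ["1", "1"],
                "pos": [100, 100],
                "base": ["T", "T"],
                "alt_count": [0, 2],
                "depth": [100, 100],
            }
        )
        model = ds.build_error_model(pileups)
        assert model.rate("1", 100, "T") == pytest.approx(0.01)
        assert model.panel_size == 2

    def test_single_sample_rate_is_its_vaf(self):
        pileups = pd.DataFrame(
            {"sample": ["s1"], "chrom": ["1"], "pos": [5], "base": ["G"],
             "alt_count": [3], "depth": [60]}
        )
        assert ds.build_error_model(pileups).rate("1", 5, "G") == pytest.approx(0.05)

    def test_zero_depth_rows_excluded_and_matches_brute_force(self):
        rng = np.random.default_rng(11)
        rows = []
        for sample in range(5):
            for pos in range(1, 21):
                for base in "ACGT":
                    depth = int(rng.integers(0, 200))
                    alt = int(rng.integers(0, depth + 1)) if depth else 0
                    rows.append(("s%d" % sample, "1", pos, base, alt, depth))
        df = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "base",
                                         "alt_count", "depth"])
        model = ds.build_error_model(df)
        for (chrom, pos, base), grp in df[df.depth > 0].groupby(["chrom", "pos", "base"]):
            expected = (grp.alt_count / grp.depth).mean()
            assert model.rate(chrom, pos, base) == pytest.approx(expected)

    def test_unmodelled_position_rate_is_zero(self):
        assert EMPTY_MODEL.rate("9", 999, "A") == 0.0


class TestContextDominance:
    def test_ninety_percent_single_base_is_dominant(self):
        assert ds.context_dominant_base("A" * 36 + "C" * 4, 0.80) is True

    def test_balanced_window_not_dominant(self):
        assert ds.context_dominant_base("ACGT" * 10, 0.80) is False

    def test_exactly_eighty_percent_not_dominant(self):
        # strict inequality at the boundary
        assert ds.context_dominant_base("A" * 32 + "CGTC" * 2, 0.80) is False

    def test_centre_base_excluded(self):
        # 41-mer: centre C surrounded by 33 A's among 40 -> 0.825 > 0.8
        ctx = "A" * 17 + "GTC" + "C" + "GTC" + "A" * 17
        assert ds.context_dominant_base(ctx, 0.80, exclude_index=20) is True


class TestCallSomatic:
    def test_clean_record_passes(self):
        (v,) = ds.call_somatic([snv()], EMPTY_MODEL)
        assert v.passed and v.failed_rules == []

    def test_short_end_distance_fails_only_that_rule(self):
        (v,) = ds.call_somatic([snv(end_dist=5.0)], EMPTY_MODEL)
        assert v.failed_rules == ["end_distance"]

    @pytest.mark.parametrize(
        "record,expected_failures",
        [
            (snv(vaf=0.02, depth=100), {"vaf", "alt_reads"}),  # VAF boundary: > is strict
            (snv(vaf=0.021, depth=1000), set()),
            (snv(end_dist=6.0), set()),                        # >= 6 bp passes
            (snv(depth=200, normal_depth=30), {"depth"}),      # strict > 30x in both
            (snv(alt_reads=9, depth=200), {"alt_reads"}),
            (snv(normal_alt=8, normal_depth=180), {"tn_ratio"}),  # 0.10 < 3 x 0.044
        ],
    )
    def test_boundary_semantics(self, record, expected_failures):
        (v,) = ds.call_somatic([record], EMPTY_MODEL)
        assert set(v.failed_rules) == expected_failures

    def test_error_rate_multiplier_doubles_near_repeats(self):
        model = ds.ErrorModel(rates={("1", 100, "T"): 0.004}, panel_size=3)
        # VAF 0.10 >= 20 x 0.004 = 0.08 but < 40 x 0.004 = 0.16
        (clean,) = ds.call_somatic([snv(vaf=0.10)], model)
        (repeat,) = ds.call_somatic([snv(vaf=0.10, repeat=True)], model)
        assert clean.passed
        assert repeat.failed_rules == ["error_rate"]

    def test_dominant_context_uses_strict_multiplier(self):
        model = ds.ErrorModel(rates={("1", 100, "T"): 0.004}, panel_size=3)
        ctx = "A" * 20 + "C" + "A" * 14 + "CGTCGT"  # 34/40 A = 0.85
        (v,) = ds.call_somatic([snv(vaf=0.10, context=ctx)], model)
        assert v.failed_rules == ["error_rate"]

    def test_twelve_record_table_matches_brute_force(self):
        config = ds.FilterConfig()
        model = ds.ErrorModel(
            rates={("1", 100, "T"): 0.003, ("1", 200, "T"): 0.0005}, panel_size=4
        )
        records = [
            snv(),                                   # clean pass
            snv(vaf=0.02, depth=100),                # VAF boundary
            snv(vaf=0.021, depth=1000),              # just above
            snv(end_dist=6.0),                       # end-distance boundary
            snv(end_dist=5.9),
            snv(depth=31, normal_depth=31, vaf=0.4),
            snv(depth=30, normal_depth=200, vaf=0.4, alt_reads=12),
            snv(normal_alt=6, normal_depth=180),
            snv(pos=100, vaf=0.05),                  # 0.05 < 20 x 0.003 x? -> 0.06 fail
            snv(pos=100, vaf=0.07),                  # 0.07 >= 0.06 pass
            snv(pos=100, vaf=0.10, repeat=True),     # 0.10 < 40 x 0.003
            snv(context="A" * 32 + "CGTC" * 2 + "C", alt_reads=20),  # exactly 80%
        ]
        verdicts = ds.call_somatic(records, model, config)
        for record, verdict in zip(records, verdicts):
            assert set(verdict.failed_rules) == brute_force_verdict(record, model, config), record

    def test_verdict_conservation_and_order_invariance(self):
        rng = np.random.default_rng(5)
        records = [
            snv(vaf=float(rng.uniform(0.01, 0.4)),
                depth=int(rng.integers(20, 300)),
                end_dist=float(rng.uniform(0, 30)),
                pos=int(rng.integers(1, 1000)))
            for _ in range(50)
        ]
        verdicts = ds.call_somatic(records, EMPTY_MODEL)
        assert len(verdicts) == len(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        by_record = {id(v.record): set(v.failed_rules)
                     for v in ds.call_somatic(shuffled, EMPTY_MODEL)}
        for v in verdicts:
            matching = [r for r in shuffled if r == v.record]
            assert set(ds.call_somatic(matching, EMPTY_MODEL)[0].failed_rules) \
                == set(v.failed_rules)

    def test_relaxing_thresholds_never_shrinks_pass_set(self):
        rng = np.random.default_rng(17)
        records = [
            snv(vaf=float(rng.uniform(0.01, 0.4)),
                depth=int(rng.integers(20, 300)),
                end_dist=float(rng.uniform(0, 30)))
            for _ in range(60)
        ]
        base = ds.FilterConfig()
        base_pass = {i for i, v in enumerate(ds.call_somatic(records, EMPTY_MODEL, base))
                     if v.passed}
        for relaxed in (
            dataclasses.replace(base, min_vaf=0.01),
            dataclasses.replace(base, min_alt_reads=5),
            dataclasses.replace(base, min_depth=20),
            dataclasses.replace(base, min_end_distance=3.0),
            dataclasses.replace(base, tumour_vs_normal_ratio=1.5),
            dataclasses.replace(base, error_multiplier=10.0),
        ):
            relaxed_pass = {
                i for i, v in enumerate(ds.call_somatic(records, EMPTY_MODEL, relaxed))
                if v.passed
            }
            assert base_pass <= relaxed_pass


class TestCallGermline:
    def germ(self, vaf, depth):
        return VariantRecord(
            chrom="1", pos=10, ref="A", alt="G", tumour_depth=0, tumour_alt=0,
            normal_depth=depth, normal_alt=int(round(vaf * depth)),
            mean_end_distance=20.0, context="", repeat_adjacent=False,
        )

    def test_heterozygous_kept(self):
        assert len(ds.call_germline([self.germ(0.50, 60)])) == 1

    def test_low_vaf_boundary_dropped(self):
        assert ds.call_germline([self.germ(0.29, 100)]) == []

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(3)
        records = [
            self.germ(float(rng.uniform(0.1, 0.9)), int(rng.integers(20, 120)))
            for _ in range(20)
        ]
        kept = ds.call_germline(records)
        expected = [
            r for r in records
            if 0.30 <= r.normal_alt / r.normal_depth <= 0.70 and r.normal_depth >= 40
        ]
        assert kept == expected
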