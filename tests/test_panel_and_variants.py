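"""Panel loading, VCF ingestion, CHIP filtering, and timepoint pairing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdyn import (
    FilterPolicy,
    filter_chip,
    load_panel,
    pair_timepoints,
    read_variants,
    write_panel_bed,
)
from chipdyn.panel_and_variants import (
    DEFAULT_PANEL_GENES,
    dt_years_by_individual,
    excluded_individuals,
    vcf_pos_to_bed,
)

from conftest import make_call, two_sample_metadata, write_vcf


class TestPanel:
    def test_default_panel_has_22_driver_genes(self, default_panel):
        assert set(default_panel.gene_symbols) == set(DEFAULT_PANEL_GENES)
        assert len(default_panel.genes) == 22
        # the assay targets on the order of 44 kb of sequence
        assert 30_000 < default_panel.target_bp < 60_000

    def test_single_record(self, tmp_path):
        bed = tmp_path / "one.bed"
        bed.write_text("chr1\t0\t100\tGENEX\n")
        panel = load_panel(bed)
        assert panel.gene_symbols == ("GENEX",)
        assert panel.target_bp == 100

    def test_overlapping_intervals_merge(self, tmp_path):
        bed = tmp_path / "overlap.bed"
        bed.write_text("chr1\t0\t100\tGENEX\nchr1\t50\t150\tGENEX\n")
        panel = load_panel(bed)
        assert panel.genes[0].intervals == (("chr1", 0, 150),)
        assert panel.target_bp == 150

    def test_malformed_record_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t100\tGENEX\nchr1\t200\n")
        with pytest.raises(ValueError, match=r":2"):
            load_panel(bed)

    def test_conflicting_capture_mode_rejected(self, tmp_path):
        bed = tmp_path / "conflict.bed"
        bed.write_text(
            "chr1\t0\t100\tGENEX\tfull-gene\nchr1\t200\t300\tGENEX\thotspot-region\n"
        )
        with pytest.raises(ValueError, match="conflicting"):
            load_panel(bed)

    def test_bed_round_trip(self, default_panel, tmp_path):
        out = tmp_path / "roundtrip.bed"
        write_panel_bed(default_panel, out)
        reloaded = load_panel(out)
        assert set(reloaded.gene_symbols) == set(default_panel.gene_symbols)
        assert reloaded.target_bp == default_panel.target_bp

    def test_gene_lookup_uses_half_open_intervals(self, tmp_path):
        bed = tmp_path / "coords.bed"
        bed.write_text("chr1\t100\t200\tGENEX\n")
        panel = load_panel(bed)
        assert vcf_pos_to_bed(101) == 100
        assert panel.gene_at("chr1", 101) == "GENEX"   # first covered base
        assert panel.gene_at("chr1", 200) == "GENEX"   # last covered base
        assert panel.gene_at("chr1", 100) is None      # BED start is exclusive in VCF coords
        assert panel.gene_at("chr1", 201) is None


class TestReadVariants:
    def test_vaf_from_ad_dp(self, default_panel, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [("chr2", 25234301, "C", ["T"], {"IND01_T1": (2000, (1960, 40))})],
            ["IND01_T1", "IND01_T2"],
        )
        calls = read_variants(vcf, default_panel, two_sample_metadata())
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.02)
        assert calls[0].gene == "DNMT3A"
        assert calls[0].timepoint == 1

    def test_off_panel_position_has_no_gene(self, default_panel, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [("chr1", 5, "C", ["T"], {"IND01_T1": (2000, (1960, 40))})],
            ["IND01_T1", "IND01_T2"],
        )
        calls = read_variants(vcf, default_panel, two_sample_metadata())
        assert calls[0].gene is None

    def test_multiallelic_decomposed_per_alt(self, default_panel, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [("chr2", 25234301, "C", ["T", "G"],
              {"IND01_T1": (2000, (1900, 60, 40))})],
            ["IND01_T1", "IND01_T2"],
        )
        calls = read_variants(vcf, default_panel, two_sample_metadata())
        assert sorted((c.alt, c.vaf) for c in calls) == [
            ("G", pytest.approx(0.02)), ("T", pytest.approx(0.03))]
        assert all(c.depth == 2000 for c in calls)

    def test_missing_format_fields_raise(self, default_panel, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tIND01_T1\tIND01_T2\n"
            "chr2\t25234301\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\n"
        )
        vcf = tmp_path / "nodp.vcf"
        vcf.write_text(text)
        with pytest.raises(ValueError, match="DP/AD"):
            read_variants(vcf, default_panel, two_sample_metadata())

    def test_unmappable_sample_raises(self, default_panel, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [("chr2", 25234301, "C", ["T"], {"MYSTERY": (100, (60, 40))})],
            ["MYSTERY"],
        )
        with pytest.raises(ValueError, match="MYSTERY"):
            read_variants(vcf, default_panel, two_sample_metadata())


def oracle_retained(call, policy):
    """Brute-force restatement of the filter: each clause independently."""
    return (
        call.depth >= policy.min_depth
        and call.alt_reads >= policy.min_alt_reads
        and call.vaf >= policy.min_vaf
        and call.gene is not None
    )


class TestFilterChip:
    @pytest.mark.parametrize(
        "depth,alt,gene,kept",
        [
            (2000, 40, "DNMT3A", True),    # all thresholds met at the boundary
            (99, 40, "DNMT3A", False),     # depth below 100
            (2000, 2, "DNMT3A", False),    # alt-read support below 3
            (2000, 30, "DNMT3A", False),   # VAF 1.5% below the 2% CHIP threshold
            (100, 3, "DNMT3A", True),      # every clause exactly at its minimum
            (2000, 40, None, False),       # off-panel
        ],
    )
    def test_three_clause_predicate(self, policy, depth, alt, gene, kept):
        call = make_call(depth=depth, alt_reads=alt, gene=gene)
        assert bool(filter_chip([call], policy)) is kept

    def test_empty_input(self, policy):
        assert filter_chip([], policy) == []

    def test_idempotent(self, policy):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(200):
            depth = int(rng.integers(1, 400))
            alt = min(int(rng.integers(0, 30)), depth)
            calls.append(make_call(
                individual_id=f"I{i}", depth=depth, alt_reads=alt,
                gene="DNMT3A" if rng.random() < 0.8 else None,
            ))
        once = filter_chip(calls, policy)
        assert filter_chip(once, policy) == once

    @given(st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=3000),   # depth
            st.floats(min_value=0, max_value=1),        # vaf quantile
            st.booleans(),                              # on-panel?
        ),
        max_size=200,
    ))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_oracle(self, records):
        policy = FilterPolicy()
        calls = []
        for i, (depth, q, on_panel) in enumerate(records):
            alt = min(int(q * 60), depth)
            calls.append(make_call(
                individual_id=f"I{i}", depth=depth, alt_reads=alt,
                gene="DNMT3A" if on_panel else None,
            ))
        kept = filter_chip(calls, policy)
        expected = [c for c in calls if oracle_retained(c, policy)]
        assert kept == expected


class TestPairTimepoints:
    def _meta(self, dt=5.0, flag=0):
        meta = two_sample_metadata(dt_years=dt)
        meta["blood_cancer_flag"] = flag
        return meta

    def test_passes_both_timepoints(self, policy):
        t1 = make_call(timepoint=1, depth=2000, alt_reads=80)   # 4%
        t2 = make_call(timepoint=2, depth=2000, alt_reads=120)  # 6%
        pairs = pair_timepoints([t1, t2], [t1, t2], policy, self._meta())
        assert len(pairs) == 1
        assert (pairs[0].vaf1, pairs[0].vaf2) == (0.04, 0.06)
        assert pairs[0].pass_t1 and pairs[0].pass_t2
        assert not (pairs[0].imputed_t1 or pairs[0].imputed_t2)

    def test_missing_timepoint_imputed_at_floor(self, policy):
        t2 = make_call(timepoint=2, depth=2000, alt_reads=100)  # 5%
        pairs = pair_timepoints([t2], [t2], policy, self._meta())
        assert len(pairs) == 1
        assert pairs[0].vaf1 == policy.floor_vaf == 0.001
        assert pairs[0].vaf2 == 0.05
        assert pairs[0].imputed_t1 and not pairs[0].imputed_t2

    def test_subthreshold_call_rescued(self, policy, default_panel, tmp_path):
        # t1 passes at 3%; t2 has a raw 1.2% call (24/2000) below the CHIP
        # threshold but with ample alt reads -> rescued, not imputed
        vcf = write_vcf(
            tmp_path / "rescue.vcf",
            [("chr2", 25234301, "C", ["T"],
              {"IND01_T1": (2000, (1940, 60)), "IND01_T2": (2000, (1976, 24))})],
            ["IND01_T1", "IND01_T2"],
        )
        calls = read_variants(vcf, default_panel, self._meta())
        retained = filter_chip(calls, policy)
        assert len(retained) == 1  # only t1 survives the filters
        pairs = pair_timepoints(retained, calls, policy, self._meta())
        assert len(pairs) == 1
        assert pairs[0].vaf1 == 0.03
        assert pairs[0].vaf2 == pytest.approx(0.012)
        assert not pairs[0].imputed_t2

    def test_rescue_requires_min_alt_reads(self, policy):
        t1 = make_call(timepoint=1, depth=2000, alt_reads=60)
        weak_t2 = make_call(timepoint=2, depth=2000, alt_reads=2)  # below min_alt
        pairs = pair_timepoints([t1], [t1, weak_t2], policy, self._meta())
        assert pairs[0].vaf2 == policy.floor_vaf
        assert pairs[0].imputed_t2

    def test_rescue_disabled_by_policy(self):
        policy = FilterPolicy(rescue_cross_timepoint=False)
        t1 = make_call(timepoint=1, depth=2000, alt_reads=60)
        sub = make_call(timepoint=2, depth=2000, alt_reads=24)
        pairs = pair_timepoints([t1], [t1, sub], policy, self._meta())
        assert pairs[0].vaf2 == policy.floor_vaf

    def test_blood_cancer_individuals_dropped(self, policy):
        t1 = make_call(timepoint=1, depth=2000, alt_reads=80)
        assert pair_timepoints([t1], [t1], policy, self._meta(flag=1)) == []

    def test_single_timepoint_individual_skipped(self, policy):
        t1 = make_call(timepoint=1, depth=2000, alt_reads=80)
        meta = self._meta().iloc[:1]
        assert pair_timepoints([t1], [t1], policy, meta) == []

    def test_pair_invariants_on_random_cohort(self, policy):
        rng = np.random.default_rng(11)
        retained, raw = [], []
        for i in range(40):
            iid = f"I{i:02d}"
            for tp in (1, 2):
                alt = int(rng.integers(0, 300))
                call = make_call(individual_id=iid, timepoint=tp,
                                 depth=2000, alt_reads=alt)
                raw.append(call)
                if alt >= 40:
                    retained.append(call)
        meta = pd.concat([two_sample_metadata(individual=f"I{i:02d}")
                          for i in range(40)], ignore_index=True)
        pairs = pair_timepoints(retained, raw, policy, meta)
        for p in pairs:
            assert policy.floor_vaf <= p.vaf1 <= 1
            assert policy.floor_vaf <= p.vaf2 <= 1
            assert max(p.vaf1, p.vaf2) >= policy.min_vaf
            assert p.pass_t1 or p.pass_t2


class TestMetadata:
    def test_dates_take_precedence_over_ages(self):
        meta = two_sample_metadata(dt_years=5.0)
        meta["draw_date"] = ["2005-01-01", "2009-01-01"]  # 4.0 years, ages say 5
        dt = dt_years_by_individual(meta)
        assert dt["IND01"] == pytest.approx(1461 / 365.25)

    def test_age_fallback(self):
        dt = dt_years_by_individual(two_sample_metadata(dt_years=7.5))
        assert dt["IND01"] == pytest.approx(7.5)

    def test_nonpositive_interval_raises(self):
        meta = two_sample_metadata()
        meta["age"] = [60.0, 60.0]
        with pytest.raises(ValueError, match="<= 0"):
            dt_years_by_individual(meta)

    def test_exclusion_flag_parsing(self):
        meta = two_sample_metadata()
        meta["blood_cancer_flag"] = ["true", "true"]
        assert excluded_individuals(meta) == {"IND01"}
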