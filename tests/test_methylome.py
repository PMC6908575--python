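import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_track, uniform_track
from imprintscan import (
    IgDMRCall,
    Region,
    ScreenThresholds,
    classify_conservation,
    read_methylome,
    region_methylation,
    screen_igdmrs,
    write_methylome,
)
from imprintscan.errors import DataError, ParseError, UsageError


class TestReaders:
    def test_bismark_line_is_one_based_inclusive(self, tmp_path):
        p = tmp_path / "t.cov"
        p.write_text("chr1\t101\t101\t75\t3\t1\n")
        track = read_methylome(p, "bismark_cov")
        row = track.df.iloc[0]
        assert (row.pos, row.count_meth, row.count_unmeth) == (100, 3, 1)
        assert row.fraction == pytest.approx(0.75)

    def test_bedgraph_with_counts_is_zero_based(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("track type=bedGraph\nchr1\t100\t101\t75\t3\t1\n")
        track = read_methylome(p, "bedgraph")
        assert track.counts_known
        assert track.df.iloc[0].pos == 100

    def test_bedgraph_percent_only_flags_unknown_coverage(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t100\t101\t40\n")
        track = read_methylome(p, "bedgraph")
        assert not track.counts_known
        assert track.df.iloc[0].fraction == pytest.approx(0.4)

    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "empty.cov"
        p.write_text("")
        assert len(read_methylome(p, "bismark_cov")) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.cov"
        p.write_text("chr1\t101\t101\t75\t3\t1\nchr1\tnotanint\n")
        with pytest.raises(ParseError, match="line 2"):
            read_methylome(p, "bismark_cov")

    def test_unknown_format_is_usage_error(self, tmp_path):
        with pytest.raises(UsageError):
            read_methylome(tmp_path / "x", "wig")

    @pytest.mark.parametrize("fmt", ["bismark_cov", "bedgraph"])
    def test_round_trip_random_tracks(self, fmt, tmp_path):
        rng = np.random.default_rng(42)
        for rep in range(5):
            n = int(rng.integers(1, 50))
            pos = np.sort(rng.choice(10_000, size=n, replace=False))
            track = make_track("t", [
                ("chr%d" % rng.integers(1, 3), int(p), int(rng.integers(0, 30)),
                 int(rng.integers(0, 30))) for p in pos
            ])
            path = tmp_path / f"{fmt}_{rep}"
            write_methylome(track, path, fmt)
            assert read_methylome(path, fmt) == track


class TestRegionMethylation:
    def test_simple_mean(self):
        track = make_track("t", [("chr1", 10, 3, 1), ("chr1", 20, 1, 3)])
        mean, n = region_methylation(track, Region("chr1", 0, 100),
                                     ScreenThresholds(min_cpgs_per_region=1))
        assert (mean, n) == (0.5, 2)

    def test_no_sites_is_flagged_undefined(self):
        track = make_track("t", [("chr1", 500, 3, 1)])
        mean, n = region_methylation(track, Region("chr1", 0, 100))
        assert np.isnan(mean) and n == 0

    def test_weighted_mean_matches_count_ratio_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            sites = [("chr1", 10 * i, int(rng.integers(0, 20)),
                      int(rng.integers(1, 20))) for i in range(n)]
            track = make_track("t", sites)
            region = Region("chr1", 0, 10 * n + 1)
            mean, _ = region_methylation(track, region,
                                         ScreenThresholds(min_cpgs_per_region=1))
            brute = sum(m for _, _, m, _ in sites) / sum(m + u for _, _, m, u in sites)
            assert mean == pytest.approx(brute)

    def test_weighted_and_unweighted_differ_on_unequal_coverage(self):
        track = make_track("t", [("chr1", 10, 9, 1), ("chr1", 20, 0, 90)])
        th = ScreenThresholds(min_cpgs_per_region=1)
        w, _ = region_methylation(track, Region("chr1", 0, 100), th)
        u, _ = region_methylation(track, Region("chr1", 0, 100), th, weighted=False)
        assert w != pytest.approx(u)
        assert u == pytest.approx(0.45)

    def test_split_and_recombine_counts_invariance(self):
        rng = np.random.default_rng(3)
        sites = [("chr1", 10 * i, int(rng.integers(0, 9)), int(rng.integers(1, 9)))
                 for i in range(20)]
        track = make_track("t", sites)
        th = ScreenThresholds(min_cpgs_per_region=1)
        whole, n_whole = region_methylation(track, Region("chr1", 0, 200), th)
        # recombine counts from two halves
        tot_m = tot_cov = 0
        for sub in (Region("chr1", 0, 100), Region("chr1", 100, 200)):
            d = track.in_region(sub)
            tot_m += d["count_meth"].sum()
            tot_cov += (d["count_meth"] + d["count_unmeth"]).sum()
        assert whole == pytest.approx(tot_m / tot_cov)
        assert n_whole == 20

    def test_site_order_invariance(self):
        sites = [("chr1", 30, 5, 5), ("chr1", 10, 2, 8), ("chr1", 20, 9, 1)]
        a = make_track("t", sites)
        b = make_track("t", sites[::-1])
        th = ScreenThresholds(min_cpgs_per_region=1)
        assert region_methylation(a, Region("chr1", 0, 100), th) == \
            region_methylation(b, Region("chr1", 0, 100), th)


class TestScreen:
    def test_canonical_igdmr_profile_is_candidate(self, region, tissue_panel):
        calls = screen_igdmrs([region], tissue_panel)
        assert calls[0].candidate is True
        assert all(calls[0].flags.values())

    def test_oocyte_exactly_at_threshold_fails_strictly(self, region, tissue_panel):
        tissue_panel["oocyte"] = uniform_track("oocyte", 0.70)
        calls = screen_igdmrs([region], tissue_panel)
        assert calls[0].candidate is False
        assert calls[0].flags["oocyte_hyper"] is False

    def test_blastocyst_optional(self, region, tissue_panel):
        del tissue_panel["blastocyst"]
        assert screen_igdmrs([region], tissue_panel)[0].candidate is True

    def test_missing_gamete_track_is_usage_error(self, region, tissue_panel):
        del tissue_panel["sperm"]
        with pytest.raises(UsageError):
            screen_igdmrs([region], tissue_panel)

    def test_undefined_required_tissue_gives_undetermined(self, region, tissue_panel):
        tissue_panel["oocyte"] = make_track("oocyte", [("chr9", 5, 1, 0)])
        assert screen_igdmrs([region], tissue_panel)[0].candidate is None

    def test_intermediate_window_is_closed(self, region, tissue_panel):
        tissue_panel["placenta"] = uniform_track("placenta", 0.65)
        assert screen_igdmrs([region], tissue_panel)[0].candidate is True
        tissue_panel["placenta"] = uniform_track("placenta", 0.70)
        assert screen_igdmrs([region], tissue_panel)[0].candidate is False

    def test_monotone_in_oocyte_methylation(self, region, tissue_panel):
        previous = False
        for frac in np.linspace(0, 1, 21):
            tissue_panel["oocyte"] = uniform_track("oocyte", float(frac))
            cand = screen_igdmrs([region], tissue_panel)[0].candidate
            assert not (previous and not cand), "candidate flipped off as oocyte rose"
            previous = cand


def _call(name, status):
    region = Region("chrX", 0, 100, name=name)
    call = IgDMRCall(region=region)
    call.candidate = {"candidate": True, "non_candidate": False, "undetermined": None}[status]
    return call


class TestConservation:
    STATUSES = ["candidate", "non_candidate", "undetermined"]

    def test_exhaustive_status_table(self):
        expected = {
            ("candidate", "candidate"): "conserved",
            ("candidate", "non_candidate"): "species_A_specific",
            ("non_candidate", "candidate"): "species_B_specific",
            ("non_candidate", "non_candidate"): "neither",
        }
        for sa, sb in itertools.product(self.STATUSES, repeat=2):
            calls_a = [_call("a", sa)]
            calls_b = [_call("b", sb)]
            out = classify_conservation(calls_a, calls_b, [("a", "b")])
            if "undetermined" in (sa, sb):
                assert out["a"] == "undetermined"
            else:
                assert out["a"] == expected[(sa, sb)]

    def test_unpaired_region_is_no_synteny(self):
        out = classify_conservation([_call("lonely", "candidate")], [], [])
        assert out["lonely"] == "no_synteny"

    def test_partner_absent_from_other_species_is_no_synteny(self):
        out = classify_conservation([_call("a", "candidate")], [], [("a", "missing")])
        assert out["a"] == "no_synteny"

    def test_duplicate_pairings_raise(self):
        with pytest.raises(DataError):
            classify_conservation([_call("a", "candidate")],
                                  [_call("b", "candidate")],
                                  [("a", "b"), ("a", "c")])
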