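"""Meta-QTL construction, classification and region summaries."""

import numpy as np
import pytest

from metaqtl.meta import (
    CLASS_HOTSPOT,
    CLASS_MQTL,
    build_metaqtls,
    meta_analyze,
    regions_to_frame,
    summarize_regions,
)
from metaqtl.mixture import fit_mixture
from metaqtl.projection import ProjectedQTL


def proj(record_factory, qtl_id, study, peak, sigma=1.0, chrom="1A", lod=4.0, pve=10.0):
    half = 1.96 * sigma
    rec = record_factory(qtl_id=qtl_id, study=study, chrom=chrom, peak=peak,
                         ci=(max(0.0, peak - half), peak + half), lod=lod, pve=pve)
    return ProjectedQTL(
        record=rec, consensus_peak=peak,
        consensus_ci_lo=max(0.0, peak - half), consensus_ci_hi=peak + half,
        anchor_lo="A", anchor_hi="B", scale_ratio=1.0,
    )


class TestBuildMetaqtls:
    def test_two_member_closed_form(self, record_factory):
        members = [
            proj(record_factory, "q1", "S1", 10.0, sigma=1.0),
            proj(record_factory, "q2", "S2", 11.0, sigma=1.0),
        ]
        fit = fit_mixture([10.0, 11.0], [1.0, 1.0], 1)
        regions, singles, nonsup = build_metaqtls(fit, members, "1A")
        assert len(regions) == 1 and not singles and not nonsup
        r = regions[0]
        assert r.position == pytest.approx(10.5)
        # var = 1/(1+1) = 0.5; width = 2*1.96*sqrt(0.5)
        assert r.ci_width == pytest.approx(2 * 1.96 * np.sqrt(0.5), abs=1e-9)
        assert r.klass == CLASS_MQTL
        assert r.mqtl_id == "MQTL1A.1"

    def test_single_study_cluster_is_hotspot(self, record_factory):
        members = [proj(record_factory, f"q{i}", "S1", 10.0 + 0.1 * i) for i in range(3)]
        fit = fit_mixture([m.consensus_peak for m in members], [1.0] * 3, 1)
        regions, _, _ = build_metaqtls(fit, members, "5D")
        assert regions[0].klass == CLASS_HOTSPOT
        assert regions[0].mqtl_id == "QTLhotspot_5D"

    def test_one_member_component_is_singleton(self, record_factory):
        members = [
            proj(record_factory, "q1", "S1", 0.0),
            proj(record_factory, "q2", "S2", 0.2),
            proj(record_factory, "q3", "S3", 80.0),
        ]
        x = [m.consensus_peak for m in members]
        fit = fit_mixture(x, [1.0] * 3, 2)
        regions, singles, _ = build_metaqtls(fit, members, "1A")
        assert len(regions) == 1
        assert [s.qtl_id for s in singles] == ["q3"]

    def test_peak_outside_ci_moved_to_non_supporting(self, record_factory):
        # many tight members pin the CI; one distant member in the same
        # component peaks outside it
        members = [
            proj(record_factory, f"q{i}", f"S{i}", 10.0, sigma=0.2) for i in range(4)
        ] + [proj(record_factory, "far", "S9", 14.0, sigma=10.0)]
        x = [m.consensus_peak for m in members]
        s2 = [m.variance for m in members]
        fit = fit_mixture(x, s2, 1)
        regions, singles, nonsup = build_metaqtls(fit, members, "1A")
        assert [m.qtl_id for m in nonsup] == ["far"]
        assert len(regions) == 1 and regions[0].n_members == 4

    def test_average_lod_pve_and_naming_order(self, record_factory):
        members = [
            proj(record_factory, "a", "S1", 10.0, lod=3.0, pve=8.0),
            proj(record_factory, "b", "S2", 10.5, lod=5.0, pve=12.0),
            proj(record_factory, "c", "S1", 90.0, lod=4.0, pve=6.0),
            proj(record_factory, "d", "S2", 90.5, lod=6.0, pve=10.0),
        ]
        x = [m.consensus_peak for m in members]
        fit = fit_mixture(x, [1.0] * 4, 2)
        regions, _, _ = build_metaqtls(fit, members, "2B")
        assert [r.mqtl_id for r in regions] == ["MQTL2B.1", "MQTL2B.2"]
        assert regions[0].avg_lod == pytest.approx(4.0)
        assert regions[0].avg_pve == pytest.approx(10.0)

    def test_flanking_markers_outside_ci(self, record_factory, simple_consensus):
        members = [
            proj(record_factory, "q1", "S1", 14.0, sigma=0.5),
            proj(record_factory, "q2", "S2", 15.0, sigma=0.5),
        ]
        x = [m.consensus_peak for m in members]
        fit = fit_mixture(x, [0.25, 0.25], 1)
        regions, _, _ = build_metaqtls(fit, members, "1A", simple_consensus)
        assert regions[0].flank_lo == "B" and regions[0].flank_hi == "C"


class TestMetaAnalyze:
    def test_two_well_separated_loci_found(self, record_factory):
        members = [
            proj(record_factory, f"a{i}", f"S{i}", 20.0 + 0.3 * i) for i in range(4)
        ] + [
            proj(record_factory, f"b{i}", f"S{i}", 80.0 + 0.3 * i) for i in range(4)
        ]
        regions, singles, nonsup, diag = meta_analyze(members, k_max=4, seed=0)
        assert diag["1A"]["chosen_k"] == 2
        assert len(regions) == 2
        assert regions[0].position == pytest.approx(20.45, abs=0.5)

    def test_lone_qtl_on_chromosome_is_singleton(self, record_factory):
        regions, singles, _, _ = meta_analyze([proj(record_factory, "q", "S1", 5.0)])
        assert not regions and [s.qtl_id for s in singles] == ["q"]


class TestSummarize:
    def test_fold_reduction_trivial_case(self, record_factory):
        projected = [
            proj(record_factory, "a", "S1", 10.0, sigma=10 / 3.92),
            proj(record_factory, "b", "S2", 11.0, sigma=10 / 3.92),
            proj(record_factory, "c", "S1", 50.0, sigma=4 / 3.92),
        ]
        x = [m.consensus_peak for m in projected[:2]]
        fit = fit_mixture(x, [m.variance for m in projected[:2]], 1)
        regions, _, _ = build_metaqtls(fit, projected[:2], "1A")
        # force the region width for the arithmetic check
        regions[0].ci_lo, regions[0].ci_hi = 8.0, 12.0
        regions[0].position = 10.0
        s = summarize_regions(regions, projected)
        assert s["fold_reduction"] == pytest.approx(np.mean([10, 10, 4]) / 4.0)
        assert s["member_bins"]["=2"] == 1

    def test_zero_regions_flagged(self, record_factory):
        s = summarize_regions([], [proj(record_factory, "a", "S1", 5.0)])
        assert s["fold_reduction"] is None and s["n_regions"] == 0

    def test_regions_frame_layout(self, record_factory):
        members = [
            proj(record_factory, "q1", "S1", 10.0),
            proj(record_factory, "q2", "S2", 11.0),
        ]
        fit = fit_mixture([10.0, 11.0], [1.0, 1.0], 1)
        regions, _, _ = build_metaqtls(fit, members, "1A")
        df = regions_to_frame(regions)
        assert list(df["name"]) == ["MQTL1A.1"]
        assert set(df.columns) >= {"name", "chr", "position_cM", "ci_95", "n_qtls", "class"}
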