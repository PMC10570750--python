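"""Promoter states, enhancer calling/clustering, signal matrices, motifs."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from isletomics.annotation import (
    GenomicInterval,
    Peak,
    PeakSet,
    gene_tss_map,
    promoter_of,
)
from isletomics.epigenome import (
    PWM,
    CoverageTrack,
    EnhancerRecord,
    aggregate_profile,
    assign_enhancers_to_genes,
    build_signal_matrix,
    call_enhancers,
    classify_promoter_state,
    cluster_enhancer_states,
    differential_motif_enrichment,
    revcomp,
    scan_contains,
)


def peakset(mark, spans):
    return PeakSet(mark, [
        Peak(GenomicInterval("chr1", a, b), a + (b - a) // 2) for a, b in spans
    ])


def region(chrom, summit):
    return EnhancerRecord(GenomicInterval(chrom, summit - 200, summit + 200), summit)


def constant_track(mark, value, length=100_000, chrom="chr1"):
    t = CoverageTrack(mark)
    t.add_chrom(chrom, [0], [length], [value])
    return t


class TestPromoterState:
    @pytest.mark.parametrize(
        "k4,k27,want",
        [
            ([(900, 1100)], [(900, 1100)], "active"),
            ([(900, 1100)], [], "marked_only"),
            ([], [(900, 1100)], "unmarked"),  # H3K4me3 is the gate
        ],
    )
    def test_state_logic(self, k4, k27, want):
        prom = GenomicInterval("chr1", 800, 1200)
        assert classify_promoter_state(
            prom, peakset("H3K4me3", k4), peakset("H3K27ac", k27)
        ) == want

    def test_planted_promoter_states_recovered(self, noisefree):
        truth, peaks = noisefree["truth"], noisefree["peaks"]
        reps = gene_tss_map(noisefree["reference"])
        for g, t in reps.items():
            got = classify_promoter_state(
                promoter_of(t), peaks["H3K4me3"], peaks["H3K27ac"]
            )
            assert got == truth.genes.loc[g, "promoter_state"]


class TestCallEnhancers:
    def test_promoter_summits_and_unsupported_peaks_excluded(self):
        atac = PeakSet("ATAC", [
            Peak(GenomicInterval("chr1", 900, 1300), 1000),   # summit in promoter
            Peak(GenomicInterval("chr1", 5000, 5400), 5200),  # good
            Peak(GenomicInterval("chr1", 9000, 9400), 9200),  # no K4me1
        ])
        k4me1 = peakset("H3K4me1", [(4900, 5500), (800, 1400)])
        promoters = [GenomicInterval("chr1", 800, 1500)]
        out = call_enhancers(atac, k4me1, promoters)
        assert [e.summit for e in out] == [5200]

    def test_planted_enhancers_all_called_and_outside_promoters(self, noisefree):
        peaks, truth = noisefree["peaks"], noisefree["truth"]
        promoters = [promoter_of(t) for t in gene_tss_map(noisefree["reference"]).values()]
        out = call_enhancers(peaks["ATAC"], peaks["H3K4me1"], promoters)
        assert {(e.interval.chrom, e.summit) for e in out} == {
            (r.chrom, r.summit) for r in truth.enhancers.itertuples()
        }
        for e in out:
            for p in promoters:
                assert not (p.chrom == e.interval.chrom
                            and p.start <= e.summit < p.end)


class TestSignalMatrix:
    def test_constant_coverage_fills_matrix_uniformly(self):
        track = constant_track("m", 2.0)
        sm = build_signal_matrix([region("chr1", 50_000)], {"m": track})
        expect = np.log2(1.0 + 2.0 * track.scale_factor())
        assert np.allclose(sm.matrix, expect)

    def test_chromosome_edge_bins_read_zero(self):
        track = CoverageTrack("m")
        track.add_chrom("chr1", [0], [1000], [4.0])
        sm = build_signal_matrix([region("chr1", 500)], {"m": track}, 6000, 60)
        # bins left of position -2500 and right of 1000 have no coverage
        row = sm.raw[0]
        assert row[:20].sum() == 0.0   # entirely before position 0
        assert row[36:].sum() == 0.0   # entirely after coverage end
        assert row[25:35].sum() > 0

    def test_triangular_peak_is_symmetric_and_center_maximal(self, noisefree):
        truth, tracks = noisefree["truth"], noisefree["tracks"]
        row = truth.enhancers[truth.enhancers.state == "active_high"].iloc[0]
        sm = build_signal_matrix(
            [region(row.chrom, row.summit)], {"H3K27ac": tracks["H3K27ac"]}
        )
        v = sm.matrix[0]
        assert np.argmax(v) in (29, 30)
        assert np.allclose(v, v[::-1], atol=1e-9)

    def test_window_must_divide_into_bins(self):
        with pytest.raises(ValueError, match="divisible"):
            build_signal_matrix([region("chr1", 5000)],
                                {"m": constant_track("m", 1.0)}, 6000, 70)

    def test_aggregate_profile_equals_column_means(self, noisefree):
        tracks, truth = noisefree["tracks"], noisefree["truth"]
        regions = [region(r.chrom, r.summit) for r in truth.enhancers.itertuples()]
        prof = aggregate_profile(regions, tracks["H3K4me1"])
        sm = build_signal_matrix(regions, {"H3K4me1": tracks["H3K4me1"]})
        assert np.allclose(prof, sm.matrix.mean(axis=0))
        one = aggregate_profile(regions[:1], tracks["H3K4me1"])
        assert np.allclose(
            one, build_signal_matrix(regions[:1],
                                     {"H3K4me1": tracks["H3K4me1"]}).matrix[0]
        )

    def test_aggregate_profile_rejects_empty_regions(self, noisefree):
        with pytest.raises(ValueError, match="empty"):
            aggregate_profile([], noisefree["tracks"]["H3K4me1"])


class TestClusterStates:
    def _matrix(self, noisefree):
        truth, tracks = noisefree["truth"], noisefree["tracks"]
        regions = [region(r.chrom, r.summit) for r in truth.enhancers.itertuples()]
        sm = build_signal_matrix(
            regions, {m: tracks[m] for m in ("H3K4me3", "H3K4me1", "H3K27ac")}
        )
        states = [r.state for r in truth.enhancers.itertuples()]
        return sm, states

    def test_planted_states_recovered_with_high_ari(self, noisefree):
        sm, truth_states = self._matrix(noisefree)
        labels = cluster_enhancer_states(sm, seed=1)
        assert adjusted_rand_score(truth_states, labels) >= 0.95
        # renaming follows descending raw K27ac signal by construction
        k27 = sm.raw[:, sm.mark_slice("H3K27ac")].mean(axis=1)
        means = {s: k27[np.array(labels) == s].mean() for s in set(labels)}
        assert means["active_high"] >= means["active_low"] >= means["poised"]

    def test_duplicated_regions_get_identical_labels(self, noisefree):
        sm, _ = self._matrix(noisefree)
        import copy
        dup = copy.deepcopy(sm)
        dup.matrix = np.vstack([sm.matrix, sm.matrix])
        dup.raw = np.vstack([sm.raw, sm.raw])
        dup.regions = sm.regions * 2
        labels = cluster_enhancer_states(dup, seed=2)
        n = len(sm.regions)
        assert labels[:n] == labels[n:]

    def test_identical_rows_still_get_total_deterministic_labels(self):
        track = constant_track("H3K27ac", 1.0)
        regions = [region("chr1", 30_000 + 10_000 * i) for i in range(6)]
        sm = build_signal_matrix(regions, {"H3K27ac": track})
        a = cluster_enhancer_states(sm, seed=5)
        b = cluster_enhancer_states(sm, seed=5)
        assert a == b and len(a) == 6
        assert set(a) <= {"active_high", "active_low", "poised"}

    def test_more_clusters_than_regions_rejected(self, noisefree):
        sm, _ = self._matrix(noisefree)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_enhancer_states(sm, k=len(sm.regions) + 1)


class TestAssignment:
    def test_nearer_gene_wins_and_cap_applies(self, noisefree):
        reference = noisefree["reference"]
        truth = noisefree["truth"]
        enh = [region(r.chrom, r.summit) for r in truth.enhancers.itertuples()]
        out = assign_enhancers_to_genes(enh, reference)
        want = {(r.chrom, r.summit): r.target_gene
                for r in truth.enhancers.itertuples()}
        for e in out:
            assert e.assigned_gene == want[(e.interval.chrom, e.summit)]
        capped = assign_enhancers_to_genes(enh, reference, max_distance=100)
        assert all(e.assigned_gene is None for e in capped)


class TestMotifs:
    def test_single_base_pwm_scan_base_case(self):
        pwm = PWM("A-only", np.array([[0.97, 0.01, 0.01, 0.01]]), threshold=0.0)
        assert not scan_contains("CCCC", pwm)
        assert scan_contains("CACC", pwm)

    def test_scan_matches_naive_both_strand_oracle(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        pwm_p = rng.dirichlet([1.0] * 4, size=8)
        pwm = PWM("rand", pwm_p)

        def naive(seq):
            found = False
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - len(pwm) + 1):
                    score = sum(
                        pwm.logodds[j, "ACGT".index(s[i + j])]
                        for j in range(len(pwm))
                    )
                    if score >= pwm.threshold:
                        found = True
            return found

        for _ in range(40):
            seq = "".join(rng.choice(list(bases), size=200))
            assert scan_contains(seq, pwm) == naive(seq)

    def test_planted_motif_enriched_with_tiny_p(self):
        rng = np.random.default_rng(8)
        motif = "GCCAGCTGTC"
        pwm = PWM("planted", np.array(
            [[0.97 if b == m else 0.01 for b in "ACGT"] for m in motif]
        ))
        def noise(n):
            return "".join(rng.choice(list("ACGT"), size=n))
        fg = [noise(200) + motif + noise(200) for _ in range(30)]
        bg = [noise(410) for _ in range(30)]
        res = differential_motif_enrichment(fg, bg, [pwm])
        row = res.iloc[0]
        assert row.fg_frac == 1.0 and row.bg_frac == 0.0
        assert row.p_fisher < 1e-6 and np.isfinite(row.odds_ratio)

    def test_identical_fg_bg_gives_null(self):
        seqs = ["ACGTACGTAC" * 10] * 5
        pwm = PWM("x", np.full((4, 4), 0.25))
        res = differential_motif_enrichment(seqs, seqs, [pwm])
        assert res.iloc[0].p_fisher == 1.0
        assert res.iloc[0].odds_ratio == pytest.approx(1.0)

    def test_empty_sets_rejected(self):
        pwm = PWM("x", np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            differential_motif_enrichment([], ["ACGT"], [pwm])
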