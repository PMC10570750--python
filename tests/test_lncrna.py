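"""ORF scanning, duplication detection, triage tree, naming scheme."""

import numpy as np
import pytest

from isletomics.annotation import GenomicInterval, TranscriptModel, compare_to_reference, gene_tss_map, promoter_of
from isletomics.epigenome import classify_promoter_state
from isletomics.lncrna import (
    STOPS,
    TriageThresholds,
    assign_names,
    classify_novel_transcript,
    coding_potential,
    detect_duplication,
    longest_orf,
    transcript_sequence,
    NoveltyCall,
)


def brute_force_orf(seq: str) -> int:
    """Enumerate every ATG...stop span in the three forward frames."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        for a in range(len(codons)):
            if codons[a] != "ATG":
                continue
            for b in range(a + 1, len(codons)):
                if "N" in codons[b]:
                    break
                if codons[b] in STOPS:
                    if all("N" not in c for c in codons[a:b]):
                        best = max(best, b - a)
                    break
    return best


class TestOrf:
    @pytest.mark.parametrize(
        "seq,want",
        [
            ("ATGAAATAA", 2),      # ATG AAA then stop
            ("CCCCCC", 0),         # no start codon
            ("ATGAAA", 0),         # never terminated
            ("ATGNNATAA", 0),      # N breaks the frame
        ],
    )
    def test_hand_enumerated_cases(self, seq, want):
        assert longest_orf(seq) == want

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert longest_orf(seq) == brute_force_orf(seq)

    @pytest.mark.parametrize("n_codons,want", [(150, True), (99, False)])
    def test_coding_potential_threshold(self, n_codons, want):
        # an ORF of exactly n codons (the ATG counts) vs the default 100-codon cut
        seq = "ATG" + "GCA" * (n_codons - 1) + "TAA"
        assert coding_potential(seq) is want


class TestDuplication:
    def _refs(self):
        rng = np.random.default_rng(2)
        return {
            f"R{i}": "".join(rng.choice(list("ACGT"), size=800)) for i in range(4)
        }

    def test_exact_copy_found_with_full_identity_and_coverage(self):
        refs = self._refs()
        m = detect_duplication(refs["R2"], refs)
        assert m.reference_id == "R2"
        assert m.identity == 1.0 and m.coverage == pytest.approx(1.0, abs=0.05)

    def test_reversed_sequence_not_matched(self):
        refs = self._refs()
        assert detect_duplication(refs["R1"][::-1], refs) is None

    def test_planted_mutation_rate_reflected_in_identity(self):
        refs = self._refs()
        rng = np.random.default_rng(9)
        seq = list(refs["R0"])
        pos = rng.choice(len(seq), size=40, replace=False)  # 5% of 800
        for p in pos:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        m = detect_duplication("".join(seq), refs)
        assert m.reference_id == "R0"
        assert abs(m.identity - 0.95) <= 0.02

    def test_partial_copy_reported_with_low_coverage(self):
        refs = self._refs()
        rng = np.random.default_rng(3)
        query = refs["R3"][:300] + "".join(rng.choice(list("ACGT"), size=600))
        m = detect_duplication(query, refs)
        assert m.reference_id == "R3"
        assert 0.2 <= m.coverage < 0.5


class TestTriage:
    def test_planted_categories_perfectly_recovered(self, noisefree):
        reference, assembled = noisefree["reference"], noisefree["assembled"]
        genome, truth = noisefree["genome"], noisefree["truth"]
        peaks, table = noisefree["peaks"], noisefree["table"]
        novelty = compare_to_reference(assembled, reference)
        unann = [t for t in assembled if novelty[t.transcript_id] == "unannotated"]
        ref_seqs = {t.transcript_id: transcript_sequence(t, genome)
                    for t in reference}
        mean_tpm = table.tpm.mean(axis=1)
        per_cat = {}
        for t in unann:
            prom = promoter_of(t)
            state = classify_promoter_state(prom, peaks["H3K4me3"],
                                            peaks["H3K27ac"])
            call = classify_novel_transcript(
                t, state, prom, peaks["H3K4me1"], peaks["H3K27ac"],
                float(mean_tpm.get(t.transcript_id, 0.0)),
                reference, ref_seqs, genome,
            )
            want = truth.novels.loc[t.transcript_id, "category"]
            assert call.category == want, (t.transcript_id, call.evidence)
            per_cat[want] = per_cat.get(want, 0) + 1
        # categories partition the unannotated set
        assert sum(per_cat.values()) == len(unann)

    def test_antisense_call_names_its_partner(self, noisefree):
        truth = noisefree["truth"]
        assembled = {t.transcript_id: t for t in noisefree["assembled"]}
        peaks, table = noisefree["peaks"], noisefree["table"]
        anti = truth.novels[truth.novels.category == "lncRNA_antisense"]
        ref_seqs = {t.transcript_id: transcript_sequence(t, noisefree["genome"])
                    for t in noisefree["reference"]}
        for tid, row in anti.iterrows():
            t = assembled[tid]
            prom = promoter_of(t)
            state = classify_promoter_state(prom, peaks["H3K4me3"],
                                            peaks["H3K27ac"])
            call = classify_novel_transcript(
                t, state, prom, peaks["H3K4me1"], peaks["H3K27ac"],
                float(table.tpm.mean(axis=1)[tid]),
                noisefree["reference"], ref_seqs, noisefree["genome"],
            )
            assert call.category == "lncRNA_antisense"
            assert call.evidence["antisense_partner"] == row["partner"]

    def test_missing_genome_chromosome_is_an_error(self, noisefree):
        t = noisefree["assembled"][0]
        bad = TranscriptModel(
            "x", "x", [GenomicInterval("chrZ", 0, 100, "+")]
        )
        with pytest.raises(KeyError, match="chrZ"):
            transcript_sequence(bad, noisefree["genome"])


class TestNaming:
    def _tm(self, tid, start, chrom="chr1"):
        return TranscriptModel(tid, tid,
                               [GenomicInterval(chrom, start, start + 300, "+")])

    def test_antisense_numbering_by_start_coordinate(self):
        calls = [
            NoveltyCall("t2", "lncRNA_antisense",
                        evidence={"antisense_partner": "Abc"}),
            NoveltyCall("t1", "lncRNA_antisense",
                        evidence={"antisense_partner": "Abc"}),
        ]
        tms = {"t1": self._tm("t1", 100), "t2": self._tm("t2", 5000)}
        out = assign_names(calls, tms, {})
        names = {c.transcript_id: c.assigned_name for c in out}
        assert names == {"t1": "Abc-as1", "t2": "Abc-as2"}

    def test_intergenic_numbered_by_descending_expression(self):
        calls = [NoveltyCall(f"t{i}", "lncRNA_intergenic") for i in range(4)]
        tms = {f"t{i}": self._tm(f"t{i}", 1000 * (i + 1)) for i in range(4)}
        tpm = {"t0": 1.0, "t1": 9.0, "t2": 4.0, "t3": 2.0}
        out = assign_names(calls, tms, tpm)
        names = {c.transcript_id: c.assigned_name for c in out}
        assert names == {"t1": "Ri-lnc1", "t2": "Ri-lnc2", "t3": "Ri-lnc3",
                         "t0": "Ri-lnc4"}

    def test_rerun_is_deterministic_and_names_unique(self):
        def build():
            calls = [
                NoveltyCall("a", "lncRNA_intergenic"),
                NoveltyCall("b", "lncRNA_intergenic"),
                NoveltyCall("c", "lncRNA_antisense",
                            evidence={"antisense_partner": "Gene1"}),
                NoveltyCall("d", "unresolved"),
            ]
            tms = {x: self._tm(x, 1000 * i) for i, x in enumerate("abcd", 1)}
            return assign_names(calls, tms, {"a": 2.0, "b": 5.0})
        first = [(c.transcript_id, c.assigned_name) for c in build()]
        second = [(c.transcript_id, c.assigned_name) for c in build()]
        assert first == second
        assert len({n for _, n in first}) == len(first)
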