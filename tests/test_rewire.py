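"""miRNA-target rewiring: windows, duplex scoring, change classification."""

import numpy as np
import pytest

from _utils import oracle_best_score, oracle_full_score, rc
from editscan.annotate import revcomp
from editscan.formats import GeneModel, GenomicInterval, Transcript
from editscan.rewire import (DuplexHit, DuplexParams, TargetWindow,
                             best_alignment, build_windows,
                             call_mirna_consequence,
                             classify_regulation_change, duplex_free_energy,
                             score_duplex)

PARAMS = DuplexParams()


def _hit(mirna, dg):
    return DuplexHit(mirna=mirna, score=150.0, dg=dg, window_start=0,
                     window_end=20)


def _utr3_gene(seq, strand="+", chrom="chr1"):
    genomic = seq if strand == "+" else rc(seq)
    genome = {chrom: genomic}
    iv = GenomicInterval(chrom, 0, len(genomic), strand)
    tx = Transcript(transcript_id="t", strand=strand, exons=[iv], utr3=[iv])
    gene = GeneModel(gene_id="g", gene_name="g", gene_type="protein_coding",
                     chrom=chrom, strand=strand, transcripts=[tx])
    return gene, genome


class TestWindows:
    def test_truncation_near_transcript_end(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pos = 200 - 31  # 30 bases of 3' flank available
        seq = seq[:pos] + "A" + seq[pos + 1:]
        gene, genome = _utr3_gene(seq)
        (w,) = build_windows("s", pos, "A", "G", gene, genome)
        assert len(w.ref_seq) == 50 + 1 + 30
        assert w.edited_seq[w.center] == "G"
        assert w.ref_seq[w.center] == "A"

    def test_minus_strand_genomic_t_to_c_becomes_transcript_a_to_g(self):
        rng = np.random.default_rng(3)
        sense = "".join(rng.choice(list("ACGT"), size=200))
        sense = sense[:100] + "A" + sense[101:]
        gene, genome = _utr3_gene(sense, strand="-")
        genomic_pos = len(sense) - 1 - 100  # sense index 100 on the - strand
        assert genome["chr1"][genomic_pos] == "T"
        (w,) = build_windows("s", genomic_pos, "T", "C", gene, genome)
        assert w.ref_seq[w.center] == "A"
        assert w.edited_seq[w.center] == "G"
        # reverse-complement oracle: the window is a slice of the sense sequence
        assert w.ref_seq == sense[100 - 50:100 + 51]

    def test_window_invariant_rejects_multi_base_difference(self):
        with pytest.raises(ValueError):
            TargetWindow("s", "t", "ACGT", "AGGA", 1)


class TestDuplexScoring:
    def test_perfect_22mer_complement_is_a_hit(self):
        rng = np.random.default_rng(5)
        win = "".join(rng.choice(list("ACGT"), p=[.2, .3, .3, .2], size=80))
        mir = revcomp(win[30:52])
        hit = score_duplex(mir, win, PARAMS)
        assert hit is not None
        assert hit.score > 140 and hit.dg < -14
        # raw score of a perfect 22-mer: 7 seed pairs doubled + 15 plain
        assert best_alignment(mir, win, PARAMS)[0] == pytest.approx(
            7 * 10 + 15 * 5)

    def test_poly_a_window_has_no_hit(self):
        assert score_duplex("ACGUACGUACGUACGUACGUAC".replace("U", "T"),
                            "A" * 101, PARAMS) is None

    def test_seed_mismatch_scores_below_perfect(self):
        rng = np.random.default_rng(6)
        win = "".join(rng.choice(list("ACGT"), p=[.2, .3, .3, .2], size=60))
        mir = revcomp(win[20:42])
        perfect, _ = best_alignment(mir, win, PARAMS)
        # corrupt miRNA position 5 (seed): replace with a non-pairing base
        target_base = win[20:42][::-1][4]
        for b in "ACGT":
            if b != mir[4] and (b, target_base) not in (("A", "T"), ("T", "A"),
                                                        ("C", "G"), ("G", "C"),
                                                        ("G", "T"), ("T", "G")):
                broken = mir[:4] + b + mir[5:]
                break
        degraded, _ = best_alignment(broken, win, PARAMS)
        assert degraded < perfect

    def test_short_mirna_is_an_error(self):
        with pytest.raises(ValueError, match="shorter"):
            score_duplex("ACGTACGTACGT", "A" * 50, PARAMS)

    def test_dp_equals_exhaustive_oracle_on_short_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = int(rng.integers(15, 23))
            n = int(rng.integers(18, 31))
            mir = "".join(rng.choice(list("ACGT"), size=m))
            win = "".join(rng.choice(list("ACGT"), size=n))
            got, _ = best_alignment(mir, win, PARAMS)
            assert got == pytest.approx(oracle_full_score(mir, win, PARAMS))
            # the restricted enumeration (ungapped + one gap) is a lower bound
            assert got >= oracle_best_score(mir, win, PARAMS) - 1e-9

    def test_dp_equals_oracle_on_near_complementary_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            win = "".join(rng.choice(list("ACGT"), size=30))
            mir = list(revcomp(win[4:26]))
            for k in rng.choice(22, size=2, replace=False):
                mir[k] = rng.choice(list("ACGT"))
            mir = "".join(mir)
            got, _ = best_alignment(mir, win, PARAMS)
            assert got == pytest.approx(oracle_full_score(mir, win, PARAMS))

    def test_free_energy_of_perfect_duplex_is_strongly_negative(self):
        win = "GCGCGCAUAUGCGCGCAUAU".replace("U", "T")
        mir = revcomp(win)
        pairs = [(i, i) for i in range(len(win))]
        dg = duplex_free_energy(win, mir, pairs)
        assert dg < -20
        # unpaired duplex: only the initiation penalty
        assert duplex_free_energy(win, mir, []) == 0.0


class TestClassification:
    def test_identity_edit_yields_zero_changes(self):
        hits = {"m1": _hit("m1", -20.0), "m2": _hit("m2", -18.0)}
        assert classify_regulation_change("s", hits, dict(hits)) == []

    def test_gain_loss_and_change_thresholds(self):
        ref = {"lost": _hit("lost", -20.0), "kept": _hit("kept", -16.0),
               "moved": _hit("moved", -16.0)}
        edited = {"gained": _hit("gained", -25.0), "kept": _hit("kept", -17.0),
                  "moved": _hit("moved", -31.0)}
        changes = {c.mirna: c for c in
                   classify_regulation_change("s", ref, edited)}
        assert changes["lost"].kind == "edited_loss"
        assert changes["gained"].kind == "edited_gain"
        assert changes["moved"].kind == "edited_change"
        assert changes["moved"].ddg == pytest.approx(-15.0)
        assert "kept" not in changes  # |ddG| = 1 below threshold

    def test_ddg_exactly_fourteen_is_not_a_change(self):
        ref = {"m": _hit("m", -16.0)}
        edited = {"m": _hit("m", -30.0)}  # |ddG| = 14, strict threshold
        assert classify_regulation_change("s", ref, edited) == []

    def test_swap_symmetry(self):
        ref = {"a": _hit("a", -20.0)}
        edited = {"b": _hit("b", -20.0)}
        fwd = {c.mirna: c.kind for c in classify_regulation_change("s", ref, edited)}
        rev = {c.mirna: c.kind for c in classify_regulation_change("s", edited, ref)}
        assert fwd == {"a": "edited_loss", "b": "edited_gain"}
        assert rev == {"a": "edited_gain", "b": "edited_loss"}

    @pytest.mark.parametrize("n,flag", [(11, True), (10, False), (0, False)])
    def test_consequence_needs_more_than_ten_changes(self, n, flag):
        from editscan.rewire import RegulationChange

        changes = [RegulationChange("s", f"m{i}", "edited_gain") for i in range(n)]
        assert call_mirna_consequence(changes) is flag


class TestPlantedRecovery:
    def test_planted_mirna_rewiring_events_are_recovered(self, default_cohort,
                                                         default_result):
        truth = default_cohort.truth_mirna
        got = {(r.site_id, r.mirna): r.kind
               for r in default_result.rewiring.itertuples(index=False)}
        for r in truth.itertuples(index=False):
            assert got.get((r.site_id, r.mirna)) == r.expected_kind
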