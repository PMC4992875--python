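"""Trimming, merging, quality filtering, primer trimming, headers."""

import pytest

from coralith.errors import InputError
from coralith.markers import MarkerSpec, revcomp
from coralith.readprep import (QCParams, Rejection, format_header,
                               global_primer_trim, mean_quality_filter,
                               merge_pair, prepare_marker_reads,
                               trim_three_prime)
from coralith.records import MergedRead, SequenceRead
from coralith.simulate import CommunityProfile, SimConfig, simulate_sample_reads
from coralith.demux import demultiplex_sample, strip_readthrough


def mkread(bases, quals=None, mate="forward"):
    quals = quals if quals is not None else (38,) * len(bases)
    return SequenceRead(read_id="r", bases=bases, quals=tuple(quals), mate=mate)


def mkmerged(bases, quals=None):
    quals = quals if quals is not None else (38,) * len(bases)
    return MergedRead(bases=bases, quals=tuple(quals))


class TestTrim:
    def test_zero_is_identity(self):
        r = mkread("ACGT" * 20)
        assert trim_three_prime(r, 0) is r

    def test_arithmetic(self):
        r = mkread("A" * 300)
        out = trim_three_prime(r, 50)
        assert len(out.bases) == 250 and len(out.quals) == 250

    def test_floor_rule_drops_short_reads(self):
        assert trim_three_prime(mkread("A" * 70), 50) is None
        assert trim_three_prime(mkread("A" * 80), 50) is not None


class TestMerge:
    PARAMS = QCParams(min_overlap=8, max_overlap_mismatch_ratio=0.25)

    def test_clean_overlap_brute_force_case(self):
        r1 = mkread("AAAATTTTGGGG")
        r2 = mkread(revcomp("TTTTGGGGCCCC"), mate="reverse")
        merged = merge_pair(r1, r2, self.PARAMS)
        assert merged.bases == "AAAATTTTGGGGCCCC"

    def test_identical_fully_overlapping_mates(self):
        seq = "ACGTACGTACGTACGT"
        merged = merge_pair(mkread(seq), mkread(revcomp(seq), mate="reverse"),
                            QCParams(min_overlap=8))
        assert merged.bases == seq

    def test_mismatch_ratio_rejection(self):
        # overlap of 8 with 3 planted disagreements: ratio 0.375 > 0.25
        left = "AAAACCCC" + "ACGTACGT"
        right_true = "ACGTACGT" + "GGGGTTTT"
        mutated = "AATTACGT" + "GGGGTTTT"  # 3 mism. in the 8-base overlap
        mutated = "ACATAGCT" + "GGGGTTTT"
        r1 = mkread(left)
        r2 = mkread(revcomp(mutated), mate="reverse")
        out = merge_pair(r1, r2, QCParams(min_overlap=8,
                                          max_overlap_mismatch_ratio=0.25))
        assert isinstance(out, Rejection)

    def test_consensus_prefers_higher_quality_base(self):
        r1 = mkread("AAAAAAAA", quals=[40] * 4 + [10] * 4)
        r2_seq = "AAAACCCC"  # disagrees on the last 4 positions
        r2 = mkread(revcomp(r2_seq), quals=[40] * 8, mate="reverse")
        merged = merge_pair(r1, r2, QCParams(min_overlap=8,
                                             max_overlap_mismatch_ratio=0.6))
        assert merged.bases == "AAAACCCC"
        assert merged.quals[0] == 40          # agreement: max
        assert merged.quals[-1] == 30         # disagreement: |40 - 10|

    def test_no_admissible_overlap(self):
        out = merge_pair(mkread("ACGT"), mkread("ACGT", mate="reverse"),
                         QCParams(min_overlap=8))
        assert isinstance(out, Rejection) and out.reason == "no_overlap"


class TestQualityFilter:
    def test_threshold_boundary_inclusive(self):
        assert mean_quality_filter(mkmerged("A" * 10, [35] * 10), 35) is True
        assert mean_quality_filter(mkmerged("A" * 10, [34] * 10), 35) is False

    def test_mean_arithmetic(self):
        m = mkmerged("A" * 110, [40] * 100 + [20] * 10)
        assert m.mean_quality == pytest.approx(38.18, abs=0.01)
        assert mean_quality_filter(m, 35) is True


@pytest.fixture(scope="module")
def toy_spec():
    return MarkerSpec("toy", "ACGTACGTACGTACG", "TGCATGCATGCATGC",
                      min_merged_length=100, amplicon_length=240)


class TestGlobalPrimerTrim:
    def _merged(self, spec, core_len=180, spacer="GG", tail_spacer="A"):
        core = ("ACGT" * 60)[:core_len]
        bases = spacer + spec.fwd_primer + core + revcomp(spec.rev_primer) + tail_spacer
        return mkmerged(bases), core

    def test_core_retained(self, toy_spec):
        m, core = self._merged(toy_spec)
        out = global_primer_trim(m, toy_spec)
        assert out.bases == core
        assert len(out.quals) == len(core)

    def test_missing_three_prime_primer_rejected(self, toy_spec):
        m = mkmerged("GG" + toy_spec.fwd_primer + "ACGT" * 50)
        out = global_primer_trim(m, toy_spec)
        assert isinstance(out, Rejection) and out.reason == "missing_primer"

    def test_short_core_rejected(self, toy_spec):
        m, _ = self._merged(toy_spec, core_len=80)
        out = global_primer_trim(m, toy_spec)
        assert isinstance(out, Rejection) and out.reason == "short_after_trim"


class TestHeaders:
    def test_format_literal(self):
        assert format_header(mkmerged("ACGT"), "S01", "RUN1", 7) == "S01.RUN1_7"

    def test_serial_must_be_positive(self):
        with pytest.raises(InputError):
            format_header(mkmerged("ACGT"), "S01", "RUN1", 0)

    def test_delimiter_guard(self):
        with pytest.raises(InputError):
            format_header(mkmerged("ACGT"), "S.01", "RUN1", 1)
        with pytest.raises(InputError):
            format_header(mkmerged("ACGT"), "S01", "RUN_1", 1)


class TestPipelineProperties:
    def _prepped(self, refs, panel, threshold=35.0, n=120):
        profile = CommunityProfile(
            "S01", False, {t.taxon_id: 1 / len(refs) for t in refs})
        cfg = SimConfig(seed=21, reads_per_sample=n, chimera_fraction=0.0,
                        substitution_rate_per_base=0.0, quality_errors=False)
        pairs, truth = simulate_sample_reads(profile, refs, panel, cfg)
        stripped = [(strip_readthrough(a, panel), strip_readthrough(b, panel))
                    for a, b in pairs]
        demuxed = demultiplex_sample(stripped, panel)
        params = QCParams(mean_quality_threshold=threshold)
        out = {}
        for spec in panel:
            out[spec.name] = prepare_marker_reads(
                demuxed.assigned[spec.name], spec, params)
        return out, truth

    def test_noise_free_round_trip_zero_rejections(self, small_refs, panel):
        """Noise-free synthetic reads survive all steps and rebuild templates."""
        prepped, truth = self._prepped(small_refs, panel)
        by_id = {t.taxon_id: t for t in small_refs}
        for spec in panel:
            records, counts = prepped[spec.name]
            assert counts.balanced
            assert counts.dropped_trim == 0 and not counts.rejected
            primer_len = len(spec.fwd_primer) + len(spec.rev_primer)
            for header, merged in records:
                # the trimmed core is the template minus its primers
                cores = {
                    t.marker_seqs[spec.name][len(spec.fwd_primer):
                                             -len(spec.rev_primer)]
                    for t in small_refs
                }
                assert merged.bases in cores

    def test_conservation_ledger(self, small_refs, panel):
        prepped, _ = self._prepped(small_refs, panel)
        for spec in panel:
            _, counts = prepped[spec.name]
            assert counts.balanced

    def test_quality_threshold_monotone(self, small_refs, panel):
        kept = []
        for thr in (41, 38, 35, 20, 0):
            prepped, _ = self._prepped(small_refs, panel, threshold=thr, n=60)
            kept.append(sum(c.merged_kept for _, c in prepped.values()))
        assert kept == sorted(kept)
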