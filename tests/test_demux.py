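"""Read-through stripping and primer-based marker demultiplexing."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from coralith.demux import (demultiplex_sample, match_primer,
                            readthrough_pattern, strip_readthrough)
from coralith.errors import ConfigError
from coralith.markers import IUPAC, MarkerSpec
from coralith.records import SequenceRead
from coralith.simulate import CommunityProfile, SimConfig, simulate_sample_reads

from oracles import oracle_primer_scan


def mkread(bases, mate="forward", rid="r1"):
    return SequenceRead(read_id=rid, bases=bases, quals=(30,) * len(bases),
                        mate=mate)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestStripReadthrough:
    def test_planted_signature_truncates_at_match_start(self, panel):
        rng = random.Random(1)
        spec = panel[0]
        pattern = readthrough_pattern(spec, "forward").pattern
        bases = random_dna(rng, 120) + pattern + random_dna(rng, 30)
        out = strip_readthrough(mkread(bases), [spec])
        assert len(out.bases) == 120
        assert out.bases == bases[:120]
        assert len(out.quals) == 120

    def test_no_signature_is_identity(self, panel):
        rng = random.Random(2)
        read = mkread(random_dna(rng, 200))
        assert strip_readthrough(read, panel).bases == read.bases

    def test_match_before_guard_position_ignored(self, panel):
        rng = random.Random(3)
        spec = panel[0]
        pattern = readthrough_pattern(spec, "forward").pattern
        bases = random_dna(rng, 10) + pattern + random_dna(rng, 100)
        out = strip_readthrough(mkread(bases), [spec])
        assert out.bases == bases  # guard region: unchanged

    def test_partial_signature_at_read_end(self, panel):
        """A 3'-truncated signature (short amplicon) still triggers."""
        rng = random.Random(4)
        spec = panel[0]
        pattern = readthrough_pattern(spec, "forward").pattern
        bases = random_dna(rng, 270) + pattern  # read ends inside the pattern
        out = strip_readthrough(mkread(bases[:300]), [spec])
        assert len(out.bases) == 270


class TestMatchPrimer:
    def test_exact_match_after_spacer(self, panel):
        primer = panel[0].fwd_primer
        ok, spacer, mm = match_primer("GG" + primer + "ACGTACGT", primer, 3, 0)
        assert (ok, spacer, mm) == (True, 2, 0)

    def test_iupac_expansion_matches(self):
        ok, spacer, mm = match_primer("ACGTGAACGTACGTAC" + "A" * 10,
                                      "ACGTRAACGTACGTAC", 3, 0)
        assert (ok, spacer, mm) == (True, 0, 0)

    def test_single_mismatch_tolerance(self, panel):
        primer = panel[0].fwd_primer
        mutated = "C" + primer[1:] if primer[0] != "C" else "A" + primer[1:]
        bases = mutated + "ACGTACGT"
        assert match_primer(bases, primer, 3, 0)[0] is False
        ok, spacer, mm = match_primer(bases, primer, 3, 1)
        assert (ok, mm) == (True, 1)

    def test_too_short_read_no_match(self, panel):
        primer = panel[0].fwd_primer
        assert match_primer(primer[:10], primer, 3, 2)[0] is False

    @settings(max_examples=120, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), spacer=st.integers(0, 3),
           n_mut=st.integers(0, 3), max_mm=st.integers(0, 2))
    def test_agrees_with_enumeration_oracle(self, seed, spacer, n_mut, max_mm):
        rng = random.Random(seed)
        primer = "GTGYCAGCMGCCGCGGTAA"
        concrete = "".join(rng.choice(sorted(IUPAC[c])) for c in primer)
        bases = list(random_dna(rng, spacer) + concrete + random_dna(rng, 20))
        for _ in range(n_mut):
            pos = rng.randrange(spacer, spacer + len(primer))
            bases[pos] = rng.choice("ACGT")
        bases = "".join(bases)
        got = match_primer(bases, primer, 3, max_mm)
        want = oracle_primer_scan(bases, primer, 3, max_mm, IUPAC)
        assert got == want


class TestDemultiplex:
    def _noise_free_pairs(self, refs, panel, n=100):
        profile = CommunityProfile(
            "S01", False, {t.taxon_id: 1 / len(refs) for t in refs})
        cfg = SimConfig(seed=11, reads_per_sample=n, chimera_fraction=0.0,
                        substitution_rate_per_base=0.0, quality_errors=False)
        return simulate_sample_reads(profile, refs, panel, cfg)

    def test_noise_free_recovers_ground_truth_markers(self, small_refs, panel):
        pairs, truth = self._noise_free_pairs(small_refs, panel)
        stripped = [(strip_readthrough(a, panel), strip_readthrough(b, panel))
                    for a, b in pairs]
        result = demultiplex_sample(stripped, panel)
        assert not result.unassigned
        for marker, assigned in result.assigned.items():
            for r1, _ in assigned:
                assert truth.read_truth[r1.read_id][1] == marker

    def test_partition_conservation(self, small_refs, panel):
        pairs, _ = self._noise_free_pairs(small_refs, panel, n=60)
        result = demultiplex_sample(pairs, panel)
        assert result.total == 60

    def test_conflicting_mates_go_unassigned(self, panel):
        s16, s18 = panel[0], panel[1]
        r1 = mkread(s16.fwd_primer + "ACGT" * 30)
        r2 = mkread(s18.rev_primer + "ACGT" * 30, mate="reverse")
        result = demultiplex_sample([(r1, r2)], panel)
        assert result.unassigned == [(r1, r2)]

    def test_planted_primer_mutations_unassigned(self, small_refs, panel):
        """Pairs whose fwd primer carries 3 substitutions exceed max_mm=2."""
        pairs, truth = self._noise_free_pairs(small_refs, panel, n=30)
        specs_by_name = {s.name: s for s in panel}
        broken_ids = set()
        out_pairs = []
        for i, (r1, r2) in enumerate(pairs):
            if i < 3:
                spec = specs_by_name[truth.read_truth[r1.read_id][1]]
                ok, spacer, _ = match_primer(r1.bases, spec.fwd_primer, 3, 2)
                assert ok
                b = list(r1.bases)
                # substitute at 3 non-degenerate primer positions
                flipped = 0
                for k, code in enumerate(spec.fwd_primer):
                    if flipped == 3:
                        break
                    if code in "ACGT":
                        b[spacer + k] = {"A": "C", "C": "G",
                                         "G": "T", "T": "A"}[code]
                        flipped += 1
                assert flipped == 3
                r1 = SequenceRead(r1.read_id, "".join(b), r1.quals, r1.mate,
                                  r1.sample_id, r1.run_id)
                broken_ids.add(r1.read_id)
            out_pairs.append((r1, r2))
        result = demultiplex_sample(out_pairs, panel)
        got = {r1.read_id for r1, _ in result.unassigned}
        assert got == broken_ids

    def test_raising_mismatch_budget_is_monotone(self, small_refs, panel):
        pairs, _ = self._noise_free_pairs(small_refs, panel, n=80)
        # mutate every read a little
        rng = random.Random(9)
        noisy = []
        for r1, r2 in pairs:
            b = list(r1.bases)
            for _ in range(2):
                pos = rng.randrange(0, 20)
                b[pos] = rng.choice("ACGT")
            noisy.append((SequenceRead(r1.read_id, "".join(b), r1.quals,
                                       r1.mate, r1.sample_id, r1.run_id), r2))
        counts = []
        for mm in (0, 1, 2, 3):
            specs = [s.with_(max_primer_mismatches=mm) for s in panel]
            result = demultiplex_sample(noisy, specs)
            counts.append(len(noisy) - len(result.unassigned))
        assert counts == sorted(counts)

    def test_indistinguishable_panel_rejected(self):
        a = MarkerSpec("A", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT")
        b = MarkerSpec("B", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT")
        with pytest.raises(ConfigError):
            demultiplex_sample([], [a, b])
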