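"""Candidate calling, the five-filter cascade, and strand/type resolution."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from editome.config import DetectionConfig
from editome import detection
from editome.detection import (
    DataIntegrityError,
    call_candidates,
    filter_genomic_snps,
    filter_homopolymer,
    filter_multimap,
    filter_read_end,
    filter_splice_proximal,
    homopolymer_run_length,
    resolve_strand_and_type,
    second_best_identity,
    select_editing_sites,
    type_percentages,
)
from editome.io_formats import GeneModel, ReferenceBundle, revcomp


def make_evidence(*groups):
    """Each group: (pos, ref, list of (base, qual, off5), strand)."""
    rows = []
    read = itertools.count()
    for pos, ref, reads, strand in groups:
        for base, qual, off5 in reads:
            rows.append(
                {
                    "chrom": "c1", "pos": pos, "ref_base": ref,
                    "sample_id": "s1", "read_id": f"r{next(read)}",
                    "base": base, "qual": qual, "off5": off5,
                    "off3": 151 - off5, "strand": strand,
                }
            )
    return pd.DataFrame(rows)


def bundle_with(seq, models=(), **kwargs):
    return ReferenceBundle(sequences={"c1": seq}, gene_models=list(models), **kwargs)


CFG = DetectionConfig()


class TestCallCandidates:
    def _genome(self):
        return "C" * 50 + "A" + "C" * 49  # A at position 50

    def test_two_alleles_with_enough_alt_reads_is_a_candidate(self):
        ev = make_evidence((50, "A", [("A", 30, 40)] * 12 + [("G", 30, 40)] * 4, "+"))
        calls = call_candidates(ev, bundle_with(self._genome()), CFG)
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref_base, c.alt_base, c.n_ref, c.n_alt) == ("A", "G", 12, 4)

    def test_fewer_than_three_alt_reads_is_not_called(self):
        ev = make_evidence((50, "A", [("A", 30, 40)] * 12 + [("G", 30, 40)] * 2, "+"))
        assert call_candidates(ev, bundle_with(self._genome()), CFG) == []

    def test_three_allele_types_are_rejected(self):
        ev = make_evidence(
            (50, "A", [("A", 30, 40)] * 10 + [("G", 30, 40)] * 3 + [("C", 30, 40)] * 3, "+")
        )
        assert call_candidates(ev, bundle_with(self._genome()), CFG) == []

    def test_low_quality_reads_are_invisible(self):
        # the three C reads fall below the quality cut, leaving two clean alleles
        ev = make_evidence(
            (50, "A", [("A", 30, 40)] * 10 + [("G", 30, 40)] * 3 + [("C", 20, 40)] * 3, "+")
        )
        calls = call_candidates(ev, bundle_with(self._genome()), CFG)
        assert len(calls) == 1 and calls[0].n_alt == 3

    def test_reference_disagreement_is_a_data_integrity_error(self):
        ev = make_evidence((50, "C", [("C", 30, 40)] * 10 + [("T", 30, 40)] * 4, "+"))
        with pytest.raises(DataIntegrityError):
            call_candidates(ev, bundle_with(self._genome()), CFG)

    def test_counts_are_pooled_across_samples(self):
        ev = make_evidence((50, "A", [("A", 30, 40)] * 6 + [("G", 30, 40)] * 2, "+"))
        ev2 = ev.copy()
        ev2["sample_id"] = "s2"
        ev2["read_id"] = ev2["read_id"] + "b"
        calls = call_candidates(pd.concat([ev, ev2]), bundle_with(self._genome()), CFG)
        assert len(calls) == 1 and calls[0].n_alt == 4
        assert calls[0].sample_counts == {"s1": (6, 2), "s2": (6, 2)}


def _call(pos, ref="A", alt="G"):
    return detection.VariantCall("c1", pos, ref, alt, 10, 5, {"s1": (10, 5)})


class TestGenomicSnpFilter:
    def test_wgs_and_dbsnp_positions_are_flagged(self):
        b = bundle_with(
            "A" * 100,
            wgs_genotypes={("c1", 10): "het", ("c1", 20): "hom_alt"},
            known_snps={("c1", 30)},
        )
        calls = [_call(10), _call(20), _call(30), _call(40)]
        filter_genomic_snps(calls, b)
        assert calls[0].flags == {"wgs_snp"}
        assert calls[1].flags == {"wgs_snp"}
        assert calls[2].flags == {"known_snp"}
        assert calls[3].flags == set()


class TestSpliceProximalFilter:
    GENE = GeneModel("g", "t", "c1", "+", exons=[(0, 20), (30, 50)], biotype="lincRNA")

    @pytest.mark.parametrize(
        "pos,flagged",
        [
            (21, True),   # 2 bp into the intron
            (23, True),   # 4 bp: boundary of the window
            (24, False),  # 5 bp: just outside
            (19, False),  # exonic, 1 bp from the junction: out of scope
            (60, False),  # intergenic
        ],
    )
    def test_window_applies_to_intronic_sites_only(self, pos, flagged):
        calls = [_call(pos)]
        filter_splice_proximal(calls, [self.GENE], CFG)
        assert ("splice_proximal" in calls[0].flags) is flagged


class TestHomopolymerFilter:
    @pytest.mark.parametrize(
        "seq,pos,flagged",
        [
            ("CCAAAAACC", 4, True),   # inside a run of 5
            ("CCAAAACCC", 4, False),  # run of 4
            ("AAAAAACCC", 0, True),   # first base of a run of 6
        ],
    )
    def test_maximal_run_rule(self, seq, pos, flagged):
        calls = [_call(pos)]
        filter_homopolymer(calls, {"c1": seq}, CFG)
        assert ("homopolymer" in calls[0].flags) is flagged

    def test_run_length_matches_a_naive_scan_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AACG"), 300))

        def naive(s, i):
            run = [j for j in range(len(s)) if s[j] == s[i]]
            lo = i
            while lo > 0 and s[lo - 1] == s[i]:
                lo -= 1
            hi = i
            while hi < len(s) - 1 and s[hi + 1] == s[i]:
                hi += 1
            return hi - lo + 1

        for pos in range(0, 300, 7):
            assert homopolymer_run_length(seq, pos) == naive(seq, pos)


class TestReadEndFilter:
    def test_alt_reads_near_either_end_are_discarded(self):
        ev = make_evidence(
            (50, "A",
             [("A", 30, 40)] * 10 + [("G", 30, 3), ("G", 30, 146), ("G", 30, 40)],
             "+")
        )
        calls = [_call(50)]
        filter_read_end(calls, ev, CFG)
        assert calls[0].n_alt_internal == 1
        assert "read_end" in calls[0].flags

    def test_internal_alt_reads_survive(self):
        ev = make_evidence((50, "A", [("A", 30, 40)] * 10 + [("G", 30, 40)] * 3, "+"))
        calls = [_call(50)]
        filter_read_end(calls, ev, CFG)
        assert calls[0].n_alt_internal == 3 and not calls[0].flags

    def test_zero_margin_makes_the_filter_a_noop(self):
        ev = make_evidence((50, "A", [("G", 30, 1), ("G", 30, 150), ("G", 30, 2)], "+"))
        calls = [_call(50)]
        filter_read_end(calls, ev, DetectionConfig(read_end_margin=0))
        assert calls[0].n_alt_internal == 3 and not calls[0].flags


class TestMultimapFilter:
    def _genome_with_duplicate(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        part = lambda n: "".join(rng.choice(bases, n))  # noqa: E731
        segment = part(80)
        return part(150) + segment + part(150) + segment + part(100)

    def test_call_inside_a_duplicated_segment_is_flagged(self):
        seq = self._genome_with_duplicate()
        calls = [_call(190, ref=seq[190])]
        filter_multimap(calls, {"c1": seq}, CFG)
        assert "multimap" in calls[0].flags

    def test_call_in_unique_sequence_is_unflagged(self):
        seq = self._genome_with_duplicate()
        calls = [_call(50, ref=seq[50])]
        filter_multimap(calls, {"c1": seq}, CFG)
        assert not calls[0].flags

    def test_ratio_one_without_an_exact_duplicate_is_unflagged(self):
        seq = self._genome_with_duplicate()
        # perturb the second copy at the base mirroring the call position
        # (190 in copy A maps to 420 in copy B) so no window matches exactly
        seq = seq[:420] + ("A" if seq[420] != "A" else "C") + seq[421:]
        calls = [_call(190, ref=seq[190])]
        filter_multimap(calls, {"c1": seq}, DetectionConfig(multimap_score_ratio=1.0))
        assert not calls[0].flags

    def test_identity_agrees_with_a_sliding_window_oracle(self):
        """Brute-force best off-locus hamming identity never exceeds the
        (indel-aware) alignment identity, and both sides of the 0.95
        threshold agree on the constructed cases."""
        seq = self._genome_with_duplicate()

        def brute(pos, flank=25):
            s, e = max(0, pos - flank), min(len(seq), pos + flank + 1)
            w = seq[s:e]
            masked = seq[:s] + "N" * (e - s) + seq[e:]
            best = 0.0
            for target in (masked, revcomp(masked)):
                for i in range(len(target) - len(w) + 1):
                    hits = sum(a == b for a, b in zip(w, target[i : i + len(w)]))
                    best = max(best, hits / len(w))
            return best

        for pos in (50, 190, 310):
            ours = second_best_identity({"c1": seq}, "c1", pos, 25)
            oracle = brute(pos)
            assert ours >= oracle - 1e-9
            assert (ours >= 0.95) == (oracle >= 0.95)


class TestStrandAndType:
    PLUS = GeneModel("gp", "gp.t", "c1", "+", exons=[(0, 100)], biotype="lincRNA")
    MINUS = GeneModel("gm", "gm.t", "c1", "-", exons=[(200, 300)], biotype="lincRNA")

    def test_minus_strand_t_to_c_is_a_to_g(self):
        calls = [detection.VariantCall("c1", 250, "T", "C", 10, 5, {})]
        resolve_strand_and_type(calls, [self.PLUS, self.MINUS], make_evidence())
        assert calls[0].strand == "-" and calls[0].mismatch_type == "A-to-G"

    def test_plus_strand_a_to_g_stays_a_to_g(self):
        calls = [detection.VariantCall("c1", 50, "A", "G", 10, 5, {})]
        resolve_strand_and_type(calls, [self.PLUS, self.MINUS], make_evidence())
        assert calls[0].strand == "+" and calls[0].mismatch_type == "A-to-G"

    def test_opposite_overlapping_genes_leave_strand_unknown(self):
        both = [
            self.PLUS,
            GeneModel("go", "go.t", "c1", "-", exons=[(0, 100)], biotype="lincRNA"),
        ]
        calls = [detection.VariantCall("c1", 50, "A", "G", 10, 5, {})]
        resolve_strand_and_type(calls, both, make_evidence())
        assert calls[0].strand is None and calls[0].mismatch_type is None

    def test_intergenic_strand_comes_from_majority_library_strand(self):
        ev = make_evidence(
            (150, "T", [("T", 30, 40)] * 3 + [("C", 30, 40)] * 3, "-"),
        )
        calls = [detection.VariantCall("c1", 150, "T", "C", 3, 3, {})]
        resolve_strand_and_type(calls, [self.PLUS, self.MINUS], ev)
        assert calls[0].strand == "-" and calls[0].mismatch_type == "A-to-G"

    def test_tied_library_strands_leave_strand_unknown(self):
        ev = make_evidence(
            (150, "T", [("T", 30, 40)] * 2, "-"),
            (150, "T", [("C", 30, 40)] * 2, "+"),
        )
        calls = [detection.VariantCall("c1", 150, "T", "C", 2, 2, {})]
        resolve_strand_and_type(calls, [self.PLUS, self.MINUS], ev)
        assert calls[0].strand is None


class TestSelection:
    def test_single_a_to_g_call_gives_100_percent(self):
        c = detection.VariantCall("c1", 5, "A", "G", 10, 5, {})
        c.strand, c.mismatch_type = "+", "A-to-G"
        sites, counts, pct = select_editing_sites([c])
        assert counts == {"A-to-G": 1} and pct == {"A-to-G": 100.0}
        assert len(sites) == 1

    def test_type_tally_conserves_strand_resolved_calls(self, tiny_calls):
        calls, _ = tiny_calls
        _, counts, _ = select_editing_sites(calls)
        surviving_typed = sum(
            1 for c in calls if not c.flags and c.mismatch_type is not None
        )
        assert sum(counts.values()) == surviving_typed

    def test_zero_surviving_calls_warn_and_return_empty(self):
        c = _call(5)
        c.flags.add("wgs_snp")
        with pytest.warns(UserWarning, match="no calls survived"):
            sites, counts, pct = select_editing_sites([c])
        assert sites == [] and counts == {} and pct == {}


class TestCascadeProperties:
    def test_filters_commute(self, tiny_bundle, tiny_evidence):
        cfg = DetectionConfig()
        filters = [
            lambda cs: filter_genomic_snps(cs, tiny_bundle),
            lambda cs: filter_splice_proximal(cs, tiny_bundle.gene_models, cfg),
            lambda cs: filter_homopolymer(cs, tiny_bundle.sequences, cfg),
            lambda cs: filter_read_end(cs, tiny_evidence, cfg),
        ]
        results = []
        for order in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]):
            calls = call_candidates(tiny_evidence, tiny_bundle, cfg)
            for i in order:
                filters[i](calls)
            results.append({(c.chrom, c.pos): frozenset(c.flags) for c in calls})
        assert results[0] == results[1] == results[2]

    def test_candidate_conservation(self, tiny_calls):
        calls, attrition = tiny_calls
        assert attrition["candidates"] == attrition["surviving"] + attrition["flagged_total"]

    def test_planted_truth_recovery_on_the_tiny_study(self, tiny_truth, tiny_sites):
        found = {(s.chrom, s.pos) for s in tiny_sites}
        truth = {(s.chrom, s.pos) for s in tiny_truth.true_sites}
        artifacts = {(a.chrom, a.pos) for a in tiny_truth.artifact_sites}
        snps = {(s.chrom, s.pos) for s in tiny_truth.het_snps}
        assert found == truth
        assert found.isdisjoint(artifacts) and found.isdisjoint(snps)


def test_percentages_from_a_published_scale_tally():
    counts = {"A-to-G": 44_267, "C-to-T": 818, "other": 2_199}
    pct = type_percentages(counts)
    assert round(pct["A-to-G"], 1) == 93.6
    assert round(pct["C-to-T"], 2) == 1.73
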