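"""Contracts of the synthetic study generator: determinism, planted truth."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio import Align

from editome.config import ConfigError, SimConfig
from editome import synthetic
from editome.synthetic import (
    PlacementError,
    SizingError,
    generate_reference,
    maximal_run_lengths,
    plant_truth,
    simulate_rna_evidence,
    simulate_wgs_genotypes,
)


def test_same_seed_gives_byte_identical_outputs(tiny_config, tmp_path):
    from editome.io_formats import write_fasta

    paths = []
    for tag in ("a", "b"):
        ref = generate_reference(tiny_config)
        truth = plant_truth(ref, tiny_config)
        ev, _ = simulate_rna_evidence(ref, truth, tiny_config)
        p = tmp_path / f"{tag}.fa"
        write_fasta(ref.sequences, p)
        first = next(iter(ev.values()))
        q = tmp_path / f"{tag}.tsv"
        first.to_csv(q, sep="\t", index=False)
        paths.append((p, q))
    assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
    assert paths[0][1].read_bytes() == paths[1][1].read_bytes()


def test_different_seed_changes_the_genome(tiny_config):
    import dataclasses

    other = dataclasses.replace(tiny_config, seed=tiny_config.seed + 1)
    a = generate_reference(tiny_config).sequences["chr1"]
    b = generate_reference(other).sequences["chr1"]
    assert a != b


def test_reference_contains_all_required_feature_classes(tiny_ref):
    models = tiny_ref.gene_models
    assert {g.strand for g in models} == {"+", "-"}
    coding = [g for g in models if g.biotype == "coding"]
    assert coding and all(g.utr5 and g.utr3 and g.introns and g.cds for g in coding)
    assert any(g.biotype in ("lincRNA", "novel_lncRNA") for g in models)
    assert any(r.family == "SINE/tRNA" for r in tiny_ref.repeats)
    # a homopolymer tract >= 5 bp inside a transcribed region
    genome = tiny_ref.sequences["chr1"]
    runs = maximal_run_lengths(genome)
    assert any(
        runs[s] >= 5 for (_, s, _e, _st) in tiny_ref.extras["homopolymer_runs"]
    )


def test_infeasible_configs_raise_sizing_errors():
    with pytest.raises(ConfigError):
        SimConfig(n_genes=-1)
    with pytest.raises(SizingError, match="n_genes"):
        generate_reference(SimConfig(n_genes=0))
    with pytest.raises(SizingError, match="genome_length"):
        generate_reference(SimConfig(genome_length=2000))


def test_duplicated_segment_identity_via_alignment_oracle(tiny_ref):
    """Self-alignment of the two copies is >= 95% identical (global oracle)."""
    (c1, s1, e1), (c2, s2, e2) = tiny_ref.extras["duplicated_segment"]
    a = tiny_ref.sequences[c1][s1:e1]
    b = tiny_ref.sequences[c2][s2:e2]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    identity = aligner.score(a, b) / max(len(a), len(b))
    assert identity >= 0.95


class TestPlantedTruth:
    def test_stage_means_of_planted_levels_hit_their_targets(self):
        cfg = SimConfig(
            seed=5, n_true_sites=500,
            stage_levels={"S1": 0.15, "S2": 0.25, "S3": 0.18},
        )
        truth = plant_truth(generate_reference(cfg), cfg)
        for stage, target in cfg.stage_levels.items():
            mean = np.mean([s.level(stage) for s in truth.true_sites])
            assert abs(mean - target) < 0.02

    def test_zero_sites_yields_empty_but_valid_truth(self):
        cfg = SimConfig(seed=2, n_true_sites=0, n_background_sites=10)
        truth = plant_truth(generate_reference(cfg), cfg)
        assert truth.true_sites == []
        assert len(truth.het_snps) == cfg.n_het_snps

    def test_every_true_site_is_adenosine_on_its_strand(self, tiny_ref, tiny_truth):
        genome = tiny_ref.sequences["chr1"]
        for s in tiny_truth.true_sites:
            base = genome[s.pos]
            assert (base, s.strand) in {("A", "+"), ("T", "-")}

    def test_repeat_fraction_of_true_sites(self, tiny_config, tiny_ref, tiny_truth):
        in_rep = sum(
            any(r.start <= s.pos < r.end for r in tiny_ref.repeats)
            for s in tiny_truth.true_sites
        )
        assert in_rep / len(tiny_truth.true_sites) >= tiny_config.repeat_site_fraction - 1e-9

    def test_homopolymer_artifacts_lie_in_long_runs(self, tiny_ref, tiny_truth):
        genome = tiny_ref.sequences["chr1"]
        runs = maximal_run_lengths(genome)
        hp = [a for a in tiny_truth.artifact_sites if a.kind == "homopolymer"]
        assert hp and all(runs[a.pos] >= 5 for a in hp)

    def test_planted_positions_never_collide(self, tiny_truth):
        pools = (
            [s.pos for s in tiny_truth.true_sites],
            [s.pos for s in tiny_truth.het_snps],
            [a.pos for a in tiny_truth.artifact_sites],
        )
        flat = [p for pool in pools for p in pool]
        assert len(flat) == len(set(flat))

    def test_not_enough_adenosines_raises_placement_error(self):
        cfg = SimConfig(seed=1, n_true_sites=5000, genome_length=30_000)
        with pytest.raises(PlacementError, match="eligible adenosines"):
            plant_truth(generate_reference(cfg), cfg)


class TestWgsGenotypes:
    def test_requested_het_snps_become_het_records(self, tiny_bundle, tiny_truth, tiny_config):
        recs = simulate_wgs_genotypes(tiny_bundle, tiny_truth, tiny_config)
        assert len(recs) == tiny_config.n_het_snps
        assert all(r.gt == "0/1" for r in recs)

    def test_true_editing_sites_are_absent_from_wgs(self, tiny_bundle, tiny_truth, tiny_config):
        recs = simulate_wgs_genotypes(tiny_bundle, tiny_truth, tiny_config)
        rec_pos = {(r.chrom, r.pos) for r in recs}
        assert rec_pos.isdisjoint({(s.chrom, s.pos) for s in tiny_truth.true_sites})

    def test_vcf_roundtrip_preserves_records(self, tiny_bundle, tiny_truth, tiny_config, tmp_path):
        from editome.io_formats import read_vcf_positions, write_vcf

        recs = simulate_wgs_genotypes(tiny_bundle, tiny_truth, tiny_config)
        p = tmp_path / "wgs.vcf"
        write_vcf(recs, p, {"chr1": tiny_config.genome_length}, sample="wgs")
        genotypes, _ = read_vcf_positions(p, "genotype")
        assert genotypes == {(r.chrom, r.pos): "het" for r in recs}


class TestRnaEvidence:
    def test_binomial_concentration_at_high_coverage(self):
        cfg = SimConfig(
            seed=9, n_true_sites=1, n_het_snps=0, n_read_end_artifacts=0,
            n_homopolymer_artifacts=0, n_mismap_artifacts=0, n_background_sites=0,
            coverage_mean=10_000.0, base_error_rate=0.0,
            stage_levels={"S": 0.5}, n_replicates=1, replicate_sd=0.0,
            site_level_spread=0.0,
        )
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        ev, _ = simulate_rna_evidence(ref, truth, cfg)
        df = next(iter(ev.values()))
        site = truth.true_sites[0]
        at = df[df["pos"] == site.pos]
        alt = "G" if site.strand == "+" else "C"
        ratio = (at["base"] == alt).mean()
        assert 0.48 <= ratio <= 0.52

    def test_zero_level_and_zero_error_give_no_edited_reads(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(
            tiny_config, stage_levels={"S": 0.0}, replicate_sd=0.0,
            site_level_spread=0.0, base_error_rate=0.0,
        )
        ref = generate_reference(cfg)
        truth = plant_truth(ref, cfg)
        ev, _ = simulate_rna_evidence(ref, truth, cfg)
        df = pd.concat(ev.values())
        site_pos = {s.pos for s in truth.true_sites}
        at = df[df["pos"].isin(site_pos)]
        assert (at["base"] == at["ref_base"]).all()

    def test_read_end_artifact_reads_always_touch_a_read_end(
        self, tiny_config, tiny_truth, tiny_evidence
    ):
        margin = tiny_config.read_end_margin
        for a in tiny_truth.artifact_sites:
            if a.kind != "read_end":
                continue
            alt = "G" if a.strand == "+" else "C"
            reads = tiny_evidence[
                (tiny_evidence["pos"] == a.pos) & (tiny_evidence["base"] == alt)
            ]
            assert len(reads) > 0
            assert ((reads["off5"] <= margin) | (reads["off3"] <= margin)).all()

    def test_het_snps_show_roughly_half_alternative_alleles(
        self, tiny_truth, tiny_evidence
    ):
        fracs = []
        for s in tiny_truth.het_snps:
            at = tiny_evidence[tiny_evidence["pos"] == s.pos]
            fracs.append((at["base"] == s.alt).mean())
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_library_strand_matches_the_transcribed_gene(self, tiny_ref, tiny_evidence):
        for g in tiny_ref.gene_models[:2]:
            s, e = g.span
            reads = tiny_evidence[(tiny_evidence["pos"] >= s) & (tiny_evidence["pos"] < e)]
            assert (reads["strand"] == g.strand).all()

    def test_planted_truth_separability_at_error_free_coverage(self):
        """Every true site at level >= 0.2 has >= 3 edited reads (several seeds)."""
        failures = total = 0
        for seed in range(3):
            cfg = SimConfig(
                seed=seed, n_true_sites=100, coverage_mean=50.0,
                base_error_rate=0.0, n_background_sites=0,
                stage_levels={"S": 0.25}, n_replicates=1,
            )
            ref = generate_reference(cfg)
            truth = plant_truth(ref, cfg)
            ev, realized = simulate_rna_evidence(ref, truth, cfg)
            df = next(iter(ev.values()))
            sample = df["sample_id"].iloc[0]
            for site in truth.true_sites:
                if realized.loc[site.key, sample] < 0.2:
                    continue
                total += 1
                alt = "G" if site.strand == "+" else "C"
                n = ((df["pos"] == site.pos) & (df["base"] == alt)).sum()
                if n < 3:
                    failures += 1
        assert total > 100
        assert failures / total <= 0.02


class TestReverseComplementTransform:
    def test_bundle_transform_is_an_involution(self, tiny_bundle):
        twice = synthetic.reverse_complement_bundle(
            synthetic.reverse_complement_bundle(tiny_bundle)
        )
        assert twice.sequences == tiny_bundle.sequences
        assert twice.known_snps == tiny_bundle.known_snps
        for a, b in zip(twice.gene_models, tiny_bundle.gene_models):
            assert (a.strand, a.exons, a.cds) == (b.strand, b.exons, b.cds)

    def test_evidence_transform_maps_bases_and_offsets(self, tiny_evidence, tiny_bundle):
        lengths = {c: len(s) for c, s in tiny_bundle.sequences.items()}
        rc = synthetic.reverse_complement_evidence(tiny_evidence, lengths)
        back = synthetic.reverse_complement_evidence(rc, lengths)
        pd.testing.assert_frame_equal(
            back.sort_values("read_id").reset_index(drop=True),
            tiny_evidence.sort_values("read_id").reset_index(drop=True),
        )
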