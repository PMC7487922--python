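"""End-to-end orchestration: simulate -> detect -> profile -> diff -> miRNA.

``run_pipeline`` drives the full analysis from one :class:`PipelineConfig`
(loadable from YAML), writes every stage's tabular outputs under the run
directory, and returns a machine-readable report with per-filter attrition,
site counts by type/feature/repeat, per-stage overall editing rates, DES
summaries and miRNA effect summaries.  All randomness derives from the one
global seed, so a rerun with the same config reproduces the report.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import detection, differential, io_formats, mirna, profiling, synthetic
from .config import DetectionConfig, DiffConfig, MirnaParams, QuantConfig, SimConfig

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "stage_simulate",
    "load_reference",
    "stage_detect",
    "stage_profile",
    "stage_diff",
    "stage_mirna",
    "sites_to_frame",
    "frame_to_sites",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    mirna: MirnaParams = field(default_factory=MirnaParams)
    deg_list: Optional[Path] = None  # TSV with a gene_id column
    terms: Optional[Path] = None  # TSV term_id <tab> gene_id

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        for name in ("deg_list", "terms"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} file {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {
            "sim": SimConfig,
            "detection": DetectionConfig,
            "quant": QuantConfig,
            "diff": DiffConfig,
            "mirna": MirnaParams,
        }
        kwargs: Dict[str, object] = {}
        for key, value in raw.items():
            if key in known:
                if not isinstance(value, dict):
                    raise ValueError(f"config section {key!r} must be a mapping")
                kwargs[key] = known[key](**value)
            elif key in ("outdir", "seed", "deg_list", "terms"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        if "outdir" not in kwargs:
            raise ValueError("config must set 'outdir'")
        return cls(**kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(sim: SimConfig, outdir: Path) -> Dict[str, object]:
    """Generate the synthetic study and write every input file."""
    outdir.mkdir(parents=True, exist_ok=True)
    ref = synthetic.generate_reference(sim)
    truth = synthetic.plant_truth(ref, sim)
    contigs = {c: len(s) for c, s in ref.sequences.items()}

    io_formats.write_fasta(ref.sequences, outdir / "genome.fa")
    io_formats.write_gtf(ref.gene_models, outdir / "genes.gtf")
    io_formats.write_repeats_bed(ref.repeats, outdir / "repeats.bed")
    io_formats.write_vcf(
        synthetic.simulate_wgs_genotypes(ref, truth, sim),
        outdir / "wgs.vcf",
        contigs,
        sample="wgs",
    )
    io_formats.write_vcf(
        synthetic.known_snp_records(truth), outdir / "known_snps.vcf", contigs
    )
    evidence, realized = synthetic.simulate_rna_evidence(ref, truth, sim)
    evidence_paths = []
    for sample, df in evidence.items():
        p = outdir / f"evidence_{sample}.tsv"
        io_formats.write_site_evidence(df, p)
        evidence_paths.append(p)
    realized.to_csv(outdir / "truth_realized_levels.tsv", sep="\t")
    synthetic.write_truth(
        truth,
        outdir / "truth_sites.tsv",
        outdir / "truth_artifacts.tsv",
        outdir / "truth_snps.tsv",
    )
    mirnas = synthetic.simulate_mirnas(ref, truth, sim)
    io_formats.write_fasta(mirnas, outdir / "mirnas.fa")
    design = pd.DataFrame(
        [
            {"sample_id": f"{stage}_r{r + 1}", "stage": stage}
            for stage in sim.stages
            for r in range(sim.n_replicates)
        ]
    )
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    return {
        "ref": ref,
        "truth": truth,
        "evidence": evidence,
        "realized_levels": realized,
        "mirnas": mirnas,
        "paths": {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "genes.gtf",
            "repeats": outdir / "repeats.bed",
            "wgs_vcf": outdir / "wgs.vcf",
            "dbsnp_vcf": outdir / "known_snps.vcf",
            "evidence": evidence_paths,
            "mirnas": outdir / "mirnas.fa",
            "design": outdir / "design.tsv",
        },
    }


def load_reference(
    genome: Path,
    gtf: Path,
    repeats: Optional[Path] = None,
    wgs_vcf: Optional[Path] = None,
    dbsnp_vcf: Optional[Path] = None,
) -> io_formats.ReferenceBundle:
    """Assemble a reference bundle from standard files."""
    sequences = io_formats.read_fasta(genome)
    models = io_formats.read_gtf(gtf)
    reps: List[io_formats.RepeatInterval] = []
    if repeats is not None:
        reader = (
            io_formats.read_repeats_out
            if str(repeats).endswith(".out")
            else io_formats.read_repeats_bed
        )
        reps = reader(repeats)
    known: set = set()
    multi: set = set()
    genotypes: Dict[Tuple[str, int], str] = {}
    if wgs_vcf is not None:
        genotypes, m = io_formats.read_vcf_positions(wgs_vcf, "genotype")
        multi |= m
    if dbsnp_vcf is not None:
        known, m = io_formats.read_vcf_positions(dbsnp_vcf, "known_snp")
        multi |= m
    return io_formats.ReferenceBundle(
        sequences=sequences,
        gene_models=models,
        repeats=reps,
        known_snps=known,
        wgs_genotypes=genotypes,
        multiallelic=multi,
    )


def read_evidence_files(paths: Sequence[Path]) -> pd.DataFrame:
    frames = [io_formats.read_site_evidence(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "sample_id", "read_id"]).reset_index(
        drop=True
    )


def sites_to_frame(calls: Sequence[detection.VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "pos_1based": c.pos + 1,
                "strand": c.strand or ".",
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                "mismatch_type": c.mismatch_type or ".",
                "filter_flags": ",".join(sorted(c.flags)) or ".",
                "n_ref": c.n_ref,
                "n_alt": c.n_alt,
                "n_alt_internal": c.n_alt_internal,
                "sample_counts": ";".join(
                    f"{s}:{nr}:{na}"
                    for s, (nr, na) in sorted(c.sample_counts.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos_1based", "strand", "ref_base", "alt_base",
            "mismatch_type", "filter_flags", "n_ref", "n_alt", "n_alt_internal",
            "sample_counts",
        ],
    )


def frame_to_sites(df: pd.DataFrame) -> List[detection.EditingSite]:
    """Rebuild accepted A-to-I sites from a detect-stage sites table."""
    out = []
    keep = df[(df["mismatch_type"] == "A-to-G") & (df["filter_flags"] == ".")]
    for _, r in keep.iterrows():
        out.append(
            detection.EditingSite(
                chrom=r["chrom"],
                pos=int(r["pos_1based"]) - 1,
                strand=r["strand"],
                ref_base=r["ref_base"],
                alt_base=r["alt_base"],
                n_ref=int(r["n_ref"]),
                n_alt=int(r["n_alt"]),
                sample_counts={},
            )
        )
    return out


def stage_detect(
    ref: io_formats.ReferenceBundle,
    evidence: pd.DataFrame,
    cfg: DetectionConfig,
    outdir: Path,
) -> Dict[str, object]:
    outdir.mkdir(parents=True, exist_ok=True)
    calls = detection.call_candidates(evidence, ref, cfg)
    calls, attrition = detection.apply_filters(calls, ref, evidence, cfg)
    sites, type_counts, type_pct = detection.select_editing_sites(calls)
    frame = sites_to_frame(calls)
    frame.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    frame[(frame["mismatch_type"] == "A-to-G") & (frame["filter_flags"] == ".")].to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    with open(outdir / "attrition.json", "w") as fh:
        json.dump(attrition, fh, indent=2)
    return {
        "calls": calls,
        "sites": sites,
        "type_counts": type_counts,
        "type_percentages": type_pct,
        "attrition": attrition,
    }


def stage_profile(
    ref: io_formats.ReferenceBundle,
    evidence: pd.DataFrame,
    sites: Sequence[detection.EditingSite],
    qcfg: QuantConfig,
    design: Mapping[str, str],
    outdir: Path,
) -> Dict[str, object]:
    outdir.mkdir(parents=True, exist_ok=True)
    levels = profiling.editing_level_matrix(evidence, sites, qcfg)
    levels.to_csv(outdir / "levels.tsv", sep="\t")
    per_sample = profiling.overall_editing_rate(evidence, sites, qcfg.min_qual)
    per_stage = profiling.stage_rates(per_sample, design)
    pd.DataFrame(
        {"sample": per_sample.index, "overall_rate": per_sample.to_numpy()}
    ).to_csv(outdir / "overall_rate_per_sample.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"stage": per_stage.index, "overall_rate": per_stage.to_numpy()}
    ).to_csv(outdir / "overall_rate_per_stage.tsv", sep="\t", index=False)

    trees = profiling._feature_trees(ref.gene_models)
    rep_labels, fam_counts, sub_counts = profiling.annotate_repeats(sites, ref.repeats)
    rows = []
    for site, rep in zip(sites, rep_labels):
        feature, hosts = profiling.annotate_feature(site, ref.gene_models, trees)
        rec = None
        if feature == "CDS":
            r = profiling.annotate_recoding(site, ref.gene_models, ref.sequences)
            rec = "synonymous" if r.synonymous else f"nonsynonymous:{r.aa_ref}>{r.aa_alt}"
        site.annotations.update(
            {"feature": feature, "host_genes": hosts, "repeat": rep, "recoding": rec}
        )
        rows.append(
            {
                "site": site.key,
                "feature": feature,
                "host_genes": ",".join(hosts) or ".",
                "repeat": rep,
                "recoding": rec or ".",
            }
        )
    annotated = pd.DataFrame(
        rows, columns=["site", "feature", "host_genes", "repeat", "recoding"]
    )
    annotated.to_csv(outdir / "sites_annotated.tsv", sep="\t", index=False)
    neighbors = profiling.neighbor_preference(sites, ref.sequences)
    neighbors.to_csv(outdir / "neighbor_preference.tsv", sep="\t")
    fam_counts.rename("count").to_csv(outdir / "repeat_families.tsv", sep="\t")
    sub_counts.rename("count").to_csv(outdir / "repeat_subfamilies.tsv", sep="\t")
    return {
        "levels": levels,
        "per_sample_rate": per_sample,
        "per_stage_rate": per_stage,
        "annotated": annotated,
        "neighbors": neighbors,
        "repeat_families": fam_counts,
        "repeat_subfamilies": sub_counts,
    }


def stage_diff(
    levels: pd.DataFrame,
    design: Mapping[str, str],
    stage_order: Sequence[str],
    cfg: DiffConfig,
    site_to_genes: Mapping[str, Sequence[str]],
    outdir: Path,
    deg_list: Optional[Sequence[str]] = None,
    term_to_genes: Optional[Mapping[str, Sequence[str]]] = None,
) -> Dict[str, object]:
    outdir.mkdir(parents=True, exist_ok=True)
    groups = {
        stage: [s for s in levels.columns if design[s] == stage]
        for stage in stage_order
    }
    des_frames: Dict[str, pd.DataFrame] = {}
    for i, early in enumerate(stage_order):
        for late in stage_order[i + 1 :]:
            name = f"{late}-{early}"
            des_frames[name] = differential.test_des(
                levels, groups[early], groups[late], name, cfg
            )
            des_frames[name].to_csv(outdir / f"des_{name}.tsv", sep="\t", index=False)
    summary, extra = differential.summarize_comparisons(des_frames)
    summary.to_csv(outdir / "des_summary.tsv", sep="\t", index=False)

    cluster = None
    try:
        cluster = differential.cluster_samples(levels)
        (outdir / "clustering.newick").write_text(cluster.newick + "\n")
    except ValueError:
        pass

    overlaps: Dict[str, int] = {}
    enrichment: Dict[str, pd.DataFrame] = {}
    universe = sorted({g for gs in site_to_genes.values() for g in gs})
    for name, df in des_frames.items():
        des_sites = df[df["is_des"]]["site"]
        genes = sorted(
            {g for s in des_sites for g in site_to_genes.get(s, [])}
        )
        if deg_list is not None:
            overlaps[name] = len(differential.overlap_genes(genes, deg_list))
        if term_to_genes is not None and genes:
            enrichment[name] = differential.enrichment_test(
                genes, universe, term_to_genes
            )
            enrichment[name].to_csv(
                outdir / f"enrichment_{name}.tsv", sep="\t", index=False
            )
    return {
        "des_frames": des_frames,
        "summary": summary,
        "union": extra["union"],
        "shared_by_all": extra["shared_by_all"],
        "cluster": cluster,
        "deg_overlap": overlaps,
        "enrichment": enrichment,
    }


def stage_mirna(
    ref: io_formats.ReferenceBundle,
    sites: Sequence[detection.EditingSite],
    mirnas: Mapping[str, str],
    params: MirnaParams,
    outdir: Path,
) -> Dict[str, object]:
    """Scan ref vs edited flanks of 3'-UTR sites and classify pair effects."""
    outdir.mkdir(parents=True, exist_ok=True)
    effects: List[mirna.PairEffect] = []
    hit_rows = []
    e_ref_all: List[float] = []
    e_edit_all: List[float] = []
    for site in sites:
        try:
            pair = mirna.extract_flank_pair(
                site, ref.sequences, ref.gene_models, params.flank
            )
        except ValueError:
            continue
        ref_hits, edit_hits, eff = mirna.site_effects(pair, mirnas, params)
        effects.extend(eff)
        for tag, hits in (("ref", ref_hits), ("edit", edit_hits)):
            for h in hits:
                hit_rows.append(
                    {
                        "site": pair.site, "flank": tag, "mirna": h.mirna,
                        "start": h.target_start, "end": h.target_end,
                        "score": h.score, "energy": h.energy,
                    }
                )
                (e_ref_all if tag == "ref" else e_edit_all).append(h.energy)
    pd.DataFrame(
        hit_rows,
        columns=["site", "flank", "mirna", "start", "end", "score", "energy"],
    ).to_csv(outdir / "mirna_hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "site": e.site, "mirna": e.mirna, "class": e.classification,
                "energy_ref": e.e_ref, "energy_edit": e.e_edit,
                "delta_energy": e.delta_e,
            }
            for e in effects
        ],
        columns=["site", "mirna", "class", "energy_ref", "energy_edit", "delta_energy"],
    ).to_csv(outdir / "mirna_effects.tsv", sep="\t", index=False)
    summary = mirna.summarize_effects(effects)
    energy_test = None
    if len(e_ref_all) >= 3 and len(e_edit_all) >= 3:
        energy_test = mirna.compare_energy_distributions(e_ref_all, e_edit_all)
    with open(outdir / "mirna_summary.json", "w") as fh:
        json.dump({"effects": summary, "energy_test": energy_test}, fh, indent=2)
    return {"effects": effects, "summary": summary, "energy_test": energy_test}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run simulate -> detect -> profile -> diff -> miRNA and write a report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"seed": config.seed, "stages": {}}
    t0 = time.time()

    def run_stage(name, fn, *args, **kwargs):
        start = time.time()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            partial = out / "report.partial.json"
            with open(partial, "w") as fh:
                json.dump(report, fh, indent=2, default=str)
            raise PipelineError(name, exc) from exc
        report["stages"][name] = {"seconds": round(time.time() - start, 3)}
        return result

    sim = run_stage("simulate", stage_simulate, config.sim, out / "sim")
    ref = run_stage(
        "load_reference",
        load_reference,
        sim["paths"]["genome"],
        sim["paths"]["gtf"],
        sim["paths"]["repeats"],
        sim["paths"]["wgs_vcf"],
        sim["paths"]["dbsnp_vcf"],
    )
    evidence = run_stage("read_evidence", read_evidence_files, sim["paths"]["evidence"])
    det = run_stage("detect", stage_detect, ref, evidence, config.detection, out / "detect")

    design = {
        f"{stage}_r{r + 1}": stage
        for stage in config.sim.stages
        for r in range(config.sim.n_replicates)
    }
    prof = run_stage(
        "profile",
        stage_profile,
        ref,
        evidence,
        det["sites"],
        config.quant,
        design,
        out / "profile",
    )
    site_to_genes = {
        s.key: s.annotations.get("host_genes", []) for s in det["sites"]
    }
    deg = None
    if config.deg_list is not None:
        deg = sorted(pd.read_csv(config.deg_list, sep="\t")["gene_id"].unique())
    terms = None
    if config.terms is not None:
        tdf = pd.read_csv(config.terms, sep="\t")
        terms = {
            t: sorted(g["gene_id"].unique()) for t, g in tdf.groupby("term_id")
        }
    diff = run_stage(
        "diff",
        stage_diff,
        prof["levels"],
        design,
        config.sim.stages,
        config.diff,
        site_to_genes,
        out / "diff",
        deg,
        terms,
    )
    # miRNA analysis targets 3'-UTR DESs; when the study design yields no
    # DES (small stage contrasts), fall back to all 3'-UTR A-to-I sites.
    des_keys = {
        s for df in diff["des_frames"].values() for s in df[df["is_des"]]["site"]
    }
    utr3_sites = [
        s for s in det["sites"] if s.annotations.get("feature") == "3UTR"
    ]
    mirna_input = [s for s in utr3_sites if s.key in des_keys] or utr3_sites
    mir = run_stage(
        "mirna",
        stage_mirna,
        ref,
        mirna_input,
        sim["mirnas"],
        config.mirna,
        out / "mirna",
    )

    features = prof["annotated"]["feature"].value_counts().to_dict()
    report.update(
        {
            "n_candidates": det["attrition"]["candidates"],
            "attrition": det["attrition"],
            "type_counts": det["type_counts"],
            "type_percentages": det["type_percentages"],
            "n_editing_sites": len(det["sites"]),
            "feature_counts": features,
            "repeat_family_counts": prof["repeat_families"].to_dict(),
            "overall_rate_per_sample": prof["per_sample_rate"].round(6).to_dict(),
            "overall_rate_per_stage": prof["per_stage_rate"].round(6).to_dict(),
            "des_summary": diff["summary"].to_dict(orient="records"),
            "des_union": diff["union"],
            "des_shared_by_all": diff["shared_by_all"],
            "deg_overlap": diff["deg_overlap"],
            "mirna_effects": mir["summary"],
            "mirna_energy_test": mir["energy_test"],
            "wall_seconds": round(time.time() - t0, 3),
        }
    )
    # consistency: every accepted A-to-I site carries exactly one feature label
    assert sum(features.values()) == len(det["sites"])
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
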