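"""Convenience drivers around the synthetic generator and the pipeline.

These functions glue the synthetic community generator to the on-disk
layout the pipeline consumes (per-sample FASTQ pairs, a TSV manifest,
per-marker reference FASTA files with lineage headers, ground-truth
tables and a ready-to-run YAML config), so a complete verifiable dataset
is one call away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .markers import MarkerSpec, default_marker_panel
from .records import write_fasta, write_fastq
from .simulate import (CommunityProfile, GroundTruth, ReferenceTaxon,
                       SimConfig, build_reference_set, derive_seed,
                       merge_truth, simulate_sample_reads)


@dataclass
class SyntheticDataset:
    refs: list[ReferenceTaxon]
    specs: list[MarkerSpec]
    profiles: list[CommunityProfile]
    pairs_by_sample: dict[str, list]
    truth: GroundTruth
    sim_config: SimConfig


def make_profiles(refs: list[ReferenceTaxon], n_samples: int, n_controls: int,
                  seed: int) -> list[CommunityProfile]:
    """Dirichlet(1) community profiles plus empty negative controls."""
    rng = np.random.default_rng(derive_seed(seed, "profiles"))
    taxa = sorted(t.taxon_id for t in refs)
    profiles = []
    for i in range(n_samples):
        w = rng.dirichlet(np.ones(len(taxa)))
        w = w / w.sum()
        abundances = dict(zip(taxa, (float(x) for x in w)))
        # renormalise exactly to absorb float round-off
        total = sum(abundances.values())
        abundances = {k: v / total for k, v in abundances.items()}
        profiles.append(CommunityProfile(f"S{i + 1:02d}", False, abundances))
    for i in range(n_controls):
        profiles.append(CommunityProfile(f"NEG{i + 1:02d}", True, {}))
    return profiles


def generate_dataset(seed: int = 0, n_genera: int = 4, seqs_per_genus: int = 1,
                     n_samples: int = 5, n_controls: int = 1,
                     reads_per_sample: int = 2000,
                     substitution_rate: float = 0.001,
                     chimera_fraction: float = 0.01,
                     quality_errors: bool = True,
                     specs: list[MarkerSpec] | None = None,
                     run_id: str = "RUN1") -> SyntheticDataset:
    """Simulate a complete in-memory multi-marker dataset with ground truth."""
    specs = specs or default_marker_panel()
    refs = build_reference_set(n_genera, seqs_per_genus, specs, seed=seed)
    profiles = make_profiles(refs, n_samples, n_controls, seed)
    cfg = SimConfig(seed=seed, reads_per_sample=reads_per_sample,
                    substitution_rate_per_base=substitution_rate,
                    chimera_fraction=chimera_fraction,
                    quality_errors=quality_errors)
    pairs_by_sample = {}
    truths = []
    for profile in profiles:
        pairs, truth = simulate_sample_reads(profile, refs, specs, cfg, run_id)
        pairs_by_sample[profile.sample_id] = pairs
        truths.append(truth)
    return SyntheticDataset(refs, specs, profiles, pairs_by_sample,
                            merge_truth(truths), cfg)


def lineage_header(taxon: ReferenceTaxon) -> str:
    d, p, c, o, f, g = taxon.lineage
    return (f"{taxon.taxon_id} d__{d};p__{p};c__{c};o__{o};f__{f};g__{g}")


def write_synthetic_dataset(outdir: str | Path, **kwargs) -> dict[str, Path]:
    """Write a synthetic dataset in the pipeline's on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(**kwargs)
    paths: dict[str, Path] = {}

    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\trun_id\tis_negative_control\tr1\tr2\n")
        for profile in ds.profiles:
            sid = profile.sample_id
            r1 = outdir / f"{sid}_R1.fastq"
            r2 = outdir / f"{sid}_R2.fastq"
            write_fastq((a for a, _ in ds.pairs_by_sample[sid]), r1)
            write_fastq((b for _, b in ds.pairs_by_sample[sid]), r2)
            fh.write(f"{sid}\tRUN1\t{int(profile.is_negative_control)}"
                     f"\t{r1.name}\t{r2.name}\n")
    paths["manifest"] = manifest

    references = {}
    for spec in ds.specs:
        ref_path = outdir / f"reference_{spec.name}.fasta"
        write_fasta(((lineage_header(t), t.marker_seqs[spec.name])
                     for t in ds.refs), ref_path)
        references[spec.name] = ref_path.name
        paths[f"reference_{spec.name}"] = ref_path

    truth_path = outdir / "ground_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tmarker\ttaxon_id\ttemplates\n")
        for (sample, marker), counts in sorted(ds.truth.template_counts.items()):
            for taxon, n in sorted(counts.items()):
                fh.write(f"{sample}\t{marker}\t{taxon}\t{n}\n")
    paths["ground_truth"] = truth_path

    chim_path = outdir / "ground_truth_chimeras.tsv"
    with open(chim_path, "w") as fh:
        fh.write("read_id\tmarker\tparent_a\tparent_b\tbreakpoint\n")
        for c in ds.truth.chimeras:
            fh.write(f"{c.read_id}\t{c.marker}\t{c.parent_a}\t{c.parent_b}"
                     f"\t{c.breakpoint}\n")
    paths["chimeras"] = chim_path

    config = PipelineConfig(
        seed=ds.sim_config.seed, output_dir="pipeline_out",
        manifest=manifest.name, references=references, markers=ds.specs)
    config_path = outdir / "config.yaml"
    config.dump(config_path)
    paths["config"] = config_path
    return paths
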