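"""End-to-end orchestration of the metabarcoding workflow.

``run_pipeline`` drives the whole chain for every sample and marker —
read-through stripping, marker demultiplexing, merging/QC, clustering,
chimera screening, taxonomy, the three OTU filters, and (when a dated
tree and trait table are configured) stochastic mapping of the
endolithic character — writing every intermediate artifact plus a
machine-readable run manifest with per-stage read ledgers. The run is a
deterministic function of the global seed, which fans out to per-stage
seeds by stable hashing of stage names.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import dendropy

from . import demux as dx
from . import readprep as rp
from .cluster import build_otu_table, dereplicate, greedy_cluster, OTUTable
from .config import PipelineConfig
from .errors import InputError
from .evolution import (count_origins, fit_mk, node_marginals, read_trait_table,
                        sample_maps, annotated_newick)
from .filters import apply_filters
from .records import read_fastq_pairs, write_fasta
from .simulate import ReferenceTaxon, derive_seed
from .taxonomy import classify, train


def read_manifest(path: str | Path) -> list[dict]:
    """Sample manifest TSV: sample_id, run_id, is_negative_control, r1, r2."""
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "run_id", "is_negative_control", "r1", "r2"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            row["is_negative_control"] = row["is_negative_control"].lower() in (
                "1", "true", "yes")
            rows.append(row)
    if not rows:
        raise InputError(f"manifest {path} has no samples")
    return rows


def parse_reference_fasta(path: str | Path, marker: str) -> list[ReferenceTaxon]:
    """Reference FASTA whose headers carry a d__;p__;c__;o__;f__;g__ lineage."""
    from .records import read_fasta

    prefixes = ("d__", "p__", "c__", "o__", "f__", "g__")
    taxa = []
    for description, seq in read_fasta(path):
        parts = description.split(None, 1)
        if len(parts) != 2:
            raise InputError(f"{path}: header {description!r} lacks a lineage")
        taxon_id, lineage_str = parts
        fields = [f.strip() for f in lineage_str.split(";")]
        if len(fields) != 6 or not all(
                f.startswith(p) for f, p in zip(fields, prefixes)):
            raise InputError(f"{path}: malformed lineage in {description!r}")
        lineage = tuple(f[3:] for f in fields)
        taxa.append(ReferenceTaxon(taxon_id=taxon_id, lineage=lineage,
                                   marker_seqs={marker: seq}))
    return taxa


def write_otu_table_tsv(table: OTUTable, path: str | Path) -> None:
    table.df.rename_axis("otu_id").to_csv(path, sep="\t")


def write_sparse_table_tsv(table: OTUTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tsample_id\tcount\n")
        for otu in table.df.index:
            for sample in table.df.columns:
                n = int(table.df.loc[otu, sample])
                if n:
                    fh.write(f"{otu}\t{sample}\t{n}\n")


def run_evolution(config: PipelineConfig, outdir: Path,
                  base: Path | None = None) -> dict:
    """Trait-evolution endgame on the configured tree and trait table."""
    base = base or Path(".")
    ev = config.evolution
    tree = dendropy.Tree.get(path=str(base / ev.tree), schema="newick")
    for idx, nd in enumerate(tree.preorder_node_iter()):
        if nd.taxon is None and not nd.label:
            nd.label = f"nd{idx}"
    states = read_trait_table(base / ev.traits)
    fit = fit_mk(tree, states, variant=ev.variant, root_prior=ev.root_prior)
    mapset = sample_maps(tree, states, fit.model, n_maps=ev.n_maps,
                         seed=derive_seed(config.seed, "stochastic_maps"))
    origins = count_origins(mapset)
    marginals = node_marginals(tree, states, fit.model)

    with open(outdir / "origin_counts.tsv", "w") as fh:
        fh.write("map\torigins\n")
        for i, n in enumerate(origins.per_map):
            fh.write(f"{i}\t{n}\n")
    with open(outdir / "node_probabilities.tsv", "w") as fh:
        fh.write("node\tp_endolithic_maps\tp_endolithic_marginal\n")
        for label in sorted(origins.node_prob):
            fh.write(f"{label}\t{origins.node_prob[label]:.6f}"
                     f"\t{marginals.get(label, float('nan')):.6f}\n")
    (outdir / "annotated_tree.nwk").write_text(
        annotated_newick(tree, origins.node_prob))
    return {
        "q01": fit.model.q01, "q10": fit.model.q10,
        "log_likelihood": fit.log_likelihood,
        "warnings": fit.warnings,
        "n_maps": mapset.n_maps,
        "origins_mean": origins.mean, "origins_median": origins.median,
        "origins_q025": origins.q025, "origins_q975": origins.q975,
    }


def run_pipeline(config: PipelineConfig, base: Path | None = None) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    base = base or Path(".")
    config.validate(base)
    outdir = base / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    samples = read_manifest(base / config.manifest)
    controls = {s["sample_id"] for s in samples if s["is_negative_control"]}
    specs = config.markers

    manifest: dict = {"seed": config.seed, "samples": {}, "markers": {}}
    per_marker: dict[str, dict[str, list[tuple[str, str]]]] = {
        s.name: {} for s in specs}
    prep_ledger: dict[str, dict] = {s.name: {} for s in specs}

    for s in samples:
        sid = s["sample_id"]
        pairs = list(read_fastq_pairs(base / s["r1"], base / s["r2"],
                                      sample_id=sid, run_id=s["run_id"]))
        stripped = [(dx.strip_readthrough(r1, specs),
                     dx.strip_readthrough(r2, specs)) for r1, r2 in pairs]
        result = dx.demultiplex_sample(stripped, specs)
        manifest["samples"][sid] = {
            "input_pairs": len(pairs),
            "demux": result.counts,
            "is_negative_control": s["is_negative_control"],
        }
        for spec in specs:
            prepped, counts = rp.prepare_marker_reads(
                result.assigned[spec.name], spec, config.qc)
            per_marker[spec.name][sid] = [(h, m.bases) for h, m in prepped]
            prep_ledger[spec.name][sid] = {
                "input_pairs": counts.input_pairs,
                "kept": counts.merged_kept,
                "dropped_trim": counts.dropped_trim,
                "rejected": counts.rejected,
                "balanced": counts.balanced,
            }

    for spec in specs:
        mdir = outdir / spec.name
        mdir.mkdir(exist_ok=True)
        reads_by_sample = per_marker[spec.name]
        pooled = [rec for sid in sorted(reads_by_sample)
                  for rec in reads_by_sample[sid]]
        write_fasta(pooled, mdir / "merged.fasta")
        entry: dict = {"prep": prep_ledger[spec.name],
                       "pooled_reads": len(pooled)}
        if not pooled:
            entry["status"] = "no reads"
            manifest["markers"][spec.name] = entry
            continue

        uniques = dereplicate(pooled)
        clustering = greedy_cluster(uniques, spec.identity_threshold,
                                    config.chimera)
        write_fasta(
            ((f"{c.otu_id};size={c.size}", c.bases) for c in clustering.centroids),
            mdir / "centroids.fasta")
        table, mapping = build_otu_table(reads_by_sample, clustering,
                                         spec.identity_threshold, spec.name)
        write_otu_table_tsv(table, mdir / "otu_table_raw.tsv")
        entry["cluster"] = {
            "uniques": len(uniques),
            "otus": len(clustering.centroids),
            "chimeric_uniques": len(clustering.chimeras),
            "mapped": mapping.mapped,
            "unmapped": mapping.unmapped,
            "chimera_discarded": mapping.chimera_discarded,
            "conservative": (mapping.mapped + mapping.unmapped
                             + mapping.chimera_discarded == len(pooled)),
        }

        if spec.name in config.references:
            refs = parse_reference_fasta(base / config.references[spec.name],
                                         spec.name)
            clf = train(refs, spec.name, k=config.classify.k)
            with open(mdir / "taxonomy.tsv", "w") as fh:
                fh.write("otu_id\trank\tlabel\tconfidence\n")
                for c in clustering.centroids:
                    a = classify(
                        c.bases, clf, otu_id=c.otu_id,
                        n_bootstrap=config.classify.n_bootstrap,
                        subsample_fraction=config.classify.subsample_fraction,
                        threshold=config.classify.confidence_threshold,
                        seed=derive_seed(config.seed, "classify", spec.name,
                                         c.otu_id))
                    for call in a.reported():
                        fh.write(f"{c.otu_id}\t{call.rank}\t{call.label}"
                                 f"\t{call.confidence:.2f}\n")
            entry["taxonomy"] = str(mdir / "taxonomy.tsv")

        table_controls = controls & set(table.df.columns)
        final, report = apply_filters(table, table_controls, config.filters)
        write_otu_table_tsv(final, mdir / "otu_table_final.tsv")
        write_sparse_table_tsv(final, mdir / "otu_table_final_sparse.tsv")
        entry["filters"] = [asdict(step) for step in report.steps]
        entry["final"] = {"otus": final.n_otus, "reads": final.n_reads}
        manifest["markers"][spec.name] = entry

    if config.evolution.tree is not None:
        manifest["evolution"] = run_evolution(config, outdir, base)

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
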