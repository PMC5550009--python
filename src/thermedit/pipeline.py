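"""End-to-end orchestration: simulate (or load) data, detect hyper-editing,
quantify, compare conditions, and emit a figure-level report bundle.

Every report number is recomputed from the stage tables written to the
output directory; the JSON report is a convenience view, not a separate
computation.  A manifest records package/library versions, the seed and a
hash of the full parameter set, and the configuration is serialized next
to the outputs verbatim, so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from thermedit import __version__
from thermedit.io_alignment import (
    AlignParams,
    Genome,
    GenomeIndex,
    ReadAlignment,
    align_reads,
    load_reference,
    read_fastq,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
    write_gtf,
    write_sites,
)
from thermedit.simulate import (
    SimConfig,
    generate_genome,
    plant_editing_clusters,
    simulate_conservation_track,
    simulate_fold_intervals,
    simulate_reads,
    stage_rng,
)
from thermedit.hyper_editing import (
    HyperParams,
    TransformedRealigner,
    collect_sites,
    compute_motif,
    detect_editing,
    merge_clusters_to_regions,
    qc_mismatch_spectrum,
    strand_split,
)
from thermedit.quantification import (
    annotate_sites,
    category_distribution,
    editing_index,
    filter_supported,
    gene_editing_counts,
    pileup_sites,
    union_site_lists,
)
from thermedit.differential import (
    differential_sites,
    geneset_editing_bootstrap,
    top_expressed_pool,
)
from thermedit.site_context import (
    StructureParams,
    conservation_profile,
    evofold_overlap,
    search_sites,
    structure_summary,
)

REPORT_SECTIONS = [
    "mismatch_spectrum", "editing_index", "site_counts", "cluster_stats",
    "motif", "categories", "structure", "conservation", "differential",
    "bootstrap",
]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    ``inputs`` (paths for genome FASTA, per-condition FASTQ, GTF, optional
    conservation track TSV and fold-interval BED) switches the pipeline to
    file mode; otherwise the synthetic generator in ``sim`` provides the
    data.
    """

    outdir: str = "thermedit_out"
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    inputs: dict | None = None
    # detection
    quality_min: int = 30
    min_edits: int = 4
    end_exclusion: int = 6
    max_gap: int = 20
    # quantification
    trim: int = 6
    min_reads: int = 2
    min_level: float = 0.01
    # differential
    min_cov: int = 50
    min_delta: float = 0.20
    q: float = 0.05
    # structure
    flank: int = 2000
    min_identity: float = 70.0
    min_coverage: float = 70.0
    max_structure_sites: int = 60
    # bootstrap / conservation
    bootstrap_B: int = 1000
    conservation_window: int = 20
    # stage toggles
    run_qc_spectrum: bool = True
    run_structure: bool = True
    run_conservation: bool = True
    run_bootstrap: bool = True

    def hyper_params(self) -> HyperParams:
        return HyperParams(
            quality_min=self.quality_min, min_edits=self.min_edits,
            end_exclusion=self.end_exclusion, max_gap=self.max_gap,
        )

    def structure_params(self) -> StructureParams:
        return StructureParams(
            min_identity=self.min_identity, min_coverage=self.min_coverage,
            flank=self.flank,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            if "sites_per_cluster" in sim:
                sim["sites_per_cluster"] = tuple(sim["sites_per_cluster"])
            cfg.sim = SimConfig(**sim)
        elif d.get("inputs"):
            cfg.sim = None
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def recover_alignments(
    pool, realigner: TransformedRealigner
) -> list[ReadAlignment]:
    """Place hyper-edited pool reads via transformed realignment so their
    original sequences can contribute to pileups.

    Tries the A>G transform first, then T>C; a read recovered by either
    gets a ReadAlignment carrying its original (untransformed) bases.
    """
    out: list[ReadAlignment] = []
    for rid, seq, qual in pool:
        hit = realigner.realign(seq, "A", "G") or realigner.realign(seq, "T", "C")
        if hit is None:
            continue
        contig, start, orient = hit
        oriented = seq if orient == "+" else revcomp(seq)
        oqual = qual if orient == "+" else qual[::-1]
        ref = realigner.genome.contigs[contig][start : start + len(seq)]
        mm = sum(1 for a, b in zip(oriented, ref) if a != b)
        out.append(ReadAlignment(rid, contig, start, orient, oriented, oqual, mm))
    return out


def gene_read_counts(
    alignments_by_sample: dict[str, list[ReadAlignment]], genes: pd.DataFrame
) -> pd.DataFrame:
    """Reads per gene per sample (a read counts for every gene span its
    start falls in) -- a minimal expression table for the control pool."""
    gene_rows = genes[genes["feature"] == "gene"]
    spans = {
        contig: sorted(
            (r.start, r.end, r.gene_id) for r in grp.itertuples(index=False)
        )
        for contig, grp in gene_rows.groupby("contig")
    }
    gene_ids = sorted(gene_rows["gene_id"].unique())
    table = {s: {g: 0 for g in gene_ids} for s in alignments_by_sample}
    for sample, alignments in alignments_by_sample.items():
        for aln in alignments:
            for start, end, gid in spans.get(aln.contig, ()):
                if start <= aln.start < end:
                    table[sample][gid] += 1
    df = pd.DataFrame({"gene_id": gene_ids})
    for sample in alignments_by_sample:
        df[sample] = [table[sample][g] for g in gene_ids]
    return df


def _load_file_inputs(cfg: RunConfig):
    inputs = cfg.inputs or {}
    for key in ("genome", "reads"):
        if key not in inputs:
            raise FileNotFoundError(f"pipeline input {key!r} missing from config")
    genome_path = Path(inputs["genome"])
    if not genome_path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    genome = load_reference(genome_path)
    reads = {}
    for cond, path in inputs["reads"].items():
        if not Path(path).exists():
            raise FileNotFoundError(f"reads FASTQ not found: {path}")
        reads[cond] = read_fastq(path)
    genes = None
    if inputs.get("gtf"):
        from thermedit.io_alignment import load_intervals

        by_feature = load_intervals(inputs["gtf"], "gtf")
        rows = []
        for feature, contigs in by_feature.items():
            for contig, tree in contigs.items():
                for iv in sorted(tree):
                    rows.append(
                        dict(contig=contig, feature=feature, start=iv.begin,
                             end=iv.end, strand=iv.data[1], gene_id=iv.data[0])
                    )
        genes = pd.DataFrame(rows)
    track = None
    if inputs.get("track"):
        from thermedit.site_context import load_track_tsv, load_wiggle

        path = str(inputs["track"])
        loader = load_wiggle if path.endswith((".wig", ".wiggle")) else load_track_tsv
        track = loader(path, genome)
    folds = None
    if inputs.get("folds"):
        from thermedit.io_alignment import load_intervals

        folds = load_intervals(inputs["folds"], "bed")
    return genome, genes, reads, track, folds


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the report dict and writes the bundle
    into ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    truth = None
    if cfg.inputs:
        genome, genes, reads_by_cond, track, folds = _load_file_inputs(cfg)
    else:
        if cfg.sim is None:
            raise ValueError("config has neither inputs nor a simulation section")
        sim = cfg.sim
        genome, genes = generate_genome(sim)
        truth = plant_editing_clusters(genome, sim)
        reads_by_cond = {}
        for cond in sim.condition_labels:
            reads, _ = simulate_reads(genome, truth, cond, sim)
            reads_by_cond[cond] = reads
        track = simulate_conservation_track(genome, truth, sim) if cfg.run_conservation else None
        folds = simulate_fold_intervals(truth, sim)
        write_fasta(genome, outdir / "genome.fa")
        write_gtf(genes, outdir / "genes.gtf")
        from thermedit.simulate import write_truth

        write_truth(truth, str(outdir / "truth"))
        for cond, reads in reads_by_cond.items():
            write_fastq(reads, outdir / f"reads_{cond}.fq")
    report = _run_stages(genome, genes, reads_by_cond, cfg, outdir,
                         truth=truth, track=track, folds=folds)
    _write_manifest(cfg, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report


def simulate_and_run(sim: SimConfig, cfg: RunConfig) -> dict:
    """Convenience wrapper: attach *sim* to *cfg* and run."""
    cfg.sim = sim
    cfg.inputs = None
    return run_pipeline(cfg)


def _run_stages(genome, genes, reads_by_cond, cfg: RunConfig, outdir: Path,
                truth=None, track=None, folds=None) -> dict:
    hyper = cfg.hyper_params()
    index = GenomeIndex(genome, hyper.align.seed_len)
    realigner = TransformedRealigner(genome, hyper.align)
    report: dict = {}
    sites_by_cond, clusters_by_cond = {}, {}
    alignments_by_cond = {}
    pooled_unaligned = []
    site_counts, cluster_stats = {}, {}
    for cond, reads in reads_by_cond.items():
        res = align_reads(reads, genome, hyper.align, index)
        clusters, det_stats = detect_editing(res.unaligned, genome, hyper, realigner)
        regions = merge_clusters_to_regions(clusters, hyper.max_gap)
        sites, summary = collect_sites(clusters)
        sites_by_cond[cond] = sites
        clusters_by_cond[cond] = (clusters, regions)
        pooled_unaligned.extend(res.unaligned)
        recovered = recover_alignments(res.unaligned, realigner)
        alignments_by_cond[cond] = res.unique + recovered
        site_counts[cond] = summary["n_sites"]
        cluster_stats[cond] = {
            "n_clusters": summary["n_clusters"],
            "n_regions": len(regions),
            "events_per_site": summary["events_per_site"],
            "mean_cluster_length": summary["mean_cluster_length"],
            "mean_sites_per_cluster": summary["mean_sites_per_cluster"],
            "mean_region_length": (
                float(np.mean([r.end - r.start for r in regions]))
                if regions else float("nan")
            ),
            "strand_split": strand_split(sites),
            "alignment": {
                "unique": len(res.unique), "ambiguous": len(res.ambiguous),
                "unaligned": len(res.unaligned), "recovered": len(recovered),
            },
            "detection": det_stats,
        }
        if len(sites):
            out = sites.copy()
            write_sites(out, outdir / f"sites_{cond}.tsv")
            write_bed(
                [(r.contig, r.start, r.end, f"region{i}", r.n_events, r.strand)
                 for i, r in enumerate(regions)],
                outdir / f"regions_{cond}.bed",
            )
    report["site_counts"] = site_counts
    report["cluster_stats"] = cluster_stats
    # QC spectrum over the pooled unaligned reads of all conditions
    if cfg.run_qc_spectrum:
        spectrum, pos_hist = qc_mismatch_spectrum(
            pooled_unaligned, genome, hyper, realigner
        )
        spectrum.to_csv(outdir / "qc_mismatch_spectrum.tsv", sep="\t", index=False)
        pos_hist.to_csv(outdir / "qc_read_positions.tsv", sep="\t", index=False)
        report["mismatch_spectrum"] = spectrum
    else:
        report["mismatch_spectrum"] = None
    # union site list and pileups from unique + recovered alignments
    nonempty = {c: s for c, s in sites_by_cond.items() if len(s)}
    if nonempty:
        union = union_site_lists(*nonempty.values(), names=list(nonempty))
        write_sites(union, outdir / "sites_union.tsv")
        pileups = pileup_sites(
            alignments_by_cond, union, genome,
            quality_min=cfg.quality_min, trim=cfg.trim,
        )
        supported = filter_supported(pileups, cfg.min_reads, cfg.min_level)
        supported.to_csv(outdir / "pileups.tsv", sep="\t", index=False)
        report["editing_index"] = {
            cond: editing_index(supported, sample=cond).value
            for cond in reads_by_cond
        }
        all_sites = pd.concat(nonempty.values()).groupby(
            ["contig", "pos", "strand"], as_index=False
        )["n_events"].max()
    else:
        union, pileups, supported, all_sites = None, None, None, None
        report["editing_index"] = {}
    # motif over the union of called sites
    if all_sites is not None and len(all_sites):
        pfm, skipped = compute_motif(all_sites, genome)
        pfm.to_csv(outdir / "motif_pfm.tsv", sep="\t")
        report["motif"] = {"pfm": pfm.reset_index(), "n_skipped": skipped}
    else:
        report["motif"] = None
    # genomic categories per condition
    if genes is not None and nonempty:
        cat_frames = []
        annotated_union = annotate_sites(union, genes)
        for cond, sites in nonempty.items():
            ann = annotate_sites(sites, genes)
            dist = category_distribution(ann)
            dist.insert(0, "condition", cond)
            cat_frames.append(dist)
        categories = pd.concat(cat_frames, ignore_index=True)
        categories.to_csv(outdir / "categories.tsv", sep="\t", index=False)
        report["categories"] = categories
    else:
        annotated_union = None
        report["categories"] = None
    # differential editing
    if supported is not None and len(reads_by_cond) >= 2:
        diff = differential_sites(
            supported, min_cov=cfg.min_cov, min_delta=cfg.min_delta, q=cfg.q
        )
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        report["differential"] = {
            "n_tested": int(diff["p"].notna().sum()),
            "n_significant": int(diff["significant"].sum()),
        }
    else:
        report["differential"] = None
    # structure search around region midpoints
    if cfg.run_structure and nonempty:
        struct_frames = []
        for cond, (clusters, regions) in clusters_by_cond.items():
            if not regions:
                continue
            mids = pd.DataFrame(
                [
                    dict(contig=r.contig, pos=(r.start + r.end) // 2,
                         strand=r.strand, condition=cond)
                    for r in regions[: cfg.max_structure_sites]
                ]
            )
            struct_frames.append(search_sites(genome, mids, cfg.structure_params()))
        if struct_frames:
            matches = pd.concat(struct_frames, ignore_index=True)
            matches.to_csv(outdir / "structure_matches.tsv", sep="\t", index=False)
            report["structure"] = structure_summary(matches)
        else:
            report["structure"] = None
    else:
        report["structure"] = None
    # conservation profile
    if cfg.run_conservation and track is not None and all_sites is not None and len(all_sites):
        profile = conservation_profile(
            all_sites, track, genome, window=cfg.conservation_window,
            seed=int(stage_rng(cfg.seed, "track").integers(2**31)),
        )
        profile.to_csv(outdir / "conservation_profile.tsv", sep="\t")
        report["conservation"] = {
            "profile": profile.reset_index(), "n": profile.attrs["n"],
        }
    else:
        report["conservation"] = None
    # conserved-fold overlap
    if folds is not None and nonempty:
        report["evofold"] = {
            cond: dict(zip(("n_sites", "n_in_folds", "percent"),
                           evofold_overlap(sites, folds)))
            for cond, sites in nonempty.items()
        }
    else:
        report["evofold"] = None
    # gene-set bootstrap: edited genes vs the most-expressed control pool
    if (cfg.run_bootstrap and genes is not None and supported is not None
            and annotated_union is not None):
        expression = gene_read_counts(alignments_by_cond, genes)
        pool = top_expressed_pool(expression, 0.60)
        counts = gene_editing_counts(supported, annotated_union)
        target = sorted(set(annotated_union["gene_id"].dropna()) & set(counts["gene_id"]))
        if target and len(pool) >= len(target):
            pool_counts = expression[["gene_id"]].merge(counts, how="left").fillna(0)
            boot = geneset_editing_bootstrap(
                target, pool, pool_counts, B=cfg.bootstrap_B,
                seed=int(stage_rng(cfg.seed, "folds").integers(2**31)),
            )
            report["bootstrap"] = {
                "observed": boot.observed, "p": boot.p, "B": boot.B,
                "n_target": len(target), "n_pool": len(pool),
            }
        else:
            report["bootstrap"] = {"note": "target/pool too small", "n_target": len(target)}
    else:
        report["bootstrap"] = None
    # truth-based evaluation for synthetic runs
    if truth is not None:
        truth_keys = set(
            zip(truth.sites["contig"], truth.sites["pos"], truth.sites["strand"])
        )
        evaluation = {}
        for cond, sites in sites_by_cond.items():
            called = set(zip(sites["contig"], sites["pos"], sites["strand"]))
            tp = len(called & truth_keys)
            evaluation[cond] = {
                "n_truth": len(truth_keys), "n_called": len(called),
                "true_positives": tp,
                "sensitivity": tp / len(truth_keys) if truth_keys else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
            }
        report["evaluation"] = evaluation
    return report


def _write_manifest(cfg: RunConfig, outdir: Path) -> None:
    import scipy

    params = _jsonable(cfg.to_dict())
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "thermedit": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "seed": cfg.seed,
        "parameter_hash": digest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
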