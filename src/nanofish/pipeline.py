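"""End-to-end orchestration: simulate -> demux -> filter -> trim -> cluster
-> assign -> curate -> stats, with a reproducibility manifest.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so adding a stage never perturbs earlier stages' randomness. The
length/quality gate runs on barcode-trimmed reads (primers still attached),
the window the 180-250 bp gate brackets for a ~170 bp insert.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import curation, ecology, io, otu, readproc, simulate, taxonomy

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimulateConfig:
    n_species: int = 10
    n_identical_pairs: int = 0
    identity_range: tuple[float, float] = (0.80, 0.92)
    amplicon_length: int = 170
    n_replicates: int = 3
    reads_per_sample: int = 1000
    blank_reads: int = 50
    positive_reads: int = 200
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    chimera_rate: float = 0.01
    contaminant_rate: float = 0.005
    experiment_id: str = "EXP_A"


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    reads_path: str | None = None
    reference_path: str | None = None
    sample_sheet_path: str | None = None
    traits_path: str | None = None
    filter_params: readproc.FilterParams = field(default_factory=readproc.FilterParams)
    min_barcode_identity: float = 0.85
    primer_max_mismatch: int = 3
    read_identity_threshold: float = 0.97
    otu_identity_threshold: float = 0.97
    min_cluster_size: int = 5
    aln_params: taxonomy.AlignmentParams = field(default_factory=taxonomy.AlignmentParams)
    tax_params: taxonomy.TaxonomyParams = field(default_factory=taxonomy.TaxonomyParams)
    positive_control_species: str | None = None
    contaminant_threshold: float = 0.5
    rarefy_fraction: float = 0.9
    n_perm: int = 10_000
    run_diel_stats: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        sim = raw.pop("simulate", None)
        filt = raw.pop("filter_params", None)
        aln = raw.pop("aln_params", None)
        tax = raw.pop("tax_params", None)
        cfg = cls(**raw)
        if sim is not None:
            if "identity_range" in sim:
                sim["identity_range"] = tuple(sim["identity_range"])
            cfg.simulate = SimulateConfig(**sim)
        elif cfg.reads_path is None:
            cfg.simulate = None
        if filt is not None:
            cfg.filter_params = readproc.FilterParams(**filt)
        if aln is not None:
            cfg.aln_params = taxonomy.AlignmentParams(**aln)
        if tax is not None:
            cfg.tax_params = taxonomy.TaxonomyParams(**tax)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("reads_path", "reference_path", "sample_sheet_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"config: {name} missing or does not exist")
        if self.run_diel_stats and (
            self.traits_path is None or not Path(self.traits_path).exists()
        ):
            raise ValueError("config: diel stats requested but traits file missing")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # where outputs land is not semantic
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_inputs(config: PipelineConfig, outdir: Path):
    sim = config.simulate
    seed = stage_seed(config.seed, "simulate")
    panel = simulate.synth_reference_panel(
        n_species=sim.n_species,
        n_identical_pairs=sim.n_identical_pairs,
        target_identity_range=sim.identity_range,
        amplicon_length=sim.amplicon_length,
        seed=seed,
    )
    design = simulate.build_design(
        sim.n_replicates, include_blanks=True, include_positive=True,
        experiment_id=sim.experiment_id,
    )
    fish = [
        rec.species for rec in panel if rec.species != simulate.HUMAN_SPECIES
    ]
    # the positive control is a species outside the simulated community,
    # as with a single-species tissue control in a field experiment
    positive_species = fish[-1]
    community = fish[:-1] if len(fish) > 1 else fish
    profile = simulate.CommunityProfile.uniform(community)
    error = simulate.ErrorModel(sim.sub_rate, sim.ins_rate, sim.del_rate)
    reads, truth_frames = [], []
    for i, sample in enumerate(design):
        if sample.sample_type == "environmental":
            n, prof, contam = sim.reads_per_sample, profile, sim.contaminant_rate
        elif sample.is_blank:
            n = sim.blank_reads
            prof = simulate.CommunityProfile({positive_species: 1.0})
            contam = 1.0  # blanks carry only contaminant molecules
        else:
            n = sim.positive_reads
            prof = simulate.CommunityProfile({positive_species: 1.0})
            contam = 0.0
        result = simulate.simulate_sample(
            panel, prof, n, error,
            barcode_id=sample.barcode_id,
            sample_id=sample.sample_id,
            chimera_rate=sim.chimera_rate if sample.sample_type == "environmental" else 0.0,
            contaminant_rate=contam,
            seed=stage_seed(config.seed, f"simulate:{sample.sample_id}"),
        )
        reads.extend(result.reads)
        truth_frames.append(result.truth)
    io.write_fastq(reads, outdir / "reads.fastq")
    io.write_reference_fasta(panel, outdir / "references.fasta")
    io.write_sample_sheet(design, outdir / "samples.csv")
    import pandas as pd

    pd.concat(truth_frames, ignore_index=True).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    return reads, panel, design, positive_species


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        reads, panel, design, sim_positive = _simulate_inputs(config, outdir)
        positive_species = config.positive_control_species or sim_positive
    else:
        reads = list(io.read_fastq(config.reads_path))
        panel = io.read_reference_fasta(config.reference_path)
        design = io.read_sample_sheet(config.sample_sheet_path)
        positive_species = config.positive_control_species
    manifest["stages"]["input"] = {"reads": len(reads)}

    # --- demultiplex (trims barcodes) -------------------------------------
    barcodes = simulate.barcode_table()
    used = {s.barcode_id: s.sample_id for s in design}
    demux_params = readproc.DemuxParams(
        barcodes={bc: barcodes[bc] for bc in used},
        min_barcode_identity=config.min_barcode_identity,
    )
    demux = readproc.demultiplex(reads, demux_params, sample_map=used)
    n_assigned = sum(len(v) for v in demux.assigned.values())
    manifest["stages"]["demux"] = {
        "input": len(reads),
        "assigned": n_assigned,
        **{f"discarded_{k}": len(v) for k, v in demux.discarded.items()},
    }

    # --- quality/length filter, primer trim -------------------------------
    per_sample_inserts: dict[str, list] = {}
    filt_stats = {"input": n_assigned, "kept": 0}
    trim_stats = {"kept": 0, "no_primer": 0}
    for sample_id, sample_reads in demux.assigned.items():
        kept, rejected = readproc.filter_reads(sample_reads, config.filter_params)
        for reason, count in rejected.items():
            filt_stats[reason] = filt_stats.get(reason, 0) + count
        filt_stats["kept"] += len(kept)
        inserts, trim_rej = readproc.trim_primers(
            kept, max_mismatch=config.primer_max_mismatch
        )
        trim_stats["kept"] += len(inserts)
        trim_stats["no_primer"] += trim_rej.get("no_primer", 0)
        per_sample_inserts[sample_id] = inserts
    manifest["stages"]["filter"] = filt_stats
    manifest["stages"]["trim"] = trim_stats

    # --- two-round clustering ---------------------------------------------
    read_params = otu.ClusterParams(
        config.read_identity_threshold, config.min_cluster_size
    )
    consensuses = []
    n_unclustered = 0
    for sample_id, inserts in per_sample_inserts.items():
        if not inserts:
            continue
        pairs = [(r.read_id, r.sequence) for r in inserts]
        cons, outcome = otu.cluster_sample(pairs, read_params, sample_id=sample_id)
        consensuses.extend(cons)
        n_unclustered += len(outcome.unclustered_ids)
    otus = otu.recluster_consensuses(
        consensuses, otu.ClusterParams(config.otu_identity_threshold, 1)
    )
    table = otu.build_otu_table(otus, design)
    manifest["stages"]["cluster"] = {
        "input": trim_stats["kept"],
        "consensuses": len(consensuses),
        "otus": len(otus),
        "clustered_reads": int(table.counts.to_numpy().sum()),
        "unclustered_reads": n_unclustered,
    }

    # --- taxonomy ----------------------------------------------------------
    collapsed = taxonomy.collapse_indistinguishable(panel)
    annotated = taxonomy.assign_otu_table(
        table, collapsed, config.aln_params, config.tax_params
    )
    io.write_count_table(annotated, outdir / "otu_table.tsv")
    species_table = taxonomy.aggregate_to_species(annotated, config.tax_params)
    io.write_count_table(species_table, outdir / "species_table.tsv")
    manifest["stages"]["assign"] = {
        "otus": len(annotated.row_ids),
        "species": len(species_table.row_ids),
    }

    # --- curation ----------------------------------------------------------
    control_taxa = [simulate.HUMAN_SPECIES]
    if positive_species:
        control_taxa.append(positive_species)
    cur_params = curation.CurationParams(
        control_taxa=control_taxa,
        contaminant_threshold=config.contaminant_threshold,
        rarefy_fraction=config.rarefy_fraction,
        seed=stage_seed(config.seed, "curate"),
    )
    curated, removed = curation.curate(species_table, cur_params)
    io.write_count_table(curated, outdir / "curated_table.tsv")
    with open(outdir / "removal_report.tsv", "w") as handle:
        handle.write("label\treason\treads_removed\tscore\n")
        for rec in removed:
            score = "." if rec.score is None else repr(rec.score)
            handle.write(f"{rec.label}\t{rec.reason}\t{rec.reads_removed}\t{score}\n")
    manifest["stages"]["curate"] = {
        "rows_removed": len(removed),
        "rows_kept": len(curated.row_ids),
        "samples_kept": len(curated.col_ids),
        "depth": int(curated.counts.sum(axis=0).iloc[0]) if curated.col_ids else 0,
    }

    # --- statistics --------------------------------------------------------
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    diversity = ecology.alpha_diversity(curated)
    diversity.to_csv(stats_dir / "alpha_diversity.tsv", sep="\t")
    if len(curated.col_ids) >= 2:
        distances = ecology.jaccard_matrix(curated)
        import pandas as pd

        pd.DataFrame(
            distances.values, index=distances.labels, columns=distances.labels
        ).to_csv(stats_dir / "jaccard.tsv", sep="\t")
        curve = ecology.accumulation_curve(
            curated, seed=stage_seed(config.seed, "stats")
        )
        curve.to_csv(stats_dir / "accumulation.tsv", sep="\t", index=False)
    if config.run_diel_stats:
        traits = io.read_activity_traits(config.traits_path)
        ecology.diel_ratios(curated, traits).to_csv(
            stats_dir / "diel_ratios.tsv", sep="\t"
        )
    manifest["stages"]["stats"] = {"samples": len(curated.col_ids)}

    manifest_blob = json.dumps(manifest, sort_keys=True, indent=2)
    manifest["manifest_hash"] = hashlib.sha256(manifest_blob.encode()).hexdigest()[:16]
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, sort_keys=True, indent=2)
    return manifest
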