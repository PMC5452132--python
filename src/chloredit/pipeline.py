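"""End-to-end orchestration: simulate -> align -> call-edits -> expression
-> qpcr, with a single YAML-able config, per-stage outputs under a fixed
run-directory layout, and a machine-readable manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chloredit import __version__, align_filter, edit_call, expression, qpcr
from chloredit import synthetic_data as synth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 42
    outdir: str = "chloredit_run"

    # synthetic genome
    cp_length: int = 8_000
    n_genes: int = 8
    cds_length: int = 400
    n_trnas: int = 4
    trna_length: int = 80
    nuclear_length: int = 12_000
    mito_length: int = 6_000

    # optional pre-existing references (FASTA); when set, simulation of the
    # genome is skipped and these files are loaded instead
    chloroplast_fasta: str | None = None
    cds_fasta: str | None = None
    trna_fasta: str | None = None
    nuclear_fasta: str | None = None
    mito_fasta: str | None = None

    # planted editing
    n_sites: int = 8
    n_diff_sites: int = 4
    base_fraction: float = 0.4
    fraction_delta: float = 0.25

    # libraries
    n_reads_per_library: int = 3_000
    read_length_range: tuple[int, int] = (18, 24)
    error_rate: float = 0.005
    offtarget_fraction: float = 0.1

    # thresholds
    max_mismatch: int = 2
    min_coverage: int = 5
    max_variant_p: float = 1e-2
    min_total_coverage: int = 4
    variant_error_rate: float = 0.01
    min_efficiency: float = 1.75
    alpha: float = 0.05
    min_read_length: int = 15

    # qPCR simulation
    qpcr_n_bio: int = 3
    qpcr_n_tech: int = 4
    qpcr_n_sites: int = 4
    qpcr_efficiency: float = 2.0
    qpcr_noise_sd: float | None = None

    libraries: dict[str, str] = field(
        default_factory=lambda: {
            "Cnt-1": "control",
            "Cnt-2": "control",
            "Salt-1": "salt",
            "Salt-2": "salt",
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.max_variant_p <= 1 or not 0 < self.alpha < 1:
            raise ValueError("p thresholds must lie in (0, 1]")
        if self.max_mismatch not in (0, 1, 2):
            raise ValueError("max_mismatch must be 0, 1 or 2")
        if self.min_coverage < 1 or self.min_total_coverage < 0:
            raise ValueError("coverage thresholds out of range")
        if not 1.0 <= self.min_efficiency <= 2.0:
            raise ValueError("min_efficiency must lie in [1, 2]")
        if self.n_diff_sites > self.n_sites:
            raise ValueError("n_diff_sites cannot exceed n_sites")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "read_length_range" in data:
            data["read_length_range"] = tuple(data["read_length_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["read_length_range"] = list(self.read_length_range)
        return d


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"reference FASTA not found: {p}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), "fasta")}


def _load_or_generate_genomes(config: RunConfig, seed: int) -> synth.GenomeSet:
    fasta_fields = (
        config.chloroplast_fasta,
        config.cds_fasta,
        config.trna_fasta,
        config.nuclear_fasta,
        config.mito_fasta,
    )
    if any(fasta_fields):
        if not all(fasta_fields):
            raise ValueError(
                "either all five reference FASTAs must be given, or none"
            )
        cp = next(iter(_read_fasta(config.chloroplast_fasta).values()))
        cds_seqs = _read_fasta(config.cds_fasta)
        # external CDSs: locate each on the genome to recover intervals
        cds_set = {}
        for gene, seq in cds_seqs.items():
            start = cp.find(seq)
            strand = "+"
            if start == -1:
                start = cp.find(synth.reverse_complement(seq))
                strand = "-"
            if start == -1:
                raise ValueError(f"CDS {gene} not found on the chloroplast genome")
            cds_set[gene] = synth.CdsRecord(gene, seq, start, start + len(seq), strand)
        gs = synth.GenomeSet(
            chloroplast_genome=cp,
            cds_set=cds_set,
            trna_set=_read_fasta(config.trna_fasta),
            nuclear_genome=next(iter(_read_fasta(config.nuclear_fasta).values())),
            mito_genome=next(iter(_read_fasta(config.mito_fasta).values())),
        )
        gs.validate()
        return gs
    return synth.generate_genome_set(
        synth.GenomeConfig(
            cp_length=config.cp_length,
            n_genes=config.n_genes,
            cds_length=config.cds_length,
            n_trnas=config.n_trnas,
            trna_length=config.trna_length,
            nuclear_length=config.nuclear_length,
            mito_length=config.mito_length,
            seed=seed,
        )
    )


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns a map of output names to paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # deterministic per-stage seeds derived from the master seed
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(8)]

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc

        return deco

    @stage("simulate-genomes")
    def genomes() -> synth.GenomeSet:
        gs = _load_or_generate_genomes(config, stage_seeds[0])
        refdir = out / "refs"
        for name, p in synth.write_genome_fastas(gs, refdir).items():
            paths[f"ref_{name}"] = p
        return gs

    @stage("simulate-sites")
    def sites():
        per_site = []
        for i in range(config.n_sites):
            f0 = config.base_fraction
            delta = config.fraction_delta if i < config.n_diff_sites else 0.0
            per_site.append({"control": f0, "salt": min(1.0, f0 + delta)})
        recs = synth.generate_site_table(
            genomes, config.n_sites, per_site, seed=stage_seeds[1]
        )
        paths["sites"] = out / "sites.tsv"
        synth.write_site_table(recs, paths["sites"])
        return recs

    @stage("simulate-reads")
    def libraries():
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        libs = {}
        for i, (lib_id, condition) in enumerate(sorted(config.libraries.items())):
            profile = synth.LibraryProfile(
                library_id=lib_id,
                condition=condition,
                n_reads=config.n_reads_per_library,
                read_length_range=config.read_length_range,
                error_rate=config.error_rate,
                offtarget_fraction=config.offtarget_fraction,
                seed=stage_seeds[2] + i,
            )
            fq = reads_dir / f"{lib_id}.fastq"
            truth = reads_dir / f"{lib_id}.truth.tsv"
            libs[lib_id] = synth.simulate_read_library(genomes, sites, profile, fq, truth)
            paths[f"fastq_{lib_id}"] = fq
            paths[f"truth_{lib_id}"] = truth
        return libs

    @stage("align")
    def aligned():
        align_dir = out / "align"
        align_dir.mkdir(exist_ok=True)
        cds_seqs = genomes.cds_sequences()
        per_lib = {}
        for lib_id, reads in sorted(libraries.items()):
            read_map = {r.read_id: r.sequence for r in reads}
            sets = align_filter.hierarchical_filter(
                read_map,
                genomes,
                max_mismatch=config.max_mismatch,
                min_read_length=config.min_read_length,
            )
            manifest = align_dir / f"{lib_id}.readsets.tsv"
            align_filter.write_readset_manifest(sets, manifest)
            paths[f"readsets_{lib_id}"] = manifest
            retained = {rid: read_map[rid] for rid in sets.cp_m0_m2}
            sam = align_dir / f"{lib_id}.cds.sam"
            per_lib[lib_id] = align_filter.realign_to_cds(
                retained,
                cds_seqs,
                max_mismatch=config.max_mismatch,
                sam_path=sam,
                min_read_length=config.min_read_length,
            )
            paths[f"sam_{lib_id}"] = sam
        return per_lib

    @stage("call-edits")
    def edit_report():
        pileups = edit_call.pileup_sites(aligned, sites, genomes.cds_sequences())
        stats = edit_call.compute_site_stats(
            pileups,
            sites,
            config.libraries,
            error_rate=config.variant_error_rate,
            min_coverage=config.min_coverage,
            max_p=config.max_variant_p,
        )
        report = edit_call.select_sites(
            stats,
            min_total_coverage=config.min_total_coverage,
            library_order=sorted(config.libraries),
        )
        edits_dir = out / "edits"
        edits_dir.mkdir(exist_ok=True)
        paths["edit_report"] = edits_dir / "editing_sites.tsv"
        edit_call.write_report(report, paths["edit_report"])
        return report

    @stage("expression")
    def de_results():
        expr_dir = out / "expression"
        expr_dir.mkdir(exist_ok=True)
        cm = expression.build_count_table(aligned, sorted(genomes.cds_set))
        paths["counts"] = expr_dir / "counts.tsv"
        cm.counts.to_csv(paths["counts"], sep="\t")
        size_factors, normalized = expression.normalize_median_ratios(cm.counts)
        paths["normalized"] = expr_dir / "normalized.tsv"
        expression.write_heatmap_matrix(normalized, paths["normalized"])
        groups: dict[str, list[str]] = {"control": [], "salt": []}
        for lib, cond in sorted(config.libraries.items()):
            groups[cond].append(lib)
        de = expression.differential_test(normalized, groups)
        paths["de"] = expr_dir / "differential_expression.tsv"
        de.to_csv(paths["de"], sep="\t", index=False, float_format="%.6g")
        return de

    @stage("qpcr")
    def qpcr_results():
        qdir = out / "qpcr"
        qdir.mkdir(exist_ok=True)
        chosen = sites[: config.qpcr_n_sites]
        site_names = [f"{s.gene_id}-{s.cds_position}" for s in chosen]
        design = synth.make_plate_design(
            site_names,
            timepoints=("4h", "24h"),
            n_bio=config.qpcr_n_bio,
            n_tech=config.qpcr_n_tech,
            efficiency=config.qpcr_efficiency,
        )
        fractions = {}
        for s, name in zip(chosen, site_names):
            for w in design:
                if w.site != name:
                    continue
                f = s.true_fraction_by_condition.get(w.treatment, 0.0)
                fractions[(name, w.sample)] = f
        params = synth.PlateParams(noise_sd=config.qpcr_noise_sd)
        paths["plate"] = qdir / "plate.csv"
        paths["plate_map"] = qdir / "plate_map.csv"
        synth.simulate_qpcr_plate(
            design,
            fractions,
            params,
            seed=stage_seeds[5],
            plate_csv=paths["plate"],
            map_csv=paths["plate_map"],
        )
        reactions, fracs, comparison = qpcr.analyze_plate(
            paths["plate"],
            paths["plate_map"],
            min_efficiency=config.min_efficiency,
            alpha=config.alpha,
        )
        paths["qpcr_fractions"] = qdir / "fractions.tsv"
        fracs.to_csv(paths["qpcr_fractions"], sep="\t", index=False, float_format="%.6g")
        paths["qpcr_comparison"] = qdir / "comparison.tsv"
        comparison.to_csv(
            paths["qpcr_comparison"], sep="\t", index=False, float_format="%.6g"
        )
        paths["qpcr_efficiency"] = qdir / "primer_efficiency.tsv"
        qpcr.primer_efficiency_report(reactions).to_csv(
            paths["qpcr_efficiency"], sep="\t", index=False, float_format="%.6g"
        )
        return comparison

    @stage("manifest")
    def manifest():
        import numpy
        import pandas
        import scipy

        readset_counts = {}
        for lib_id in sorted(config.libraries):
            mpath = paths.get(f"readsets_{lib_id}")
            if mpath is not None:
                counts: dict[str, int] = {}
                with open(mpath) as fh:
                    next(fh)
                    for line in fh:
                        counts[line.rsplit("\t", 1)[1].strip()] = (
                            counts.get(line.rsplit("\t", 1)[1].strip(), 0) + 1
                        )
                readset_counts[lib_id] = counts
        data = {
            "chloredit_version": __version__,
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
            "seed": config.seed,
            "config": config.to_dict(),
            "readset_counts": readset_counts,
            "outputs": {k: str(v) for k, v in sorted(paths.items())},
        }
        mpath = out / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = mpath
        return mpath

    return paths
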