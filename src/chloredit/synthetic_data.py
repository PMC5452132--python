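"""Seeded generators for every input the pipeline consumes.

Produces reference genomes (chloroplast + decoys), editing-site tables with
planted per-condition editing fractions, FASTQ read libraries with matching
truth tables, and qPCR amplification plates whose Ct values encode
edited/unedited template ratios. Everything is deterministic for a fixed
seed, and outputs are written as plain text (FASTA/FASTQ/TSV/CSV).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONDITIONS = ("control", "salt")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Reference genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdsRecord:
    """A chloroplast coding sequence with its genomic interval.

    ``sequence`` is the sense (transcript) strand: the genome substring at
    ``[start, end)`` for '+' features, its reverse complement for '-'.
    """

    gene_id: str
    sequence: str
    start: int  # 0-based on the chloroplast genome
    end: int  # half-open
    strand: str  # '+' or '-'


@dataclass
class GenomeSet:
    """Chloroplast genome + CDS/tRNA set and nuclear/mitochondrial decoys."""

    chloroplast_genome: str
    cds_set: dict[str, CdsRecord]
    trna_set: dict[str, str]
    nuclear_genome: str
    mito_genome: str

    def validate(self) -> None:
        allowed = set("ACGT")
        for name, seq in [
            ("chloroplast_genome", self.chloroplast_genome),
            ("nuclear_genome", self.nuclear_genome),
            ("mito_genome", self.mito_genome),
            *((f"tRNA {k}", v) for k, v in self.trna_set.items()),
        ]:
            if not set(seq) <= allowed:
                raise ValueError(f"{name} contains non-ACGT characters")
        for cds in self.cds_set.values():
            sub = self.chloroplast_genome[cds.start : cds.end]
            if cds.strand == "-":
                sub = reverse_complement(sub)
            if sub != cds.sequence:
                raise ValueError(
                    f"CDS {cds.gene_id} does not match its genomic interval"
                )

    def cds_sequences(self) -> dict[str, str]:
        return {g: c.sequence for g, c in self.cds_set.items()}


@dataclass(frozen=True)
class GenomeConfig:
    cp_length: int = 20_000
    n_genes: int = 10
    cds_length: int = 600
    n_trnas: int = 5
    trna_length: int = 80
    nuclear_length: int = 30_000
    mito_length: int = 10_000
    n_shared_kmers: int = 2
    shared_kmer_length: int = 25
    seed: int = 0


def generate_genome_set(config: GenomeConfig) -> GenomeSet:
    """Generate a GenomeSet with non-overlapping CDS intervals.

    Raises ``ValueError`` if the requested CDSs cannot be packed into the
    chloroplast genome.
    """
    total_cds = config.n_genes * config.cds_length
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if total_cds > config.cp_length:
        raise ValueError(
            f"cannot pack {config.n_genes} CDSs of {config.cds_length} nt "
            f"into a {config.cp_length} nt chloroplast genome"
        )
    rng = np.random.default_rng(config.seed)
    genome = _random_seq(rng, config.cp_length)

    # random non-overlapping placement: spread the slack over the gaps
    slack = config.cp_length - total_cds
    gaps = rng.multinomial(slack, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))
    cds_set: dict[str, CdsRecord] = {}
    pos = 0
    for i in range(config.n_genes):
        pos += int(gaps[i])
        start, end = pos, pos + config.cds_length
        strand = "+" if rng.random() < 0.5 else "-"
        sub = genome[start:end]
        seq = reverse_complement(sub) if strand == "-" else sub
        gene_id = f"gene{i + 1:02d}"
        cds_set[gene_id] = CdsRecord(gene_id, seq, start, end, strand)
        pos = end

    trna_set = {
        f"trna{i + 1:02d}": _random_seq(rng, config.trna_length)
        for i in range(config.n_trnas)
    }

    nuclear = _random_seq(rng, config.nuclear_length)
    mito = _random_seq(rng, config.mito_length)
    # plant chloroplast k-mers in the nuclear decoy to exercise subtraction
    # order (chloroplast wins in round 1)
    if config.n_shared_kmers > 0 and config.shared_kmer_length < config.cp_length:
        nuc = list(nuclear)
        for _ in range(config.n_shared_kmers):
            src = int(rng.integers(0, config.cp_length - config.shared_kmer_length + 1))
            dst = int(
                rng.integers(0, config.nuclear_length - config.shared_kmer_length + 1)
            )
            kmer = genome[src : src + config.shared_kmer_length]
            nuc[dst : dst + config.shared_kmer_length] = kmer
        nuclear = "".join(nuc)

    gs = GenomeSet(genome, cds_set, trna_set, nuclear, mito)
    gs.validate()
    return gs


# ---------------------------------------------------------------------------
# Editing-site tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditingSiteRecord:
    """One predicted C->U site on a plastid CDS.

    ``cds_position`` is 1-based within the CDS (site tables follow the
    1-based convention). ``true_fraction_by_condition`` holds the simulation
    ground truth and is absent (empty) for real inputs.
    """

    gene_id: str
    cds_position: int
    score: float
    ref_base: str = "C"
    edited_base: str = "T"
    true_fraction_by_condition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_base != "C" or self.edited_base != "T":
            raise ValueError("editing sites must be C->T")
        if self.cds_position < 1:
            raise ValueError("cds_position is 1-based and must be >= 1")
        for f in self.true_fraction_by_condition.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("editing fractions must lie in [0, 1]")


def generate_site_table(
    genomes: GenomeSet,
    n_sites: int,
    fractions: Mapping[str, float] | Sequence[Mapping[str, float]],
    seed: int = 0,
    score_cutoff: float = 0.5,
    min_flank: int = 0,
) -> list[EditingSiteRecord]:
    """Pick ``n_sites`` C positions across the CDS set and plant fractions.

    ``fractions`` is either one condition->fraction map (applied to every
    site) or a sequence of ``n_sites`` such maps. Scores are sampled
    uniformly in [score_cutoff, 1]. ``min_flank`` keeps sites at least that
    many nt away from the CDS ends (useful for read-coverage uniformity and
    primer design).
    """
    rng = np.random.default_rng(seed)
    candidates = [
        (gene_id, i + 1)
        for gene_id, cds in sorted(genomes.cds_set.items())
        for i, base in enumerate(cds.sequence)
        if base == "C" and min_flank <= i < len(cds.sequence) - min_flank
    ]
    if len(candidates) < n_sites:
        raise ValueError(
            f"only {len(candidates)} C positions available for {n_sites} sites"
        )
    if isinstance(fractions, Mapping):
        per_site = [dict(fractions)] * n_sites
    else:
        per_site = [dict(f) for f in fractions]
        if len(per_site) != n_sites:
            raise ValueError("need one fraction map per site")

    chosen_idx = rng.choice(len(candidates), size=n_sites, replace=False)
    chosen = sorted(
        (candidates[int(i)], per_site[j] ) for j, i in enumerate(chosen_idx)
    )
    scores = rng.uniform(score_cutoff, 1.0, size=n_sites)
    return [
        EditingSiteRecord(
            gene_id=gene,
            cds_position=pos,
            score=round(float(s), 3),
            true_fraction_by_condition=frac,
        )
        for ((gene, pos), frac), s in zip(chosen, scores)
    ]


def write_site_table(sites: Sequence[EditingSiteRecord], path: str | Path) -> None:
    conditions = sorted({c for s in sites for c in s.true_fraction_by_condition})
    with open(path, "w") as fh:
        cols = ["gene_id", "cds_position", "score", "ref_base", "edited_base"]
        cols += [f"true_frac_{c}" for c in conditions]
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [s.gene_id, str(s.cds_position), f"{s.score:g}", s.ref_base, s.edited_base]
            row += [f"{s.true_fraction_by_condition[c]:g}" for c in conditions]
            fh.write("\t".join(row) + "\n")


def read_site_table(path: str | Path) -> list[EditingSiteRecord]:
    df = pd.read_csv(path, sep="\t")
    cond_cols = [c for c in df.columns if c.startswith("true_frac_")]
    sites = []
    for _, row in df.iterrows():
        fracs = {c[len("true_frac_"):]: float(row[c]) for c in cond_cols}
        sites.append(
            EditingSiteRecord(
                gene_id=str(row["gene_id"]),
                cds_position=int(row["cds_position"]),
                score=float(row["score"]),
                ref_base=str(row.get("ref_base", "C")),
                edited_base=str(row.get("edited_base", "T")),
                true_fraction_by_condition=fracs,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Read libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryProfile:
    """Parameters of one simulated sequencing library."""

    library_id: str
    condition: str
    n_reads: int
    read_length_range: tuple[int, int] = (18, 24)
    error_rate: float = 0.0
    offtarget_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.read_length_range[0] < 15:
            raise ValueError("read lengths must be >= 15 nt")
        if self.read_length_range[0] > self.read_length_range[1]:
            raise ValueError("read_length_range must be (min, max) with min <= max")
        if not 0.0 <= self.offtarget_fraction <= 1.0:
            raise ValueError("offtarget_fraction must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin: str  # cds | trna | nuclear | mito
    target_id: str
    start: int  # 0-based on the origin sequence
    # (gene_id, cds_position, edited?) for each covered editing site
    edited_sites: tuple[tuple[str, int, bool], ...]
    n_errors: int


def simulate_read_library(
    genomes: GenomeSet,
    sites: Sequence[EditingSiteRecord],
    profile: LibraryProfile,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> list[SimulatedRead]:
    """Draw forward-strand reads from transcripts (CDS/tRNA) and decoys.

    At every covered editing site the base is T with the site's planted
    fraction for ``profile.condition`` (C otherwise), then uniform per-base
    substitution errors are injected at ``profile.error_rate``.
    """
    rng = np.random.default_rng(profile.seed)
    lmin, lmax = profile.read_length_range

    transcripts = [
        *(("cds", g, c.sequence) for g, c in sorted(genomes.cds_set.items())),
        *(("trna", t, seq) for t, seq in sorted(genomes.trna_set.items())),
    ]
    transcripts = [t for t in transcripts if len(t[2]) >= lmin]
    if not transcripts:
        raise ValueError("no transcript long enough for the requested read length")
    decoys = [
        ("nuclear", "nuclear_genome", genomes.nuclear_genome),
        ("mito", "mito_genome", genomes.mito_genome),
    ]
    t_weights = np.array([len(s) for _, _, s in transcripts], dtype=float)
    t_weights /= t_weights.sum()
    d_weights = np.array([len(s) for _, _, s in decoys], dtype=float)
    d_weights /= d_weights.sum()

    sites_by_gene: dict[str, list[EditingSiteRecord]] = {}
    for s in sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    reads: list[SimulatedRead] = []
    for i in range(profile.n_reads):
        offtarget = rng.random() < profile.offtarget_fraction
        pool, weights = (decoys, d_weights) if offtarget else (transcripts, t_weights)
        origin, target_id, seq = pool[int(rng.choice(len(pool), p=weights))]
        length = int(rng.integers(lmin, min(lmax, len(seq)) + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        bases = list(seq[start : start + length])

        covered: list[tuple[str, int, bool]] = []
        if origin == "cds":
            for site in sites_by_gene.get(target_id, ()):
                off = site.cds_position - 1 - start
                if 0 <= off < length:
                    f = site.true_fraction_by_condition.get(profile.condition, 0.0)
                    edited = bool(rng.random() < f)
                    bases[off] = site.edited_base if edited else site.ref_base
                    covered.append((site.gene_id, site.cds_position, edited))

        n_errors = 0
        if profile.error_rate > 0:
            err_mask = rng.random(length) < profile.error_rate
            for j in np.flatnonzero(err_mask):
                alt = [b for b in "ACGT" if b != bases[j]]
                bases[j] = alt[int(rng.integers(0, 3))]
                n_errors += 1

        reads.append(
            SimulatedRead(
                read_id=f"{profile.library_id}_r{i:06d}",
                sequence="".join(bases),
                origin=origin,
                target_id=target_id,
                start=start,
                edited_sites=tuple(covered),
                n_errors=n_errors,
            )
        )

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        write_truth_table(reads, truth_path)
    return reads


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    # constant quality: quality strings are unused downstream
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_table(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\ttarget_id\tstart\tlength\tedited_sites\tn_errors\n")
        for r in reads:
            ed = (
                ",".join(f"{g}:{p}={int(e)}" for g, p, e in r.edited_sites)
                if r.edited_sites
                else "."
            )
            fh.write(
                f"{r.read_id}\t{r.origin}\t{r.target_id}\t{r.start}\t"
                f"{len(r.sequence)}\t{ed}\t{r.n_errors}\n"
            )


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellDesign:
    """One well of the simulated plate (one allele-specific reaction)."""

    well_id: str
    site: str  # e.g. "gene03-149"
    allele: str  # 'C' (unedited) or 'T' (edited)
    treatment: str
    timepoint: str = "4h"
    sample: str = "s1"  # biological replicate id
    replicate: int = 1  # technical replicate index
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.allele not in ("C", "T"):
            raise ValueError("allele must be 'C' or 'T'")
        if not 1.0 < self.efficiency <= 2.05:
            raise ValueError("efficiency must lie in (1, 2.05]")


@dataclass(frozen=True)
class PlateParams:
    n_cycles: int = 40
    baseline: float = 100.0
    fmax: float = 10_000.0
    k: float = 1.0
    template: float = 1e-6  # total template amount N per sample
    noise_sd: float | None = None  # default: 0.5% of fmax

    def resolved_noise_sd(self) -> float:
        return 0.005 * self.fmax if self.noise_sd is None else self.noise_sd


def amplification_curve(
    n_cycles: int,
    n0: float,
    efficiency: float,
    baseline: float = 100.0,
    fmax: float = 10_000.0,
    k: float = 1.0,
) -> np.ndarray:
    """Noise-free saturating-exponential model F(c) = b + Fmax*N0*E^c / (N0*E^c + K)."""
    c = np.arange(1, n_cycles + 1, dtype=float)
    x = n0 * efficiency**c
    return baseline + fmax * x / (x + k)


def make_plate_design(
    sites: Sequence[str],
    treatments: Sequence[str] = CONDITIONS,
    timepoints: Sequence[str] = ("4h",),
    n_bio: int = 3,
    n_tech: int = 4,
    efficiency: float | Mapping[str, float] = 2.0,
) -> list[WellDesign]:
    """Lay out quadruplicate C/T reactions on 384-well ids (A01..P24)."""
    rows = string.ascii_uppercase[:16]
    well_ids = [f"{r}{c:02d}" for r in rows for c in range(1, 25)]
    wells: list[WellDesign] = []
    i = 0
    for site in sites:
        for tp in timepoints:
            for trt in treatments:
                for b in range(1, n_bio + 1):
                    for allele in ("T", "C"):
                        for rep in range(1, n_tech + 1):
                            if i >= len(well_ids):
                                raise ValueError("design exceeds 384 wells")
                            eff = (
                                efficiency[site]
                                if isinstance(efficiency, Mapping)
                                else efficiency
                            )
                            wells.append(
                                WellDesign(
                                    well_id=well_ids[i],
                                    site=site,
                                    allele=allele,
                                    treatment=trt,
                                    timepoint=tp,
                                    sample=f"{trt}-{tp}-b{b}",
                                    replicate=rep,
                                    efficiency=eff,
                                )
                            )
                            i += 1
    return wells


def simulate_qpcr_plate(
    design: Sequence[WellDesign],
    fractions: Mapping[tuple[str, str], float] | Mapping[str, float],
    params: PlateParams = PlateParams(),
    seed: int = 0,
    plate_csv: str | Path | None = None,
    map_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fluorescence curves for every well of ``design``.

    ``fractions`` maps (site, sample) -> planted edited fraction f, or
    site -> f to broadcast over samples. The edited-allele well of a sample
    amplifies template f*N, the unedited well (1-f)*N.

    Returns (plate long table: well,cycle,fluorescence; plate map).
    """
    if not design:
        raise ValueError("empty plate design")
    rng = np.random.default_rng(seed)
    sd = params.resolved_noise_sd()

    def frac_for(w: WellDesign) -> float:
        if (w.site, w.sample) in fractions:  # type: ignore[operator]
            f = fractions[(w.site, w.sample)]  # type: ignore[index]
        elif w.site in fractions:  # type: ignore[operator]
            f = fractions[w.site]  # type: ignore[index]
        else:
            raise KeyError(f"no planted fraction for site {w.site!r}")
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"planted fraction {f} outside [0, 1]")
        return float(f)

    if params.template <= 0:
        raise ValueError("template amount must be > 0")

    plate_rows = []
    map_rows = []
    for w in design:
        f = frac_for(w)
        n0 = (f if w.allele == "T" else 1.0 - f) * params.template
        curve = amplification_curve(
            params.n_cycles, n0, w.efficiency, params.baseline, params.fmax, params.k
        )
        if sd > 0:
            curve = curve + rng.normal(0.0, sd, size=params.n_cycles)
        for cyc, fl in enumerate(curve, start=1):
            plate_rows.append((w.well_id, cyc, round(float(fl), 4)))
        map_rows.append(
            (w.well_id, w.site, w.allele, w.treatment, w.timepoint, w.sample, w.replicate)
        )

    plate_df = pd.DataFrame(plate_rows, columns=["well", "cycle", "fluorescence"])
    map_df = pd.DataFrame(
        map_rows,
        columns=["well", "site", "allele", "treatment", "timepoint", "sample", "replicate"],
    )
    if plate_csv is not None:
        plate_df.to_csv(plate_csv, index=False)
    if map_csv is not None:
        map_df.to_csv(map_csv, index=False)
    return plate_df, map_df


# ---------------------------------------------------------------------------
# FASTA output
# ---------------------------------------------------------------------------


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_fastas(genomes: GenomeSet, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chloroplast": outdir / "chloroplast.fasta",
        "cds": outdir / "cds.fasta",
        "trna": outdir / "trna.fasta",
        "nuclear": outdir / "nuclear.fasta",
        "mito": outdir / "mito.fasta",
    }
    write_fasta({"chloroplast_genome": genomes.chloroplast_genome}, paths["chloroplast"])
    write_fasta(genomes.cds_sequences(), paths["cds"])
    write_fasta(genomes.trna_set, paths["trna"])
    write_fasta({"nuclear_genome": genomes.nuclear_genome}, paths["nuclear"])
    write_fasta({"mito_genome": genomes.mito_genome}, paths["mito"])
    return paths
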