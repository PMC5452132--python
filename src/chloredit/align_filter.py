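"""Forward-strand, ungapped, bounded-mismatch read matching and the
three-round subtractive filter.

Round 1: chloroplast genome + CDS + tRNAs, 0 mismatches  -> cp_m0
Round 2: round-1 leftovers vs nuclear + mito, 0 mismatches -> subtracted
Round 3: leftovers vs chloroplast genome + CDS, <=2 mismatches -> cp_m2
cp_m0_m2 = cp_m0 | cp_m2; everything else is unplaced.

Mismatch counting is positional Hamming over the whole read (no indels, no
quality weighting); N in a read always counts as a mismatch. Reverse-
complement placements are never searched (reverse-strand search is an
explicit non-goal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

DEFAULT_MIN_READ_LENGTH = 15
_CHUNK = 128  # reads per vectorized scan block


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped forward-strand placement of a read on a target.

    ``start`` is a 0-based offset; the read occupies the half-open interval
    [start, start + length) on the target.
    """

    read_id: str
    target_id: str
    start: int
    length: int
    mismatches: int
    round: str | None = None  # 'm0_cp' or 'm2_cp' once assigned by the filter


@dataclass(frozen=True)
class CdsAlignment:
    """A retained read placed on CDS coordinates, with its sequence."""

    read_id: str
    gene_id: str
    start: int  # 0-based on the CDS
    sequence: str
    mismatches: int


@dataclass
class FilteredReadSets:
    """Outcome of the three-round subtractive filter."""

    cp_m0: dict[str, list[AlignmentRecord]] = field(default_factory=dict)
    subtracted: set[str] = field(default_factory=set)
    cp_m2: dict[str, list[AlignmentRecord]] = field(default_factory=dict)
    unplaced: set[str] = field(default_factory=set)
    too_short: set[str] = field(default_factory=set)

    @property
    def cp_m0_m2(self) -> dict[str, list[AlignmentRecord]]:
        merged = dict(self.cp_m0)
        merged.update(self.cp_m2)
        return merged

    def validate(self) -> None:
        m0, m2 = set(self.cp_m0), set(self.cp_m2)
        if m0 & m2:
            raise AssertionError("cp_m0 and cp_m2 overlap")
        if self.subtracted & (m0 | m2):
            raise AssertionError("subtracted reads leaked into cp_m0_m2")
        if set(self.cp_m0_m2) != m0 | m2:
            raise AssertionError("cp_m0_m2 is not the union of cp_m0 and cp_m2")

    def counts(self) -> dict[str, int]:
        return {
            "cp_m0": len(self.cp_m0),
            "subtracted": len(self.subtracted),
            "cp_m2": len(self.cp_m2),
            "cp_m0_m2": len(self.cp_m0) + len(self.cp_m2),
            "unplaced": len(self.unplaced),
            "too_short": len(self.too_short),
        }


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _exact_hits(read: str, targets: Mapping[str, str]) -> list[tuple[str, int]]:
    hits = []
    for tid, tseq in targets.items():
        pos = tseq.find(read)
        while pos != -1:
            hits.append((tid, pos))
            pos = tseq.find(read, pos + 1)
    return hits


def align_reads(
    reads: Mapping[str, str],
    targets: Mapping[str, str],
    max_mismatch: int = 0,
    allow_revcomp: bool = False,
    report: str = "best-stratum",
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> list[AlignmentRecord]:
    """Place every read on every target at <= ``max_mismatch`` Hamming distance.

    Returns, per read, all placements in the best stratum (minimal mismatch
    count); with ``report='first'`` only the leftmost placement on the
    lexicographically smallest target id. Output is sorted by
    (read_id, target_id, start).
    """
    if not reads:
        raise ValueError("empty read set")
    if not targets:
        raise ValueError("empty target set")
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    if allow_revcomp:
        raise NotImplementedError("reverse-complement placement is not supported")
    if report not in ("best-stratum", "first"):
        raise ValueError("report must be 'best-stratum' or 'first'")

    usable = {rid: s for rid, s in reads.items() if len(s) >= min_read_length}
    n_short = len(reads) - len(usable)
    if n_short:
        logger.info("dropped %d reads shorter than %d nt", n_short, min_read_length)

    placements: dict[str, list[tuple[str, int, int]]] = {rid: [] for rid in usable}

    # stratum-0 fast path: substring search settles any read with an exact hit
    pending: dict[str, str] = {}
    for rid, seq in usable.items():
        if "N" in seq:
            hits = []
        else:
            hits = _exact_hits(seq, targets)
        if hits:
            placements[rid] = [(tid, pos, 0) for tid, pos in hits]
        elif max_mismatch > 0:
            pending[rid] = seq

    if pending:
        _scan_mismatches(pending, targets, max_mismatch, placements)

    target_order = sorted(targets)
    records: list[AlignmentRecord] = []
    for rid in sorted(placements):
        plc = placements[rid]
        if not plc:
            continue
        best = min(mm for _, _, mm in plc)
        stratum = sorted(
            (tid, pos, mm) for tid, pos, mm in plc if mm == best
        )
        if report == "first":
            stratum = stratum[:1]
        length = len(usable[rid])
        records.extend(
            AlignmentRecord(rid, tid, pos, length, mm) for tid, pos, mm in stratum
        )
    # keep target order deterministic even if dict order differs
    records.sort(key=lambda r: (r.read_id, target_order.index(r.target_id), r.start))
    return records


def _scan_mismatches(
    pending: Mapping[str, str],
    targets: Mapping[str, str],
    max_mismatch: int,
    placements: dict[str, list[tuple[str, int, int]]],
) -> None:
    """Vectorized sliding-window Hamming scan for reads without exact hits."""
    by_length: dict[int, list[str]] = {}
    for rid, seq in pending.items():
        by_length.setdefault(len(seq), []).append(rid)

    encoded_targets = {tid: _encode(seq) for tid, seq in targets.items()}
    for length, rids in by_length.items():
        mats = np.stack([_encode(pending[r]) for r in rids])
        for tid, tarr in encoded_targets.items():
            if tarr.size < length:
                continue
            windows = sliding_window_view(tarr, length)
            for lo in range(0, len(rids), _CHUNK):
                chunk = mats[lo : lo + _CHUNK]
                mm = (chunk[:, None, :] != windows[None, :, :]).sum(
                    axis=2, dtype=np.int16
                )
                rows, cols = np.nonzero(mm <= max_mismatch)
                for r, c in zip(rows.tolist(), cols.tolist()):
                    placements[rids[lo + r]].append((tid, int(c), int(mm[r, c])))


def hierarchical_filter(
    reads: Mapping[str, str],
    genomes,
    max_mismatch: int = 2,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    report: str = "best-stratum",
) -> FilteredReadSets:
    """Run the three-round subtractive alignment on one library.

    ``genomes`` is a :class:`~chloredit.synthetic_data.GenomeSet` (or any
    object with the same attributes).
    """
    if not reads:
        raise ValueError("empty read set")

    result = FilteredReadSets()
    usable = {}
    for rid, seq in reads.items():
        if len(seq) >= min_read_length:
            usable[rid] = seq
        else:
            result.too_short.add(rid)
    if result.too_short:
        logger.info(
            "dropped %d reads shorter than %d nt", len(result.too_short), min_read_length
        )

    cds_seqs = genomes.cds_sequences()
    round1_targets = {
        "chloroplast_genome": genomes.chloroplast_genome,
        **cds_seqs,
        **genomes.trna_set,
    }
    round2_targets = {
        "nuclear_genome": genomes.nuclear_genome,
        "mito_genome": genomes.mito_genome,
    }
    # round 3 deliberately excludes tRNAs
    round3_targets = {"chloroplast_genome": genomes.chloroplast_genome, **cds_seqs}

    def run_round(pool, targets, mm, tag):
        if not pool:
            return {}
        recs = align_reads(
            pool, targets, max_mismatch=mm, report=report, min_read_length=min_read_length
        )
        out: dict[str, list[AlignmentRecord]] = {}
        for r in recs:
            out.setdefault(r.read_id, []).append(
                AlignmentRecord(r.read_id, r.target_id, r.start, r.length, r.mismatches, tag)
            )
        return out

    result.cp_m0 = run_round(usable, round1_targets, 0, "m0_cp")
    remainder = {r: s for r, s in usable.items() if r not in result.cp_m0}

    sub_hits = run_round(remainder, round2_targets, 0, None)
    result.subtracted = set(sub_hits)
    remainder = {r: s for r, s in remainder.items() if r not in result.subtracted}

    result.cp_m2 = run_round(remainder, round3_targets, max_mismatch, "m2_cp")
    result.unplaced = set(remainder) - set(result.cp_m2)

    result.validate()
    logger.info("filter rounds: %s", result.counts())
    return result


def realign_to_cds(
    reads: Mapping[str, str],
    cds_set: Mapping[str, str],
    max_mismatch: int = 2,
    sam_path: str | Path | None = None,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> list[CdsAlignment]:
    """Place retained (cp_m0_m2) reads on CDS coordinates.

    Each read contributes its first best-stratum placement per CDS, so a
    read never hits the same CDS twice. Optionally writes a SAM file
    (1-based POS, FLAG 0, NM mismatch tag).
    """
    alignments: list[CdsAlignment] = []
    if reads:
        records = align_reads(
            reads, cds_set, max_mismatch=max_mismatch, min_read_length=min_read_length
        )
        seen: set[tuple[str, str]] = set()
        for r in records:
            key = (r.read_id, r.target_id)
            if key in seen:
                continue
            seen.add(key)
            alignments.append(
                CdsAlignment(r.read_id, r.target_id, r.start, reads[r.read_id], r.mismatches)
            )
    if sam_path is not None:
        write_cds_sam(alignments, cds_set, sam_path)
    return alignments


def write_cds_sam(
    alignments: Sequence[CdsAlignment],
    cds_set: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write alignments as plain-text SAM (valid header, FLAG 0 only)."""
    from chloredit import __version__

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for gene in sorted(cds_set):
            fh.write(f"@SQ\tSN:{gene}\tLN:{len(cds_set[gene])}\n")
        fh.write(f"@PG\tID:chloredit\tPN:chloredit\tVN:{__version__}\n")
        for a in sorted(alignments, key=lambda x: (x.gene_id, x.start, x.read_id)):
            fh.write(
                f"{a.read_id}\t0\t{a.gene_id}\t{a.start + 1}\t255\t"
                f"{len(a.sequence)}M\t*\t0\t0\t{a.sequence}\t*\tNM:i:{a.mismatches}\n"
            )


def read_cds_sam(path: str | Path) -> list[CdsAlignment]:
    """Load CDS alignments back from a SAM file (uses pysam)."""
    import pysam

    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            alignments.append(
                CdsAlignment(
                    read_id=rec.query_name,
                    gene_id=rec.reference_name,
                    start=rec.reference_start,
                    sequence=rec.query_sequence or "",
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    return alignments


def write_readset_manifest(sets: FilteredReadSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tset\n")
        for rid in sorted(sets.cp_m0):
            fh.write(f"{rid}\tcp_m0\n")
        for rid in sorted(sets.subtracted):
            fh.write(f"{rid}\tsubtracted\n")
        for rid in sorted(sets.cp_m2):
            fh.write(f"{rid}\tcp_m2\n")
        for rid in sorted(sets.unplaced):
            fh.write(f"{rid}\tunplaced\n")
        for rid in sorted(sets.too_short):
            fh.write(f"{rid}\ttoo_short\n")
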