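import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chloredit import align_filter as af
from chloredit import synthetic_data as synth
from tests.conftest import hamming_scan


def _mutate(seq: str, pos: int) -> str:
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + alt + seq[pos + 1 :]


class TestAlignReads:
    def test_exact_match_reported(self, rng):
        target = "".join(rng.choice(list("ACGT"), 500))
        read = target[100:120]
        recs = af.align_reads({"r1": read}, {"t": target}, max_mismatch=0)
        assert any(r.start == 100 and r.mismatches == 0 for r in recs)

    def test_mismatch_bound(self, rng):
        target = "".join(rng.choice(list("ACGT"), 500))
        read = _mutate(target[100:120], 5)
        assert af.align_reads({"r1": read}, {"t": target}, max_mismatch=0) == []
        recs = af.align_reads({"r1": read}, {"t": target}, max_mismatch=2)
        assert any(r.start == 100 and r.mismatches == 1 for r in recs)

    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_matches_brute_force_oracle(self, rng, k):
        target = "".join(rng.choice(list("ACGT"), 10_000))
        reads = {}
        for i in range(30):
            start = int(rng.integers(0, 9_980))
            read = target[start : start + 20]
            for _ in range(int(rng.integers(0, 3))):
                read = _mutate(read, int(rng.integers(0, 20)))
            reads[f"r{i}"] = read
        got = af.align_reads(reads, {"t": target}, max_mismatch=k)
        by_read = {}
        for r in got:
            by_read.setdefault(r.read_id, []).append((r.target_id, r.start, r.mismatches))
        for rid, read in reads.items():
            assert by_read.get(rid, []) == hamming_scan(read, {"t": target}, k)

    def test_no_reverse_complement_placement(self, rng):
        target = "".join(rng.choice(list("ACGT"), 300))
        read = synth.reverse_complement(target[50:80])
        # a reverse-complement-only match must be invisible
        if target.find(read) == -1:
            assert af.align_reads({"r": read}, {"t": target}, max_mismatch=0) == []

    def test_revcomp_flag_unsupported(self):
        with pytest.raises(NotImplementedError):
            af.align_reads({"r": "A" * 20}, {"t": "A" * 50}, allow_revcomp=True)

    def test_first_mode_single_leftmost(self):
        target = "ACGTACGTACGTACGTACGTACGT"
        read = "ACGTACGTACGTACGT"
        best = af.align_reads({"r": read}, {"a": target, "b": target}, report="first")
        assert len(best) == 1
        assert best[0].target_id == "a"
        assert best[0].start == 0

    def test_best_stratum_only(self):
        target = "A" * 40
        read = "A" * 19 + "C"  # 1 mismatch everywhere
        exact = "A" * 20
        recs = af.align_reads({"r": read, "e": exact}, {"t": target}, max_mismatch=2)
        mms = {r.read_id: {x.mismatches for x in recs if x.read_id == r.read_id} for r in recs}
        assert mms["e"] == {0}
        assert mms["r"] == {1}

    def test_n_counts_as_mismatch(self):
        target = "ACGTACGTACGTACGTACGT"
        read = target[:16].replace(target[0], "N", 1)
        assert af.align_reads({"r": read}, {"t": target}, max_mismatch=0) == []
        recs = af.align_reads({"r": read}, {"t": target}, max_mismatch=1)
        assert recs and recs[0].mismatches == 1

    def test_short_reads_dropped(self):
        recs = af.align_reads({"tiny": "ACGTACGT"}, {"t": "ACGTACGT" * 10})
        assert recs == []

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            af.align_reads({}, {"t": "ACGT" * 10})
        with pytest.raises(ValueError):
            af.align_reads({"r": "ACGT" * 5}, {})

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.data(),
        k=st.sampled_from([0, 1, 2]),
    )
    def test_property_oracle_equivalence(self, data, k):
        target = data.draw(
            st.text(alphabet="ACGT", min_size=40, max_size=200), label="target"
        )
        read = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=25), label="read")
        got = af.align_reads({"r": read}, {"t": target}, max_mismatch=k)
        expected = hamming_scan(read, {"t": target}, k)
        assert [(r.target_id, r.start, r.mismatches) for r in got] == expected


class TestHierarchicalFilter:
    def test_chloroplast_priority_over_decoy(self, genome_set):
        # a read matching both chloroplast and nuclear exactly goes to cp_m0
        kmer = genome_set.chloroplast_genome[100:125]
        gs = synth.GenomeSet(
            chloroplast_genome=genome_set.chloroplast_genome,
            cds_set=genome_set.cds_set,
            trna_set=genome_set.trna_set,
            nuclear_genome=kmer + genome_set.nuclear_genome,
            mito_genome=genome_set.mito_genome,
        )
        sets = af.hierarchical_filter({"r": kmer}, gs)
        assert "r" in sets.cp_m0
        assert "r" not in sets.subtracted

    def test_decoy_exact_beats_chloroplast_mismatch(self, genome_set):
        kmer = _mutate(genome_set.chloroplast_genome[200:225], 10)
        gs = synth.GenomeSet(
            chloroplast_genome=genome_set.chloroplast_genome,
            cds_set=genome_set.cds_set,
            trna_set=genome_set.trna_set,
            nuclear_genome=kmer + genome_set.nuclear_genome,
            mito_genome=genome_set.mito_genome,
        )
        sets = af.hierarchical_filter({"r": kmer}, gs)
        assert "r" in sets.subtracted
        assert "r" not in sets.cp_m2

    def test_error_free_library_fully_retained(self, genome_set, sites):
        prof = synth.LibraryProfile(
            "L", "control", 2000, seed=4, error_rate=0.0, offtarget_fraction=0.0
        )
        reads = synth.simulate_read_library(genome_set, sites, prof)
        read_map = {r.read_id: r.sequence for r in reads}
        sets = af.hierarchical_filter(read_map, genome_set)
        assert set(sets.cp_m0_m2) == set(read_map)
        # reads carrying a planted edit differ from the reference -> cp_m2
        for r in reads:
            edited = any(e for _, _, e in r.edited_sites)
            if edited:
                assert r.read_id in sets.cp_m2
            else:
                assert r.read_id in sets.cp_m0

    def test_set_algebra_invariants(self, genome_set, sites):
        prof = synth.LibraryProfile(
            "L", "salt", 1500, seed=13, error_rate=0.01, offtarget_fraction=0.2
        )
        reads = synth.simulate_read_library(genome_set, sites, prof)
        sets = af.hierarchical_filter({r.read_id: r.sequence for r in reads}, genome_set)
        sets.validate()
        m0, m2 = set(sets.cp_m0), set(sets.cp_m2)
        assert not m0 & m2
        assert set(sets.cp_m0_m2) == m0 | m2
        assert not sets.subtracted & set(sets.cp_m0_m2)
        assert not sets.unplaced & (m0 | m2 | sets.subtracted)
        all_ids = m0 | m2 | sets.subtracted | sets.unplaced | sets.too_short
        assert all_ids == {r.read_id for r in reads}

    def test_mismatch_cap_respected(self, genome_set, sites):
        prof = synth.LibraryProfile(
            "L", "salt", 1000, seed=14, error_rate=0.02, offtarget_fraction=0.1
        )
        reads = synth.simulate_read_library(genome_set, sites, prof)
        sets = af.hierarchical_filter({r.read_id: r.sequence for r in reads}, genome_set)
        for recs in sets.cp_m0_m2.values():
            for rec in recs:
                assert rec.mismatches <= 2


class TestRealignToCds:
    def test_sam_pos_is_one_based(self, genome_set, tmp_path):
        cds = genome_set.cds_sequences()
        gene = sorted(cds)[0]
        read = cds[gene][50:75]
        sam = tmp_path / "out.sam"
        alns = af.realign_to_cds({"r1": read}, cds, sam_path=sam)
        assert alns[0].start == 50
        line = [l for l in sam.read_text().splitlines() if l.startswith("r1")][0]
        assert line.split("\t")[3] == "51"

    def test_roundtrip_through_pysam(self, genome_set, tmp_path):
        cds = genome_set.cds_sequences()
        gene = sorted(cds)[1]
        reads = {
            "a": cds[gene][10:40],
            "b": _mutate(cds[gene][100:130], 4),
        }
        sam = tmp_path / "out.sam"
        alns = af.realign_to_cds(reads, cds, sam_path=sam)
        back = af.read_cds_sam(sam)
        assert {(a.read_id, a.gene_id, a.start, a.mismatches) for a in back} == {
            (a.read_id, a.gene_id, a.start, a.mismatches) for a in alns
        }

    def test_empty_input_gives_header_only_sam(self, genome_set, tmp_path):
        sam = tmp_path / "empty.sam"
        alns = af.realign_to_cds({}, genome_set.cds_sequences(), sam_path=sam)
        assert alns == []
        lines = sam.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        with pysam.AlignmentFile(str(sam), "r") as fh:
            assert list(fh) == []

    def test_mismatches_consistent_with_filter(self, genome_set, sites):
        prof = synth.LibraryProfile("L", "control", 1000, seed=3, error_rate=0.01)
        reads = synth.simulate_read_library(genome_set, sites, prof)
        read_map = {r.read_id: r.sequence for r in reads}
        sets = af.hierarchical_filter(read_map, genome_set)
        retained = {rid: read_map[rid] for rid in sets.cp_m0_m2}
        alns = af.realign_to_cds(retained, genome_set.cds_sequences())
        best_realign: dict[str, int] = {}
        for a in alns:
            best_realign[a.read_id] = min(a.mismatches, best_realign.get(a.read_id, 99))
        origin = {r.read_id: r for r in reads}
        for rid, mm in best_realign.items():
            r = origin[rid]
            if r.origin == "cds":
                filter_mm = min(
                    rec.mismatches for rec in sets.cp_m0_m2[rid]
                )
                assert mm == filter_mm

    def test_one_placement_per_cds(self, genome_set):
        cds = genome_set.cds_sequences()
        gene = sorted(cds)[0]
        # tandem repeat read matching twice within one CDS
        seq = cds[gene]
        read = seq[20:40]
        duped = {g: (seq[:60] + read + seq[60:]) for g in [gene]}
        alns = af.realign_to_cds({"r": read}, duped)
        assert len([a for a in alns if a.gene_id == gene]) <= 1
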