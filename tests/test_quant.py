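"""Feature loading, 1/(x*y) weighting, UMI collapse and junction counts."""

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import pytest

from rockroi.quant import (MODE_TSO_MULTI, MODE_TSO_UNIQUE, MODE_WTA_UNIQUE,
                           CountMatrix, FeatureInterval, FeatureModel,
                           ReadAlignments, assign_read_weights,
                           count_junctions, dedup_and_count, load_features,
                           read_mtx, write_mtx)

# ---------------------------------------------------------------------------
# GTF loading
# ---------------------------------------------------------------------------

GTF = """\
chr1\tsrc\tgene\t101\t1000\t.\t+\t.\tgene_id "g1"; transcript_id "g1_t";
chr1\tsrc\ttranscript\t101\t1000\t.\t+\t.\tgene_id "g1"; transcript_id "g1_t";
chr1\tsrc\texon\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1_t";
chr1\tsrc\texon\t601\t1000\t.\t+\t.\tgene_id "g1"; transcript_id "g1_t";
chr1\tsrc\tCDS\t201\t900\t.\t+\t.\tgene_id "g1"; transcript_id "g1_t";
chr2\tsrc\tgene\t1\t500\t.\t-\t.\tgene_id "g2"; transcript_id "g2_t"; gene_name "mt-g2";
"""


class TestLoadFeatures:
    def test_two_exons_derive_one_junction(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        fm = load_features(p)
        assert len(fm.junctions) == 1
        j = fm.junctions[0]
        # GTF 1-based closed -> 0-based half-open
        assert (j.chrom, j.donor_end, j.acceptor_start) == ("chr1", 400, 600)

    def test_cds_contained_in_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        fm = load_features(p)
        tx = [iv for iv in fm.intervals if iv.level == "transcript"][0]
        cds = [iv for iv in fm.intervals if iv.level == "CDS"][0]
        assert tx.start <= cds.start < cds.end <= tx.end
        assert cds.id == "g1.CDS"

    def test_mito_flag_from_gene_name_prefix(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        assert load_features(p).mito_ids() == {"g2"}

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(GTF + "chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 7"):
            load_features(p)

    def test_missing_on_target_id_raises(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF)
        with pytest.raises(ValueError, match="absent"):
            load_features(p, on_target_ids=["nope"])

    def test_simulator_gtf_has_three_on_one_off(self, small_sim):
        truth = small_sim.truth
        fm = load_features(small_sim.ref_files["gtf"],
                           on_target_ids=truth.refs.on_target_ids)
        genes = fm.feature_ids(levels=("gene",))
        assert len(genes) == 4
        on = fm.feature_ids(levels=("gene",), on_target_only=True)
        assert len(on) == 3


# ---------------------------------------------------------------------------
# weighting: fake alignments quacking like pysam records
# ---------------------------------------------------------------------------

@dataclass
class FakeAln:
    reference_name: str
    blocks: list
    is_reverse: bool = False

    def get_blocks(self):
        return self.blocks


def toy_model():
    ivs = [
        FeatureInterval("chr1", 100, 500, "+", "gene", "gA", on_target=True),
        FeatureInterval("chr1", 400, 800, "+", "gene", "gB", on_target=True),
        # one feature at two loci (tandem-duplicate style)
        FeatureInterval("chr2", 100, 500, "+", "gene", "gC", on_target=True),
        FeatureInterval("chr3", 100, 500, "+", "gene", "gC", on_target=True),
        FeatureInterval("chr4", 100, 500, "-", "gene", "gD", on_target=False),
    ]
    return FeatureModel(ivs)


def ra(read_id, loci, cb="CB1", umi="UMIUMIUM"):
    return ReadAlignments(read_id, cb, umi,
                          [FakeAln(c, b, rev) for c, b, rev in loci])


class TestAssignWeights:
    fm = toy_model()

    def test_single_locus_single_feature_weight_one(self):
        wa = assign_read_weights(ra("r1", [("chr1", [(150, 200)], False)]),
                                 self.fm, MODE_TSO_MULTI)
        assert wa.feature_weights() == {"gA": 1.0}

    def test_two_loci_one_feature_each_half_weight(self):
        wa = assign_read_weights(
            ra("r1", [("chr2", [(150, 200)], False),
                      ("chr3", [(150, 200)], False)]),
            self.fm, MODE_TSO_MULTI)
        assert wa.x == 2
        assert wa.feature_weights() == {"gC": pytest.approx(1.0)}

    def test_multioverlap_splits_by_y(self):
        wa = assign_read_weights(ra("r1", [("chr1", [(420, 480)], False)]),
                                 self.fm, MODE_TSO_MULTI)
        assert wa.feature_weights() == {"gA": 0.5, "gB": 0.5}

    def test_unique_mode_discards_multimappers(self):
        multi = ra("r1", [("chr2", [(150, 200)], False),
                          ("chr3", [(150, 200)], False)])
        assert assign_read_weights(multi, self.fm, MODE_TSO_UNIQUE) is None
        overlap = ra("r2", [("chr1", [(420, 480)], False)])
        assert assign_read_weights(overlap, self.fm, MODE_TSO_UNIQUE) is None

    def test_strand_policy(self):
        sense = ra("r1", [("chr4", [(150, 200)], True)])
        anti = ra("r2", [("chr4", [(150, 200)], False)])
        assert assign_read_weights(sense, self.fm,
                                   MODE_TSO_UNIQUE).feature_weights() == \
            {"gD": 1.0}
        assert assign_read_weights(anti, self.fm, MODE_TSO_UNIQUE) is None
        assert assign_read_weights(
            anti, self.fm, MODE_TSO_UNIQUE, stranded=False) is not None

    def test_multi_mode_requires_an_on_target_overlap(self):
        off_only = ra("r1", [("chr4", [(150, 200)], True)])
        assert assign_read_weights(off_only, self.fm, MODE_TSO_MULTI) is None

    def test_missing_annotation_raises(self):
        bad = ReadAlignments("r1", "", "", [FakeAln("chr1", [(150, 200)])])
        with pytest.raises(ValueError, match="CB/UMI"):
            assign_read_weights(bad, self.fm, MODE_TSO_MULTI)


class TestDedupAndCount:
    fm = toy_model()

    def wa(self, rid, cb, umi, loci):
        return assign_read_weights(ra(rid, loci, cb, umi), self.fm,
                                   MODE_TSO_MULTI)

    def test_umi_duplicates_collapse_to_one_molecule(self):
        loci = [("chr1", [(150, 200)], False)]
        m = dedup_and_count([self.wa("r1", "CB1", "AAAAAAAA", loci),
                             self.wa("r2", "CB1", "AAAAAAAA", loci)],
                            ["CB1"], self.fm, MODE_TSO_MULTI)
        assert m.to_frame().loc["CB1", "gA"] == 1

    def test_same_umi_on_two_genes_collapses_per_feature(self):
        m = dedup_and_count(
            [self.wa("r1", "CB1", "AAAAAAAA", [("chr1", [(150, 200)], False)]),
             self.wa("r2", "CB1", "AAAAAAAA", [("chr2", [(150, 200)], False)])],
            ["CB1"], self.fm, MODE_TSO_MULTI)
        df = m.to_frame()
        assert df.loc["CB1", "gA"] == 1 and df.loc["CB1", "gC"] == 1

    def test_representative_read_has_smallest_x(self):
        # same molecule seen once uniquely (x=1) and once at 2 loci (x=2)
        m = dedup_and_count(
            [self.wa("r2", "CB1", "AAAAAAAA",
                     [("chr2", [(150, 200)], False),
                      ("chr3", [(150, 200)], False)]),
             self.wa("r1", "CB1", "AAAAAAAA",
                     [("chr2", [(150, 200)], False)])],
            ["CB1"], self.fm, MODE_TSO_MULTI)
        assert m.to_frame().loc["CB1", "gC"] == 1.0

    def test_no_assignments_gives_zero_matrix(self):
        m = dedup_and_count([], ["CB1", "CB2"], self.fm, MODE_TSO_MULTI)
        assert m.matrix.shape == (2, 3) and m.matrix.nnz == 0

    def test_empty_cell_set_raises(self):
        with pytest.raises(ValueError, match="empty cell set"):
            dedup_and_count([], [], self.fm, MODE_TSO_MULTI)


# ---------------------------------------------------------------------------
# brute-force oracle for the multi-mode recount
# ---------------------------------------------------------------------------

def brute_force_recount(reads, intervals, cells):
    """Exhaustive regrouping and 1/(x*y) weighting, no shared code paths."""
    per_molecule = {}
    for rd in reads:
        x = len(rd["loci"])
        fid_weights = {}
        for chrom, blocks, rev in rd["loci"]:
            strand = "-" if rev else "+"
            fids = []
            for iv in intervals:
                if not iv.on_target or iv.chrom != chrom:
                    continue
                if iv.strand != strand:
                    continue
                if any(lo < iv.end and iv.start < hi for lo, hi in blocks):
                    if iv.id not in fids:
                        fids.append(iv.id)
            y = len(fids)
            for fid in fids:
                fid_weights[fid] = fid_weights.get(fid, 0) + 1.0 / (x * y)
        for fid, w in fid_weights.items():
            key = (rd["cb"], fid, rd["umi"])
            cur = per_molecule.get(key)
            if cur is None or (x, rd["id"]) < cur[0]:
                per_molecule[key] = ((x, rd["id"]), w)
    out = {}
    for (cb, fid, _), (_, w) in per_molecule.items():
        if cb in cells:
            out[(cb, fid)] = out.get((cb, fid), 0.0) + w
    return out


def random_instance(rng):
    loci_choices = [
        ("chr1", (150, 210)), ("chr1", (420, 470)), ("chr2", (130, 190)),
        ("chr3", (200, 260)), ("chr4", (150, 210)), ("chr1", (900, 950)),
    ]
    reads = []
    for i in range(rng.randint(1, 50)):
        n_loci = rng.randint(1, 3)
        loci = []
        for pos in rng.sample(range(len(loci_choices)), n_loci):
            chrom, (lo, hi) = loci_choices[pos]
            loci.append((chrom, [(lo, hi)], rng.random() < 0.2))
        reads.append({"id": f"r{i:03d}", "cb": rng.choice(["c1", "c2", "c3"]),
                      "umi": rng.choice(["U1", "U2", "U3", "U4"]),
                      "loci": loci})
    return reads


@pytest.mark.parametrize("seed", range(30))
def test_multi_mode_matches_brute_force_recount(seed):
    fm = toy_model()
    rng = random.Random(seed)
    reads = random_instance(rng)
    cells = ["c1", "c2", "c3"]
    assignments = []
    for rd in reads:
        wa = assign_read_weights(ra(rd["id"], rd["loci"], rd["cb"],
                                    rd["umi"]), fm, MODE_TSO_MULTI)
        if wa is not None:
            assignments.append(wa)
    m = dedup_and_count(assignments, cells, fm, MODE_TSO_MULTI).to_frame()
    expected = brute_force_recount(reads, fm.intervals, set(cells))
    for (cb, fid), w in expected.items():
        assert m.loc[cb, fid] == pytest.approx(w)
    assert m.values.sum() == pytest.approx(sum(expected.values()))


# ---------------------------------------------------------------------------
# junction counting from a real SAM
# ---------------------------------------------------------------------------

JUNC_GTF = """\
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "j1"; transcript_id "j1_t";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "j1"; transcript_id "j1_t";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "j1"; transcript_id "j1_t";
"""


def write_sam(path, records):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 2000}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, pos, cigar, nh, flag in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            length = sum(n for op, n in a.cigartuples if op in (0, 1, 4))
            a.query_sequence = "A" * length
            a.mapping_quality = 255
            a.set_tag("NH", nh)
            a.set_tag("CB", "CELL1")
            a.set_tag("UB", name[:2].upper() * 4)
            out.write(a)


class TestCountJunctions:
    def fm(self, tmp_path):
        p = tmp_path / "j.gtf"
        p.write_text(JUNC_GTF)
        return load_features(p)

    def test_annotated_gap_counts_one(self, tmp_path):
        # junction in 0-based coords: donor_end 200, acceptor_start 300
        write_sam(tmp_path / "a.sam", [("aa", 150, "50M100N50M", 1, 0)])
        df = count_junctions(tmp_path / "a.sam", self.fm(tmp_path), ["CELL1"])
        assert len(df) == 1
        assert df["count"].iloc[0] == 1.0
        assert df["junction"].iloc[0] == "chr1:200-300"

    def test_multimapper_spanning_same_junction_twice_totals_one(self,
                                                                 tmp_path):
        write_sam(tmp_path / "a.sam", [("aa", 160, "40M100N10M", 2, 0),
                                       ("aa", 170, "30M100N20M", 2, 256)])
        df = count_junctions(tmp_path / "a.sam", self.fm(tmp_path), ["CELL1"])
        assert df["count"].iloc[0] == pytest.approx(1.0)

    def test_unannotated_gap_ignored(self, tmp_path):
        write_sam(tmp_path / "a.sam", [("aa", 140, "50M100N50M", 1, 0)])
        df = count_junctions(tmp_path / "a.sam", self.fm(tmp_path), ["CELL1"])
        assert df.empty


# ---------------------------------------------------------------------------
# MatrixMarket IO
# ---------------------------------------------------------------------------

class TestMtxIO:
    def test_fractional_multi_matrix_round_trips_exactly(self, tmp_path):
        import scipy.sparse
        vals = scipy.sparse.csr_matrix(
            np.array([[0.5, 0.0], [0.25, 2.0]]))
        m = CountMatrix(vals, ["c1", "c2"], ["f1", "f2"], "TSO",
                        MODE_TSO_MULTI)
        write_mtx(m, tmp_path / "mtx")
        back = read_mtx(tmp_path / "mtx")
        assert (back.matrix != m.matrix).nnz == 0
        assert back.barcodes == m.barcodes and back.features == m.features
        assert (back.modality, back.mode) == ("TSO", MODE_TSO_MULTI)

    def test_unique_mode_written_as_integers(self, tmp_path):
        import scipy.sparse
        m = CountMatrix(scipy.sparse.csr_matrix(np.array([[1, 3]])),
                        ["c1"], ["f1", "f2"], "WTA", MODE_WTA_UNIQUE)
        write_mtx(m, tmp_path / "mtx")
        header = (tmp_path / "mtx" / "matrix.mtx").read_text().splitlines()[0]
        assert "integer" in header
        back = read_mtx(tmp_path / "mtx")
        assert back.matrix.dtype.kind == "i"

    def test_empty_matrix_round_trips(self, tmp_path):
        import scipy.sparse
        m = CountMatrix(scipy.sparse.csr_matrix((2, 2)), ["c1", "c2"],
                        ["f1", "f2"], "WTA", MODE_WTA_UNIQUE)
        write_mtx(m, tmp_path / "mtx")
        assert read_mtx(tmp_path / "mtx").matrix.nnz == 0

    def test_negative_counts_rejected(self):
        import scipy.sparse
        with pytest.raises(ValueError, match="non-negative"):
            CountMatrix(scipy.sparse.csr_matrix(np.array([[-1.0]])),
                        ["c1"], ["f1"], "WTA", MODE_WTA_UNIQUE)
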