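"""UMI-level quantification with unique-mapper and downweighted-multimapper rules.

Three run modes mirror the workflow's count tables:

* ``wta_unique`` — WTA reads, unique mappers only (one locus, one feature);
* ``tso_off_and_ontarget_unique`` — TSO reads, same uniqueness rule, same
  feature space as the WTA table;
* ``tso_ontarget_multi`` — TSO reads on the targeted features only, keeping
  multimapping/multioverlapping reads downweighted to ``1/(x*y)`` where ``x``
  is the number of aligned loci and ``y`` the number of features overlapped
  at a locus. This is what makes repetitive targets (a tandem-duplicated
  fluorophore, say) quantifiable: a molecule aligning to both copies of the
  repeat still contributes total mass 1 to the feature.

UMI deduplication collapses exact-match UMIs within (cell barcode, feature);
the molecule's weight comes from one representative read (smallest ``x``,
ties by read id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse
from intervaltree import IntervalTree

MODE_WTA_UNIQUE = "wta_unique"
MODE_TSO_UNIQUE = "tso_off_and_ontarget_unique"
MODE_TSO_MULTI = "tso_ontarget_multi"
UNIQUE_MODES = (MODE_WTA_UNIQUE, MODE_TSO_UNIQUE)


# ---------------------------------------------------------------------------
# feature model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureInterval:
    """One genomic interval of a feature (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    level: str  # gene | transcript | CDS | ROI
    id: str
    on_target: bool = False
    species: Optional[str] = None
    mito: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate interval {self.id}: "
                             f"[{self.start}, {self.end})")


@dataclass(frozen=True)
class Junction:
    chrom: str
    donor_end: int       # 0-based exclusive end of the upstream exon
    acceptor_start: int  # 0-based start of the downstream exon
    strand: str

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.donor_end}-{self.acceptor_start}({self.strand})"


class FeatureModel:
    """Strand-aware feature intervals plus annotated splice junctions.

    A feature id may own several intervals (e.g. a target present at two
    loci); counting is keyed on the id, so multimapping molecules of such a
    feature conserve mass.
    """

    def __init__(self, intervals: Sequence[FeatureInterval],
                 junctions: Iterable[Junction] = ()):
        self.intervals = list(intervals)
        self.junctions = sorted(set(junctions),
                                key=lambda j: (j.chrom, j.donor_end,
                                               j.acceptor_start))
        self._junction_set = set(
            (j.chrom, j.donor_end, j.acceptor_start) for j in self.junctions)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for iv in self.intervals:
            key = (iv.chrom, iv.level)
            self._trees.setdefault(key, IntervalTree()).addi(
                iv.start, iv.end, iv)

    def feature_ids(self, levels: Sequence[str] = ("gene",),
                    on_target_only: bool = False) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            if iv.level in levels and (iv.on_target or not on_target_only):
                seen.setdefault(iv.id)
        return list(seen)

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: Optional[str] = None,
                    levels: Sequence[str] = ("gene",),
                    on_target_only: bool = False) -> list[FeatureInterval]:
        hits = []
        for level in levels:
            tree = self._trees.get((chrom, level))
            if tree is None:
                continue
            for node in tree.overlap(start, end):
                iv = node.data
                if strand is not None and iv.strand != strand:
                    continue
                if on_target_only and not iv.on_target:
                    continue
                hits.append(iv)
        return hits

    def is_annotated_junction(self, chrom: str, gap_start: int,
                              gap_end: int) -> bool:
        return (chrom, gap_start, gap_end) in self._junction_set

    def mito_ids(self) -> set[str]:
        return {iv.id for iv in self.intervals if iv.mito}


_MITO_NAME_PREFIXES = ("mt-", "MT-")
_MITO_CONTIGS = {"chrM", "MT", "chrMT"}


def load_features(gtf_path, on_target_ids: Sequence[str] = (),
                  species_map: Optional[dict[str, str]] = None,
                  mito_prefixes: Sequence[str] = _MITO_NAME_PREFIXES,
                  mito_contigs: Iterable[str] = _MITO_CONTIGS) -> FeatureModel:
    """Load a GTF into a :class:`FeatureModel`.

    GTF 1-based closed coordinates become internal 0-based half-open ones.
    Junctions are derived from consecutive exons of each transcript.
    ``on_target_ids`` flags gene ids (and their sub-features) as targeted;
    ``species_map`` maps chromosome-name prefixes to species tags.

    Sub-feature intervals (CDS, ROI) are counted under derived ids
    ``<gene_id>.CDS`` / ``<gene_id>.ROI`` so they can be quantified
    separately from their host gene.
    """
    gtf_path = Path(gtf_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    on_target = set(on_target_ids)
    mito_contigs = set(mito_contigs)
    intervals: list[FeatureInterval] = []
    exons_by_tx: dict[str, list] = {}
    seen_gene_ids: set[str] = set()
    for f in db.all_features():
        gene_id = (f.attributes.get("gene_id") or [f.id])[0]
        gene_name = (f.attributes.get("gene_name") or [gene_id])[0]
        if f.featuretype == "exon":
            tx_id = (f.attributes.get("transcript_id") or [gene_id])[0]
            exons_by_tx.setdefault(tx_id, []).append(f)
            continue
        if f.featuretype not in ("gene", "transcript", "CDS", "ROI"):
            continue
        feat_id = (gene_id if f.featuretype == "gene"
                   else (f.attributes.get("transcript_id") or [gene_id])[0]
                   if f.featuretype == "transcript"
                   else f"{gene_id}.{f.featuretype}")
        species = None
        if species_map:
            for prefix, tag in species_map.items():
                if f.seqid.startswith(prefix):
                    species = tag
                    break
        mito = (f.seqid in mito_contigs
                or any(gene_name.startswith(p) for p in mito_prefixes))
        intervals.append(FeatureInterval(
            chrom=f.seqid, start=f.start - 1, end=f.end, strand=f.strand,
            level=f.featuretype, id=feat_id,
            on_target=gene_id in on_target, species=species, mito=mito))
        if f.featuretype == "gene":
            seen_gene_ids.add(gene_id)
    missing = on_target - seen_gene_ids
    if missing:
        raise ValueError(f"on-target ids absent from GTF: {sorted(missing)}")
    junctions = []
    for tx_id, exons in exons_by_tx.items():
        exons = sorted(exons, key=lambda e: e.start)
        for up, down in zip(exons, exons[1:]):
            junctions.append(Junction(chrom=up.seqid, donor_end=up.end,
                                      acceptor_start=down.start - 1,
                                      strand=up.strand))
    return FeatureModel(intervals, junctions)


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(
                    f"malformed GTF line {lineno} in {path}: {line!r}")


# ---------------------------------------------------------------------------
# alignment ingestion and weighting
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignments:
    """All alignment records of one read, with its CB/UMI annotation."""

    read_id: str
    cb: str
    umi: str
    loci: list  # list of pysam.AlignedSegment

    @property
    def x(self) -> int:
        return len(self.loci)


@dataclass
class WeightedAssignment:
    """Per-(locus, feature) weights of one read: weight = 1/(x*y)."""

    read_id: str
    cb: str
    umi: str
    x: int
    hits: list[tuple[int, str, float]]  # (locus index, feature id, weight)

    def feature_weights(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for _, fid, w in self.hits:
            out[fid] = out.get(fid, 0.0) + w
        return out


def iter_read_alignments(path, annotations: Optional[dict] = None,
                         modality: Optional[str] = None,
                         modality_tag: str = "XM"
                         ) -> Iterator[ReadAlignments]:
    """Group SAM/BAM records by read id, yielding annotated bundles.

    CB/UMI come from ``CB``/``UB`` tags, a ``readid|CB|UMI`` name convention,
    or an external ``annotations`` map (read_id -> (cb, umi, modality)) such
    as the one demux produces. Unmapped records are skipped. When
    ``modality`` is given, reads of other modalities are skipped.
    """
    bundles: dict[str, ReadAlignments] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            name = a.query_name
            key = name.rsplit("|", 2)[0] if "|" in name else name
            cb = umi = mod = None
            if annotations is not None:
                ann = annotations.get(name, annotations.get(key))
                if ann is None:
                    continue  # demux did not retain this read
                cb, umi, mod = ann
            elif a.has_tag("CB") and a.has_tag("UB"):
                cb, umi = a.get_tag("CB"), a.get_tag("UB")
                mod = (a.get_tag(modality_tag)
                       if a.has_tag(modality_tag) else None)
            elif "|" in name:
                _, cb, umi = name.rsplit("|", 2)
            if cb is None or umi is None:
                raise ValueError(
                    f"read {name!r} lacks CB/UMI annotation "
                    "(no tags, no name convention, no annotation map)")
            if modality is not None and mod is not None and mod != modality:
                continue
            bundle = bundles.get(key)
            if bundle is None:
                bundles[key] = ReadAlignments(key, cb, umi, [a])
            else:
                bundle.loci.append(a)
    yield from bundles.values()


def _alignment_span(a: "pysam.AlignedSegment") -> list[tuple[int, int]]:
    return a.get_blocks()


def assign_read_weights(ra: ReadAlignments, fm: FeatureModel, mode: str,
                        stranded: bool = True,
                        levels: Sequence[str] = ("gene",)
                        ) -> Optional[WeightedAssignment]:
    """Apply the mode's mapping/overlap rules to one read's alignments.

    Unique modes retain reads only when ``x == 1`` aligned locus overlaps
    exactly ``y == 1`` feature (weight 1). Multi mode retains any read with at
    least one on-target overlap; each (locus, feature) pair gets ``1/(x*y)``.
    """
    if not ra.cb or not ra.umi:
        raise ValueError(f"read {ra.read_id} lacks CB/UMI annotation")
    x = ra.x
    on_target_only = mode == MODE_TSO_MULTI
    per_locus: list[list[str]] = []
    for a in ra.loci:
        strand = "-" if a.is_reverse else "+"
        ids: dict[str, None] = {}
        for block_start, block_end in _alignment_span(a):
            for iv in fm.overlapping(a.reference_name, block_start, block_end,
                                     strand=strand if stranded else None,
                                     levels=levels,
                                     on_target_only=on_target_only):
                ids.setdefault(iv.id)
        per_locus.append(list(ids))
    if mode in UNIQUE_MODES:
        if x != 1 or len(per_locus[0]) != 1:
            return None
        return WeightedAssignment(ra.read_id, ra.cb, ra.umi, x,
                                  [(0, per_locus[0][0], 1.0)])
    if mode != MODE_TSO_MULTI:
        raise ValueError(f"unknown mode {mode!r}")
    if not any(per_locus):
        return None
    hits = []
    for locus_idx, ids in enumerate(per_locus):
        y = len(ids)
        for fid in ids:
            hits.append((locus_idx, fid, 1.0 / (x * y)))
    return WeightedAssignment(ra.read_id, ra.cb, ra.umi, x, hits)


# ---------------------------------------------------------------------------
# UMI collapse and count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x features matrix of UMI-deduplicated (possibly fractional) counts."""

    matrix: scipy.sparse.csr_matrix
    barcodes: list[str]
    features: list[str]
    modality: str
    mode: str

    def __post_init__(self) -> None:
        self.matrix = scipy.sparse.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.barcodes), len(self.features)):
            raise ValueError("matrix shape does not match labels")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.barcodes,
                            columns=self.features)

    def subset_barcodes(self, barcodes: Sequence[str]) -> "CountMatrix":
        keep = [b for b in barcodes if b in set(self.barcodes)]
        idx = {b: i for i, b in enumerate(self.barcodes)}
        rows = [idx[b] for b in keep]
        sub = (self.matrix[rows, :] if rows
               else scipy.sparse.csr_matrix((0, len(self.features))))
        return CountMatrix(sub, keep, list(self.features),
                           self.modality, self.mode)

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def dedup_and_count(assignments: Iterable[WeightedAssignment],
                    cells: Sequence[str], fm: FeatureModel, mode: str,
                    levels: Sequence[str] = ("gene",)) -> CountMatrix:
    """Collapse UMI duplicates and build the cells x features count matrix.

    Within (cell barcode, feature, UMI) all reads collapse to one molecule
    whose weight is taken from a single representative read: the one with the
    smallest ``x``, ties broken by read id.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    features = fm.feature_ids(levels=levels,
                              on_target_only=(mode == MODE_TSO_MULTI))
    cell_idx = {c: i for i, c in enumerate(cells)}
    feat_idx = {f: i for i, f in enumerate(features)}
    # (cb, feature, umi) -> (sort key, weight on that feature)
    representative: dict[tuple, tuple[tuple, float]] = {}
    for wa in assignments:
        if wa.cb not in cell_idx:
            continue
        key_rank = (wa.x, wa.read_id)
        for fid, weight in wa.feature_weights().items():
            if fid not in feat_idx:
                continue
            mol = (wa.cb, fid, wa.umi)
            prev = representative.get(mol)
            if prev is None or key_rank < prev[0]:
                representative[mol] = (key_rank, weight)
    rows, cols, vals = [], [], []
    for (cb, fid, _umi), (_, weight) in representative.items():
        rows.append(cell_idx[cb])
        cols.append(feat_idx[fid])
        vals.append(weight)
    m = scipy.sparse.coo_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)),
        shape=(len(cells), len(features))).tocsr()
    if mode in UNIQUE_MODES:
        m = m.astype(np.int64)
    modality = "WTA" if mode == MODE_WTA_UNIQUE else "TSO"
    return CountMatrix(m, cells, features, modality, mode)


def quantify(path, fm: FeatureModel, cells: Sequence[str], mode: str,
             annotations: Optional[dict] = None, stranded: bool = True,
             levels: Sequence[str] = ("gene",)) -> CountMatrix:
    """SAM/BAM -> count matrix for one run mode."""
    modality = "WTA" if mode == MODE_WTA_UNIQUE else "TSO"
    assignments = (
        wa for ra in iter_read_alignments(path, annotations, modality)
        if (wa := assign_read_weights(ra, fm, mode, stranded, levels))
        is not None)
    return dedup_and_count(assignments, cells, fm, mode, levels)


# ---------------------------------------------------------------------------
# junction counting
# ---------------------------------------------------------------------------

def count_junctions(path, fm: FeatureModel, cells: Sequence[str],
                    annotations: Optional[dict] = None,
                    modality: Optional[str] = None) -> pd.DataFrame:
    """Fractional counts of annotated splice junctions per cell.

    Each alignment gap (CIGAR ``N``) matching an annotated junction exactly
    adds ``1/x`` for the representative read of its (cell, junction, UMI)
    molecule; unannotated gaps are ignored. Junctions whose summed count
    reaches 1 are reported.
    """
    cells = set(cells)
    representative: dict[tuple, tuple[tuple, float]] = {}
    for ra in iter_read_alignments(path, annotations, modality):
        if ra.cb not in cells:
            continue
        x = ra.x
        key_rank = (x, ra.read_id)
        # a read adds 1/x per locus gap; loci may hit the same junction
        per_junction: dict[str, float] = {}
        for a in ra.loci:
            for gap_start, gap_end in _n_gaps(a):
                if fm.is_annotated_junction(a.reference_name, gap_start,
                                            gap_end):
                    jname = f"{a.reference_name}:{gap_start}-{gap_end}"
                    per_junction[jname] = per_junction.get(jname, 0.0) + 1.0 / x
        for jname, w in per_junction.items():
            mol = (ra.cb, jname, ra.umi)
            prev = representative.get(mol)
            if prev is None or key_rank < prev[0]:
                representative[mol] = (key_rank, w)
    counts: dict[tuple[str, str], float] = {}
    for (cb, jname, _umi), (_, w) in representative.items():
        counts[(cb, jname)] = counts.get((cb, jname), 0.0) + w
    df = pd.DataFrame(
        [(cb, jname, c) for (cb, jname), c in sorted(counts.items())],
        columns=["cell", "junction", "count"])
    if df.empty:
        return df
    totals = df.groupby("junction")["count"].sum()
    keep = set(totals[totals >= 1].index)
    return df[df["junction"].isin(keep)].reset_index(drop=True)


def _n_gaps(a: "pysam.AlignedSegment") -> list[tuple[int, int]]:
    gaps = []
    pos = a.reference_start
    for op, length in a.cigartuples or ():
        if op == 3:  # N: reference skip
            gaps.append((pos, pos + length))
            pos += length
        elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
    return gaps


# ---------------------------------------------------------------------------
# MatrixMarket IO (STARsolo-style triplet layout)
# ---------------------------------------------------------------------------

def write_mtx(m: CountMatrix, out_dir) -> Path:
    """Write matrix.mtx + barcodes.tsv + features.tsv into ``out_dir``.

    Multi-mode matrices are written real-valued so fractional weights
    round-trip exactly; unique modes stay integer.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = m.matrix.T.tocoo()  # features x cells on disk, like STARsolo
    if m.mode in UNIQUE_MODES:
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat)
    (out_dir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in m.barcodes))
    (out_dir / "features.tsv").write_text(
        "".join(f"{f}\n" for f in m.features))
    (out_dir / "mode.txt").write_text(f"{m.modality}\t{m.mode}\n")
    return out_dir


def read_mtx(out_dir) -> CountMatrix:
    out_dir = Path(out_dir)
    mat = scipy.sparse.csr_matrix(
        scipy.io.mmread(str(out_dir / "matrix.mtx")).T)
    barcodes = (out_dir / "barcodes.tsv").read_text().split()
    features = (out_dir / "features.tsv").read_text().split()
    modality, mode = (out_dir / "mode.txt").read_text().split()
    return CountMatrix(mat, barcodes, features, modality, mode)
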