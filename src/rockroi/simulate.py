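"""Synthetic references, truth tables and reads for the dual-oligo workflow.

The simulator emulates the statistical structure the processing method
assumes, so every downstream module can be exercised — and oracle-tested —
without any external data:

* a small genome of random-sequence genes (default three on-target targets
  and one off-target gene), each with two exons, a CDS, a capture site and a
  ROI primer site; optionally one target duplicated at a second locus with
  identical sequence (tdTomato-style) to exercise multimapping;
* negative-binomial per-cell expression, Bernoulli-planted target-positive
  cells, and a pool of empty droplets drawing ambient molecules;
* read geometry matching the assay: 3'-biased WTA positions, capture-site
  peaked on-target TSO positions, uniform off-target TSO positions,
  ROI-primed reads starting exactly at the 12-nt primer, chimeric APP reads
  (primer followed by decoy sequence), and fusion-junction reads;
* read 1 composed from the dual-oligo barcode structure (60 nt by default)
  and substitution errors at a configurable rate.

Truth is recorded at molecule and read level (SAM with CB/UB tags, class
tag, one record per origin locus), so pipeline closure can be asserted
exactly at zero error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .barcode import TSO, WTA, BarcodeScheme, ParsedRead, Whitelist, \
    compose_read, synthetic_whitelist
from .fusion import DecoyReference, FusionReference, ROIPrimer

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FusionPlan:
    """Planted fusion-positive cells, stratified by cell type.

    ``type_fractions`` maps cell type -> (fusion ref name or None, fraction
    of that type's cells carrying the fusion). Defaults mirror a three-line
    mixing design: one type mostly positive for one junction, one sparsely
    positive for another, one negative.
    """

    type_fractions: dict[str, tuple[Optional[str], float]] = field(
        default_factory=lambda: {
            "typeA": ("fusA", 0.9),
            "typeB": ("fusB", 0.18),
            "typeC": (None, 0.0),
        })
    molecules_mean: float = 3.0  # per positive cell, 1 + Poisson(mean - 1)


@dataclass
class SimConfig:
    """Study conditions for one simulation run. ``seed`` is mandatory."""

    seed: int
    n_cells: int = 300
    n_empty: int = 3000
    n_on_target: int = 3
    n_off_target: int = 1
    exon_len: int = 400
    intron_len: int = 200
    flank_len: int = 100
    fraction_positive: float = 0.5   # per target, per cell
    wta_mean: float = 60.0           # NB mean molecules per (cell, gene)
    wta_dispersion: float = 10.0     # NB size; smaller = more variable
    tso_on_mean: float = 10.0        # capture molecules per positive cell
    tso_fraction: float = 0.1        # off-target molecules emitted as TSO
    ambient_mean: float = 20.0       # molecules per empty droplet
    ambient_contamination: float = 0.02  # ambient molecules leaking into cells
    roi_primed_fraction: float = 0.3
    app_rate: float = 0.5            # APP molecules per cell (Poisson mean)
    error_rate: float = 0.0          # per-base substitution probability
    r1_len: int = 60
    r2_len: int = 62
    reads_per_molecule_mean: float = 1.5
    capture_sd: float = 15.0         # spread of TSO starts around capture
    three_prime_scale: float = 300.0  # exponential 3' bias scale (nt)
    tandem_duplicate: bool = True
    fusion: Optional[FusionPlan] = field(default_factory=FusionPlan)

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_empty", "n_on_target", "n_off_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_positive", "tso_fraction",
                     "ambient_contamination", "roi_primed_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(m < 0 for m in (self.wta_mean, self.tso_on_mean,
                               self.ambient_mean, self.app_rate)):
            raise ValueError("negative rate parameter")

    @property
    def tx_len(self) -> int:
        return 2 * self.exon_len


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

@dataclass
class TranscriptLayout:
    """Genomic layout of one transcript locus; seq is the coding strand."""

    gene_id: str
    tx_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    seq: str                      # spliced transcript, 5'->3'

    @property
    def tx_len(self) -> int:
        return len(self.seq)

    def genomic_blocks(self, tx_start: int, tx_end: int
                       ) -> list[tuple[int, int]]:
        """Map a transcript interval to sorted genomic blocks."""
        if not 0 <= tx_start < tx_end <= self.tx_len:
            raise ValueError("transcript interval out of range")
        segs = []  # (tx_s, tx_e, g_s, g_e) with orientation handled below
        offset = 0
        exons = (self.exons if self.strand == "+"
                 else list(reversed(self.exons)))
        for g_s, g_e in exons:
            length = g_e - g_s
            segs.append((offset, offset + length, g_s, g_e))
            offset += length
        blocks = []
        for t_s, t_e, g_s, g_e in segs:
            lo, hi = max(tx_start, t_s), min(tx_end, t_e)
            if lo >= hi:
                continue
            if self.strand == "+":
                blocks.append((g_s + (lo - t_s), g_s + (hi - t_s)))
            else:
                blocks.append((g_e - (hi - t_s), g_e - (lo - t_s)))
        return sorted(blocks)


@dataclass
class SimReferences:
    genome: dict[str, str]
    gtf_text: str
    layouts: dict[str, list[TranscriptLayout]]  # gene id -> loci
    gene_ids: list[str]
    on_target_ids: list[str]
    capture_tx_pos: dict[str, int]
    roi_tx_pos: dict[str, int]
    primers: list[ROIPrimer]
    fusion_primer_start: int           # primer offset within fusion refs
    fusion_refs: list[FusionReference]
    decoys: list[DecoyReference]
    whitelist: Whitelist
    scheme: BarcodeScheme

    def n_loci(self, gene_id: str) -> int:
        return len(self.layouts.get(gene_id, []))

    def write_files(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        gtf = out_dir / "annotation.gtf"
        gtf.write_text(self.gtf_text)
        fusion_fa = out_dir / "fusion_refs.fa"
        with open(fusion_fa, "w") as fh:
            for ref in self.fusion_refs:
                fh.write(f">{ref.name}\n{ref.sequence}\n")
        fusion_tsv = out_dir / "fusion_refs.tsv"
        fusion_tsv.write_text("".join(
            f"{r.name}\t{r.breakpoint}\t{r.partner5}\t{r.partner3}\n"
            for r in self.fusion_refs))
        decoy_fa = out_dir / "decoys.fa"
        with open(decoy_fa, "w") as fh:
            for d in self.decoys:
                fh.write(f">{d.name}\n{d.sequence}\n")
        return {"fasta": fasta, "gtf": gtf, "fusion_fasta": fusion_fa,
                "fusion_table": fusion_tsv, "decoy_fasta": decoy_fa}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_references(cfg: SimConfig,
                     scheme: BarcodeScheme = BarcodeScheme()
                     ) -> SimReferences:
    """Deterministically generate genome, GTF, targets, fusions and decoys."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.r2_len > cfg.tx_len:
        raise ValueError("r2_len longer than the shortest transcript")
    tx_len = cfg.tx_len
    capture_tx = int(round(tx_len * 0.75))
    roi_tx = capture_tx - 80
    if roi_tx < 0 or capture_tx + 12 > tx_len:
        raise ValueError("transcript too short to host ROI and capture site")

    gene_ids = ([f"on{i + 1}" for i in range(cfg.n_on_target)]
                + [f"off{i + 1}" for i in range(cfg.n_off_target)])
    on_target_ids = gene_ids[:cfg.n_on_target]

    genome: dict[str, str] = {}
    layouts: dict[str, list[TranscriptLayout]] = {}
    gtf_lines: list[str] = []
    capture_pos: dict[str, int] = {}
    roi_pos: dict[str, int] = {}
    primers: list[ROIPrimer] = []

    for gi, gene_id in enumerate(gene_ids):
        # the off-target gene exercises the minus strand
        strand = "-" if gene_id.startswith("off") else "+"
        tx_seq = _random_seq(rng, tx_len)
        intron = _random_seq(rng, cfg.intron_len)
        flank5 = _random_seq(rng, cfg.flank_len)
        flank3 = _random_seq(rng, cfg.flank_len)
        loci = [f"chr_{gene_id}"]
        if cfg.tandem_duplicate and gene_id == "on1":
            loci.append(f"chr_{gene_id}b")
        layouts[gene_id] = []
        for li, chrom in enumerate(loci):
            body = tx_seq[:cfg.exon_len] + intron + tx_seq[cfg.exon_len:]
            if strand == "-":
                contig = flank5 + _revcomp(body) + flank3
            else:
                contig = flank5 + body + flank3
            genome[chrom] = contig
            g0 = cfg.flank_len
            e1 = (g0, g0 + cfg.exon_len)
            e2 = (e1[1] + cfg.intron_len,
                  e1[1] + cfg.intron_len + cfg.exon_len)
            exons = [e1, e2]
            tx_id = f"{gene_id}_tx" + ("" if li == 0 else "b")
            layouts[gene_id].append(TranscriptLayout(
                gene_id, tx_id, chrom, strand, exons, tx_seq))
            gtf_lines.extend(_gtf_lines_for_locus(
                layouts[gene_id][-1], gene_id, tx_id, cfg,
                roi_tx if gene_id in on_target_ids else None))
        capture_pos[gene_id] = capture_tx
        roi_pos[gene_id] = roi_tx
        if gene_id in on_target_ids:
            primers.append(ROIPrimer(f"ROI_{gene_id}",
                                     tx_seq[roi_tx:roi_tx + 12]))

    # fusion junction references and decoys
    fusion_refs: list[FusionReference] = []
    decoys: list[DecoyReference] = []
    fusion_primer_start = 0
    plan = cfg.fusion
    if plan is not None:
        ref_names = sorted({r for r, _ in plan.type_fractions.values()
                            if r is not None})
        bp = 150
        fusion_primer_start = bp - 40
        for name in ref_names:
            p5 = _random_seq(rng, bp)
            p3 = _random_seq(rng, 150)
            seq = p5 + p3
            fusion_refs.append(FusionReference(
                name, seq, bp, partner5=f"{name}_5p", partner3=f"{name}_3p"))
            primers.append(ROIPrimer(
                f"ROI_{name}",
                seq[fusion_primer_start:fusion_primer_start + 12]))
        for di in range(2):
            # APPs carry the first fusion primer followed by off-target bases
            decoys.append(DecoyReference(
                f"decoy{di + 1}",
                primers[-len(ref_names)].gene_specific
                + _random_seq(rng, 188)))

    wl = synthetic_whitelist(segment_len=scheme.segment_len)
    return SimReferences(genome=genome, gtf_text="".join(gtf_lines),
                         layouts=layouts, gene_ids=gene_ids,
                         on_target_ids=on_target_ids,
                         capture_tx_pos=capture_pos, roi_tx_pos=roi_pos,
                         primers=primers,
                         fusion_primer_start=fusion_primer_start,
                         fusion_refs=fusion_refs, decoys=decoys,
                         whitelist=wl, scheme=scheme)


def _gtf_lines_for_locus(layout: TranscriptLayout, gene_id: str, tx_id: str,
                         cfg: SimConfig, roi_tx: Optional[int]) -> list[str]:
    """Emit 1-based closed GTF lines for one locus."""
    attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}"; ' \
            f'gene_name "{gene_id}";'
    chrom, strand = layout.chrom, layout.strand
    g_start = min(s for s, _ in layout.exons)
    g_end = max(e for _, e in layout.exons)

    def line(feat: str, s0: int, e0: int) -> str:
        return (f"{chrom}\trockroi_sim\t{feat}\t{s0 + 1}\t{e0}\t.\t"
                f"{strand}\t.\t{attrs}\n")

    out = [line("gene", g_start, g_end), line("transcript", g_start, g_end)]
    for s, e in layout.exons:
        out.append(line("exon", s, e))
    # CDS: transcript coords [100, tx_len - 100); ROI: [roi_tx, capture)
    cds_blocks = layout.genomic_blocks(100, layout.tx_len - 100)
    for s, e in cds_blocks:
        out.append(line("CDS", s, e))
    if roi_tx is not None:
        for s, e in layout.genomic_blocks(roi_tx,
                                          int(round(layout.tx_len * 0.75))):
            out.append(line("ROI", s, e))
    return out


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

@dataclass
class Molecule:
    barcode: str
    umi: str
    feature: str        # gene id, fusion ref name, or decoy name
    modality: str       # WTA or TSO
    cls: str            # wta | tso_capture | tso_offtarget | roi_primed
    #                     app | ambient | fusion


@dataclass
class SimTruth:
    cells: pd.DataFrame        # barcode, prepend, cell_type, fusion_ref, ...
    empties: pd.DataFrame      # barcode, prepend
    molecules: list[Molecule]
    refs: SimReferences
    cfg: SimConfig

    def molecule_counts(self) -> pd.DataFrame:
        rows: dict[tuple, int] = {}
        for m in self.molecules:
            key = (m.barcode, m.feature, m.modality, m.cls)
            rows[key] = rows.get(key, 0) + 1
        return pd.DataFrame(
            [k + (v,) for k, v in sorted(rows.items())],
            columns=["barcode", "feature", "modality", "class", "count"])

    def expected_counts(self, mode: str) -> pd.DataFrame:
        """Per-(barcode, feature) molecule counts the quantifier should see.

        Unique modes keep only single-locus genes; the multi mode keeps
        on-target genes with every molecule at total weight 1 (mass is
        conserved across a tandem duplicate's loci).
        """
        genomic = {"wta", "tso_capture", "tso_offtarget", "roi_primed",
                   "ambient"}
        rows: dict[tuple[str, str], float] = {}
        for m in self.molecules:
            if m.cls not in genomic:
                continue
            if mode == "wta_unique":
                if m.modality != WTA or self.refs.n_loci(m.feature) != 1:
                    continue
            elif mode == "tso_off_and_ontarget_unique":
                if m.modality != TSO or self.refs.n_loci(m.feature) != 1:
                    continue
            elif mode == "tso_ontarget_multi":
                if (m.modality != TSO
                        or m.feature not in self.refs.on_target_ids):
                    continue
            else:
                raise ValueError(f"unknown mode {mode!r}")
            key = (m.barcode, m.feature)
            rows[key] = rows.get(key, 0) + 1
        return pd.DataFrame(
            [(b, f, c) for (b, f), c in sorted(rows.items())],
            columns=["barcode", "feature", "count"])


def _nb_draw(rng, mean: float, size_param: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _draw_barcodes(rng, wl: Whitelist, n: int,
                   used: set) -> list[tuple[str, str, str]]:
    segs = [sorted(s) for s in wl.segments]
    out = []
    while len(out) < n:
        combo = tuple(segs[k][rng.integers(0, len(segs[k]))]
                      for k in range(3))
        if combo in used:
            continue
        used.add(combo)
        out.append(combo)
    return out


def simulate_truth(cfg: SimConfig, refs: SimReferences) -> SimTruth:
    """Plant per-cell expression, positives, ambient pool and fusions."""
    rng = np.random.default_rng(cfg.seed + 1)
    scheme = refs.scheme
    used: set = set()
    cell_combos = _draw_barcodes(rng, refs.whitelist, cfg.n_cells, used)
    empty_combos = _draw_barcodes(rng, refs.whitelist, cfg.n_empty, used)
    prepends = list(scheme.prepends)
    cells = pd.DataFrame({
        "cb1": [c[0] for c in cell_combos],
        "cb2": [c[1] for c in cell_combos],
        "cb3": [c[2] for c in cell_combos],
        "prepend": [prepends[i] for i in
                    rng.integers(0, len(prepends), cfg.n_cells)],
    })
    cells["barcode"] = cells.cb1 + cells.cb2 + cells.cb3
    empties = pd.DataFrame({
        "cb1": [c[0] for c in empty_combos],
        "cb2": [c[1] for c in empty_combos],
        "cb3": [c[2] for c in empty_combos],
        "prepend": [prepends[i] for i in
                    rng.integers(0, len(prepends), cfg.n_empty)],
    })
    if cfg.n_empty:
        empties["barcode"] = empties.cb1 + empties.cb2 + empties.cb3
    else:
        empties["barcode"] = pd.Series(dtype=str)

    # target positivity and fusion plan
    for t in refs.on_target_ids:
        cells[f"positive_{t}"] = (rng.random(cfg.n_cells)
                                  < cfg.fraction_positive)
    plan = cfg.fusion
    cells["cell_type"] = ""
    cells["fusion_ref"] = None
    cells["fusion_positive"] = False
    if plan is not None and cfg.n_cells:
        types = sorted(plan.type_fractions)
        cells["cell_type"] = [types[i % len(types)]
                              for i in range(cfg.n_cells)]
        for t, (ref, frac) in plan.type_fractions.items():
            idx = cells.index[cells.cell_type == t]
            if ref is None or not len(idx):
                continue
            pos = rng.random(len(idx)) < frac
            cells.loc[idx[pos], "fusion_positive"] = True
            cells.loc[idx, "fusion_ref"] = ref

    used_umis: dict[tuple, set] = {}

    def new_umi(barcode: str, feature: str, modality: str) -> str:
        # without replacement within the collapse group, so exact-match UMI
        # dedup recovers molecule counts exactly
        key = (barcode, feature, modality)
        pool = used_umis.setdefault(key, set())
        while True:
            umi = _random_seq(rng, scheme.umi_len)
            if umi not in pool:
                pool.add(umi)
                return umi

    molecules: list[Molecule] = []

    def add(barcode: str, feature: str, modality: str, cls: str,
            n: int) -> None:
        for _ in range(int(n)):
            molecules.append(Molecule(barcode, new_umi(barcode, feature,
                                                       modality),
                                      feature, modality, cls))

    # per-cell expression
    for gene in refs.gene_ids:
        counts = _nb_draw(rng, cfg.wta_mean, cfg.wta_dispersion, cfg.n_cells)
        is_target = gene in refs.on_target_ids
        for ci, total in enumerate(counts):
            bc = cells.barcode.iloc[ci]
            if not is_target and cfg.tso_fraction > 0 and total > 0:
                n_tso = rng.binomial(total, cfg.tso_fraction)
            else:
                n_tso = 0
            add(bc, gene, WTA, "wta", total - n_tso)
            add(bc, gene, TSO, "tso_offtarget", n_tso)
        if is_target:
            tso_counts = _nb_draw(rng, cfg.tso_on_mean, cfg.wta_dispersion,
                                  cfg.n_cells)
            positive = cells[f"positive_{gene}"].values
            for ci, total in enumerate(tso_counts):
                if not positive[ci] or total == 0:
                    continue
                bc = cells.barcode.iloc[ci]
                n_roi = rng.binomial(total, cfg.roi_primed_fraction)
                add(bc, gene, TSO, "tso_capture", total - n_roi)
                add(bc, gene, TSO, "roi_primed", n_roi)

    # APPs in real cells
    if refs.decoys and cfg.app_rate > 0:
        app_counts = rng.poisson(cfg.app_rate, cfg.n_cells)
        for ci, total in enumerate(app_counts):
            bc = cells.barcode.iloc[ci]
            for _ in range(int(total)):
                decoy = refs.decoys[int(rng.integers(0, len(refs.decoys)))]
                add(bc, decoy.name, TSO, "app", 1)

    # fusions
    if plan is not None:
        ref_by_name = {r.name: r for r in refs.fusion_refs}
        for ci in cells.index[cells.fusion_positive]:
            ref = ref_by_name[cells.fusion_ref.iloc[ci]]
            n = 1 + rng.poisson(max(plan.molecules_mean - 1, 0))
            add(cells.barcode.iloc[ci], ref.name, TSO, "fusion", n)

    # ambient molecules: pooled profile proportional to expression means
    if cfg.n_empty and cfg.ambient_mean > 0:
        probs = np.full(len(refs.gene_ids), 1.0 / len(refs.gene_ids))
        amb_counts = rng.poisson(cfg.ambient_mean, cfg.n_empty)
        for ei, total in enumerate(amb_counts):
            own_bc = empties.barcode.iloc[ei]
            genes = rng.choice(len(refs.gene_ids), size=int(total), p=probs)
            for g in genes:
                if (cfg.n_cells and cfg.ambient_contamination > 0
                        and rng.random() < cfg.ambient_contamination):
                    bc = cells.barcode.iloc[
                        int(rng.integers(0, cfg.n_cells))]
                else:
                    bc = own_bc
                add(bc, refs.gene_ids[g], WTA, "ambient", 1)

    return SimTruth(cells=cells, empties=empties, molecules=molecules,
                    refs=refs, cfg=cfg)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    r1_fastq: Path
    r2_fastq: Path
    truth_sam: Path
    truth_counts: Path
    provenance: Path
    ref_files: dict[str, Path]
    truth: SimTruth


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def emit_reads(truth: SimTruth, out_dir) -> SimOutput:
    """Write R1/R2 FASTQ, a coordinate-sorted truth SAM and truth tables."""
    cfg, refs = truth.cfg, truth.refs
    scheme = refs.scheme
    rng = np.random.default_rng(cfg.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_files = refs.write_files(out_dir)

    prepend_by_bc = dict(zip(truth.cells.barcode, truth.cells.prepend))
    prepend_by_bc.update(zip(truth.empties.barcode, truth.empties.prepend))
    segs_by_bc = {
        row.barcode: (row.cb1, row.cb2, row.cb3)
        for row in pd.concat([truth.cells, truth.empties]).itertuples()}

    sam_records: list[tuple] = []  # (chrom_idx or -1, pos, record dict)
    chroms = list(refs.genome)
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    prov_rows = []
    serial = 0

    r1_path = out_dir / "reads_R1.fastq"
    r2_path = out_dir / "reads_R2.fastq"
    fusion_by_name = {r.name: r for r in refs.fusion_refs}
    decoy_by_name = {d.name: d for d in refs.decoys}

    with open(r1_path, "w") as fq1, open(r2_path, "w") as fq2:
        for mol in truth.molecules:
            n_reads = 1 + rng.poisson(max(cfg.reads_per_molecule_mean - 1,
                                          0.0))
            layouts = refs.layouts.get(mol.feature, [])
            for _ in range(int(n_reads)):
                serial += 1
                read_id = f"r{serial:08d}"
                r2_seq, mapping = _draw_read(mol, cfg, refs, layouts,
                                             fusion_by_name, decoy_by_name,
                                             rng)
                prepend = (prepend_by_bc[mol.barcode]
                           if mol.modality == WTA else "")
                s1, s2, s3 = segs_by_bc[mol.barcode]
                r1_core = compose_read(ParsedRead(
                    mol.modality, prepend, s1, s2, s3, mol.umi), scheme)
                pad = cfg.r1_len - len(r1_core)
                if pad < 0:
                    raise ValueError("r1_len shorter than barcode structure")
                r1_seq = r1_core + _random_seq(rng, pad)
                r1_seq = _apply_errors(r1_seq, cfg.error_rate, rng)
                r2_seq = _apply_errors(r2_seq, cfg.error_rate, rng)
                fq1.write(f"@{read_id}\n{r1_seq}\n+\n{'I' * len(r1_seq)}\n")
                fq2.write(f"@{read_id}\n{r2_seq}\n+\n{'I' * len(r2_seq)}\n")
                prov_rows.append((read_id, mol.barcode, mol.umi,
                                  mol.modality, mol.cls, mol.feature))
                if mapping is None:
                    sam_records.append((len(chroms), 0, {
                        "name": read_id, "flag": 4, "ref_id": -1, "pos": -1,
                        "cigar": None, "seq": r2_seq, "nh": 0,
                        "cb": mol.barcode, "ub": mol.umi,
                        "mod": mol.modality, "cls": mol.cls}))
                else:
                    n_loci = len(mapping)
                    for li, (layout, blocks) in enumerate(mapping):
                        flag = 0
                        if layout.strand == "-":
                            flag |= 16
                        if li > 0:
                            flag |= 256
                        cigar = _blocks_to_cigar(blocks)
                        seq = (r2_seq if layout.strand == "+"
                               else _revcomp(r2_seq))
                        sam_records.append((
                            chrom_idx[layout.chrom], blocks[0][0], {
                                "name": read_id, "flag": flag,
                                "ref_id": chrom_idx[layout.chrom],
                                "pos": blocks[0][0], "cigar": cigar,
                                "seq": seq, "nh": n_loci,
                                "cb": mol.barcode, "ub": mol.umi,
                                "mod": mol.modality, "cls": mol.cls}))

    sam_path = out_dir / "truth.sam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(refs.genome[c])} for c in chroms]}
    sam_records.sort(key=lambda r: (r[0], r[1], r[2]["name"]))
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for _, _, rec in sam_records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.flag = rec["flag"]
            a.reference_id = rec["ref_id"]
            a.reference_start = rec["pos"]
            a.mapping_quality = 255 if rec["nh"] == 1 else 3
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            if rec["nh"]:
                a.set_tag("NH", rec["nh"])
            a.set_tag("CB", rec["cb"])
            a.set_tag("UB", rec["ub"])
            a.set_tag("XM", rec["mod"])
            a.set_tag("XC", rec["cls"])
            out.write(a)

    counts_path = out_dir / "truth_counts.tsv"
    truth.molecule_counts().to_csv(counts_path, sep="\t", index=False)
    prov_path = out_dir / "provenance.tsv"
    pd.DataFrame(prov_rows, columns=["read_id", "barcode", "umi", "modality",
                                     "class", "feature"]
                 ).to_csv(prov_path, sep="\t", index=False)
    return SimOutput(r1_path, r2_path, sam_path, counts_path, prov_path,
                     ref_files, truth)


def _draw_read(mol: Molecule, cfg: SimConfig, refs: SimReferences,
               layouts: Sequence[TranscriptLayout],
               fusion_by_name, decoy_by_name, rng):
    """Pick a read start per the molecule's class; return (seq, mapping).

    ``mapping`` is a list of (layout, genomic blocks) per origin locus, or
    None for junction/decoy reads that have no genomic origin.
    """
    L = cfg.r2_len
    if mol.cls == "fusion":
        ref = fusion_by_name[mol.feature]
        start = refs.fusion_primer_start
        return ref.sequence[start:start + L], None
    if mol.cls == "app":
        return decoy_by_name[mol.feature].sequence[:L], None
    layout = layouts[0]
    tx_len = layout.tx_len
    max_start = tx_len - L
    if mol.cls in ("wta", "ambient"):
        offset = min(int(rng.exponential(cfg.three_prime_scale)), max_start)
        start = max_start - offset
    elif mol.cls == "tso_offtarget":
        start = int(rng.integers(0, max_start + 1))
    elif mol.cls == "tso_capture":
        center = refs.capture_tx_pos[mol.feature] - L // 2
        start = int(np.clip(round(rng.normal(center, cfg.capture_sd)),
                            0, max_start))
    elif mol.cls == "roi_primed":
        start = min(refs.roi_tx_pos[mol.feature], max_start)
    else:
        raise ValueError(f"unknown molecule class {mol.cls!r}")
    seq = layout.seq[start:start + L]
    mapping = [(lay, lay.genomic_blocks(start, start + L))
               for lay in layouts]
    return seq, mapping


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def run_simulation(cfg: SimConfig, out_dir,
                   scheme: BarcodeScheme = BarcodeScheme()) -> SimOutput:
    """build_references -> simulate_truth -> emit_reads, one call."""
    refs = build_references(cfg, scheme)
    truth = simulate_truth(cfg, refs)
    return emit_reads(truth, out_dir)
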