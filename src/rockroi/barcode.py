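"""Parsing, validation and correction of BD Rhapsody dual-oligo barcode reads.

BD Rhapsody beads carry two oligo species whose read-1 layout differs only in
the fixed 4-nt linkers between the three 9-nt cell-barcode segments:

* WTA (dT capture):  ``prepend-N{9}-GTGA-N{9}-GACA-N{9}-UMI`` with a prepend
  drawn from {none, T, GT, TCA};
* TSO (template switch): ``N{9}-AATG-N{9}-CCAC-N{9}-UMI`` with no prepend.

Because the linkers are modality-specific, a single read-1 sequence can be
assigned to a modality purely structurally, before any whitelist matching.
This module implements that structural parse, Hamming-1 whitelist correction
of the three segments, and the inverse composition used by the simulator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

WTA = "WTA"
TSO = "TSO"
UNASSIGNED = "UNASSIGNED"

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class BarcodeScheme:
    """Fixed geometry of the dual-oligo read-1 structure.

    Defaults follow the BD Rhapsody layout; every field can be overridden so
    the parser is not tied to one bead lot.
    """

    wta_linker1: str = "GTGA"
    wta_linker2: str = "GACA"
    tso_linker1: str = "AATG"
    tso_linker2: str = "CCAC"
    segment_len: int = 9
    umi_len: int = 8
    prepends: tuple[str, ...] = ("", "T", "GT", "TCA")

    def __post_init__(self) -> None:
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        if "" not in self.prepends:
            raise ValueError('the empty prepend "" must be allowed')
        if (self.wta_linker1 == self.tso_linker1
                or self.wta_linker2 == self.tso_linker2):
            raise ValueError("WTA and TSO linkers must differ at each position")
        # shortest-first trial order is part of the contract
        object.__setattr__(
            self, "prepends", tuple(sorted(self.prepends, key=len))
        )

    @property
    def structured_len(self) -> int:
        """Length of the barcode+UMI block, excluding any prepend."""
        return (3 * self.segment_len
                + len(self.wta_linker1) + len(self.wta_linker2)
                + self.umi_len)

    def min_len(self, prepend: str = "") -> int:
        return len(prepend) + self.structured_len


@dataclass(frozen=True)
class ParsedRead:
    """One read decomposed into modality, barcode segments, UMI and cDNA."""

    modality: str
    prepend: str = ""
    cb1: str = ""
    cb2: str = ""
    cb3: str = ""
    umi: str = ""
    cdna: str = ""
    read_id: str = ""

    @property
    def cell_barcode(self) -> str:
        """Canonical cell barcode: the three segments concatenated."""
        return self.cb1 + self.cb2 + self.cb3


@dataclass(frozen=True)
class Whitelist:
    """Per-segment sets of valid barcode 9-mers."""

    seg1: frozenset[str]
    seg2: frozenset[str]
    seg3: frozenset[str]

    def __post_init__(self) -> None:
        lens = {len(s) for seg in (self.seg1, self.seg2, self.seg3) for s in seg}
        if len(lens) > 1:
            raise ValueError("whitelist entries have inconsistent lengths")

    @property
    def segments(self) -> tuple[frozenset[str], ...]:
        return (self.seg1, self.seg2, self.seg3)

    @classmethod
    def from_files(cls, path1: str | Path, path2: str | Path,
                   path3: str | Path) -> "Whitelist":
        """Load three one-9-mer-per-line text files."""
        sets = []
        for p in (path1, path2, path3):
            entries = [ln.strip().upper() for ln in Path(p).read_text().splitlines()
                       if ln.strip()]
            sets.append(frozenset(entries))
        return cls(*sets)

    @classmethod
    def from_single_file(cls, path: str | Path) -> "Whitelist":
        """Load one file with three tab-separated columns."""
        cols: tuple[list[str], list[str], list[str]] = ([], [], [])
        for ln in Path(path).read_text().splitlines():
            if not ln.strip():
                continue
            parts = ln.strip().split("\t")
            if len(parts) != 3:
                raise ValueError(f"expected 3 tab-separated columns, got: {ln!r}")
            for c, p in zip(cols, parts):
                c.append(p.upper())
        return cls(*(frozenset(c) for c in cols))


def synthetic_whitelist(n: int = 96, segment_len: int = 9,
                        seed: int = 20, min_dist: int = 3) -> Whitelist:
    """Deterministic synthetic whitelists for testing and simulation.

    Entries within a segment are kept at pairwise Hamming distance
    ``>= min_dist`` so that Hamming-1 correction is always unambiguous.
    """
    rng = random.Random(seed)
    segs = []
    for _ in range(3):
        chosen: list[str] = []
        while len(chosen) < n:
            cand = "".join(rng.choice("ACGT") for _ in range(segment_len))
            if all(_hamming(cand, c) >= min_dist for c in chosen):
                chosen.append(cand)
        segs.append(frozenset(chosen))
    return Whitelist(*segs)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _linker_match(seq: str, pos: int, linker: str) -> bool:
    # N never matches a linker base
    window = seq[pos:pos + len(linker)]
    return window == linker and "N" not in window


def parse_read(r1_seq: str, scheme: BarcodeScheme = BarcodeScheme(),
               cdna: str = "", read_id: str = "") -> ParsedRead:
    """Structurally classify one read-1 sequence.

    A read is WTA if both WTA linkers match exactly at the offsets implied by
    some prepend (trialled shortest-first), TSO if both TSO linkers match at
    offset 0, and UNASSIGNED otherwise — including when both structures match,
    and when the read is too short to host either structure.
    """
    r1_seq = r1_seq.upper()
    if not _VALID_BASES.issuperset(r1_seq):
        bad = sorted(set(r1_seq) - _VALID_BASES)
        raise ValueError(f"non-ACGTN characters in read: {bad}")

    k = scheme.segment_len
    l1w, l2w = len(scheme.wta_linker1), len(scheme.wta_linker2)

    wta_hit: Optional[str] = None
    for prepend in scheme.prepends:
        if len(r1_seq) < scheme.min_len(prepend):
            continue
        p = len(prepend)
        if (r1_seq.startswith(prepend)
                and _linker_match(r1_seq, p + k, scheme.wta_linker1)
                and _linker_match(r1_seq, p + 2 * k + l1w, scheme.wta_linker2)):
            wta_hit = prepend
            break

    tso_hit = (len(r1_seq) >= scheme.min_len("")
               and _linker_match(r1_seq, k, scheme.tso_linker1)
               and _linker_match(r1_seq, 2 * k + len(scheme.tso_linker1),
                                 scheme.tso_linker2))

    if wta_hit is not None and tso_hit:
        return ParsedRead(UNASSIGNED, cdna=cdna, read_id=read_id)
    if wta_hit is not None:
        p = len(wta_hit)
        cb1 = r1_seq[p:p + k]
        cb2 = r1_seq[p + k + l1w:p + 2 * k + l1w]
        base3 = p + 2 * k + l1w + l2w
        cb3 = r1_seq[base3:base3 + k]
        umi = r1_seq[base3 + k:base3 + k + scheme.umi_len]
        return ParsedRead(WTA, wta_hit, cb1, cb2, cb3, umi, cdna, read_id)
    if tso_hit:
        l1t, l2t = len(scheme.tso_linker1), len(scheme.tso_linker2)
        cb1 = r1_seq[0:k]
        cb2 = r1_seq[k + l1t:2 * k + l1t]
        base3 = 2 * k + l1t + l2t
        cb3 = r1_seq[base3:base3 + k]
        umi = r1_seq[base3 + k:base3 + k + scheme.umi_len]
        return ParsedRead(TSO, "", cb1, cb2, cb3, umi, cdna, read_id)
    return ParsedRead(UNASSIGNED, cdna=cdna, read_id=read_id)


def correct_barcode(parsed: ParsedRead, wl: Whitelist,
                    max_dist: int = 1) -> Optional[ParsedRead]:
    """Whitelist-correct the three barcode segments.

    Each segment is replaced by its exact whitelist match, or — when
    ``max_dist == 1`` — by a unique Hamming-1 neighbour. Any segment without a
    match, or with an ambiguous one, rejects the whole read (returns None).
    """
    if parsed.modality == UNASSIGNED:
        raise ValueError("cannot correct an UNASSIGNED read")
    if max_dist not in (0, 1):
        raise ValueError("max_dist must be 0 or 1")
    if any(not seg for seg in wl.segments):
        raise ValueError("empty whitelist segment")

    corrected = []
    for seg, entries in zip((parsed.cb1, parsed.cb2, parsed.cb3), wl.segments):
        if seg in entries and "N" not in seg:
            corrected.append(seg)
            continue
        if max_dist == 0:
            return None
        hits = {cand for cand in _hamming1_neighbors(seg) if cand in entries}
        if len(hits) != 1:
            return None
        corrected.append(next(iter(hits)))
    return replace(parsed, cb1=corrected[0], cb2=corrected[1], cb3=corrected[2])


def _hamming1_neighbors(seg: str) -> Iterable[str]:
    for i, base in enumerate(seg):
        for b in "ACGT":
            if b != base:
                yield seg[:i] + b + seg[i + 1:]


def compose_read(parsed: ParsedRead,
                 scheme: BarcodeScheme = BarcodeScheme()) -> str:
    """Inverse of :func:`parse_read` for fully populated reads."""
    if parsed.modality == UNASSIGNED:
        raise ValueError("cannot compose an UNASSIGNED read")
    for name, seg in (("cb1", parsed.cb1), ("cb2", parsed.cb2),
                      ("cb3", parsed.cb3)):
        if len(seg) != scheme.segment_len:
            raise ValueError(f"{name} has length {len(seg)}, "
                             f"expected {scheme.segment_len}")
    if len(parsed.umi) != scheme.umi_len:
        raise ValueError(f"UMI has length {len(parsed.umi)}, "
                         f"expected {scheme.umi_len}")
    if parsed.modality == TSO:
        if parsed.prepend:
            raise ValueError("TSO reads carry no prepend")
        return (parsed.cb1 + scheme.tso_linker1 + parsed.cb2
                + scheme.tso_linker2 + parsed.cb3 + parsed.umi)
    if parsed.prepend not in scheme.prepends:
        raise ValueError(f"prepend {parsed.prepend!r} not in scheme")
    return (parsed.prepend + parsed.cb1 + scheme.wta_linker1 + parsed.cb2
            + scheme.wta_linker2 + parsed.cb3 + parsed.umi)
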