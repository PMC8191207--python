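"""Scan protein alignments for group-fixed amino-acid changes.

A *fixed change* is an alignment column where every species of a focal
body-size group carries one residue and the remaining scanned carnivores
carry a different one.  In strict mode (the default) the background must be
uniform as well, matching reported sites such as CDC7 S513L where all
non-focal species share serine; relaxed mode only requires that no
background species carries the focal residue.  Columns containing a gap or
an ambiguous residue ('X') in any scanned row are excluded, since ambiguity
cannot certify fixation.  Site coordinates can be mapped onto an ungapped
reference row (e.g. the human sequence) to produce labels in the familiar
"S513L" style.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import AlignmentError

__all__ = [
    "ProteinAlignment",
    "FixedChangeSite",
    "scan_fixed_changes",
    "map_to_reference",
    "annotate_domains",
    "read_alignment_fasta",
    "write_alignment_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_LIKE = {"-", "X"}
ALPHABET = AMINO_ACIDS | GAP_LIKE


@dataclass
class ProteinAlignment:
    """A rectangular protein multiple sequence alignment for one gene."""

    gene: str
    rows: dict[str, str]    # species -> aligned sequence (uppercase + '-')

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError(f"{self.gene}: empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1 or 0 in lengths:
            raise AlignmentError(
                f"{self.gene}: rows must share one positive length, got {lengths}")
        for sp, seq in self.rows.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.gene}: row {sp!r} contains invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, col: int, species: list[str]) -> list[str]:
        """Residues of ``species`` at 1-based column ``col``."""
        if not 1 <= col <= self.length:
            raise AlignmentError(f"column {col} out of range 1..{self.length}")
        return [self.rows[s][col - 1] for s in species]


@dataclass
class FixedChangeSite:
    """One group-fixed alignment column."""

    gene: str
    column: int                     # 1-based alignment coordinate
    focal_residue: str
    background_residues: str        # sorted unique background residues
    ref_position: int | None = None  # 1-based in the reference sequence
    label: str | None = None         # e.g. "S513L" when reference present
    domains: list[str] = field(default_factory=list)


def scan_fixed_changes(aln: ProteinAlignment, focal: list[str],
                       background: list[str],
                       mode: str = "strict") -> list[FixedChangeSite]:
    """Return every column fixed for a different residue in the focal group.

    ``focal`` and ``background`` must be disjoint subsets of the alignment
    rows with at least two focal species; rows outside the two sets (e.g. an
    outgroup or a reference sequence) are ignored.  Strict mode requires a
    single residue in the background; relaxed mode only forbids the focal
    residue there.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown scan mode {mode!r}")
    focal, background = list(focal), list(background)
    if set(focal) & set(background):
        raise AlignmentError("focal and background sets overlap")
    if len(focal) < 2:
        raise AlignmentError("need at least two focal species")
    missing = [s for s in focal + background if s not in aln.rows]
    if missing:
        raise AlignmentError(f"{aln.gene}: species missing from alignment: {missing}")
    if not background:
        raise AlignmentError("background set is empty")

    sites: list[FixedChangeSite] = []
    for col in range(1, aln.length + 1):
        fres = aln.column(col, focal)
        bres = aln.column(col, background)
        if any(c in GAP_LIKE for c in fres + bres):
            continue
        if len(set(fres)) != 1:
            continue
        a = fres[0]
        bset = set(bres)
        if a in bset:
            continue
        if mode == "strict" and len(bset) != 1:
            continue
        sites.append(FixedChangeSite(
            gene=aln.gene, column=col, focal_residue=a,
            background_residues="".join(sorted(bset))))
    return sites


def map_to_reference(aln: ProteinAlignment, ref_species: str,
                     column: int) -> int | None:
    """Position of alignment ``column`` (1-based) in the ungapped reference
    sequence, or None when the reference has a gap there."""
    if ref_species not in aln.rows:
        raise AlignmentError(f"reference row {ref_species!r} not in alignment")
    if not 1 <= column <= aln.length:
        raise AlignmentError(f"column {column} out of range 1..{aln.length}")
    ref = aln.rows[ref_species]
    if ref[column - 1] == "-":
        return None
    return sum(1 for c in ref[:column] if c != "-")


def attach_reference(sites: list[FixedChangeSite], aln: ProteinAlignment,
                     ref_species: str) -> list[FixedChangeSite]:
    """Fill ``ref_position`` and a "S513L"-style label on each site; sites at
    reference gaps keep their alignment coordinate with no label."""
    for s in sites:
        pos = map_to_reference(aln, ref_species, s.column)
        s.ref_position = pos
        if pos is not None:
            bg = s.background_residues[0] if len(s.background_residues) == 1 else "x"
            s.label = f"{bg}{pos}{s.focal_residue}"
    return sites


def annotate_domains(sites: list[FixedChangeSite],
                     domains: dict[str, list[tuple[str, int, int]]]) -> list[FixedChangeSite]:
    """Attach protein-domain names to sites falling inside supplied intervals.

    ``domains`` maps gene id to (name, start, end) intervals, 1-based
    inclusive, in reference coordinates.  Sites without a reference position
    or outside every interval are left unlabeled.
    """
    for gene, ivals in domains.items():
        for name, start, end in ivals:
            if start > end:
                raise ValueError(f"{gene}: domain {name!r} has start {start} > end {end}")
    for s in sites:
        s.domains = []
        if s.ref_position is None:
            continue
        for name, start, end in domains.get(s.gene, []):
            if start <= s.ref_position <= end:
                s.domains.append(name)
    return sites


def read_alignment_fasta(path, gene: str | None = None) -> ProteinAlignment:
    """Read one aligned FASTA file; record ids are species names."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"{path}: duplicate species {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if gene is None:
        gene = os.path.splitext(os.path.basename(str(path)))[0]
    return ProteinAlignment(gene=gene, rows=rows)


def write_alignment_fasta(aln: ProteinAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp, seq in aln.rows.items():
            fh.write(f">{sp}\n{seq}\n")
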