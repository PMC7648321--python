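"""Per-gene codon alignments for the fixed 16-taxon avian panel.

Alignments arrive as in-frame codon FASTA (one file per gene, headers are
the five-letter taxon codes).  Before any likelihood work, every codon
column containing a gap, an ambiguity character, or a stop codon in any
taxon is removed, mirroring the gap/ambiguity/stop cleaning applied to the
source data set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .treekit import TAXA_16

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(standard_dna_table.forward_table)


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


@dataclass
class CleanReport:
    """Tally of codon columns removed by cleaning, by reason.

    A column offending for several reasons is attributed to the first
    matching rule in the order gap > ambiguous > stop.
    """

    gene_id: str
    columns_removed_gap: int = 0
    columns_removed_ambiguous: int = 0
    columns_removed_stop: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.columns_removed_gap
            + self.columns_removed_ambiguous
            + self.columns_removed_stop
        )


@dataclass
class GeneAlignment:
    """One gene's codon alignment over an ordered taxon panel.

    ``codon_seqs`` maps taxon code to its nucleotide sequence; after
    cleaning, sequences are equal-length, frame-aligned, and free of gaps,
    ambiguity codes and stop codons.  ``L`` is the locus length in codons.
    """

    gene_id: str
    taxa: tuple[str, ...]
    codon_seqs: dict[str, str]
    cleaned: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.codon_seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.gene_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        (self._nt_len,) = lengths

    @property
    def nt_length(self) -> int:
        return self._nt_len

    @property
    def L(self) -> int:
        if self._nt_len % 3:
            raise AlignmentError(f"{self.gene_id}: length not divisible by 3")
        return self._nt_len // 3

    @property
    def aa_seqs(self) -> dict[str, str]:
        return {t: translate(s) for t, s in self.codon_seqs.items()}

    def codon_columns(self):
        """Iterate codon columns as per-taxon tuples (taxon order fixed)."""
        seqs = [self.codon_seqs[t] for t in self.taxa]
        for i in range(0, self._nt_len - self._nt_len % 3, 3):
            yield tuple(s[i : i + 3] for s in seqs)

    def subset_taxa(self, keep) -> "GeneAlignment":
        keep = [t for t in self.taxa if t in set(keep)]
        return GeneAlignment(
            self.gene_id,
            tuple(keep),
            {t: self.codon_seqs[t] for t in keep},
            cleaned=self.cleaned,
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.codon_seqs[t]}\n")


def translate(codon_seq: str) -> str:
    """Standard-code translation of a cleaned in-frame codon string."""
    if len(codon_seq) % 3:
        raise AlignmentError("sequence length not divisible by 3")
    out = []
    for i in range(0, len(codon_seq), 3):
        codon = codon_seq[i : i + 3].upper()
        if codon in STOP_CODONS:
            raise AlignmentError(f"internal stop codon {codon} at nt {i}")
        try:
            out.append(_CODON_TO_AA[codon])
        except KeyError:
            raise AlignmentError(f"untranslatable codon {codon!r} at nt {i}")
    return "".join(out)


def read_gene_alignment(
    path, expected_taxa=TAXA_16, gene_id: str | None = None
) -> GeneAlignment:
    """Read one gene's FASTA; validate and order taxa canonically."""
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        code = rec.id.strip()
        if code in records:
            raise AlignmentError(f"taxon {code} duplicated in {path.name}")
        records[code] = str(rec.seq).upper()
    for taxon in expected_taxa:
        if taxon not in records:
            raise AlignmentError(f"taxon {taxon} absent from {path.name}")
    unknown = set(records) - set(expected_taxa)
    if unknown:
        raise AlignmentError(
            f"unknown taxa in {path.name}: {sorted(unknown)}"
        )
    return GeneAlignment(
        gene_id or path.stem,
        tuple(expected_taxa),
        {t: records[t] for t in expected_taxa},
    )


_GAP_CHARS = set("-.?")
_NUCS = set("ACGT")


def clean_alignment(aln: GeneAlignment) -> tuple[GeneAlignment, CleanReport]:
    """Drop every codon column with any gap, ambiguity code or stop codon.

    The column rule is all-or-nothing: one offending taxon removes the
    column for the whole panel, so downstream likelihoods always see
    complete codon columns.
    """
    if aln.nt_length % 3:
        raise AlignmentError(
            f"{aln.gene_id}: raw length {aln.nt_length} not divisible by 3"
        )
    report = CleanReport(aln.gene_id)
    kept: list[tuple[str, ...]] = []
    for column in aln.codon_columns():
        chars = set("".join(column))
        if chars & _GAP_CHARS:
            report.columns_removed_gap += 1
        elif not chars <= _NUCS:
            report.columns_removed_ambiguous += 1
        elif any(codon in STOP_CODONS for codon in column):
            report.columns_removed_stop += 1
        else:
            kept.append(column)
    if not kept:
        raise AlignmentError(f"{aln.gene_id}: empty alignment after cleaning")
    seqs = {
        t: "".join(col[i] for col in kept) for i, t in enumerate(aln.taxa)
    }
    return GeneAlignment(aln.gene_id, aln.taxa, seqs, cleaned=True), report
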