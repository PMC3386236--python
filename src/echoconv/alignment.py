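"""Alignment container and FASTA / PHYLIP I/O.

Coordinates are 1-based at the protein level everywhere a site is reported
(site 204 of the protein alignment is column 204), matching the usual
"R204Q" notation for amino-acid replacements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .models import AA_INDEX, CODON_INDEX, STOP_CODONS

NT_ALPHABET = set("ACGT-")
AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVX-")


@dataclass
class Alignment:
    """A multiple alignment of equal-length sequences.

    kind is one of "nucleotide", "codon", "protein".  A codon alignment is a
    nucleotide alignment read in frame: its length must be divisible by 3
    and no sequence may contain an in-frame stop codon (whole-codon gaps are
    allowed).
    """

    names: list[str]
    sequences: list[str]
    kind: str = "nucleotide"

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate taxon names: {', '.join(dupes)}")
        if self.kind not in ("nucleotide", "codon", "protein"):
            raise ValueError(f"unknown alignment kind: {self.kind!r}")
        if self.sequences:
            L = len(self.sequences[0])
            for name, seq in zip(self.names, self.sequences):
                if len(seq) != L:
                    raise ValueError(
                        f"ragged alignment: sequence {name!r} has length "
                        f"{len(seq)}, expected {L}")
        if self.kind == "codon":
            if self.length % 3 != 0:
                raise ValueError("codon alignment length not divisible by 3")
            for name, seq in zip(self.names, self.sequences):
                for k in range(0, len(seq), 3):
                    if seq[k:k + 3] in STOP_CODONS:
                        raise ValueError(
                            f"in-frame stop codon {seq[k:k + 3]} in "
                            f"{name!r} at codon {k // 3 + 1}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def take_columns(self, columns: np.ndarray, kind: str | None = None) -> "Alignment":
        """New alignment keeping the given 0-based columns, in order."""
        cols = np.asarray(columns, dtype=int)
        seqs = ["".join(s[c] for c in cols) for s in self.sequences]
        return Alignment(list(self.names), seqs, kind or self.kind)

    def drop_protein_sites(self, sites: list[int]) -> "Alignment":
        """Remove 1-based protein sites (for a protein alignment)."""
        if self.kind != "protein":
            raise ValueError("drop_protein_sites requires a protein alignment")
        drop = set(sites)
        bad = [s for s in drop if not 1 <= s <= self.length]
        if bad:
            raise ValueError(f"sites out of range: {sorted(bad)}")
        keep = [c for c in range(self.length) if c + 1 not in drop]
        if not keep:
            raise ValueError("excluding all alignment columns")
        return self.take_columns(np.array(keep))


def read_fasta(path: str | Path, kind: str = "nucleotide") -> Alignment:
    """Read an aligned FASTA file.

    The taxon name is the header up to the first whitespace.  Gaps ('-') are
    preserved; a ragged alignment or duplicate names raise ValueError.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(names, seqs, kind)


def write_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed (name + two spaces) sequential PHYLIP writer."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.length}\n")
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f"{name}  {seq}\n")


def translate(aln: Alignment) -> Alignment:
    """Translate a codon alignment to protein (standard genetic code).

    Column i of the output corresponds to codon i of the input.  A whole-gap
    codon '---' becomes '-'; a codon mixing gaps and bases becomes 'X' and is
    excluded from downstream counting.
    """
    if aln.kind != "codon":
        raise ValueError("translate requires a codon alignment")
    table = standard_dna_table.forward_table
    out = []
    for name, seq in zip(aln.names, aln.sequences):
        residues = []
        for k in range(0, len(seq), 3):
            codon = seq[k:k + 3]
            if codon == "---":
                residues.append("-")
            elif "-" in codon:
                residues.append("X")
            elif codon in STOP_CODONS:
                raise ValueError(
                    f"stop codon {codon} in {name!r} at codon {k // 3 + 1}")
            else:
                residues.append(table.get(codon, "X"))
        out.append("".join(residues))
    return Alignment(list(aln.names), out, "protein")


# ---------------------------------------------------------------------------
# Integer encodings used by the numerical modules (missing/ambiguous -> -1).

def encode_nucleotides(aln: Alignment) -> np.ndarray:
    """(n_taxa, L) int8 array with T=0 C=1 A=2 G=3, else -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("TCAG"):
        lut[ord(b)] = i
    mat = np.frombuffer("".join(aln.sequences).encode(), dtype=np.uint8)
    return lut[mat].reshape(aln.n_taxa, aln.length)


def encode_codons(aln: Alignment) -> np.ndarray:
    """(n_taxa, L/3) int16 array of sense-codon indices, gaps/ambig -> -1."""
    if aln.kind != "codon":
        raise ValueError("encode_codons requires a codon alignment")
    n_codons = aln.length // 3
    out = np.full((aln.n_taxa, n_codons), -1, dtype=np.int16)
    for i, seq in enumerate(aln.sequences):
        for k in range(n_codons):
            out[i, k] = CODON_INDEX.get(seq[3 * k:3 * k + 3], -1)
    return out


def encode_protein(aln: Alignment) -> np.ndarray:
    """(n_taxa, L) int8 array of amino-acid indices, gaps/X -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for a, i in AA_INDEX.items():
        lut[ord(a)] = i
    mat = np.frombuffer("".join(aln.sequences).encode(), dtype=np.uint8)
    return lut[mat].reshape(aln.n_taxa, aln.length)
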