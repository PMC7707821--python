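"""Receptor variant-library designs.

A design is a coding sequence split into contiguous segments plus the full
single-substitution mutagenesis manifest: every residue crossed with the 19
non-wild-type amino acids, each substitution realised as one concrete mutant
codon. For the beta-2 adrenergic receptor this is 412 residues x 19 = 7828
designed missense variants over eight segments.

Coordinates: residue positions are 1-based; nucleotide and codon intervals
are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

_TABLE = unambiguous_dna_by_id[1]

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: codons per amino acid (standard table), deterministic order
CODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in _TABLE.forward_table.items() if a == aa))
    for aa in AMINO_ACIDS
}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)


@dataclass(frozen=True)
class Variant:
    """One designed missense substitution with its encoding codon."""

    position: int  # 1-based residue index
    wt_aa: str
    mut_aa: str
    codon: str

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class ReceptorDesign:
    """Coding sequence, segment partition, and designed-variant manifest."""

    cds: str
    segments: list[tuple[int, int]]  # half-open codon ranges, 0-based
    variants: list[Variant] = field(repr=False)

    @property
    def L(self) -> int:
        return len(self.cds) // 3

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())

    def codon(self, position: int) -> str:
        """Reference codon at 1-based residue ``position``."""
        return self.cds[3 * (position - 1) : 3 * position]

    def segment_of(self, position: int) -> int:
        """Segment index containing 1-based residue ``position``."""
        for i, (s, e) in enumerate(self.segments):
            if s <= position - 1 < e:
                return i
        raise ValueError(f"position {position} outside design of length {self.L}")

    def segment_nt_range(self, i: int) -> tuple[int, int]:
        """Nucleotide half-open interval of segment ``i`` on the CDS."""
        s, e = self.segments[i]
        return 3 * s, 3 * e

    def segment_seq(self, i: int) -> str:
        s, e = self.segment_nt_range(i)
        return self.cds[s:e]

    def variant_seq(self, v: Variant) -> str:
        """Segment-length nucleotide sequence carrying variant ``v``."""
        i = self.segment_of(v.position)
        s, _ = self.segment_nt_range(i)
        off = 3 * (v.position - 1) - s
        seg = self.segment_seq(i)
        return seg[:off] + v.codon + seg[off + 3 :]

    def variant_lookup(self) -> dict[str, Variant]:
        """Exact-sequence dictionary: mutant segment sequence -> variant."""
        return {self.variant_seq(v): v for v in self.variants}


def split_segments(L: int, n_segments: int) -> list[tuple[int, int]]:
    """Partition codons 0..L into ``n_segments`` near-equal half-open ranges.

    Sizes differ by at most one codon; the remainder goes to the first
    segments (L=10, n=3 gives sizes 4,3,3).
    """
    if not 1 <= n_segments <= L:
        raise ValueError(f"need 1 <= n_segments <= L, got n_segments={n_segments}, L={L}")
    base, rem = divmod(L, n_segments)
    sizes = [base + (1 if i < rem else 0) for i in range(n_segments)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_segments)]


def make_design(L: int, n_segments: int = 8, seed: int | None = None) -> ReceptorDesign:
    """Generate a random receptor design with the full 19-substitution manifest.

    The CDS starts with ATG, contains no internal stop codon, and is drawn
    uniformly over codons otherwise. Each designed substitution picks one
    codon of the target amino acid at random.
    """
    rng = np.random.default_rng(seed)
    segments = split_segments(L, n_segments)

    sense_codons = sorted(set(_TABLE.forward_table) - STOP_CODONS)
    codons = ["ATG"] + [str(rng.choice(sense_codons)) for _ in range(L - 1)]
    cds = "".join(codons)
    protein = str(Seq(cds).translate())

    variants: list[Variant] = []
    for pos in range(1, L + 1):
        wt = protein[pos - 1]
        for mut in AMINO_ACIDS:
            if mut == wt:
                continue
            choices = CODONS_BY_AA[mut]
            codon = choices[int(rng.integers(len(choices)))]
            variants.append(Variant(pos, wt, mut, codon))
    return ReceptorDesign(cds=cds, segments=segments, variants=variants)
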