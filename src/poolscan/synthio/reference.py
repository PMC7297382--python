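"""Synthetic reference sequences with gene annotations and a TE library.

The generated reference emulates a BAC-scale resistance locus: a single main
contig carrying a cluster of non-overlapping gene features, plus a separate
"TE library" contig holding transposable-element sequences.  DNA transposons
of the mariner class begin with a terminal inverted repeat (TIR) and end with
its reverse complement; the default element uses a 29 bp mariner-type TIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import random_seq, revcomp

#: 29 bp mariner-class terminal inverted repeat used by the default TE.
MARINER_TIR = "GGCTAAAGAGTAGAAAGAGCCCACAAGTT"

TE_CONTIG = "te_library"


class ParameterError(ValueError):
    """Raised when generator parameters are infeasible."""


@dataclass
class ReferenceSet:
    """A synthetic reference: contigs, gene annotations and a TE library.

    Attributes
    ----------
    contigs:
        Map of contig name to nucleotide sequence.  Contains the main contig
        and one TE-library contig (named ``te_library``) formed by
        concatenating the TE sequences.
    annotations:
        ``(contig, start, end, label)`` gene features, 1-based inclusive.
    te_library:
        Map of TE name to its full sequence (TIR ... revcomp(TIR)).
    te_offsets:
        0-based offset of each TE within the TE-library contig.
    """

    contigs: dict[str, str]
    annotations: list[tuple[str, int, int, str]]
    te_library: dict[str, str]
    te_offsets: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")
        for contig, start, end, label in self.annotations:
            if contig not in self.contigs:
                raise ValueError(f"annotation {label} on unknown contig {contig}")
            if not (1 <= start <= end <= len(self.contigs[contig])):
                raise ValueError(f"annotation {label} outside contig {contig}")
        for name, seq in self.te_library.items():
            tir_len = _tir_length(seq)
            if tir_len < 2:
                raise ValueError(f"TE {name} lacks terminal inverted repeats")

    def main_contig(self) -> str:
        """Name of the main (non-TE-library) contig."""
        return next(n for n in self.contigs if n != TE_CONTIG)


def _tir_length(seq: str) -> int:
    """Length of the terminal inverted repeat at the ends of ``seq``."""
    n = len(seq) // 2
    k = 0
    rc = revcomp(seq)
    while k < n and seq[k] == rc[k]:
        k += 1
    return k


def make_te_sequence(
    rng: np.random.Generator,
    tir: str = MARINER_TIR,
    interior_length: int = 1200,
) -> str:
    """Build a TE sequence: TIR + random interior + reverse complement of TIR."""
    return tir + random_seq(rng, interior_length) + revcomp(tir)


def build_reference(
    length: int,
    n_genes: int,
    seed: int,
    contig_name: str = "rp1",
    te_names: tuple[str, ...] = ("mariner1",),
    te_interior_length: int = 1200,
) -> ReferenceSet:
    """Generate a deterministic synthetic reference.

    Parameters
    ----------
    length:
        Main contig length in bp (>= 10000).
    n_genes:
        Number of non-overlapping gene annotations to place.
    seed:
        Seed for the generator; identical calls are byte-identical.

    Raises
    ------
    ParameterError
        If the contig is too small to place ``n_genes`` features.
    """
    if length < 10000:
        raise ParameterError(f"length {length} < 10000")
    rng = np.random.default_rng(seed)
    gene_len = max(300, min(2000, length // (3 * max(n_genes, 1))))
    gap = gene_len // 4
    if n_genes * (gene_len + gap) > length:
        raise ParameterError(
            f"cannot place {n_genes} genes of {gene_len} bp on a {length} bp contig"
        )

    seq = random_seq(rng, length)

    # place genes left-to-right with random jitter in the leftover slack
    slack = length - n_genes * (gene_len + gap)
    extra = np.sort(rng.integers(0, slack + 1, size=n_genes)) if n_genes else []
    annotations = []
    cursor = 0
    prev_extra = 0
    for i in range(n_genes):
        cursor += int(extra[i] - prev_extra) + gap // 2
        prev_extra = int(extra[i])
        start = cursor + 1  # 1-based
        end = cursor + gene_len
        annotations.append((contig_name, start, end, f"gene{i + 1:02d}"))
        cursor = end + gap // 2

    te_library: dict[str, str] = {}
    te_offsets: dict[str, int] = {}
    offset = 0
    for name in te_names:
        te_seq = make_te_sequence(rng, interior_length=te_interior_length)
        te_library[name] = te_seq
        te_offsets[name] = offset
        offset += len(te_seq)
    contigs = {contig_name: seq, TE_CONTIG: "".join(te_library.values())}

    ref = ReferenceSet(contigs, annotations, te_library, te_offsets)
    ref.validate()
    return ref
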