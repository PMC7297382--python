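"""Synthetic paralog sequence sets with and without gene conversion.

Emulates a two-paralog gene family sampled across populations: the paralogs
descend from duplicated ancestors separated by ``divergence`` substitutions
per site, and individual gene copies carry additional within-paralog
diversity.  A converted sequence is labelled as paralog b but its sequence
derives from the paralog-a ancestor — the signature whole-gene conversion
leaves in a phylogeny (the b-labelled copy places inside the a clade).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._seq import mutate, random_seq


@dataclass
class ParalogSimTruth:
    """Identifiers of the simulated conversion events."""

    converted_ids: list[str]


def simulate_paralog_sequences(
    n_a: int = 281,
    n_b: int = 119,
    n_converted: int = 4,
    length: int = 1464,
    divergence: float = 0.10,
    diversity: float = 0.005,
    seed: int = 0,
    converted_population: str = "Benin",
    populations: tuple[str, ...] = (
        "Malawi",
        "Mozambique",
        "Zambia",
        "Uganda",
        "Ghana",
        "Cameroon",
        "Benin",
    ),
) -> tuple[list[tuple[str, str, str, str]], ParalogSimTruth]:
    """Simulate labelled paralog sequences.

    Returns ``(records, truth)`` where each record is
    ``(id, paralog_label, population, sequence)``.  ``n_converted`` of the
    b-labelled sequences are drawn from the a ancestor (gene conversion);
    they carry the ``converted_population`` tag.

    Defaults mirror a 400-sequence two-paralog survey (281 a, 119 b, 4
    converted) over a 1464 bp trimmed coding alignment, with between-paralog
    divergence 20x the within-paralog diversity.
    """
    if n_converted > n_b:
        raise ValueError("n_converted cannot exceed n_b")
    rng = np.random.default_rng(seed)
    ancestor_a = random_seq(rng, length)
    ancestor_b = mutate(ancestor_a, divergence, rng)

    records: list[tuple[str, str, str, str]] = []
    truth = ParalogSimTruth([])
    for i in range(n_a):
        pop = populations[i % len(populations)]
        seq = mutate(ancestor_a, diversity, rng)
        records.append((f"a{i + 1:03d}", "paralog_a", pop, seq))
    for i in range(n_b):
        converted = i < n_converted
        pop = converted_population if converted else populations[i % len(populations)]
        ancestor = ancestor_a if converted else ancestor_b
        name = f"b{i + 1:03d}"
        seq = mutate(ancestor, diversity, rng)
        records.append((name, "paralog_b", pop, seq))
        if converted:
            truth.converted_ids.append(name)
    return records, truth


def write_paralog_fasta(
    records: list[tuple[str, str, str, str]], path: str, width: int = 80
) -> None:
    """Write labelled paralog sequences as aligned FASTA.

    Headers follow the ``name|paralog|population`` convention consumed by
    the gene-conversion analysis.
    """
    with open(path, "w") as fh:
        for name, paralog, pop, seq in records:
            fh.write(f">{name}|{paralog}|{pop}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
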