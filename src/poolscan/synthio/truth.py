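"""Machine-readable truth files for simulated data.

Truth intervals use the same breakpoint convention as SV records: 1-based
``left`` = last unaffected base, ``right`` = last affected base, so the BED
interval (0-based half-open) is simply ``[left, right)`` and the name column
reproduces the ``contig:left–right`` labelling.
"""

from __future__ import annotations

import csv

import pandas as pd

from .coalescent import CoalescentWindowParams
from .edits import StructuralEdit

_EDIT_COLUMNS = ["kind", "contig", "left", "right", "payload", "tsd_len", "copies"]


def write_truth_bed(edits: list[StructuralEdit], path: str) -> None:
    """Write edit truth intervals as BED (name column = breakpoint label)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in edits:
            lo, hi = e.interval0()
            w.writerow([e.contig, lo, hi, e.label, e.kind])


def write_truth_tsv(edits: list[StructuralEdit], path: str) -> None:
    """Write full edit truth as TSV (round-trips via :func:`read_truth_tsv`)."""
    rows = [
        {
            "kind": e.kind,
            "contig": e.contig,
            "left": e.left,
            "right": e.right,
            "payload": e.payload or "",
            "tsd_len": e.tsd_len,
            "copies": e.copies,
        }
        for e in edits
    ]
    pd.DataFrame(rows, columns=_EDIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> list[StructuralEdit]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            StructuralEdit(
                kind=r["kind"],
                contig=r["contig"],
                left=int(r["left"]),
                right=int(r["right"]),
                payload=str(r["payload"]) or None,
                tsd_len=int(r["tsd_len"]),
                copies=int(r["copies"]),
            )
        )
    return out


def write_window_truth(
    params_by_window: dict[int, CoalescentWindowParams], path: str
) -> None:
    """Record per-window simulation modes (which windows carry a sweep)."""
    rows = [
        {
            "window": w,
            "mode": p.mode,
            "theta": p.theta,
            "n_haplotypes": p.n_haplotypes,
            "sweep_scaling": p.sweep_scaling,
            "seed": p.seed,
        }
        for w, p in sorted(params_by_window.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
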