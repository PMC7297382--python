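"""End-to-end orchestration, marker-level calls and reporting.

Runs the stages — synthetic data (optional), pooled window statistics, SV
scan, TE scan, gene-conversion analysis — from a single YAML config, writes
plain-TSV reports plus a JSON manifest recording every output file, stage
parameters and seeds.  Also implements two small marker-level operations on
alignments: codon allele frequencies (e.g. an L119F resistance marker read
straight off spanning reads) and indel detection near an annotated feature
(e.g. a 1 bp deletion adjacent to a transcription start site).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import paralogconv, poolstats, svscan, synthio, tescan

log = logging.getLogger("poolscan")


class ConfigError(ValueError):
    """Raised when a config is invalid before any stage runs."""


@dataclass
class Config:
    """Validated pipeline configuration.

    ``simulate`` holds synthetic-data parameters (used when no external
    inputs are given); ``paths`` points at existing inputs; ``params`` holds
    per-stage parameter overrides; ``seeds`` one integer per random stage.
    """

    output_dir: str
    pools: list[dict] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        cfg = cls(
            output_dir=raw["output_dir"],
            pools=raw.get("pools", []),
            simulate=raw.get("simulate", {}),
            paths=raw.get("paths", {}),
            params=raw.get("params", {}),
            seeds=raw.get("seeds", {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ConfigError(f"configured path {key} = {p} does not exist")
        if not self.simulate and not self.paths:
            raise ConfigError("config needs either a simulate section or input paths")


@dataclass
class MarkerCall:
    """Codon-level allele frequencies at a resistance marker."""

    marker_id: str
    contig: str
    codon_pos: int  # 1-based position of the first codon base
    counts: dict[str, int]  # allele name -> spanning-read count
    other: int  # reads with a third codon
    frequency: float  # resistant / (resistant + susceptible)
    low_confidence: bool


def codon_allele_freq(
    records: list[svscan.AlignmentRecord],
    contig: str,
    codon_pos: int,
    alleles: dict[str, str],
    resistant: str,
    marker_id: str = "",
    min_coverage: int = 10,
) -> MarkerCall:
    """Count reads whose aligned bases fully span a codon, per allele.

    ``alleles`` maps allele names to codons, e.g. ``{"L": "CTT", "F":
    "TTT"}``; the frequency reported is resistant / (resistant +
    susceptible) over fully spanning reads, with third codons tabulated
    separately.  Coverage below ``min_coverage`` sets a low-confidence flag.
    """
    positions = (codon_pos, codon_pos + 1, codon_pos + 2)
    counts = {name: 0 for name in alleles}
    other = 0
    for r in records:
        if r.contig != contig or r.pos > codon_pos or r.end < codon_pos + 2:
            continue
        bases = r.ref_positions()
        try:
            codon = "".join(bases[p] for p in positions)
        except KeyError:
            continue  # indel or clip interrupts the codon
        for name, allele in alleles.items():
            if codon == allele:
                counts[name] += 1
                break
        else:
            other += 1
    total = sum(counts.values())
    susceptible = total - counts[resistant]
    freq = counts[resistant] / total if total else float("nan")
    return MarkerCall(
        marker_id or f"{contig}:{codon_pos}",
        contig,
        codon_pos,
        counts,
        other,
        freq,
        total + other < min_coverage,
    )


@dataclass
class IndelCall:
    """A within-read indel near an annotated feature."""

    contig: str
    pos: int  # 1-based reference position of the base before the event
    kind: str  # "del" | "ins"
    length: int
    support: int
    spanning: int
    frequency: float


def indel_near_feature(
    records: list[svscan.AlignmentRecord],
    contig: str,
    feature_pos: int,
    radius: int = 100,
    min_flank: int = 5,
) -> list[IndelCall]:
    """Report within-read indels within ``radius`` of a feature position.

    Support is the number of reads carrying the identical indel (same
    position, kind, length); the denominator counts reads whose alignment
    spans the event position with ``min_flank`` aligned bases either side.
    """
    events: dict[tuple[int, str, int], int] = {}
    for r in records:
        if r.contig != contig:
            continue
        rpos = r.pos
        for op, n in r.cigar:
            if op == 0:
                rpos += n
            elif op == 2:  # deletion in read relative to reference
                if abs(rpos - 1 - feature_pos) <= radius:
                    events[(rpos - 1, "del", n)] = events.get((rpos - 1, "del", n), 0) + 1
                rpos += n
            elif op == 1:  # insertion
                if abs(rpos - 1 - feature_pos) <= radius:
                    events[(rpos - 1, "ins", n)] = events.get((rpos - 1, "ins", n), 0) + 1
    calls = []
    for (pos, kind, length), support in sorted(events.items()):
        spanning = 0
        for r in records:
            if r.contig != contig:
                continue
            if r.pos + min_flank - 1 <= pos and r.end - min_flank + 1 >= pos + 1:
                has_event = False
                rpos = r.pos
                for op, n in r.cigar:
                    if op == 0:
                        rpos += n
                    elif op == 2:
                        if rpos - 1 == pos and kind == "del" and n == length:
                            has_event = True
                        rpos += n
                    elif op == 1:
                        if rpos - 1 == pos and kind == "ins" and n == length:
                            has_event = True
                if not has_event:
                    spanning += 1
        total = support + spanning
        calls.append(
            IndelCall(contig, pos, kind, length, support, spanning, support / total if total else float("nan"))
        )
    return calls


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class StageFailure(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(config: Config) -> dict:
    """Execute the configured stages; return (and write) the output manifest.

    Stage order: synthio (optional) -> poolstats -> svscan -> tescan ->
    paralogconv -> report.  A stage failure aborts the run but the partial
    manifest (with an ``error`` entry) is still written.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seeds": dict(config.seeds),
        "params": dict(config.params),
        "outputs": {},
        "stages": [],
    }
    t0 = time.time()

    def record(stage: str, outputs: dict[str, str]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].update(outputs)
        log.info("stage %s done (%.1fs elapsed)", stage, time.time() - t0)

    stage = "init"
    try:
        sim = config.simulate
        if sim:
            stage = "synthio"
            outputs = _run_synthio(config, outdir)
            record(stage, outputs)
        stage = "poolstats"
        record(stage, _run_poolstats(config, outdir))
        stage = "svscan"
        record(stage, _run_svscan(config, outdir))
        stage = "tescan"
        record(stage, _run_tescan(config, outdir))
        stage = "paralogconv"
        record(stage, _run_conversion(config, outdir))
    except Exception as exc:  # noqa: BLE001 - partial manifest on any failure
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageFailure(stage, manifest, exc) from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo_config(output_dir: str, seed: int = 0) -> Config:
    """A self-contained demo: simulate a BAC-scale locus and analyse it."""
    return Config(
        output_dir=output_dir,
        simulate={
            "length": 120_000,
            "n_genes": 13,
            "coverage": 40.0,
            "edits": [
                {"kind": "deletion", "left": 37_410, "right": 43_954, "frequency": 0.2},
                {"kind": "tandem_duplication", "left": 17_910, "right": 24_836, "copies": 2, "frequency": 0.4},
                {"kind": "te_insertion", "left": 76_470, "payload": "mariner1", "tsd_len": 8, "frequency": 0.4},
            ],
            "windows": {"n_windows": 60, "sweep_windows": [30], "theta": 10.0},
            "paralogs": {"n_a": 60, "n_b": 40, "n_converted": 3},
        },
        seeds={"reads": seed, "windows": seed + 1, "paralogs": seed + 2, "subsample": seed + 3},
        params={"subsample_n": 20, "window": 50_000, "step": 25_000},
    )


def _run_synthio(config: Config, outdir: Path) -> dict[str, str]:
    sim = config.simulate
    seed = int(config.seeds.get("reads", 0))
    ref = synthio.build_reference(sim.get("length", 120_000), sim.get("n_genes", 13), seed)
    contig = ref.main_contig()
    base = synthio.apply_edits(ref, [], contig=contig, name="reference")
    haplotypes, freqs, edits = [base], [0.0], []
    for spec_edit in sim.get("edits", []):
        e = dict(spec_edit)
        freq = float(e.pop("frequency", 1.0))
        edit = synthio.StructuralEdit(contig=contig, **e)
        edits.append(edit)
        haplotypes.append(synthio.apply_edits(ref, [edit], contig=contig, name=edit.label))
        freqs.append(freq)
    # remaining frequency mass goes to the unedited haplotype
    if sum(freqs[1:]) > 1.0 + 1e-9:
        raise ConfigError("edit frequencies sum to more than 1")
    freqs[0] = max(0.0, 1.0 - sum(freqs[1:]))
    pool = synthio.HaplotypePool(haplotypes, freqs, pool_size=sim.get("pool_size", 40))
    pairs = synthio.simulate_pool_reads(pool, sim.get("coverage", 40.0), seed=seed)
    out = {
        "reference_fasta": str(outdir / "reference.fa"),
        "alignments_sam": str(outdir / "pool.sam"),
        "truth_bed": str(outdir / "truth.bed"),
        "truth_tsv": str(outdir / "truth.tsv"),
        "site_counts": str(outdir / "site_counts.tsv"),
    }
    synthio.write_reference_fasta(ref, out["reference_fasta"])
    synthio.write_sam(pairs, ref, out["alignments_sam"])
    synthio.write_truth_bed(edits, out["truth_bed"])
    synthio.write_truth_tsv(edits, out["truth_tsv"])

    win = sim.get("windows", {})
    params = synthio.CoalescentWindowParams(
        theta=win.get("theta", 10.0),
        coverage=sim.get("coverage", 40.0),
        sweep_scaling=win.get("sweep_scaling", 0.05),
        seed=int(config.seeds.get("windows", 1)),
    )
    counts = synthio.simulate_window_series(
        params, win.get("n_windows", 40), set(win.get("sweep_windows", []))
    )
    poolstats.write_site_counts({"pool1": counts}, out["site_counts"])

    par = sim.get("paralogs", {})
    records, truth = synthio.simulate_paralog_sequences(
        n_a=par.get("n_a", 60),
        n_b=par.get("n_b", 40),
        n_converted=par.get("n_converted", 3),
        seed=int(config.seeds.get("paralogs", 2)),
    )
    out["paralog_fasta"] = str(outdir / "paralogs.fa")
    synthio.write_paralog_fasta(records, out["paralog_fasta"])
    (outdir / "paralog_truth.json").write_text(json.dumps({"converted": truth.converted_ids}))
    out["paralog_truth"] = str(outdir / "paralog_truth.json")
    return out


def _counts_path(config: Config, outdir: Path) -> str:
    return config.paths.get("counts", str(outdir / "site_counts.tsv"))


def _run_poolstats(config: Config, outdir: Path) -> dict[str, str]:
    p = config.params
    pools = poolstats.read_site_counts(_counts_path(config, outdir))
    n = int(p.get("subsample_n", 20))
    out: dict[str, str] = {}
    for name, df in pools.items():
        filtered = poolstats.filter_sites(
            df, p.get("min_depth", 20), p.get("max_depth_centile", 95)
        )
        sub = poolstats.subsample_table(filtered, n, int(config.seeds.get("subsample", 3)))
        stats = poolstats.window_stats(sub, n, p.get("window", 50_000), p.get("step", 25_000))
        stats_path = outdir / f"window_stats_{name}.tsv"
        stats.to_csv(stats_path, sep="\t", index=False)
        out[f"window_stats_{name}"] = str(stats_path)
        flagged = poolstats.outlier_windows(stats, tail=p.get("tail", 0.001), side="low")
        fl_path = outdir / f"outlier_windows_{name}.tsv"
        flagged.to_csv(fl_path, sep="\t", index=False)
        out[f"outlier_windows_{name}"] = str(fl_path)
    return out


def _load_ref(config: Config, outdir: Path) -> dict[str, str]:
    from Bio import SeqIO

    path = config.paths.get("reference", str(outdir / "reference.fa"))
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _run_svscan(config: Config, outdir: Path) -> dict[str, str]:
    sam = config.paths.get("alignments", str(outdir / "pool.sam"))
    ref = _load_ref(config, outdir)
    svs, _profile = svscan.scan(sam, ref, min_mapq=config.params.get("min_mapq", 10))
    svscan.classify_polymorphic(svs)
    out = {
        "sv_calls_tsv": str(outdir / "sv_calls.tsv"),
        "sv_calls_bed": str(outdir / "sv_calls.bed"),
    }
    svscan.write_sv_tsv(svs, out["sv_calls_tsv"])
    svscan.write_sv_bed(svs, out["sv_calls_bed"])
    return out


def _run_tescan(config: Config, outdir: Path) -> dict[str, str]:
    sam = config.paths.get("alignments", str(outdir / "pool.sam"))
    ref = _load_ref(config, outdir)
    records = svscan.preprocess(svscan.read_alignments(sam))
    te_lib = {
        name: ref[synthio.TE_CONTIG]
        for name in ["mariner1"]
        if synthio.TE_CONTIG in ref
    }
    calls = tescan.call_te_insertions(records, ref, te_lib)
    out = {"te_calls_tsv": str(outdir / "te_calls.tsv")}
    tescan.write_te_tsv(calls, out["te_calls_tsv"])
    return out


def _run_conversion(config: Config, outdir: Path) -> dict[str, str]:
    fasta = config.paths.get("paralogs", str(outdir / "paralogs.fa"))
    aln = paralogconv.SeqAlignment.from_fasta(fasta)
    labels = dict(zip(aln.ids, aln.labels))
    n_reps = int(config.params.get("bootstrap_reps", 100))
    tree, support = paralogconv.bootstrap_support(
        aln, n_reps=n_reps, seed=int(config.seeds.get("paralogs", 2))
    )
    calls = paralogconv.classify_conversion(tree, labels, support=support)
    pdist = paralogconv.pairwise_distances(aln, "p")
    coords = paralogconv.classical_mds(pdist.d, k=2)
    out = {
        "conversion_tree": str(outdir / "paralogs.nwk"),
        "conversion_calls": str(outdir / "conversion_calls.tsv"),
        "mds_coords": str(outdir / "mds_coords.tsv"),
    }
    Path(out["conversion_tree"]).write_text(tree.to_newick() + "\n")
    paralogconv.write_conversion_tsv(calls, out["conversion_calls"])
    paralogconv.write_embedding_tsv(aln.ids, coords, out["mds_coords"])
    return out


def plot_tracks(manifest: dict, outdir: str) -> list[str]:
    """Optional static plots of window statistics (presentation only)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is never load-bearing
        return []
    import pandas as pd

    written = []
    for key, path in manifest.get("outputs", {}).items():
        if not key.startswith("window_stats_"):
            continue
        df = pd.read_csv(path, sep="\t")
        fig, ax = plt.subplots(figsize=(8, 3))
        mid = (df["start"] + df["end"]) / 2
        ax.plot(mid / 1e3, df["tajimas_d"], lw=0.8)
        ax.set_xlabel("position (kb)")
        ax.set_ylabel("Tajima's D")
        out = str(Path(outdir) / f"{key}.png")
        fig.savefig(out, dpi=100)
        plt.close(fig)
        written.append(out)
    return written
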