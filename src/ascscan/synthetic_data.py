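"""Synthetic genomes, expression tables, and orthologous triplets.

The generator emulates the statistical structure the analyses assume:
downstream windows drawn from a configurable first-order dinucleotide
chain (started at its stationary distribution, so every codon position
shares the same null stop probability), primary stops drawn from
configurable usage weights, optional per-position ASC enrichment injected
by rejection-resampling whole windows (preserving the chain's dinucleotide
structure), log-normal expression abundances, and species triplets evolved
from chain-drawn ancestors by per-branch per-site substitution. Every
dataset ships a ground-truth ledger sufficient to recompute the downstream
statistics independently.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_switch import TripletAlignment
from .null_models import NUCS, DinucleotideModel, _IDX
from .sequence_io import (
    STOP_SETS,
    CDSFeature,
    GenomeAnnotation,
    GenomeUTRSet,
    UTRRecord,
    reverse_complement,
)


def iid_model(gc: float = 0.45) -> DinucleotideModel:
    """Memoryless chain with the given GC content (equal strands)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return DinucleotideModel(p, np.tile(p, (4, 1)))


def stationary_distribution(model: DinucleotideModel) -> np.ndarray:
    vals, vecs = np.linalg.eig(model.transition.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def stationary_codon_probability(model: DinucleotideModel, codons) -> float:
    """P(a codon drawn at a stationary chain position is in ``codons``)."""
    pi = stationary_distribution(model)
    T = model.transition
    return float(
        sum(pi[_IDX[a]] * T[_IDX[a], _IDX[b]] * T[_IDX[b], _IDX[c]] for a, b, c in codons)
    )


@dataclass
class SyntheticConfig:
    """Full parameterisation of the generator.

    ``enrichment`` maps codon positions (+1..+6) to a multiplier delta:
    the stop probability at that position becomes (1 + delta) times the
    chain's stationary codon stop probability. ``plus4_bias`` optionally
    maps a primary stop to a 4-vector of first-window-base probabilities.
    ``triplet_rates`` are per-branch per-site substitution probabilities
    (outgroup, ingroup1, ingroup2).
    """

    seed: int = 0
    n_genes: int = 500
    gc: float = 0.45
    model: DinucleotideModel | None = None
    stop_weights: tuple = (0.55, 0.30, 0.15)  # TAA, TGA, TAG
    translation_table: int | str = 11
    enrichment: dict = field(default_factory=dict)
    plus4_bias: dict = field(default_factory=dict)
    expression_sigma: float = 1.0
    window_nt: int = 27
    body_codons: int = 30
    triplet_rates: tuple = (0.01, 0.01, 0.01)
    inframe_stop_loss_boost: float = 0.0
    genome_id: str = "synth"
    organism_name: str = "Synthia exemplaris"

    def chain(self) -> DinucleotideModel:
        return self.model if self.model is not None else iid_model(self.gc)

    @property
    def stop_set(self):
        return STOP_SETS[self.translation_table]

    def validate(self) -> None:
        if abs(sum(self.stop_weights) - 1) > 1e-9:
            raise ValueError("stop_weights must sum to 1")
        p0 = stationary_codon_probability(self.chain(), self.stop_set)
        for k, delta in self.enrichment.items():
            if delta < 0:
                raise ValueError("enrichment multipliers must be >= 0")
            if (1 + delta) * p0 > 1:
                raise ValueError(
                    f"infeasible enrichment at +{k}: (1+{delta}) * {p0:.4f} > 1"
                )


# ---------------------------------------------------------------------------
# Window generation


def _draw_chain(
    model: DinucleotideModel, n: int, length: int, rng: np.random.Generator,
    start_dist: np.ndarray,
) -> np.ndarray:
    seqs = np.empty((n, length), dtype=np.int8)
    cum0 = np.cumsum(start_dist)
    seqs[:, 0] = np.searchsorted(cum0, rng.random(n) * cum0[-1], side="right")
    cumT = np.cumsum(model.transition, axis=1)
    for j in range(1, length):
        rows = cumT[seqs[:, j - 1]]
        u = rng.random(n) * rows[:, -1]
        seqs[:, j] = (u[:, None] >= rows).sum(axis=1)
    return seqs


def _to_str(row: np.ndarray) -> str:
    return "".join(NUCS[i] for i in row)


def draw_windows(config: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], list[dict]]:
    """Draw n_genes downstream windows from the chain, injecting the
    configured per-position enrichment by rejection-resampling whole
    windows until each flagged position matches its drawn stop indicator.
    Returns the windows and a per-gene ledger of planted indicators."""
    config.validate()
    model = config.chain()
    pi = stationary_distribution(model)
    n, L = config.n_genes, config.window_nt
    stop_set = config.stop_set
    p0 = stationary_codon_probability(model, stop_set)

    def stop_at(row: np.ndarray, k: int) -> bool:
        return _to_str(row[3 * (k - 1) : 3 * k]) in stop_set

    windows = [_to_str(r) for r in _draw_chain(model, n, L, rng, pi)]
    ledger = [{"planted": {}} for _ in range(n)]
    if config.enrichment:
        targets = {k: (1 + d) * p0 for k, d in config.enrichment.items()}
        for i in range(n):
            want = {k: bool(rng.random() < t) for k, t in targets.items()}
            row = _draw_chain(model, 1, L, rng, pi)[0]
            while not all(stop_at(row, k) == w for k, w in want.items()):
                row = _draw_chain(model, 1, L, rng, pi)[0]
            windows[i] = _to_str(row)
            ledger[i]["planted"] = {str(k): w for k, w in want.items()}
    return windows, ledger


def _draw_primary_stops(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    stops = ("TAA", "TGA", "TAG") if config.translation_table != 4 else ("TAA", "TAG", "TAG")
    weights = np.asarray(config.stop_weights, dtype=float)
    if config.translation_table == 4:
        weights = np.array([weights[0], 0.0, weights[1] + weights[2]])
    weights = weights / weights.sum()
    idx = rng.choice(3, size=config.n_genes, p=weights)
    return [stops[i] for i in idx]


def generate_utr_set(config: SyntheticConfig) -> tuple[GenomeUTRSet, list[dict]]:
    """Fast in-memory path: a GenomeUTRSet drawn directly from the chain,
    bypassing flat-file round-tripping. Same draws as generate_genome."""
    rng = np.random.default_rng(config.seed)
    windows, ledger = draw_windows(config, rng)
    stops = _draw_primary_stops(config, rng)
    if config.plus4_bias:
        windows = _apply_plus4_bias(config, windows, stops, rng)
    records = [
        UTRRecord(f"{config.genome_id}_g{i + 1:05d}", stops[i], windows[i])
        for i in range(config.n_genes)
    ]
    for entry, rec in zip(ledger, records):
        entry["gene_id"] = rec.gene_id
        entry["primary_stop"] = rec.primary_stop
        entry["window"] = rec.downstream_seq
    gc3 = float(config.chain().initial[1] + config.chain().initial[2])
    utr_set = GenomeUTRSet(
        config.genome_id, config.stop_set, gc3, records, config.translation_table
    )
    return utr_set, ledger


def _apply_plus4_bias(config, windows, stops, rng) -> list[str]:
    """Overwrite the first window base per primary stop with a draw from
    the configured base distribution, then redraw the remainder of the
    window from the chain so transitions stay consistent."""
    model = config.chain()
    out = []
    for w, s in zip(windows, stops):
        dist = config.plus4_bias.get(s)
        if dist is None:
            out.append(w)
            continue
        first = rng.choice(4, p=np.asarray(dist) / np.sum(dist))
        rest = _draw_chain(model, 1, len(w), rng, np.eye(4)[first])[0]
        out.append(_to_str(rest))
    return out


# ---------------------------------------------------------------------------
# Full genome emission (EMBL flat file + expression table + ledger)


def _draw_cds(config: SyntheticConfig, stop: str, rng: np.random.Generator) -> str:
    """ATG + body_codons chain-drawn sense codons (stops rejected) + stop."""
    model = config.chain()
    pi = stationary_distribution(model)
    codons = ["ATG"]
    prev = _IDX["G"]
    cumT = np.cumsum(model.transition, axis=1)
    for _ in range(config.body_codons):
        while True:
            c = []
            p = prev
            for _ in range(3):
                p = int(np.searchsorted(cumT[p], rng.random() * cumT[p][-1], side="right"))
                c.append(p)
            codon = _to_str(np.array(c))
            if codon not in config.stop_set:
                codons.append(codon)
                prev = c[-1]
                break
    codons.append(stop)
    return "".join(codons)


def build_annotation(
    config: SyntheticConfig, pad: int = 60, tail: int = 13
) -> tuple[GenomeAnnotation, dict[str, float], list[dict]]:
    """Assemble a single-replicon annotation whose qualifying genes carry
    exactly the drawn primary stops and windows.

    Gene cassettes (CDS + window + random tail) alternate strands; the
    tail keeps every 3' intergenic distance above the default filters.
    Also returns per-gene expression abundances (log-normal) and the
    ground-truth ledger.
    """
    rng = np.random.default_rng(config.seed)
    windows, ledger = draw_windows(config, rng)
    stops = _draw_primary_stops(config, rng)
    if config.plus4_bias:
        windows = _apply_plus4_bias(config, windows, stops, rng)
    model = config.chain()
    pi = stationary_distribution(model)

    parts = [_to_str(_draw_chain(model, 1, pad, rng, pi)[0])]
    pos = pad
    features = []
    expression: dict[str, float] = {}
    for i in range(config.n_genes):
        gene_id = f"{config.genome_id}_g{i + 1:05d}"
        cds = _draw_cds(config, stops[i], rng)
        spacer = _to_str(_draw_chain(model, 1, tail, rng, pi)[0])
        cassette = cds + windows[i] + spacer
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            features.append((gene_id, pos, pos + len(cds), strand))
            parts.append(cassette)
        else:
            features.append((gene_id, pos + len(cassette) - len(cds), pos + len(cassette), strand))
            parts.append(reverse_complement(cassette))
        pos += len(cassette)
        expression[gene_id] = float(rng.lognormal(0.0, config.expression_sigma))
        ledger[i].update(
            gene_id=gene_id, primary_stop=stops[i], window=windows[i], strand=strand,
            abundance=expression[gene_id],
        )
    parts.append(_to_str(_draw_chain(model, 1, pad, rng, pi)[0]))
    sequence = "".join(parts)

    annotation = GenomeAnnotation(
        genome_id=config.genome_id,
        organism_name=config.organism_name,
        replicons={config.genome_id: sequence},
        cds_features=[CDSFeature(g, config.genome_id, s, e, st) for g, s, e, st in features],
        translation_table=config.translation_table,
        topology={config.genome_id: "linear"},
    )
    return annotation, expression, ledger


def write_flatfile(annotation: GenomeAnnotation, path) -> None:
    """Emit the annotation as an EMBL flat file (one entry per replicon)."""
    records = []
    for rid, seq in annotation.replicons.items():
        rec = SeqRecord(Seq(seq), id=rid, name=rid, description=annotation.organism_name)
        rec.annotations["molecule_type"] = "genomic DNA"
        rec.annotations["topology"] = annotation.topology.get(rid, "linear")
        rec.annotations["organism"] = annotation.organism_name
        rec.annotations["accessions"] = [rid]
        for f in annotation.cds_features:
            if f.replicon_id != rid:
                continue
            loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
            feat = SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "locus_tag": [f.locus_tag],
                    "transl_table": [str(annotation.translation_table)],
                },
            )
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "embl")


def generate_genome(config: SyntheticConfig, outdir) -> dict:
    """Write flat file, expression TSV, and ground-truth ledger; returns
    the paths. Output is deterministic for a fixed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, expression, ledger = build_annotation(config)
    paths = {
        "flatfile": outdir / f"{config.genome_id}.embl",
        "expression": outdir / f"{config.genome_id}.abundance.tsv",
        "ledger": outdir / f"{config.genome_id}.ledger.json",
    }
    write_flatfile(annotation, paths["flatfile"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tabundance\n")
        for gene, value in expression.items():
            fh.write(f"{gene}\t{value:.6g}\n")
    with open(paths["ledger"], "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "n_genes": config.n_genes,
                "enrichment": {str(k): v for k, v in config.enrichment.items()},
                "translation_table": str(config.translation_table),
                "genes": ledger,
            },
            fh,
            indent=1,
        )
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Orthologous triplets


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = (out[i] + 1 + rng.integers(3)) % 4
    return out, hits.tolist()


def generate_triplets(
    config: SyntheticConfig, n_orthogroups: int, outdir=None
) -> tuple[list[TripletAlignment], list[dict]]:
    """Evolve gapless aligned triplets from chain-drawn ancestors.

    Each branch (outgroup, ingroup1, ingroup2) substitutes independently
    per site at its configured rate — frame-agnostic, so in-frame and
    +1-shift switch rates are equal in expectation. With
    ``inframe_stop_loss_boost`` > 0, ancestral in-frame stop codons on the
    ingroup branches are additionally overwritten with a random non-stop
    codon at that extra per-codon probability (plants elevated in-frame
    stop loss). The ledger stores ancestral and derived sequences plus
    mutated sites per branch. Optionally writes one aligned FASTA per
    orthogroup and a manifest.
    """
    if max(config.triplet_rates) > 0.3:
        warnings.warn("substitution rate > 0.3/site strains parsimony assumptions")
    rng = np.random.default_rng(config.seed)
    model = config.chain()
    pi = stationary_distribution(model)
    L = config.window_nt
    stop_set = config.stop_set
    non_stops = [
        c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3))
        if c not in stop_set
    ]
    triplets, ledger = [], []
    ancestors = _draw_chain(model, n_orthogroups, L, rng, pi)
    for i in range(n_orthogroups):
        anc = ancestors[i]
        og_id = f"og{i + 1:05d}"
        branches, sites = {}, {}
        for name, rate in zip(("outgroup", "ingroup1", "ingroup2"), config.triplet_rates):
            seq, hits = _mutate(anc, rate, rng)
            if config.inframe_stop_loss_boost and name != "outgroup":
                for k in range(L // 3):
                    codon = _to_str(anc[3 * k : 3 * k + 3])
                    if codon in stop_set and rng.random() < config.inframe_stop_loss_boost:
                        repl = non_stops[rng.integers(len(non_stops))]
                        seq[3 * k : 3 * k + 3] = [_IDX[b] for b in repl]
                        hits.extend(range(3 * k, 3 * k + 3))
            branches[name] = _to_str(seq)
            sites[name] = sorted(set(hits))
        triplets.append(
            TripletAlignment(og_id, branches["outgroup"], branches["ingroup1"], branches["ingroup2"])
        )
        ledger.append(
            {
                "orthogroup_id": og_id,
                "ancestral": _to_str(anc),
                "sequences": branches,
                "mutated_sites": sites,
            }
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.tsv", "w") as mf:
            for trip in triplets:
                fasta = outdir / f"{trip.orthogroup_id}.fasta"
                with open(fasta, "w") as fh:
                    fh.write(f">outgroup\n{trip.outgroup_seq}\n")
                    fh.write(f">ingroup1\n{trip.ingroup1_seq}\n")
                    fh.write(f">ingroup2\n{trip.ingroup2_seq}\n")
                mf.write(f"{trip.orthogroup_id}\t{fasta}\n")
        with open(outdir / "triplets.ledger.json", "w") as fh:
            json.dump({"seed": config.seed, "orthogroups": ledger}, fh, indent=1)
    return triplets, ledger


def ledger_switch_counts(ledger: list[dict], frame: str, stop_set, positions=(1, 2, 3, 4, 5, 6)) -> dict:
    """Ground-truth oracle: count true single-ingroup-branch switch events
    recoverable by parsimony (the other two branches untouched in that
    codon and outgroup codon equal to ancestral)."""
    shift = {"in-frame": 0, "+1 shift": 1}[frame]
    counts = {"ancestral_stop": 0, "stop_to_ns": 0, "ancestral_ns": 0, "ns_to_stop": 0}
    for entry in ledger:
        anc = entry["ancestral"]
        seqs = entry["sequences"]
        for k in positions:
            lo = shift + 3 * (k - 1)
            hi = lo + 3
            if hi > len(anc):
                continue
            a = anc[lo:hi]
            cods = {n: seqs[n][lo:hi] for n in seqs}
            changed = [n for n in cods if cods[n] != a]
            if cods["outgroup"] != a:
                continue  # parsimony anchor broken or ambiguous
            if len(changed) > 1:
                continue
            if a in stop_set:
                counts["ancestral_stop"] += 1
            else:
                counts["ancestral_ns"] += 1
            if len(changed) == 1:
                derived = cods[changed[0]]
                if a in stop_set and derived not in stop_set:
                    counts["stop_to_ns"] += 1
                elif a not in stop_set and derived in stop_set:
                    counts["ns_to_stop"] += 1
    return counts
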