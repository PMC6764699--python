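"""Genome flat-file parsing, UTR window extraction, and gene filtering.

The analyses in this package operate on one record per qualifying gene: the
gene's primary (annotated) stop codon plus a fixed-length window of
downstream sequence on the coding strand. This module reads annotated
genomes (EMBL or GenBank dialect), applies the qualifying-gene filters
(coding length a multiple of three, a single in-frame stop which is the
terminal codon, clean ACGT sequence, sufficient 3' intergenic space), and
computes per-genome GC3 and expression classes.

Coordinates are 0-based half-open internally; flat-file I/O converts
from/to the 1-based inclusive convention at the parsing boundary only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Stop-codon sets by translation table. Table 4 (some mollicutes)
#: reassigns TGA to tryptophan; "TGA-only" covers ciliate-style codes
#: where TGA is the sole stop.
STOP_SETS: dict[int | str, frozenset[str]] = {
    1: frozenset({"TAA", "TGA", "TAG"}),
    11: frozenset({"TAA", "TGA", "TAG"}),
    4: frozenset({"TAA", "TAG"}),
    "TGA-only": frozenset({"TGA"}),
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FlatFileParseError(ValueError):
    """Raised when a genome flat file cannot be parsed."""


@dataclass(frozen=True)
class CDSFeature:
    """One CDS feature; start/end are 0-based half-open on the replicon."""

    locus_tag: str
    replicon_id: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass
class GenomeAnnotation:
    genome_id: str
    organism_name: str
    replicons: dict[str, str]  # replicon_id -> uppercase sequence
    cds_features: list[CDSFeature]
    translation_table: int | str = 11
    topology: dict[str, str] = field(default_factory=dict)  # id -> linear|circular

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())

    @property
    def genus(self) -> str:
        return self.organism_name.split()[0] if self.organism_name else ""


@dataclass
class UTRRecord:
    """A gene's primary stop plus its downstream window on the coding strand."""

    gene_id: str
    primary_stop: str
    downstream_seq: str
    expression_class: str = "NA"  # HEG | LEG | NA


@dataclass
class GenomeUTRSet:
    genome_id: str
    stop_set: frozenset[str]
    gc3: float
    records: list[UTRRecord]
    translation_table: int | str = 11
    expression_eligible: bool = False
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def subset(self, records: list[UTRRecord]) -> "GenomeUTRSet":
        return replace(self, records=records)


def read_flatfile(path, dialect: str = "EMBL") -> GenomeAnnotation:
    """Parse an EMBL or GenBank flat file into a :class:`GenomeAnnotation`.

    Every CDS feature with resolvable coordinates on a single replicon is
    captured; features whose coordinates exceed the replicon length are
    rejected with a logged warning. A malformed file raises
    :class:`FlatFileParseError` and no partial annotation is returned.
    """
    fmt = {"EMBL": "embl", "GENBANK": "genbank"}.get(dialect.upper())
    if fmt is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'EMBL' or 'GenBank'")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FlatFileParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if not records:
        raise FlatFileParseError(f"no records found in {path} ({dialect})")

    replicons: dict[str, str] = {}
    topology: dict[str, str] = {}
    features: list[CDSFeature] = []
    organism = ""
    tables: list[int] = []
    anon = 0
    for rec in records:
        seq = str(rec.seq).upper()
        replicons[rec.id] = seq
        topology[rec.id] = rec.annotations.get("topology", "linear")
        organism = organism or rec.annotations.get("organism", "")
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None:
                logger.warning("CDS without location in %s skipped", rec.id)
                continue
            start, end = int(loc.start), int(loc.end)
            if end > len(seq) or start < 0:
                logger.warning(
                    "CDS %s coordinates %d..%d beyond %s length %d; rejected",
                    feat.qualifiers.get("locus_tag", ["?"])[0],
                    start + 1,
                    end,
                    rec.id,
                    len(seq),
                )
                continue
            tag = feat.qualifiers.get("locus_tag", [None])[0]
            if tag is None:
                anon += 1
                tag = f"cds_{anon:05d}"
            strand = "-" if loc.strand == -1 else "+"
            if "transl_table" in feat.qualifiers:
                try:
                    tables.append(int(feat.qualifiers["transl_table"][0]))
                except (TypeError, ValueError):
                    pass
            features.append(CDSFeature(tag, rec.id, start, end, strand))

    table: int | str = 11
    if tables:
        table = max(set(tables), key=tables.count)
    return GenomeAnnotation(
        genome_id=records[0].id,
        organism_name=organism,
        replicons=replicons,
        cds_features=features,
        translation_table=table,
        topology=topology,
    )


def compute_gc3(cds_sequences: list[str]) -> float:
    """Unweighted mean of per-gene GC3 over sense codons (stop excluded).

    Per-gene GC3 is the fraction of third-codon-position bases in {G, C},
    counting every codon except the terminal stop.
    """
    if not cds_sequences:
        raise ValueError("compute_gc3 requires at least one sequence")
    per_gene = []
    for seq in cds_sequences:
        if len(seq) % 3:
            raise ValueError("CDS length must be a multiple of 3")
        thirds = seq[2:-3:3]  # third positions, terminal codon dropped
        if not thirds:
            per_gene.append(0.0)
            continue
        per_gene.append(sum(1 for b in thirds if b in "GC") / len(thirds))
    return float(np.mean(per_gene))


def _cds_sequence(annotation: GenomeAnnotation, feat: CDSFeature) -> str:
    seq = annotation.replicons[feat.replicon_id][feat.start : feat.end]
    return reverse_complement(seq) if feat.strand == "-" else seq


def _downstream_window(
    annotation: GenomeAnnotation, feat: CDSFeature, window_nt: int
) -> str | None:
    """window_nt nucleotides 3' of the CDS on the coding strand, or None
    if the window runs off a linear replicon end."""
    replicon = annotation.replicons[feat.replicon_id]
    n = len(replicon)
    circular = annotation.topology.get(feat.replicon_id) == "circular"
    if feat.strand == "+":
        lo, hi = feat.end, feat.end + window_nt
        if hi <= n:
            return replicon[lo:hi]
        if circular:
            return replicon[lo:] + replicon[: hi - n]
        return None
    lo, hi = feat.start - window_nt, feat.start
    if lo >= 0:
        return reverse_complement(replicon[lo:hi])
    if circular:
        return reverse_complement(replicon[lo % n :] + replicon[:hi])
    return None


def _intergenic_distance(
    annotation: GenomeAnnotation, feat: CDSFeature, others: list[CDSFeature]
) -> int:
    """Nucleotides between the focal CDS 3' end and the nearest boundary of
    any other CDS (either strand) in the focal gene's downstream direction.
    Falls back to the distance to the replicon end on linear replicons."""
    n = len(annotation.replicons[feat.replicon_id])
    circular = annotation.topology.get(feat.replicon_id) == "circular"
    if feat.strand == "+":
        three_prime = feat.end  # first downstream base index
        dists = []
        for o in others:
            for b in (o.start, o.end):
                d = b - three_prime
                if circular:
                    d %= n
                if d >= 0:
                    dists.append(d)
        if not dists:
            return n if circular else n - three_prime
        return min(dists)
    three_prime = feat.start  # exclusive; downstream runs leftward
    dists = []
    for o in others:
        for b in (o.start, o.end):
            d = three_prime - b
            if circular:
                d %= n
            if d >= 0:
                dists.append(d)
    if not dists:
        return n if circular else three_prime
    return min(dists)


def extract_utr_records(
    annotation: GenomeAnnotation,
    window_nt: int = 27,
    min_intergenic: int = 30,
    stop_set: frozenset[str] | None = None,
) -> GenomeUTRSet:
    """Extract qualifying primary-stop + downstream-window records.

    A gene qualifies if its CDS length is a multiple of three, its codons
    contain exactly one stop which is the terminal codon, both CDS and
    window are pure ACGT, the window is not truncated by a linear replicon
    end, and the 3' intergenic space exceeds ``min_intergenic``.
    Exclusion counts per rule are stored on the returned set.
    """
    if stop_set is None:
        stop_set = STOP_SETS.get(annotation.translation_table, STOP_SETS[11])
    excl = {
        "length_not_multiple_of_3": 0,
        "non_acgt_cds": 0,
        "no_terminal_stop": 0,
        "internal_stop": 0,
        "window_truncated": 0,
        "non_acgt_window": 0,
        "intergenic_too_short": 0,
    }
    if not annotation.cds_features:
        warnings.warn(f"genome {annotation.genome_id} has no CDS features")
        return GenomeUTRSet(
            annotation.genome_id, stop_set, float("nan"), [],
            annotation.translation_table, exclusions=excl,
        )

    by_replicon: dict[str, list[CDSFeature]] = {}
    for f in sorted(annotation.cds_features, key=lambda f: (f.replicon_id, f.start, f.end, f.locus_tag)):
        by_replicon.setdefault(f.replicon_id, []).append(f)

    records: list[UTRRecord] = []
    kept_cds: list[str] = []
    for replicon_id in sorted(by_replicon):
        feats = by_replicon[replicon_id]
        for feat in feats:
            cds = _cds_sequence(annotation, feat)
            if len(cds) % 3:
                excl["length_not_multiple_of_3"] += 1
                continue
            if any(b not in "ACGT" for b in cds):
                excl["non_acgt_cds"] += 1
                continue
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            if not codons or codons[-1] not in stop_set:
                excl["no_terminal_stop"] += 1
                continue
            if any(c in stop_set for c in codons[1:-1]):
                excl["internal_stop"] += 1
                continue
            window = _downstream_window(annotation, feat, window_nt)
            if window is None:
                excl["window_truncated"] += 1
                continue
            if any(b not in "ACGT" for b in window):
                excl["non_acgt_window"] += 1
                continue
            others = [o for o in feats if o is not feat]
            if _intergenic_distance(annotation, feat, others) <= min_intergenic:
                excl["intergenic_too_short"] += 1
                continue
            records.append(UTRRecord(feat.locus_tag, codons[-1], window))
            kept_cds.append(cds)

    gc3 = compute_gc3(kept_cds) if kept_cds else float("nan")
    return GenomeUTRSet(
        annotation.genome_id, stop_set, gc3, records,
        annotation.translation_table, exclusions=excl,
    )


def filter_genomes(
    annotations: list[GenomeAnnotation],
    min_genome_nt: int = 500_000,
    min_genes: int = 100,
    one_per_genus: bool = True,
) -> list[GenomeAnnotation]:
    """Genome-level filters: size floor, annotated-CDS floor, one genome per
    genus (the largest by total nucleotides is kept). Output ordering is
    deterministic (sorted by genome_id)."""
    kept = [
        a
        for a in annotations
        if a.total_length > min_genome_nt and len(a.cds_features) > min_genes
    ]
    if one_per_genus:
        best: dict[str, GenomeAnnotation] = {}
        for a in kept:
            if not a.organism_name:
                raise ValueError(f"genome {a.genome_id} lacks organism_name for genus dedup")
            g = a.genus
            if g not in best or a.total_length > best[g].total_length:
                best[g] = a
        kept = list(best.values())
    return sorted(kept, key=lambda a: a.genome_id)


# ---------------------------------------------------------------------------
# Expression tables and HEG/LEG classing


def read_expression_table(path, id_map: dict[str, str] | None = None) -> dict[str, float]:
    """Two-column tab-separated gene-id -> abundance table; header optional.

    ``id_map`` translates external ids to locus tags (the flat-file ids).
    """
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            gene, raw = parts[0], parts[1]
            try:
                value = float(raw)
            except ValueError:
                continue  # header row
            if value < 0:
                raise ValueError(f"negative abundance for {gene}")
            if id_map is not None:
                gene = id_map.get(gene, gene)
            table[gene] = value
    return table


def classify_expression(
    table: dict[str, float],
    utr_set: GenomeUTRSet,
    min_per_class: int = 100,
) -> GenomeUTRSet:
    """Assign HEG/LEG classes by abundance quartiles of the matched genes.

    Top-quartile genes become HEG, bottom-quartile LEG, everything else
    (including genes absent from the table) NA. Ties are resolved by stable
    input order. The genome is flagged expression-eligible only when both
    classes exceed ``min_per_class``.
    """
    matched = [(i, r) for i, r in enumerate(utr_set.records) if r.gene_id in table]
    new_records = [replace(r, expression_class="NA") for r in utr_set.records]
    n = len(matched)
    k = n // 4
    if k:
        abund = np.array([table[r.gene_id] for _, r in matched])
        # single stable ascending sort keeps the classes disjoint under ties:
        # LEG takes the lowest quartile, HEG the highest, ties broken by
        # input order
        order = np.argsort(abund, kind="stable")
        for j in order[:k]:
            i, r = matched[j]
            new_records[i] = replace(r, expression_class="LEG")
        for j in order[-k:]:
            i, r = matched[j]
            new_records[i] = replace(r, expression_class="HEG")
    n_heg = sum(1 for r in new_records if r.expression_class == "HEG")
    n_leg = sum(1 for r in new_records if r.expression_class == "LEG")
    eligible = n_heg > min_per_class and n_leg > min_per_class
    if not table:
        eligible = False
    return replace(utr_set, records=new_records, expression_eligible=eligible)


# ---------------------------------------------------------------------------
# Serialisation


def write_utr_tsv(utr_set: GenomeUTRSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# genome_id={utr_set.genome_id}\ttranslation_table={utr_set.translation_table}"
            f"\tgc3={utr_set.gc3:.6f}\n"
        )
        fh.write("gene_id\tprimary_stop\tdownstream_seq\texpression_class\n")
        for r in utr_set.records:
            fh.write(f"{r.gene_id}\t{r.primary_stop}\t{r.downstream_seq}\t{r.expression_class}\n")


def read_utr_tsv(path) -> GenomeUTRSet:
    genome_id, table, gc3 = "unknown", 11, float("nan")
    records: list[UTRRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for kv in line[1:].strip().split("\t"):
                    key, _, val = kv.partition("=")
                    if key == "genome_id":
                        genome_id = val
                    elif key == "translation_table":
                        table = val if val == "TGA-only" else int(val)
                    elif key == "gc3":
                        gc3 = float(val)
                continue
            if not line or line.startswith("gene_id\t"):
                continue
            gene, stop, seq, cls = line.split("\t")
            records.append(UTRRecord(gene, stop, seq, cls))
    return GenomeUTRSet(genome_id, STOP_SETS.get(table, STOP_SETS[11]), gc3, records, table)


def write_utr_fasta(utr_set: GenomeUTRSet, path) -> None:
    with open(path, "w") as fh:
        for r in utr_set.records:
            fh.write(f">{r.gene_id}\n{r.primary_stop}{r.downstream_seq}\n")
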