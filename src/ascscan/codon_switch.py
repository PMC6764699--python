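"""Parsimony counting of stop<->non-stop codon switches in species triplets.

Given aligned, gapless downstream regions from an outgroup and two ingroup
species, the ancestral codon at each downstream position is inferred where
the outgroup codon matches at least one ingroup codon; a switch is recorded
where one ingroup codon differs from both the other ingroup and the
outgroup. In-frame switch rates are compared against the same sequences
read in the +1-shifted frame, which serves as the null: a frame-agnostic
substitution process gives equal rates in both frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .enrichment import TestResult

logger = logging.getLogger(__name__)

POSITIONS = (1, 2, 3, 4, 5, 6)
FRAME_OFFSETS = {"in-frame": 0, "+1 shift": 1}


@dataclass
class TripletAlignment:
    """Aligned downstream regions (after each gene's primary stop) for one
    orthogroup: outgroup plus two ingroup species."""

    orthogroup_id: str
    outgroup_seq: str
    ingroup1_seq: str
    ingroup2_seq: str

    @property
    def gapless(self) -> bool:
        return all(
            set(s) <= set("ACGT")
            for s in (self.outgroup_seq, self.ingroup1_seq, self.ingroup2_seq)
        )

    def __post_init__(self):
        if not (len(self.outgroup_seq) == len(self.ingroup1_seq) == len(self.ingroup2_seq)):
            raise ValueError(f"unequal aligned lengths in {self.orthogroup_id}")


@dataclass
class SwitchCounts:
    """Ancestral-codon and switch tallies per position and pooled."""

    frame: str
    ancestral_stop: dict = field(default_factory=dict)  # position -> count
    stop_to_ns: dict = field(default_factory=dict)
    ancestral_ns: dict = field(default_factory=dict)
    ns_to_stop: dict = field(default_factory=dict)

    def total(self, which: str) -> int:
        return sum(getattr(self, which).values())

    def frequency(self, switch: str) -> float:
        """Pooled switch frequency: switch count / ancestral count."""
        if switch == "stop_to_ns":
            return self.total("stop_to_ns") / self.total("ancestral_stop")
        if switch == "ns_to_stop":
            return self.total("ns_to_stop") / self.total("ancestral_ns")
        raise ValueError(switch)


def infer_ancestral_and_switch(out_codon: str, in1_codon: str, in2_codon: str, stop_set):
    """Parsimony call for one codon column.

    Returns (ancestral, switch) where ancestral is the outgroup codon when
    it matches at least one ingroup codon (else None), and switch is
    ``(derived_codon, kind)`` with kind in {"stop_to_ns", "ns_to_stop",
    "other"} when exactly one ingroup deviates from both the other ingroup
    and the outgroup (else None).
    """
    if out_codon not in (in1_codon, in2_codon):
        return None, None
    ancestral = out_codon
    derived = None
    if in1_codon != ancestral and in1_codon != in2_codon:
        derived = in1_codon
    elif in2_codon != ancestral and in2_codon != in1_codon:
        derived = in2_codon
    if derived is None:
        return ancestral, None
    anc_stop, der_stop = ancestral in stop_set, derived in stop_set
    if anc_stop and not der_stop:
        kind = "stop_to_ns"
    elif not anc_stop and der_stop:
        kind = "ns_to_stop"
    else:
        kind = "other"
    return ancestral, (derived, kind)


def count_switches(
    triplets: list[TripletAlignment],
    frame: str = "in-frame",
    positions=POSITIONS,
    stop_set=frozenset({"TAA", "TGA", "TAG"}),
) -> SwitchCounts:
    """Tally ancestral codons and switches over gapless triplets.

    In-frame codons sit at nucleotide offsets 0, 3, ..., 15 after the
    primary stop; the +1-shifted frame reads offsets 1, 4, ..., 16. Codons
    containing non-ACGT characters in any of the three sequences are
    excluded; orthogroups too short for a position skip that position.
    """
    shift = FRAME_OFFSETS[frame]
    counts = SwitchCounts(
        frame,
        {k: 0 for k in positions},
        {k: 0 for k in positions},
        {k: 0 for k in positions},
        {k: 0 for k in positions},
    )
    for trip in triplets:
        if not trip.gapless:
            logger.info("orthogroup %s not gapless; skipped", trip.orthogroup_id)
            continue
        for k in positions:
            lo = shift + 3 * (k - 1)
            hi = lo + 3
            if hi > len(trip.outgroup_seq):
                continue
            codons = (
                trip.outgroup_seq[lo:hi],
                trip.ingroup1_seq[lo:hi],
                trip.ingroup2_seq[lo:hi],
            )
            if any(set(c) - set("ACGT") for c in codons):
                continue
            ancestral, switch = infer_ancestral_and_switch(*codons, stop_set)
            if ancestral is None:
                continue
            if ancestral in stop_set:
                counts.ancestral_stop[k] += 1
                if switch and switch[1] == "stop_to_ns":
                    counts.stop_to_ns[k] += 1
            else:
                counts.ancestral_ns[k] += 1
                if switch and switch[1] == "ns_to_stop":
                    counts.ns_to_stop[k] += 1
    return counts


def _chi2_2x2(a_hit, a_n, b_hit, b_n) -> tuple[float, float] | None:
    if a_hit + b_hit == 0 or a_hit + b_hit == a_n + b_n:
        return None  # a margin is empty; the test is undefined
    table = [[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]]
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_switch_rates(
    inframe: SwitchCounts, shifted: SwitchCounts, per_position: bool = True
) -> list[TestResult]:
    """Two-tailed 2x2 Pearson chi-squares (no continuity correction) of
    switch rates, in-frame vs +1 shift, pooled and per position. Cells
    with zero ancestral counts skip the test. Per-position results carry a
    0.05/6 Bonferroni significance note."""
    results: list[TestResult] = []
    for kind, anc in (("stop_to_ns", "ancestral_stop"), ("ns_to_stop", "ancestral_ns")):
        a_n, b_n = inframe.total(anc), shifted.total(anc)
        pooled = _chi2_2x2(inframe.total(kind), a_n, shifted.total(kind), b_n) if a_n and b_n else None
        if pooled is not None:
            stat, p = pooled
            results.append(
                TestResult(
                    f"{kind}@total", stat, p, df=1,
                    extra={
                        "inframe": (inframe.total(kind), a_n),
                        "shifted": (shifted.total(kind), b_n),
                    },
                )
            )
        if not per_position:
            continue
        for k in getattr(inframe, anc):
            a_k, b_k = getattr(inframe, anc)[k], getattr(shifted, anc)[k]
            if a_k == 0 or b_k == 0:
                logger.info("zero ancestral count at +%d for %s; skipped", k, kind)
                continue
            res = _chi2_2x2(getattr(inframe, kind)[k], a_k, getattr(shifted, kind)[k], b_k)
            if res is None:
                continue
            stat, p = res
            results.append(
                TestResult(
                    f"{kind}@{k}", stat, p, df=1,
                    extra={"bonferroni_significant": p < 0.05 / 6},
                )
            )
    return results


# ---------------------------------------------------------------------------
# I/O: one aligned FASTA per orthogroup (outgroup, ingroup1, ingroup2) plus
# a manifest table


def read_triplet_fasta(path, orthogroup_id: str | None = None) -> TripletAlignment:
    names, seqs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                seqs.append([])
            elif line:
                seqs[-1].append(line.upper())
    if len(seqs) != 3:
        raise ValueError(f"{path}: expected 3 records, found {len(seqs)}")
    joined = ["".join(s) for s in seqs]
    return TripletAlignment(orthogroup_id or names[0], *joined)


def read_manifest(path) -> list[tuple[str, str]]:
    """Manifest rows: orthogroup_id <tab> fasta path."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            og, fasta = line.split("\t")[:2]
            rows.append((og, fasta))
    return rows


def write_switch_table(inframe: SwitchCounts, shifted: SwitchCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "switch\tframe\tancestral_codons\tswitch_count\tswitch_frequency\n"
        )
        for counts in (inframe, shifted):
            for kind, anc in (("stop_to_ns", "ancestral_stop"), ("ns_to_stop", "ancestral_ns")):
                n = counts.total(anc)
                c = counts.total(kind)
                f = c / n if n else float("nan")
                fh.write(f"{kind}\t{counts.frame}\t{n}\t{c}\t{f:.4f}\n")
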