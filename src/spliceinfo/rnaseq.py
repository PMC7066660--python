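"""Junction-read evidence classification around a variant-affected exon.

Spliced-alignment summaries (read id, contig, aligned blocks, optional base
observed at the variant) are binned into the evidence categories: reads
spanning the annotated junction (wildtype), reads joining the flanking
exons (exon skipping), reads using an unannotated junction (cryptic site
use), and reads extending into or lying within the adjacent intron
(intron retention). Case counts are compared against a control cohort by
a one-sided empirical p on counts normalized per exon read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .infomodel import ValidationError
from .variant_effects import GeneModel, Transcript, Variant

logger = logging.getLogger(__name__)

CATEGORIES = ("wildtype_junction", "skip_junction", "cryptic_junction",
              "intron_retention", "other")


@dataclass(frozen=True)
class ReadRecord:
    """Simplified spliced-alignment record; blocks are 0-based half-open."""

    read_id: str
    contig: str
    blocks: tuple[tuple[int, int], ...]
    base_at_variant: str | None = None

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class JunctionCounts:
    locus_id: str
    wildtype_junction: int = 0
    skip_junction: int = 0
    cryptic_junction: dict[tuple[int, int], int] = field(default_factory=dict)
    intron_retention: int = 0
    other: int = 0
    exon_reads: int = 0
    per_allele: dict[str, Counter] = field(default_factory=dict)
    ignored_contig: int = 0

    @property
    def cryptic_total(self) -> int:
        return sum(self.cryptic_junction.values())

    @property
    def classified_total(self) -> int:
        return (self.wildtype_junction + self.skip_junction
                + self.cryptic_total + self.intron_retention + self.other)

    def category_count(self, category: str) -> int:
        if category == "cryptic_junction":
            return self.cryptic_total
        return getattr(self, category)


def _affected_exon_index(tx: Transcript, pos0: int) -> int:
    """Exon containing the variant, else the exon with the nearest junction."""
    for i, ex in enumerate(tx.exons):
        if ex.start <= pos0 < ex.end:
            return i
    best, best_d = 0, None
    for i, ex in enumerate(tx.exons):
        d = min(abs(pos0 - ex.start), abs(pos0 - (ex.end - 1)))
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best


def classify_alignments(
    records: Iterable[ReadRecord],
    model: GeneModel,
    variant: Variant,
    k: int = 10,
    locus_id: str | None = None,
) -> JunctionCounts:
    """Assign each record to exactly one evidence category.

    Classification is relative to the exon affected by the variant (the
    exon containing it, or with the nearest junction). ``k`` is the
    minimum overhang (nt) past an exon boundary for a contiguous read to
    count as intron retention. Records on the wrong contig are ignored
    and counted.
    """
    tx = model.transcripts[0]
    pos0 = variant.pos0
    idx = _affected_exon_index(tx, pos0)
    exon = tx.exons[idx]
    annotated = set(tx.introns)
    adjacent = set()
    if idx > 0:
        adjacent.add((tx.exons[idx - 1].end, exon.start))
    if idx < len(tx.exons) - 1:
        adjacent.add((exon.end, tx.exons[idx + 1].start))
    skip_intron = (
        (tx.exons[idx - 1].end, tx.exons[idx + 1].start)
        if 0 < idx < len(tx.exons) - 1
        else None
    )

    counts = JunctionCounts(locus_id=locus_id or model.gene_id)

    def allele_key(rec: ReadRecord) -> str:
        covered = any(s <= pos0 < e for s, e in rec.blocks)
        if not covered or rec.base_at_variant is None:
            return "unresolved"
        b = rec.base_at_variant.upper()
        if b == variant.ref.upper():
            return "ref"
        if b == variant.alt.upper():
            return "alt"
        return "other_base"

    def classify(rec: ReadRecord) -> tuple[str, tuple[int, int] | None]:
        introns = rec.introns
        if introns:
            if any(iv in adjacent for iv in introns):
                return "wildtype_junction", None
            if skip_intron is not None and skip_intron in introns:
                return "skip_junction", None
            novel = [iv for iv in introns if iv not in annotated]
            if novel:
                return "cryptic_junction", novel[0]
            return "other", None
        # contiguous read: retention if it crosses an affected boundary by
        # >= k nt, or lies fully within an adjacent intron
        for s, e in adjacent:
            if rec.start < s <= e < rec.end:  # spans the whole (tiny) intron
                return "intron_retention", None
        left_cross = rec.start < exon.start and rec.end > exon.start and (
            exon.start - rec.start
        ) >= k and idx > 0
        right_cross = rec.start < exon.end and rec.end > exon.end and (
            rec.end - exon.end
        ) >= k and idx < len(tx.exons) - 1
        if left_cross or right_cross:
            return "intron_retention", None
        fully_intronic = any(
            s <= rec.start and rec.end <= e for s, e in adjacent
        )
        if fully_intronic:
            return "intron_retention", None
        return "other", None

    for rec in records:
        if rec.contig != variant.contig:
            counts.ignored_contig += 1
            continue
        category, key = classify(rec)
        if category == "cryptic_junction":
            counts.cryptic_junction[key] = counts.cryptic_junction.get(key, 0) + 1
        else:
            setattr(counts, category, getattr(counts, category) + 1)
        if any(b_end > exon.start and b_start < exon.end
               for b_start, b_end in rec.blocks):
            counts.exon_reads += 1
        allele = allele_key(rec)
        counts.per_allele.setdefault(allele, Counter())[category] += 1

    if counts.ignored_contig:
        logger.info("ignored %d records on other contigs", counts.ignored_contig)
    return counts


def expression_gate(counts: JunctionCounts, min_reads: int = 5) -> bool:
    """True iff the affected exon has at least ``min_reads`` reads."""
    return counts.exon_reads >= min_reads


@dataclass(frozen=True)
class ControlDistribution:
    """Per-category normalized counts (per exon read) from control samples."""

    normalized: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.normalized.values()}
        if not sizes or min(sizes) < 1:
            raise ValidationError("at least one control sample is required")
        for cat, v in self.normalized.items():
            if (np.asarray(v) < 0).any():
                raise ValidationError(f"negative normalized count in {cat!r}")

    @property
    def n_controls(self) -> int:
        return len(next(iter(self.normalized.values())))

    @classmethod
    def from_counts(cls, controls: Sequence[JunctionCounts]) -> "ControlDistribution":
        norm: dict[str, list[float]] = {c: [] for c in CATEGORIES}
        for ctl in controls:
            if ctl.exon_reads <= 0:
                raise ValidationError(
                    f"control {ctl.locus_id!r} has no exon reads"
                )
            for cat in CATEGORIES:
                norm[cat].append(ctl.category_count(cat) / ctl.exon_reads)
        return cls({c: np.asarray(v, dtype=float) for c, v in norm.items()})


@dataclass(frozen=True)
class EvidenceResult:
    category: str
    case_normalized: float | None
    p_value: float | None
    n_controls: int
    status: str  # "ok" or "insufficient expression"


def evidence_significance(
    case: JunctionCounts,
    controls: ControlDistribution,
    category: str,
    min_reads: int = 5,
) -> EvidenceResult:
    """One-sided empirical p: share of controls at or above the case level.

    p = (1 + #{controls with normalized count >= case}) / (N + 1), with
    counts normalized per exon read. No p is reported when the case fails
    the expression gate.
    """
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    if not expression_gate(case, min_reads):
        return EvidenceResult(category, None, None, controls.n_controls,
                              "insufficient expression")
    value = case.category_count(category) / case.exon_reads
    ctl = controls.normalized[category]
    p = (1 + int((ctl >= value).sum())) / (len(ctl) + 1)
    return EvidenceResult(category, value, p, len(ctl), "ok")


def allele_assignment(
    records: Iterable[ReadRecord],
    model: GeneModel,
    variant: Variant,
    k: int = 10,
) -> dict[str, Counter]:
    """Evidence-category counts split by the base observed at the variant.

    Reads not covering the variant (or with no base call) fall under
    "unresolved"; bases matching neither allele under "other_base".
    """
    counts = classify_alignments(records, model, variant, k=k)
    return counts.per_allele


# ---------------------------------------------------------------------------
# simplified spliced-alignment TSV
# ---------------------------------------------------------------------------

def read_alignment_tsv(path) -> list[ReadRecord]:
    """Columns: read_id, contig, blocks ("s-e,s-e,..."), base_at_variant ('.')."""
    out = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        blocks = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in row["blocks"].split(",")
        )
        base = row.get("base_at_variant")
        if base in (None, ".", "") or (isinstance(base, float) and np.isnan(base)):
            base = None
        out.append(
            ReadRecord(
                read_id=row["read_id"], contig=row["contig"],
                blocks=blocks, base_at_variant=base,
            )
        )
    return out


def write_alignment_tsv(path, records: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tblocks\tbase_at_variant\n")
        for rec in records:
            blocks = ",".join(f"{s}-{e}" for s, e in rec.blocks)
            fh.write(
                f"{rec.read_id}\t{rec.contig}\t{blocks}\t"
                f"{rec.base_at_variant or '.'}\n"
            )
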