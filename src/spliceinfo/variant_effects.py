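"""Variant evaluation against gene models.

Computes the information change a single-nucleotide variant causes at
natural splice sites, enumerates cryptic sites around the affected
junction under both alleles, classifies the effect, applies the candidate
filters, and scores exon definition totals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .infomodel import (
    FoldChange,
    InformationWeightMatrix,
    Origin,
    SiteKind,
    SiteScore,
    ValidationError,
    fold_change,
    reverse_complement,
    score_site,
)

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Exon:
    contig: str
    start: int  # 0-based, half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"exon start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Exon, ...]  # sorted by genomic start, non-overlapping

    def __post_init__(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"exons overlap or unsorted in {self.transcript_id}"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass(frozen=True)
class Variant:
    """Single-nucleotide variant, 1-based position (VCF convention)."""

    contig: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    het: float | None = None  # average heterozygosity in [0, 1]

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError("only single-nucleotide variants are supported")
        if self.ref == self.alt:
            raise ValidationError("ref and alt must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1


class Classification(str, Enum):
    INACTIVATING = "inactivating"
    LEAKY_WEAKENED = "leaky_weakened"
    STRENGTHENED = "strengthened"
    CRYPTIC_ACTIVATED = "cryptic_activated"
    PSEUDOEXON_CANDIDATE = "pseudoexon_candidate"
    NONE = "none"


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds for effect classification and candidate filtering.

    ri_min: minimum functional splice-site strength (bits). delta_min:
    smallest reportable |delta R_i|. sp_flag: natural-site weakening
    threshold for the SP-style screen. het_min: heterozygosity gate for
    the SP screen. cryptic_window: scan radius around the natural
    junction. comparable_margin: how close (bits) a cryptic site must be
    to the neighbouring natural site to count as comparable.
    """

    ri_min: float = 1.6
    delta_min: float = 0.1
    sp_flag: float = -1.0
    het_min: float = 0.10
    cryptic_window: int = 300
    comparable_margin: float = 1.0
    deep_intron_min: int = 50


@dataclass(frozen=True)
class VariantSpliceEffect:
    variant: Variant
    site: SiteScore
    ri_initial: float
    ri_final: float
    delta_ri: float
    fold: FoldChange | None
    distance_to_natural: int
    classification: Classification = Classification.NONE
    exceeds_natural: bool = False
    comparable: bool = False
    deep_intronic: bool = False


@dataclass(frozen=True)
class CandidateFlags:
    effect: VariantSpliceEffect
    sp_flagged: bool
    array_flagged: bool


@dataclass(frozen=True)
class ExonDefinitionScore:
    ri_acceptor: float
    ri_donor: float
    length_term: float
    ri_total: float


# ---------------------------------------------------------------------------
# junction geometry
# ---------------------------------------------------------------------------

def natural_junctions(model: GeneModel) -> list[tuple[str, int, SiteKind]]:
    """(contig, junction, kind) for every internal junction, deduplicated.

    The junction coordinate is 0-based: the first intronic base for donors
    and the first exonic base for acceptors, both in transcript orientation.
    """
    seen: set[tuple[str, int, SiteKind]] = set()
    out: list[tuple[str, int, SiteKind]] = []
    for tx in model.transcripts:
        for a, b in zip(tx.exons, tx.exons[1:]):
            if model.strand == "+":
                pairs = [(a.contig, a.end, SiteKind.DONOR),
                         (b.contig, b.start, SiteKind.ACCEPTOR)]
            else:
                pairs = [(b.contig, b.start - 1, SiteKind.DONOR),
                         (a.contig, a.end - 1, SiteKind.ACCEPTOR)]
            for key in pairs:
                if key not in seen:
                    seen.add(key)
                    out.append(key)
    return out


def extract_window(
    genome: Mapping[str, str],
    contig: str,
    junction: int,
    strand: str,
    window_start: int,
    length: int,
) -> str:
    """Splice-site window in transcript orientation around a junction."""
    if contig not in genome:
        raise ValidationError(f"contig {contig!r} not in genome")
    seq = genome[contig]
    if strand == "+":
        s, e = junction + window_start, junction + window_start + length
        if s < 0 or e > len(seq):
            raise ValidationError(f"window [{s},{e}) out of bounds on {contig}")
        return seq[s:e].upper()
    e = junction - window_start + 1
    s = e - length
    if s < 0 or e > len(seq):
        raise ValidationError(f"window [{s},{e}) out of bounds on {contig}")
    return reverse_complement(seq[s:e].upper())


def natural_sites_for(
    model: GeneModel,
    genome: Mapping[str, str],
    matrices: Mapping[SiteKind, InformationWeightMatrix],
) -> list[SiteScore]:
    """Score every internal acceptor and donor junction of a gene model."""
    out = []
    for contig, junction, kind in natural_junctions(model):
        m = matrices[kind]
        window = extract_window(
            genome, contig, junction, model.strand, m.window_start, m.length
        )
        out.append(
            SiteScore(
                contig=contig,
                junction_position=junction,
                strand=model.strand,
                site_kind=kind,
                ri=score_site(m, window),
                origin=Origin.NATURAL,
            )
        )
    return out


# ---------------------------------------------------------------------------
# variant evaluation
# ---------------------------------------------------------------------------

def _intron_intervals(model: GeneModel) -> list[tuple[int, int]]:
    ivals = set()
    for tx in model.transcripts:
        ivals.update(tx.introns)
    return sorted(ivals)


def _region(genome: Mapping[str, str], contig: str, junction: int,
            strand: str, radius: int) -> tuple[str, int]:
    """Sequence around a junction in transcript orientation.

    Returns (region, lo) where region[r] is the base at transcript offset
    lo + r from the junction (offset 0 = the junction base itself).
    """
    seq = genome[contig]
    s = max(0, junction - radius)
    e = min(len(seq), junction + radius + 1)
    if strand == "+":
        return seq[s:e].upper(), s - junction
    return reverse_complement(seq[s:e].upper()), junction - (e - 1)


def evaluate_variant(
    variant: Variant,
    model: GeneModel,
    genome: Mapping[str, str],
    matrices: Mapping[SiteKind, InformationWeightMatrix],
    criteria: CriteriaConfig = CriteriaConfig(),
) -> list[VariantSpliceEffect]:
    """Score a variant against every nearby natural junction.

    For each natural site whose window covers the variant, reports the
    natural-site effect (R_i initial/final, delta, fold). Around every
    junction within ``cryptic_window`` of the variant, cryptic candidate
    sites are scored under both alleles; a cryptic site is reported when
    its alt-allele R_i clears ``ri_min`` and it either exceeds a weakened
    natural site, is within ``comparable_margin`` of the natural site, or
    is itself strengthened by at least ``delta_min`` by the variant.
    """
    strand = model.strand
    pos0 = variant.pos0
    ref_base = variant.ref.upper()
    alt_base = variant.alt.upper()
    seq = genome.get(variant.contig)
    if seq is None:
        raise ValidationError(f"contig {variant.contig!r} not in genome")
    if seq[pos0].upper() != ref_base:
        raise ValidationError(
            f"reference mismatch at {variant.contig}:{variant.pos}: "
            f"genome has {seq[pos0]!r}, variant says {ref_base!r}"
        )
    introns = _intron_intervals(model)
    effects: list[VariantSpliceEffect] = []
    seen: set[tuple[int, SiteKind, str]] = set()

    for contig, junction, kind in natural_junctions(model):
        if contig != variant.contig:
            continue
        if abs(pos0 - junction) > criteria.cryptic_window:
            continue
        matrix = matrices[kind]
        L, ws = matrix.length, matrix.window_start
        radius = criteria.cryptic_window
        region_ref, lo = _region(genome, contig, junction, strand, radius)
        # variant position within the region, transcript orientation
        t_var = (pos0 - junction) if strand == "+" else (junction - pos0)
        r_var = t_var - lo
        if not (0 <= r_var < len(region_ref)):
            continue
        sub = alt_base if strand == "+" else _COMP[alt_base]
        region_alt = region_ref[:r_var] + sub + region_ref[r_var + 1 :]

        # --- natural-site effect -------------------------------------
        nat_i = -lo + ws  # region index where the natural window starts
        natural_effect = None
        nat_ri_ref = nat_ri_alt = None
        if 0 <= nat_i and nat_i + L <= len(region_ref):
            nat_ri_ref = score_site(matrix, region_ref[nat_i : nat_i + L])
            nat_ri_alt = score_site(matrix, region_alt[nat_i : nat_i + L])
            if nat_i <= r_var < nat_i + L:
                key = (junction, kind, Origin.NATURAL.value)
                if key not in seen:
                    seen.add(key)
                    delta = nat_ri_alt - nat_ri_ref
                    fc = (
                        fold_change(nat_ri_ref, nat_ri_alt)
                        if math.isfinite(nat_ri_ref) and math.isfinite(nat_ri_alt)
                        else None
                    )
                    natural_effect = VariantSpliceEffect(
                        variant=variant,
                        site=SiteScore(contig, junction, strand, kind,
                                       nat_ri_ref, Origin.NATURAL),
                        ri_initial=nat_ri_ref,
                        ri_final=nat_ri_alt,
                        delta_ri=delta,
                        fold=fc,
                        distance_to_natural=0,
                    )
                    natural_effect = replace(
                        natural_effect,
                        classification=classify_effect(natural_effect, criteria),
                    )
                    effects.append(natural_effect)

        natural_weakened = (
            natural_effect is not None and natural_effect.delta_ri < 0
        )

        # --- cryptic candidates --------------------------------------
        for i in range(len(region_ref) - L + 1):
            t_junc = lo + i - ws  # transcript offset of candidate junction
            if t_junc == 0:
                continue  # the natural site itself
            overlaps = i <= r_var < i + L
            if not overlaps and natural_effect is None:
                continue
            c_ref = score_site(matrix, region_ref[i : i + L])
            c_alt = score_site(matrix, region_alt[i : i + L])
            if not overlaps and c_ref == c_alt and not natural_weakened:
                continue
            if c_alt < criteria.ri_min:
                continue
            exceeds = bool(
                natural_weakened
                and natural_effect is not None
                and c_alt >= natural_effect.ri_final
            )
            comparable = bool(
                nat_ri_ref is not None
                and math.isfinite(nat_ri_ref)
                and c_alt >= nat_ri_ref - criteria.comparable_margin
            )
            strengthened_here = overlaps and (c_alt - c_ref) >= criteria.delta_min
            if not (exceeds or comparable or strengthened_here):
                continue
            g_junc = junction + t_junc if strand == "+" else junction - t_junc
            deep = any(s <= g_junc < e for s, e in introns) and (
                abs(t_junc) >= criteria.deep_intron_min
            )
            key = (g_junc, kind, Origin.CRYPTIC.value)
            if key in seen:
                continue
            seen.add(key)
            fc = (
                fold_change(c_ref, c_alt)
                if math.isfinite(c_ref) and math.isfinite(c_alt)
                else None
            )
            eff = VariantSpliceEffect(
                variant=variant,
                site=SiteScore(contig, g_junc, strand, kind, c_ref,
                               Origin.CRYPTIC),
                ri_initial=c_ref,
                ri_final=c_alt,
                delta_ri=c_alt - c_ref,
                fold=fc,
                distance_to_natural=t_junc,
                exceeds_natural=exceeds,
                comparable=comparable,
                deep_intronic=deep,
            )
            eff = replace(eff, classification=classify_effect(eff, criteria))
            effects.append(eff)

    if not effects:
        logger.info(
            "variant %s:%d %s>%s overlaps no splice-site window",
            variant.contig, variant.pos, variant.ref, variant.alt,
        )
    return effects


def classify_effect(
    effect: VariantSpliceEffect, criteria: CriteriaConfig = CriteriaConfig()
) -> Classification:
    """Assign the effect category from the configured thresholds."""
    d = effect.delta_ri
    ri_f = effect.ri_final
    if effect.site.origin == Origin.NATURAL:
        if d < 0 and ri_f < criteria.ri_min:
            return Classification.INACTIVATING
        if d <= -criteria.delta_min and ri_f >= criteria.ri_min:
            return Classification.LEAKY_WEAKENED
        if d >= criteria.delta_min:
            return Classification.STRENGTHENED
        return Classification.NONE
    # cryptic origin
    if (
        effect.deep_intronic
        and effect.ri_initial < criteria.ri_min <= ri_f
    ):
        return Classification.PSEUDOEXON_CANDIDATE
    if ri_f >= criteria.ri_min and (
        d >= criteria.delta_min or effect.exceeds_natural or effect.comparable
    ):
        return Classification.CRYPTIC_ACTIVATED
    return Classification.NONE


def candidate_filter(
    effects: Sequence[VariantSpliceEffect],
    criteria: CriteriaConfig = CriteriaConfig(),
) -> list[CandidateFlags]:
    """Apply the two candidate screens.

    SP-style flag: natural-site delta R_i below ``sp_flag`` with average
    heterozygosity above ``het_min`` (the het test is skipped when no
    heterozygosity is available). Microarray-style flag: |delta R_i| at or
    above ``delta_min``, or a comparable cryptic site.
    """
    out = []
    for eff in effects:
        het_ok = eff.variant.het is None or eff.variant.het > criteria.het_min
        sp = (
            eff.site.origin == Origin.NATURAL
            and eff.delta_ri < criteria.sp_flag
            and het_ok
        )
        array = abs(eff.delta_ri) >= criteria.delta_min or (
            eff.site.origin == Origin.CRYPTIC and eff.comparable
        )
        out.append(CandidateFlags(effect=eff, sp_flagged=sp, array_flagged=array))
    return out


# ---------------------------------------------------------------------------
# exon definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthHistogram:
    """Exon-length histogram supplying a self-information length term."""

    bin_edges: np.ndarray  # k+1 edges
    counts: np.ndarray  # k counts

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], bins: int = 20) -> "LengthHistogram":
        counts, edges = np.histogram(np.asarray(lengths), bins=bins)
        return cls(bin_edges=edges, counts=counts.astype(float))

    def _bin_index(self, length: float) -> int | None:
        idx = int(np.searchsorted(self.bin_edges, length, side="right")) - 1
        if idx == len(self.counts) and length == self.bin_edges[-1]:
            idx -= 1  # right edge inclusive, numpy convention
        if idx < 0 or idx >= len(self.counts) or self.counts[idx] == 0:
            return None
        return idx

    def length_term(self, length: float) -> float:
        """-log2 p(bin) minus the modal bin's self-information (bits).

        The modal length contributes 0; lengths outside the histogram
        support incur the largest observed penalty, with a warning.
        """
        total = float(self.counts.sum())
        probs = self.counts / total
        with np.errstate(divide="ignore"):
            si = -np.log2(probs, where=probs > 0,
                          out=np.full_like(probs, -np.inf))
        si_mode = float(si.min())
        idx = self._bin_index(length)
        if idx is None:
            penalty = float(si[np.isfinite(si)].max()) - si_mode
            warnings.warn(
                f"exon length {length} outside histogram support; "
                f"applying largest-bin penalty {penalty:.3f} bits"
            )
            return penalty
        return float(si[idx]) - si_mode


def exon_definition_total(
    ri_acceptor: float,
    ri_donor: float,
    exon_length: int,
    length_model: LengthHistogram | None = None,
) -> ExonDefinitionScore:
    """Total exon information: acceptor + donor minus the length term."""
    if not (math.isfinite(ri_acceptor) and math.isfinite(ri_donor)):
        raise ValidationError("exon definition requires finite R_i values")
    if exon_length < 1:
        raise ValidationError("exon_length must be >= 1")
    term = 0.0 if length_model is None else length_model.length_term(exon_length)
    return ExonDefinitionScore(
        ri_acceptor=ri_acceptor,
        ri_donor=ri_donor,
        length_term=term,
        ri_total=ri_acceptor + ri_donor - term,
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def effects_to_dataframe(effects: Sequence[VariantSpliceEffect]) -> pd.DataFrame:
    """One row per variant x site, full precision plus one-decimal report columns."""
    rows = []
    for e in effects:
        rows.append({
            "contig": e.variant.contig,
            "pos": e.variant.pos,
            "rsid": e.variant.rsid,
            "ref": e.variant.ref,
            "alt": e.variant.alt,
            "site_kind": e.site.site_kind.value,
            "origin": e.site.origin.value,
            "junction": e.site.junction_position,
            "strand": e.site.strand,
            "ri_initial": e.ri_initial,
            "ri_final": e.ri_final,
            "delta_ri": e.delta_ri,
            "fold": e.fold.fold if e.fold else math.nan,
            "ri_initial_1dp": round(e.ri_initial, 1),
            "ri_final_1dp": round(e.ri_final, 1),
            "delta_ri_1dp": round(e.delta_ri, 1),
            "fold_1dp": e.fold.fold_1dp if e.fold else math.nan,
            "distance_to_natural": e.distance_to_natural,
            "classification": e.classification.value,
        })
    return pd.DataFrame(rows)
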