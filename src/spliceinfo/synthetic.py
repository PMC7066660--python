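"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without downloads: training
sites drawn from a ground-truth frequency model, loci with planted natural
and cryptic sites, variants with a chosen information change, genotype
cohorts with a multiplicative allele-dose intensity effect, genotype-
dependent Ct tables, and multinomial junction-read draws.

One master seed fans out to per-stage child seeds via numpy SeedSequence,
so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .infomodel import (
    BASES,
    BASE_INDEX,
    InformationWeightMatrix,
    Origin,
    SiteKind,
    SiteScore,
    TrainingAlignment,
    ValidationError,
    build_weight_matrix,
    reverse_complement,
    scan_sequence,
    score_site,
)
from .qpcr import CtTable
from .rnaseq import ReadRecord
from .variant_effects import (
    Exon,
    GeneModel,
    Transcript,
    Variant,
    extract_window,
)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _consensus_freqs(consensus: str, strengths: Sequence[float]) -> np.ndarray:
    """Per-column frequencies: consensus base gets its strength, the rest
    share the remainder equally."""
    out = np.empty((len(consensus), 4))
    for l, (base, s) in enumerate(zip(consensus, strengths)):
        out[l] = (1.0 - s) / 3.0
        out[l, BASE_INDEX[base]] = s
    return out


def _default_donor_freqs() -> np.ndarray:
    # offsets -3..+5 around the exon|intron junction; GT at 0..1 near-invariant
    return _consensus_freqs(
        "CAGGTAAGT",
        [0.42, 0.65, 0.85, 0.97, 0.97, 0.72, 0.75, 0.85, 0.55],
    )


def _default_acceptor_freqs() -> np.ndarray:
    # offsets -25..+2 around the intron|exon junction: a deliberately
    # high-specificity model (information concentrated near the AG core,
    # weak pyrimidine tract) so synthetic backgrounds stay clean
    freqs = np.empty((28, 4))
    for l in range(13):  # offsets -25..-13: uninformative
        freqs[l] = [0.25, 0.25, 0.25, 0.25]
    for l in range(13, 20):  # offsets -12..-6: mild pyrimidine bias
        freqs[l] = [0.18, 0.30, 0.18, 0.34]
    freqs[20] = [0.10, 0.40, 0.10, 0.40]  # -5
    freqs[21] = _consensus_freqs("C", [0.80])[0]  # -4
    freqs[22] = [0.25, 0.40, 0.05, 0.30]  # -3
    freqs[23] = _consensus_freqs("A", [0.97])[0]  # -2
    freqs[24] = _consensus_freqs("G", [0.97])[0]  # -1
    freqs[25] = _consensus_freqs("G", [0.60])[0]  # 0 (first exonic base)
    freqs[26] = [0.30, 0.20, 0.30, 0.20]  # +1
    freqs[27] = [0.25, 0.25, 0.25, 0.25]  # +2
    return freqs


@dataclass(frozen=True)
class CrypticSpec:
    site_kind: SiteKind
    junction_index: int  # which natural junction (order of natural_junctions)
    offset: int  # nt from that junction, transcript orientation
    target_ri: float


@dataclass
class TruthModel:
    """Ground truth for every synthetic input."""

    donor_freqs: np.ndarray = field(default_factory=_default_donor_freqs)
    acceptor_freqs: np.ndarray = field(default_factory=_default_acceptor_freqs)
    donor_window_start: int = -3
    acceptor_window_start: int = -25
    exon_length_range: tuple[int, int] = (80, 160)
    intron_length_range: tuple[int, int] = (300, 500)
    flank: int = 350
    n_exons: int = 3
    natural_min_ri: float = 5.0
    cryptic_specs: tuple[CrypticSpec, ...] = ()
    si_effect_s: float = 0.7
    si_noise_sigma: float = 0.1
    maf: float = 0.3
    isoform_props: dict = field(default_factory=lambda: {
        "hom_common": {"iso_normal": 0.95, "iso_aberrant": 0.05},
        "het": {"iso_normal": 0.70, "iso_aberrant": 0.30},
        "hom_rare": {"iso_normal": 0.40, "iso_aberrant": 0.60},
    })
    junction_props: dict = field(default_factory=lambda: {
        "hom_common": {"wildtype_junction": 0.94, "skip_junction": 0.02,
                       "cryptic_junction": 0.02, "intron_retention": 0.02},
        "het": {"wildtype_junction": 0.70, "skip_junction": 0.10,
                "cryptic_junction": 0.10, "intron_retention": 0.10},
        "hom_rare": {"wildtype_junction": 0.40, "skip_junction": 0.20,
                     "cryptic_junction": 0.20, "intron_retention": 0.20},
    })
    ct_noise_sd: float = 0.2
    ct_baseline: float = 20.0
    ct_max_cycle: float = 40.0
    efficiency: float = 2.0
    depth: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in (("donor", self.donor_freqs), ("acceptor", self.acceptor_freqs)):
            if not np.allclose(f.sum(axis=1), 1.0):
                raise ValidationError(f"{name} frequencies must sum to 1 per column")
        if not 0 < self.maf < 0.5:
            raise ValidationError("maf must be in (0, 0.5)")
        for g, props in self.isoform_props.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValidationError(f"isoform proportions for {g} must sum to 1")

    def freqs(self, kind: SiteKind) -> np.ndarray:
        return self.donor_freqs if kind == SiteKind.DONOR else self.acceptor_freqs

    def window_start(self, kind: SiteKind) -> int:
        return (self.donor_window_start if kind == SiteKind.DONOR
                else self.acceptor_window_start)


# ---------------------------------------------------------------------------
# training sites and matrices
# ---------------------------------------------------------------------------

def sample_training_sites(
    truth: TruthModel, n: int, seed: int, site_kind: SiteKind = SiteKind.DONOR
) -> TrainingAlignment:
    """n i.i.d. windows, each column drawn from the ground-truth frequencies."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = truth.freqs(site_kind)
    cols = [rng.choice(4, size=n, p=freqs[l]) for l in range(freqs.shape[0])]
    seqs = tuple(
        "".join(BASES[cols[l][i]] for l in range(freqs.shape[0]))
        for i in range(n)
    )
    return TrainingAlignment(
        site_kind=site_kind, window_start=truth.window_start(site_kind),
        sequences=seqs,
    )


def build_truth_matrices(
    truth: TruthModel, seed: int, n_train: int = 2000, pseudocount: float = 0.25
) -> dict[SiteKind, InformationWeightMatrix]:
    """Matrices trained on large samples from the ground-truth model."""
    s_d, s_a = spawn_seeds(seed, 2)
    return {
        SiteKind.DONOR: build_weight_matrix(
            sample_training_sites(truth, n_train, s_d, SiteKind.DONOR),
            pseudocount=pseudocount,
        ),
        SiteKind.ACCEPTOR: build_weight_matrix(
            sample_training_sites(truth, n_train, s_a, SiteKind.ACCEPTOR),
            pseudocount=pseudocount,
        ),
    }


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    genome: dict[str, str]
    model: GeneModel
    matrices: dict[SiteKind, InformationWeightMatrix]
    natural_sites: list[SiteScore]
    cryptic_sites: list[SiteScore]
    truth: TruthModel
    contig: str = "chrS"

    def manifest(self) -> dict:
        return {
            "contig": self.contig,
            "gene_id": self.model.gene_id,
            "strand": self.model.strand,
            "exons": [[e.start, e.end] for e in self.model.transcripts[0].exons],
            "natural_sites": [
                {"kind": s.site_kind.value, "junction": s.junction_position,
                 "ri": s.ri} for s in self.natural_sites
            ],
            "cryptic_sites": [
                {"kind": s.site_kind.value, "junction": s.junction_position,
                 "ri": s.ri} for s in self.cryptic_sites
            ],
        }


def _sample_window(rng: np.random.Generator, freqs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=freqs[l])] for l in range(freqs.shape[0]))


def _plant_window(
    seq: list[str], start: int, rng: np.random.Generator,
    matrix: InformationWeightMatrix, freqs: np.ndarray,
    accept, max_tries: int = 20000,
) -> float:
    for _ in range(max_tries):
        window = _sample_window(rng, freqs)
        ri = score_site(matrix, window)
        if accept(ri):
            seq[start : start + len(window)] = list(window)
            return ri
    raise ValidationError("could not plant a site meeting the target R_i")


def build_locus(truth: TruthModel, seed: int) -> Locus:
    """Random locus with consensus-like natural sites at every junction and
    cryptic sites planted at the specified offsets (within 0.5 bits of the
    target R_i). Incidental background sites at or above 1.6 bits outside
    the planted junctions are suppressed by mutating one high-weight base.
    """
    s_bg, s_mat, s_nat, s_cry = spawn_seeds(seed, 4)
    rng = np.random.default_rng(s_bg)
    rng_site = np.random.default_rng(s_nat)
    rng_cry = np.random.default_rng(s_cry)
    matrices = build_truth_matrices(truth, s_mat)

    lo, hi = truth.exon_length_range
    exon_lens = [int(rng.integers(lo, hi + 1)) for _ in range(truth.n_exons)]
    lo, hi = truth.intron_length_range
    intron_lens = [int(rng.integers(lo, hi + 1)) for _ in range(truth.n_exons - 1)]

    total = truth.flank * 2 + sum(exon_lens) + sum(intron_lens)
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=total)))

    exons = []
    cursor = truth.flank
    for i, el in enumerate(exon_lens):
        exons.append(Exon(contig="chrS", start=cursor, end=cursor + el))
        cursor += el
        if i < len(intron_lens):
            cursor += intron_lens[i]
    model = GeneModel(
        gene_id="geneS", strand="+",
        transcripts=(Transcript(transcript_id="geneS.t1", exons=tuple(exons)),),
    )

    protected: list[tuple[int, int]] = []
    natural_sites: list[SiteScore] = []
    junction_list: list[tuple[int, SiteKind]] = []
    for a, b in zip(exons, exons[1:]):
        junction_list.append((a.end, SiteKind.DONOR))
        junction_list.append((b.start, SiteKind.ACCEPTOR))

    for junction, kind in junction_list:
        m = matrices[kind]
        freqs = truth.freqs(kind)
        start = junction + m.window_start
        ri = _plant_window(
            seq, start, rng_site, m, freqs,
            accept=lambda r: r >= truth.natural_min_ri,
        )
        protected.append((start, start + m.length))
        natural_sites.append(
            SiteScore("chrS", junction, "+", kind, ri, Origin.NATURAL)
        )

    cryptic_sites: list[SiteScore] = []
    for spec in truth.cryptic_specs:
        junction = junction_list[spec.junction_index][0] + spec.offset
        m = matrices[spec.site_kind]
        freqs = truth.freqs(spec.site_kind)
        start = junction + m.window_start
        for s, e in protected:
            if start < e and start + m.length > s:
                raise ValidationError(
                    f"cryptic spec at junction {junction} overlaps a planted window"
                )
        ri = _plant_window(
            seq, start, rng_cry, m, freqs,
            accept=lambda r, t=spec.target_ri: abs(r - t) <= 0.5,
        )
        protected.append((start, start + m.length))
        cryptic_sites.append(
            SiteScore("chrS", junction, "+", spec.site_kind, ri, Origin.CRYPTIC)
        )

    _suppress_background(seq, matrices, protected,
                         {s.junction_position for s in natural_sites}
                         | {s.junction_position for s in cryptic_sites},
                         rng)

    # planted natural sites are rescored from the final sequence
    genome = {"chrS": "".join(seq)}
    natural_sites = [
        dc_replace_site(s, score_site(
            matrices[s.site_kind],
            extract_window(genome, "chrS", s.junction_position, "+",
                           matrices[s.site_kind].window_start,
                           matrices[s.site_kind].length),
        ))
        for s in natural_sites
    ]
    return Locus(
        genome=genome, model=model, matrices=matrices,
        natural_sites=natural_sites, cryptic_sites=cryptic_sites, truth=truth,
    )


def dc_replace_site(site: SiteScore, ri: float) -> SiteScore:
    return SiteScore(site.contig, site.junction_position, site.strand,
                     site.site_kind, ri, site.origin)


def _suppress_background(
    seq: list[str],
    matrices: Mapping[SiteKind, InformationWeightMatrix],
    protected: list[tuple[int, int]],
    planted_junctions: set[int],
    rng: np.random.Generator,
    threshold: float = 1.1,
    max_rounds: int = 80,
) -> None:
    """Mutate away incidental sites scoring near/above ri_min off-junction.

    Mutations never introduce G (so no new GT/AG anchors can form), never
    place T after a G and never place A before a G; anchor counts are
    therefore non-increasing and the loop converges. Windows overlapping a
    planted site are left untouched.
    """

    def in_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    def mutate(pos: int, l: int, m: InformationWeightMatrix) -> bool:
        cur = seq[pos]
        prev = seq[pos - 1] if pos > 0 else ""
        nxt = seq[pos + 1] if pos < len(seq) - 1 else ""
        for b_idx in np.argsort(m.weights[l]):  # weakest base first
            b = BASES[int(b_idx)]
            if b == cur or b == "G":
                continue
            if b == "T" and prev == "G":
                continue
            if b == "A" and nxt == "G":
                continue
            seq[pos] = b
            return True
        return False

    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for kind, m in matrices.items():
            for hit in scan_sequence(m, text):
                if hit.ri < threshold or hit.junction_position in planted_junctions:
                    continue
                start = hit.junction_position + m.window_start
                # mutate the position contributing most to this window
                contrib = [
                    (float(m.weights[l, BASE_INDEX[seq[start + l]]]), l)
                    for l in range(m.length)
                    if 0 <= start + l < len(seq) and not in_protected(start + l)
                ]
                for _, l in sorted(contrib, reverse=True):
                    if mutate(start + l, l, m):
                        dirty = True
                        break
        if not dirty:
            return


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    variant: Variant
    site: SiteScore
    ri_initial: float
    ri_final: float
    delta_ri: float


def plant_variant(
    locus: Locus, site: SiteScore, target_delta: float, seed: int = 0,
    het: float | None = 0.3,
) -> PlantedVariant:
    """Substitution inside the site window whose delta R_i is closest to
    ``target_delta``; the exact expected change from the weight matrix is
    recorded. Raises if no substitution lands within 1 bit of the target.
    """
    m = locus.matrices[site.site_kind]
    window = extract_window(
        locus.genome, site.contig, site.junction_position,
        locus.model.strand, m.window_start, m.length,
    )
    best = None
    for l in range(m.length):
        ref_idx = BASE_INDEX[window[l]]
        for alt_idx in range(4):
            if alt_idx == ref_idx:
                continue
            delta = m.weights[l, alt_idx] - m.weights[l, ref_idx]
            if not math.isfinite(delta):
                continue
            score = abs(delta - target_delta)
            if best is None or score < best[0]:
                best = (score, l, alt_idx, delta)
    if best is None or best[0] > 1.0:
        raise ValidationError(
            f"no substitution within 1 bit of target delta {target_delta}"
        )
    _, l, alt_idx, delta = best
    strand = locus.model.strand
    if strand == "+":
        g = site.junction_position + m.window_start + l
        ref_base = locus.genome[site.contig][g]
        alt_base = BASES[alt_idx]
    else:
        g = site.junction_position - (m.window_start + l)
        ref_base = locus.genome[site.contig][g]
        alt_base = reverse_complement(BASES[alt_idx])
    ri_initial = score_site(m, window)
    ri_final = ri_initial + delta
    return PlantedVariant(
        variant=Variant(contig=site.contig, pos=g + 1, ref=ref_base,
                        alt=alt_base, rsid="planted1", het=het),
        site=site, ri_initial=ri_initial, ri_final=ri_final, delta_ri=delta,
    )


# ---------------------------------------------------------------------------
# cohort simulation (exon array)
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    genotype_calls: pd.DataFrame  # snp x sample
    snps: pd.DataFrame
    intensities: pd.DataFrame  # probeset x sample
    gene_intensities: pd.DataFrame
    probesets: pd.DataFrame
    doses: pd.Series  # minor-allele dose per sample


def simulate_cohort(
    truth: TruthModel, n_samples: int, seed: int, n_probesets: int = 8,
    snp_id: str = "snp1", affected_probeset: str = "ps1",
) -> Cohort:
    """Genotypes under HWE at the stated maf; the affected probeset's
    intensity is I0 * s**dose * lognormal(0, sigma); other probesets are
    dose-independent; gene intensities are probeset means."""
    if n_samples < 3:
        raise ValidationError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    q = truth.maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    doses = rng.choice(3, size=n_samples, p=probs)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    labels = np.array(["hom_common", "het", "hom_rare"])[doses]

    pids = [affected_probeset] + [f"ps{i+2}" for i in range(n_probesets - 1)]
    base = rng.lognormal(mean=np.log(100.0), sigma=0.3, size=n_probesets)
    inten = np.empty((n_probesets, n_samples))
    for p in range(n_probesets):
        noise = rng.lognormal(0.0, truth.si_noise_sigma, size=n_samples)
        inten[p] = base[p] * noise
    inten[0] *= truth.si_effect_s ** doses

    intensities = pd.DataFrame(inten, index=pids, columns=samples)
    gene_intensities = pd.DataFrame(
        [intensities.mean(axis=0)], index=["geneS"]
    )
    probesets = pd.DataFrame({
        "probeset_id": pids,
        "gene_id": "geneS",
        "contig": "chrS",
        "start": [1000 + 400 * i for i in range(n_probesets)],
        "end": [1100 + 400 * i for i in range(n_probesets)],
        "strand": "+",
    })
    snps = pd.DataFrame(
        [{"snp_id": snp_id, "contig": "chrS", "pos": 950, "strand": "+"}]
    )
    calls = pd.DataFrame([labels], index=[snp_id], columns=samples)
    return Cohort(
        genotype_calls=calls, snps=snps, intensities=intensities,
        gene_intensities=gene_intensities, probesets=probesets,
        doses=pd.Series(doses, index=samples),
    )


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    truth: TruthModel, genotypes: Mapping[str, str], seed: int,
    replicates: int = 3,
) -> CtTable:
    """Ct = baseline - log_E(isoform proportion) + N(0, sd), in triplicate;
    reference assays are dose-independent; zero proportions are censored at
    the configured max cycle."""
    rng = np.random.default_rng(seed)
    e = truth.efficiency
    rows = []
    assays = list(next(iter(truth.isoform_props.values())).keys())
    for sample, geno in genotypes.items():
        props = truth.isoform_props[geno]
        quantities = {a: props[a] for a in assays}
        quantities["internal_ref"] = 1.0
        quantities["external_ref"] = 1.0
        for assay, qty in quantities.items():
            for rep in range(replicates):
                if qty <= 0:
                    ct = truth.ct_max_cycle
                else:
                    ct = (truth.ct_baseline - math.log(qty, e)
                          + rng.normal(0.0, truth.ct_noise_sd))
                rows.append({
                    "sample": sample, "group": geno, "assay": assay,
                    "replicate": rep, "ct": ct,
                })
    roles = {a: "isoform" for a in assays}
    roles["internal_ref"] = "internal_ref"
    roles["external_ref"] = "external_ref"
    return CtTable(
        data=pd.DataFrame(rows),
        efficiencies={a: e for a in roles},
        roles=roles,
    )


# ---------------------------------------------------------------------------
# junction-read simulation
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    truth: TruthModel,
    model: GeneModel,
    variant: Variant,
    genotype: str,
    depth: int,
    seed: int,
    cryptic_offset: int = 20,
    k: int = 10,
    read_flank: int = 30,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Multinomial junction reads around the middle exon of a 3+ exon model.

    Returns the records plus the generating category draw, for exact
    round-trip checks against :func:`spliceinfo.rnaseq.classify_alignments`.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    tx = model.transcripts[0]
    if len(tx.exons) < 3:
        raise ValidationError("junction simulation needs >= 3 exons")
    rng = np.random.default_rng(seed)
    e0, e1, e2 = tx.exons[0], tx.exons[1], tx.exons[2]
    props = truth.junction_props[genotype]
    cats = list(props.keys())
    draw = rng.multinomial(depth, [props[c] for c in cats])
    drawn = dict(zip(cats, (int(x) for x in draw)))

    cpos = e1.end - cryptic_offset
    pos0 = variant.pos0

    def blocks_for(cat: str) -> tuple[tuple[int, int], ...]:
        if cat == "wildtype_junction":
            return ((e1.end - read_flank, e1.end), (e2.start, e2.start + read_flank))
        if cat == "skip_junction":
            return ((e0.end - read_flank, e0.end), (e2.start, e2.start + read_flank))
        if cat == "cryptic_junction":
            return ((cpos - read_flank, cpos), (e2.start, e2.start + read_flank))
        return ((e1.end - read_flank, e1.end + k + 15),)  # intron retention

    def allele_for(cat: str) -> str:
        if genotype == "hom_common":
            return variant.ref
        if genotype == "hom_rare":
            return variant.alt
        return variant.ref if cat == "wildtype_junction" else variant.alt

    records: list[ReadRecord] = []
    i = 0
    for cat in cats:
        for _ in range(drawn[cat]):
            blocks = blocks_for(cat)
            covered = any(s <= pos0 < e for s, e in blocks)
            records.append(ReadRecord(
                read_id=f"r{i:05d}", contig=variant.contig, blocks=blocks,
                base_at_variant=allele_for(cat) if covered else None,
            ))
            i += 1
    return records, drawn
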