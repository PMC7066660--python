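"""Exon-microarray splicing-index screen.

The splicing index (SI) of a probeset in a sample is its intensity divided
by the overall intensity of its gene. SNPs are linked to their nearest
like-stranded probeset (within 500 nt), and probesets whose mean SI drops
stepwise with minor-allele dose (het and rare-homozygote means both below
90% of the common-homozygote mean, with the het mean strictly between the
homozygote means) are flagged as splicing-affected candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .infomodel import ValidationError

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_common", "het", "hom_rare", "missing")

PROBESET_COLUMNS = ["probeset_id", "gene_id", "contig", "start", "end", "strand"]
SNP_COLUMNS = ["snp_id", "contig", "pos", "strand"]


def _check_probesets(probesets: pd.DataFrame) -> None:
    missing = set(PROBESET_COLUMNS) - set(probesets.columns)
    if missing:
        raise ValidationError(f"probeset table missing columns {sorted(missing)}")
    if (probesets["start"] >= probesets["end"]).any():
        raise ValidationError("probeset with start >= end")
    if probesets["probeset_id"].duplicated().any():
        raise ValidationError("duplicate probeset ids")


def remove_probes_overlapping_snps(
    probesets: pd.DataFrame, snp_positions: pd.DataFrame
) -> pd.DataFrame:
    """Drop probesets whose [start, end) interval contains any SNP position."""
    _check_probesets(probesets)
    drop = pd.Series(False, index=probesets.index)
    for contig, grp in snp_positions.groupby("contig"):
        on_contig = probesets["contig"] == contig
        if not on_contig.any():
            continue
        pos = grp["pos"].to_numpy()
        starts = probesets.loc[on_contig, "start"].to_numpy()[:, None]
        ends = probesets.loc[on_contig, "end"].to_numpy()[:, None]
        hit = ((pos[None, :] >= starts) & (pos[None, :] < ends)).any(axis=1)
        drop.loc[on_contig] = hit
    kept = probesets.loc[~drop].reset_index(drop=True)
    logger.info(
        "removed %d of %d probesets overlapping SNPs", int(drop.sum()), len(probesets)
    )
    return kept


def link_snp_to_probeset(
    snp: Mapping, probesets: pd.DataFrame, max_dist: int = 500
) -> str | None:
    """Nearest like-stranded probeset by gap distance; None beyond max_dist.

    Distance is 0 for an overlapping probeset; ties break on the smaller
    start coordinate.
    """
    cand = probesets[
        (probesets["contig"] == snp["contig"])
        & (probesets["strand"] == snp["strand"])
    ]
    if cand.empty:
        return None
    pos = snp["pos"]
    dist = np.where(
        (pos >= cand["start"]) & (pos < cand["end"]),
        0,
        np.where(pos < cand["start"], cand["start"] - pos, pos - (cand["end"] - 1)),
    )
    order = np.lexsort((cand["start"].to_numpy(), dist))
    best = order[0]
    if dist[best] > max_dist:
        return None
    return cand.iloc[best]["probeset_id"]


def splicing_index(
    intensities: pd.DataFrame,
    probesets: pd.DataFrame,
    gene_intensities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SI(p, s) = I(p, s) / I(gene(p), s), as a probeset x sample frame.

    When no gene-level summaries are supplied, the gene intensity falls
    back to the mean over that gene's probesets (logged loudly). Samples
    with zero gene intensity are excluded (NaN) for that gene.
    """
    if (intensities < 0).any().any():
        raise ValidationError("negative intensities")
    gene_of = probesets.set_index("probeset_id")["gene_id"]
    if gene_intensities is None:
        logger.warning(
            "no gene-level intensities supplied; falling back to the mean of "
            "each gene's probesets"
        )
        gene_intensities = intensities.groupby(
            gene_of.reindex(intensities.index)
        ).mean()
    denom = gene_intensities.reindex(gene_of.reindex(intensities.index))
    denom.index = intensities.index
    zero = denom <= 0
    if zero.any().any():
        warnings.warn(
            f"{int(zero.any(axis=0).sum())} sample(s) with zero gene intensity "
            "excluded for the affected gene(s)"
        )
        denom = denom.where(~zero)
    return intensities / denom


@dataclass(frozen=True)
class StepwiseResult:
    flag: bool
    partial: bool  # two-group reduction applied (hom_rare absent)
    means: dict
    sizes: dict
    reason: str = ""


def stepwise_filter(
    group_means: Mapping[str, float],
    ratio_threshold: float = 0.90,
    min_group_n: int = 1,
    group_sizes: Mapping[str, int] | None = None,
    direction: str = "decrease",
) -> StepwiseResult:
    """The stepwise genotype criterion on per-genotype mean SI.

    Decrease form: flag iff the het mean lies strictly between the two
    homozygote means AND both het and rare-homozygote means are < 90% of
    the common-homozygote mean ("< 90%" is strict). With no rare
    homozygotes the two-group reduction (het < 90% of common) applies and
    the result is labelled partial. ``direction="increase"`` mirrors the
    criterion (means > common / 0.90).
    """
    if direction not in ("decrease", "increase"):
        raise ValidationError(f"unknown direction {direction!r}")
    sizes = dict(group_sizes or {})

    def ok(g: str) -> bool:
        if group_means.get(g) is None or (
            isinstance(group_means.get(g), float) and np.isnan(group_means[g])
        ):
            return False
        return sizes.get(g, min_group_n) >= min_group_n

    have = [g for g in ("hom_common", "het", "hom_rare") if ok(g)]
    if len(have) < 2 or "hom_common" not in have:
        raise ValidationError(
            "stepwise filter needs the common-homozygote group plus at least "
            "one other genotype group"
        )
    mc = float(group_means["hom_common"])
    t = ratio_threshold
    if direction == "decrease":
        passes = lambda m: m < t * mc
    else:
        passes = lambda m: m > mc / t

    if "het" in have and "hom_rare" in have:
        mh = float(group_means["het"])
        mr = float(group_means["hom_rare"])
        between = min(mc, mr) < mh < max(mc, mr)
        flag = between and passes(mh) and passes(mr)
        reason = "" if flag else (
            "het mean not strictly between homozygote means" if not between
            else f"group mean(s) fail the {t:.0%} criterion"
        )
        return StepwiseResult(flag, False, dict(group_means), sizes, reason)
    if "het" in have:
        mh = float(group_means["het"])
        flag = passes(mh)
        return StepwiseResult(
            flag, True, dict(group_means), sizes,
            "" if flag else f"het mean fails the {t:.0%} criterion (partial)",
        )
    mr = float(group_means["hom_rare"])
    flag = passes(mr)
    return StepwiseResult(
        flag, True, dict(group_means), sizes,
        "" if flag else f"hom_rare mean fails the {t:.0%} criterion (partial)",
    )


def genotype_group_means(
    si: pd.DataFrame, calls: pd.Series, probeset_id: str
) -> tuple[dict, dict]:
    """Mean SI and group size per genotype, over non-missing samples."""
    row = si.loc[probeset_id]
    means: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for g in ("hom_common", "het", "hom_rare"):
        samples = calls.index[calls == g]
        vals = row.reindex(samples).dropna()
        sizes[g] = int(len(vals))
        means[g] = float(vals.mean()) if len(vals) else float("nan")
    return means, sizes


def si_screen(
    intensities: pd.DataFrame,
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    probesets: pd.DataFrame,
    gene_intensities: pd.DataFrame | None = None,
    max_dist: int = 500,
    ratio_threshold: float = 0.90,
    min_group_n: int = 1,
    direction: str = "decrease",
    drop_snp_probes: bool = True,
) -> pd.DataFrame:
    """Full screen: probe filtering, SNP linking, SI, stepwise criterion.

    ``genotypes`` is a SNP x sample frame of genotype strings; ``snps``
    carries the SNP coordinates (columns snp_id, contig, pos, strand).
    """
    if drop_snp_probes:
        probesets = remove_probes_overlapping_snps(
            probesets, snps.rename(columns={"pos": "pos"})[["contig", "pos"]]
        )
    si = splicing_index(intensities, probesets, gene_intensities)
    rows = []
    for _, snp in snps.iterrows():
        pid = link_snp_to_probeset(snp, probesets, max_dist=max_dist)
        row: dict = {"snp_id": snp["snp_id"], "probeset_id": pid}
        if pid is not None and pid in si.index:
            calls = genotypes.loc[snp["snp_id"]]
            means, sizes = genotype_group_means(si, calls, pid)
            try:
                res = stepwise_filter(
                    means, ratio_threshold, min_group_n, sizes, direction
                )
                row.update(
                    flag=res.flag, partial=res.partial, reason=res.reason,
                )
            except ValidationError as exc:
                row.update(flag=False, partial=False, reason=str(exc))
            for g in ("hom_common", "het", "hom_rare"):
                row[f"mean_{g}"] = means[g]
                row[f"n_{g}"] = sizes[g]
        else:
            row.update(flag=False, partial=False, reason="no linked probeset")
        rows.append(row)
    return pd.DataFrame(rows)


def export_boxplot_data(
    si: pd.DataFrame, calls: pd.Series, probeset_id: str
) -> pd.DataFrame:
    """Tidy (genotype, sample, si) table for plotting, missing excluded.

    Rows are ordered by genotype (common, het, rare) then sample id, so the
    export is deterministic.
    """
    if probeset_id not in si.index:
        raise ValidationError(f"probeset {probeset_id!r} not in SI table")
    rows = []
    for g in ("hom_common", "het", "hom_rare"):
        for sample in sorted(calls.index[calls == g]):
            val = si.loc[probeset_id].get(sample, np.nan)
            if not np.isnan(val):
                rows.append({"genotype": g, "sample": sample, "si": float(val)})
    return pd.DataFrame(rows, columns=["genotype", "sample", "si"])
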