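"""Relative expression from replicate quantification-cycle (Ct) tables.

Ratio estimation follows the efficiency-corrected ddCt convention used by
REST: ratio = E_target**(dCt_target) / E_ref**(dCt_ref), where dCt is the
difference of group mean Cts (group_a minus group_b), so a ratio above 1
means higher target expression in group_b. Significance comes from a
fixed-reallocation randomization in which whole samples (target and
reference Cts travelling together) are permuted between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infomodel import ValidationError

ASSAY_ROLES = ("isoform", "internal_ref", "external_ref")

CT_COLUMNS = ["sample", "group", "assay", "replicate", "ct"]


@dataclass
class CtTable:
    """Tidy replicate Ct table plus per-assay efficiency and role maps."""

    data: pd.DataFrame  # columns: sample, group, assay, replicate, ct
    efficiencies: dict[str, float] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    default_efficiency: float = 2.0

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        for a, e in self.efficiencies.items():
            if e <= 0:
                raise ValidationError(f"non-positive efficiency for assay {a!r}")
        ext = [a for a, r in self.roles.items() if r == "external_ref"]
        if self.roles and len(ext) != 1:
            raise ValidationError("exactly one external_ref assay is required")

    def efficiency(self, assay: str) -> float:
        return self.efficiencies.get(assay, self.default_efficiency)

    def sample_means(self) -> pd.DataFrame:
        """Mean Ct per (sample, group, assay) — replicate aggregation."""
        return (
            self.data.groupby(["sample", "group", "assay"], as_index=False)["ct"]
            .mean()
        )

    @classmethod
    def read_tsv(cls, path, **kwargs) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)


@dataclass(frozen=True)
class ExpressionRatio:
    ratio: float
    group_a: str
    group_b: str
    p_value: float
    iterations: int
    seed: int | None


def _group_mean_ct(means: pd.DataFrame, assay: str, group: str) -> float:
    sel = means[(means["assay"] == assay) & (means["group"] == group)]
    if sel.empty:
        raise ValidationError(f"no Ct data for assay {assay!r} in group {group!r}")
    return float(sel["ct"].mean())


def _ratio_from_means(
    means: pd.DataFrame, ct: CtTable, target_assay: str, ref_assay: str,
    group_a: str, group_b: str,
) -> float:
    d_t = _group_mean_ct(means, target_assay, group_a) - _group_mean_ct(
        means, target_assay, group_b
    )
    d_r = _group_mean_ct(means, ref_assay, group_a) - _group_mean_ct(
        means, ref_assay, group_b
    )
    return ct.efficiency(target_assay) ** d_t / ct.efficiency(ref_assay) ** d_r


def relative_ratio(
    ct: CtTable, target_assay: str, ref_assay: str, group_a: str, group_b: str
) -> float:
    """Efficiency-corrected expression ratio of group_b relative to group_a."""
    return _ratio_from_means(
        ct.sample_means(), ct, target_assay, ref_assay, group_a, group_b
    )


def randomization_test(
    ct: CtTable,
    target_assay: str,
    ref_assay: str,
    groups: tuple[str, str],
    iterations: int = 2000,
    seed: int | None = None,
) -> ExpressionRatio:
    """Fixed-reallocation randomization test on the expression ratio.

    Whole-sample group labels are permuted; the two-sided empirical p is
    (1 + #{|log ratio_perm| >= |log ratio_obs|}) / (iterations + 1).
    """
    group_a, group_b = groups
    means = ct.sample_means()
    means = means[means["group"].isin(groups)]
    observed = _ratio_from_means(means, ct, target_assay, ref_assay, group_a, group_b)

    per_sample = means.pivot_table(
        index="sample", columns="assay", values="ct", aggfunc="mean"
    )
    labels = means.drop_duplicates("sample").set_index("sample")["group"]
    samples = per_sample.index.to_numpy()
    n_a = int((labels.reindex(samples) == group_a).sum())
    n_b = len(samples) - n_a
    if n_a == 1 or n_b == 1:
        warnings.warn("single-sample group: randomization p reported as 1")
        return ExpressionRatio(observed, group_a, group_b, 1.0, 0, seed)

    e_t = ct.efficiency(target_assay)
    e_r = ct.efficiency(ref_assay)
    ct_t = per_sample[target_assay].to_numpy()
    ct_r = per_sample[ref_assay].to_numpy()

    def log_ratio(mask_a: np.ndarray) -> float:
        d_t = ct_t[mask_a].mean() - ct_t[~mask_a].mean()
        d_r = ct_r[mask_a].mean() - ct_r[~mask_a].mean()
        return d_t * math.log(e_t) - d_r * math.log(e_r)

    obs_stat = abs(math.log(observed))
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(samples))
    for _ in range(iterations):
        perm = rng.permutation(idx)
        mask = np.zeros(len(samples), dtype=bool)
        mask[perm[:n_a]] = True
        if abs(log_ratio(mask)) >= obs_stat - 1e-12:
            hits += 1
    p = (1 + hits) / (iterations + 1)
    return ExpressionRatio(observed, group_a, group_b, p, iterations, seed)


@dataclass(frozen=True)
class AbundanceResult:
    percent: float  # raw value, retained even when >= 100
    sd: float
    n: int

    @property
    def formatted(self) -> str:
        if self.percent >= 100:
            return "~100"
        return f"{self.percent:.1f} ± {self.sd:.1f}"


def isoform_relative_abundance(
    ct: CtTable, isoform_assay: str, internal_ref_assay: str, group: str
) -> AbundanceResult:
    """Isoform abundance as a percentage of the internal gene reference.

    percent = 100 * E**(-(mean Ct_isoform - mean Ct_internal_ref)) within
    the group; the spread is the sd over per-sample percentages (or over
    per-replicate percentages when only one sample is available).
    """
    means = ct.sample_means()
    grp = means[means["group"] == group]
    iso = grp[grp["assay"] == isoform_assay].set_index("sample")["ct"]
    ref = grp[grp["assay"] == internal_ref_assay].set_index("sample")["ct"]
    if iso.empty or ref.empty:
        raise ValidationError(
            f"missing assay data for group {group!r}: need both "
            f"{isoform_assay!r} and {internal_ref_assay!r}"
        )
    e = ct.efficiency(isoform_assay)
    common = iso.index.intersection(ref.index)
    per_sample = 100.0 * e ** (-(iso[common] - ref[common]))
    if len(per_sample) > 1:
        return AbundanceResult(
            percent=float(per_sample.mean()),
            sd=float(per_sample.std(ddof=1)),
            n=len(per_sample),
        )
    # single sample: spread from replicates against the sample-mean reference
    sample = common[0]
    reps = ct.data[
        (ct.data["group"] == group)
        & (ct.data["assay"] == isoform_assay)
        & (ct.data["sample"] == sample)
    ]["ct"]
    per_rep = 100.0 * e ** (-(reps - float(ref[sample])))
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return AbundanceResult(percent=float(per_rep.mean()), sd=sd, n=1)
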