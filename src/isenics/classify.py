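"""Senescence groups per unit and STIME classes per sample.

Units (samples of one deconvolved cell type, or single cells) are split into
low / medium / high senescence groups either by the first and third
quartiles of their ICSS distribution (bulk convention) or by fixed top and
bottom fractions of the ranking (single-cell convention, default 25%).

Samples are then classified over their immune cell subtypes: a strict
majority of high-ICSS subtypes makes the sample HSTIME (high senescent tumor
immune microenvironment), a strict majority of low-ICSS subtypes makes it
LSTIME, and anything else — including an exact half — is MSTIME.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GroupSizeError, ValidationError
from .scoring import ScoreVector

LABELS = ("low", "medium", "high")
STIME_LABELS = ("LSTIME", "MSTIME", "HSTIME")


@dataclass
class GroupAssignment:
    """Per-unit {low, medium, high} labels with the thresholds that made them."""

    unit_ids: list[str]
    labels: list[str]
    thresholds: tuple[float, float]
    scheme: str

    def __post_init__(self) -> None:
        if len(self.unit_ids) != len(self.labels):
            raise ValidationError("labels length does not match unit_ids")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown labels {bad}")

    def units_with(self, label: str) -> list[str]:
        return [u for u, l in zip(self.unit_ids, self.labels) if l == label]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.unit_ids, self.labels))


@dataclass
class StimeLabel:
    """A sample's STIME class with the per-cell-type votes behind it."""

    sample_id: str
    label: str
    votes: dict[str, str]
    n_celltypes: int

    def __post_init__(self) -> None:
        if self.label not in STIME_LABELS:
            raise ValidationError(f"unknown STIME label {self.label!r}")
        if self.n_celltypes != len(self.votes):
            raise ValidationError("n_celltypes does not match votes")


def quartile_groups(scores: ScoreVector) -> GroupAssignment:
    """Label units low/medium/high by the first and third score quartiles.

    Quartiles use linear interpolation between order statistics (the
    "type 7" convention).  Boundary rule: score <= q1 -> low, score >= q3 ->
    high, else medium, which guarantees non-empty extreme groups for
    distinct scores.  When q1 == q3 (near-constant scores) a degenerate-
    distribution warning is emitted and boundary units are labeled medium.
    """
    v = scores.values
    n = len(v)
    if n < 4:
        raise GroupSizeError(f"quartile grouping needs >= 4 units, got {n}")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation
    if q1 == q3:
        warnings.warn(
            "degenerate score distribution: q1 == q3; boundary units labeled medium",
            stacklevel=2,
        )
        labels = ["low" if x < q1 else "high" if x > q3 else "medium" for x in v]
    else:
        labels = ["low" if x <= q1 else "high" if x >= q3 else "medium" for x in v]
    return GroupAssignment(list(scores.unit_ids), labels, (float(q1), float(q3)), "quartile")


def top_bottom_groups(scores: ScoreVector, fraction: float = 0.25) -> GroupAssignment:
    """Label the top / bottom ``fraction`` of units high / low, the rest medium.

    ``ceil(fraction * n)`` units go to each extreme.  Ties at a cut are
    broken by stable unit order; high quota is filled first, then low from
    the remaining units, so all-equal scores still fill both quotas
    deterministically (with a warning).
    """
    if not 0 < fraction <= 0.5:
        raise ValidationError("fraction must be in (0, 0.5]")
    v = scores.values
    n = len(v)
    if n < math.ceil(1.0 / fraction):
        raise GroupSizeError(f"need >= {math.ceil(1.0 / fraction)} units for fraction {fraction}")
    k = math.ceil(fraction * n)
    desc = np.argsort(-v, kind="stable")
    high_idx = list(desc[:k])
    asc = np.argsort(v, kind="stable")
    taken = set(high_idx)
    low_idx = [i for i in asc if i not in taken][:k]
    if v[desc[k - 1]] == v[desc[k]] or v[asc[k - 1]] == v[asc[k]] if n > k else False:
        warnings.warn("ties at the top/bottom cut broken by stable unit order", stacklevel=2)
    labels = ["medium"] * n
    for i in high_idx:
        labels[i] = "high"
    for i in low_idx:
        labels[i] = "low"
    lo_cut = float(max(v[i] for i in low_idx))
    hi_cut = float(min(v[i] for i in high_idx))
    return GroupAssignment(list(scores.unit_ids), labels, (lo_cut, hi_cut), "top_bottom_fraction")


def stime_classify(votes: dict[str, str], sample_id: str = "") -> StimeLabel:
    """Majority rule over per-cell-type senescence votes.

    HSTIME iff strictly more than half the evaluated cell types vote high;
    LSTIME iff strictly more than half vote low; otherwise MSTIME.
    """
    if not votes:
        raise ValidationError("stime_classify needs at least one vote")
    bad = set(votes.values()) - set(LABELS)
    if bad:
        raise ValidationError(f"unknown votes {bad}")
    n = len(votes)
    n_high = sum(1 for x in votes.values() if x == "high")
    n_low = sum(1 for x in votes.values() if x == "low")
    if n_high * 2 > n:
        label = "HSTIME"
    elif n_low * 2 > n:
        label = "LSTIME"
    else:
        label = "MSTIME"
    return StimeLabel(sample_id, label, dict(votes), n)


def classify_cohort(
    icss_by_celltype: dict[str, ScoreVector],
    pool_thresholds: bool = False,
) -> list[StimeLabel]:
    """Classify samples into STIME classes from per-cell-type ICSS vectors.

    Quartile groups are computed independently per cell type (thresholds are
    cell-type-specific); with ``pool_thresholds`` a single q1/q3 pair from
    the concatenated scores is applied to every cell type.  Each sample is
    then voted on by the cell types in which it appears.
    """
    if not icss_by_celltype:
        raise ValidationError("classify_cohort needs >= 1 cell type")
    if pool_thresholds:
        pooled = np.concatenate([sv.values for sv in icss_by_celltype.values()])
        q1, q3 = np.quantile(pooled, [0.25, 0.75])
        groups = {}
        for ct, sv in icss_by_celltype.items():
            if q1 == q3:
                labels = ["low" if x < q1 else "high" if x > q3 else "medium" for x in sv.values]
            else:
                labels = ["low" if x <= q1 else "high" if x >= q3 else "medium" for x in sv.values]
            groups[ct] = GroupAssignment(
                list(sv.unit_ids), labels, (float(q1), float(q3)), "quartile"
            )
    else:
        groups = {ct: quartile_groups(sv) for ct, sv in icss_by_celltype.items()}
    sample_order: list[str] = []
    seen = set()
    for sv in icss_by_celltype.values():
        for u in sv.unit_ids:
            if u not in seen:
                seen.add(u)
                sample_order.append(u)
    label_maps = {ct: g.as_dict() for ct, g in groups.items()}
    out = []
    for sample in sample_order:
        votes = {ct: m[sample] for ct, m in label_maps.items() if sample in m}
        out.append(stime_classify(votes, sample_id=sample))
    return out
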