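"""Parcellation overlap and P-FIT network membership.

The Parieto-Frontal Integration Theory (P-FIT) describes intelligence-related
cortex as a set of Brodmann areas (BA).  To decide whether an area of a finer
multimodal parcellation belongs to the network, the two label maps are
compared element-by-element on a common grid (voxels or vertices): an area is
P-FIT if at least ``overlap_threshold`` of its elements fall inside one P-FIT
BA in *both* hemispheres, or if a meta-analysis flagged the area's activity as
intelligence-related in both hemispheres.

Real annotation volumes are not shipped; :func:`synthetic_label_maps` builds a
small synthetic pair with known overlaps for testing and for annotating
simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabelMap:
    """Integer labels over a flat element grid, with a label dictionary."""

    labels: np.ndarray  # (n_elements,) integer; 0 = unlabeled background
    names: dict[int, str]
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("label map must be a flat array")


@dataclass
class PFITRule:
    """Membership rule: overlap with P-FIT BAs or meta-analytic flags."""

    pfit_areas: set[str]  # names of P-FIT areas in the reference map
    overlap_threshold: float = 0.8
    meta_analysis_areas: dict[str, set[str]] = field(default_factory=dict)  # hemi -> area names

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")


def overlap_fractions(parc_a: LabelMap, parc_b: LabelMap) -> pd.DataFrame:
    """Fraction of each A-area's elements carrying each B label.

    Rows are A areas, columns B areas; the denominator is the A-area's full
    element count, so rows sum to <= 1 when some of its elements are
    unlabeled in B.
    """
    if parc_a.labels.shape != parc_b.labels.shape:
        raise ValueError("label maps must cover the same grid")
    a = parc_a.labels
    b = parc_b.labels
    a_ids = sorted(set(np.unique(a)) - {0})
    b_ids = sorted(set(np.unique(b)) - {0})
    a_pos = {v: i for i, v in enumerate(a_ids)}
    b_pos = {v: i for i, v in enumerate(b_ids)}
    counts = np.zeros((len(a_ids), len(b_ids)))
    inside = (a != 0) & (b != 0)
    for av, bv in zip(a[inside], b[inside]):
        counts[a_pos[av], b_pos[bv]] += 1
    denom = np.array([(a == v).sum() for v in a_ids], dtype=float)
    frac = counts / denom[:, None]
    return pd.DataFrame(
        frac,
        index=[parc_a.names.get(v, str(v)) for v in a_ids],
        columns=[parc_b.names.get(v, str(v)) for v in b_ids],
    )


def classify_pfit(
    overlap_left: pd.DataFrame, overlap_right: pd.DataFrame, rule: PFITRule
) -> pd.Series:
    """P-FIT membership per area from both hemispheres' overlap tables.

    An area is a member iff its maximal overlap with any P-FIT BA reaches the
    threshold in both hemispheres, or it carries the meta-analysis flag in
    both.  Ties at exactly the threshold count as satisfying it.
    """
    areas_l = set(overlap_left.index)
    areas_r = set(overlap_right.index)
    if areas_l != areas_r:
        missing = areas_l ^ areas_r
        raise ValueError(f"areas present in one hemisphere only: {sorted(missing)}")

    def best(tbl: pd.DataFrame) -> pd.Series:
        cols = [c for c in tbl.columns if c in rule.pfit_areas]
        if not cols:
            return pd.Series(0.0, index=tbl.index)
        return tbl[cols].max(axis=1)

    bl, br = best(overlap_left), best(overlap_right)
    by_overlap = (bl >= rule.overlap_threshold) & (
        br.reindex(bl.index) >= rule.overlap_threshold
    )
    meta_l = rule.meta_analysis_areas.get("L", set())
    meta_r = rule.meta_analysis_areas.get("R", set())
    by_meta = pd.Series(
        [a in meta_l and a in meta_r for a in bl.index], index=bl.index
    )
    member = by_overlap | by_meta
    member.name = "pfit_member"
    return member


def synthetic_label_maps(
    regions: list[str],
    n_ba: int = 20,
    elements_per_region: int = 40,
    pfit_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[dict[str, tuple[LabelMap, LabelMap]], PFITRule]:
    """Synthetic fine/coarse parcellation pair with a known P-FIT rule.

    Builds, per hemisphere, a grid where each fine region occupies a
    contiguous block and each block is assigned mostly (or partly) to one
    coarse "Brodmann" area; a random subset of coarse areas is declared
    P-FIT.  Returned purely for testing and synthetic-cohort annotation —
    this is not a real atlas.
    """
    rng = np.random.default_rng(seed)
    ba_ids = list(range(1, n_ba + 1))
    ba_names = {i: f"BA{i}" for i in ba_ids}
    n_pfit = max(1, int(round(pfit_fraction * n_ba)))
    pfit_bas = set(rng.choice([f"BA{i}" for i in ba_ids], size=n_pfit, replace=False))
    fine_names = {i + 1: r for i, r in enumerate(regions)}
    # each region gets one dominant BA and a contamination fraction
    dominant = rng.integers(1, n_ba + 1, size=len(regions))
    purity = rng.uniform(0.5, 1.0, size=len(regions))
    maps = {}
    for hemi in ("L", "R"):
        fine = np.zeros(len(regions) * elements_per_region, dtype=int)
        coarse = np.zeros_like(fine)
        for i in range(len(regions)):
            sl = slice(i * elements_per_region, (i + 1) * elements_per_region)
            fine[sl] = i + 1
            n_dom = int(round(purity[i] * elements_per_region))
            block = np.full(elements_per_region, dominant[i])
            if n_dom < elements_per_region:
                other = rng.integers(1, n_ba + 1, size=elements_per_region - n_dom)
                block[n_dom:] = other
            coarse[sl] = block
        maps[hemi] = (
            LabelMap(fine, fine_names, hemisphere=hemi),
            LabelMap(coarse, ba_names, hemisphere=hemi),
        )
    meta = set(rng.choice(regions, size=max(1, len(regions) // 10), replace=False))
    rule = PFITRule(
        pfit_areas=pfit_bas,
        overlap_threshold=0.8,
        meta_analysis_areas={"L": meta, "R": meta},
    )
    return maps, rule


def pfit_membership(regions: list[str], seed: int = 0) -> pd.Series:
    """Membership flags for a synthetic parcellation (see synthetic_label_maps)."""
    maps, rule = synthetic_label_maps(regions, seed=seed)
    ol = overlap_fractions(*maps["L"])
    orr = overlap_fractions(*maps["R"])
    return classify_pfit(ol, orr, rule)
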