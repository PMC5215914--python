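"""End-to-end hybrid-ancestry census pipeline.

The framework proceeds in three stages:

1. **Stringent screen** — with the donor species as the only known-origin
   anchor, run both the admixture model (replicated, label-aligned) and
   the genotype-class model at a 99% purity rule on the
   morphologically-pure candidates, intersect the pure calls, and drop
   individuals carrying the donor-species mtDNA lineage.  The survivors
   form the *pre-defined pure group* that parameterizes everything later.
2. **Calibration** — simulate parental and hybrid classes from the
   pre-defined group and the donor anchors, build the power table, and
   choose the operating threshold by an explicit parental-risk rule.
3. **Final census** — re-run the admixture model over the whole
   population (morphological hybrids included) with both anchor groups
   flagged, classify at the chosen threshold, apply the mtDNA filter, and
   emit the census with its internal identities checked.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .admixture import (
    AdmixtureConfig,
    QMatrix,
    align_replicates,
    run_replicates,
)
from .core import MicrosatDataset
from .genepop import write_genepop
from .hybridclass import ClassModelConfig, run_class_mcmc
from .power import PowerTable, choose_threshold, simulate_power_table

__all__ = [
    "CensusReport",
    "Stage1Result",
    "Stage2Result",
    "stage1_stringent",
    "stage2_calibrate",
    "stage3_final",
    "parental_group_filter",
    "run_pipeline",
]


class CensusIdentityError(RuntimeError):
    """Internal census arithmetic failed — indicates a pipeline bug."""


@dataclass
class Stage1Result:
    admixture_pure: list[str]
    class_pure: list[str]
    intersection: list[str]
    mtdna_excluded: list[str]
    predefined_pure: list[str]
    qmatrix: QMatrix


@dataclass
class Stage2Result:
    power_table: PowerTable
    threshold: float
    rationale: str


@dataclass
class CensusReport:
    """Stage counts of the census with the two defining identities.

    Identity 1: ``final_pure == (stringent intersection - mtDNA excluded)
    + reincorporated``; identity 2: ``final_pure == assigned at the final
    threshold - mtDNA excluded at the final stage``.  Both are enforced at
    construction.
    """

    n_total: int
    n_morphology_hybrid: int
    n_morphology_pure: int
    stringent_admixture_pure: int
    stringent_class_pure: int
    stringent_intersection: int
    stage1_mtdna_excluded: int
    predefined_pure: int
    threshold: float
    assigned_pure_final: int
    final_mtdna_excluded: int
    reincorporated: int
    final_pure: int
    final_pure_ids: list[str] = field(default_factory=list)
    sex_counts: dict[str, int] = field(default_factory=dict)
    hybrid_attribution: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for name in (
            "n_total", "n_morphology_hybrid", "n_morphology_pure",
            "stringent_admixture_pure", "stringent_class_pure",
            "stringent_intersection", "stage1_mtdna_excluded",
            "predefined_pure", "assigned_pure_final", "final_mtdna_excluded",
            "reincorporated", "final_pure",
        ):
            if getattr(self, name) < 0:
                raise CensusIdentityError(f"negative count {name}")
        lhs1 = self.predefined_pure + self.reincorporated
        if self.final_pure != lhs1:
            raise CensusIdentityError(
                f"identity 1 violated: final {self.final_pure} != predefined "
                f"{self.predefined_pure} + reincorporated {self.reincorporated}"
            )
        lhs2 = self.assigned_pure_final - self.final_mtdna_excluded
        if self.final_pure != lhs2:
            raise CensusIdentityError(
                f"identity 2 violated: final {self.final_pure} != assigned "
                f"{self.assigned_pure_final} - mtDNA-excluded {self.final_mtdna_excluded}"
            )

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("final_pure_ids", "hybrid_attribution")
        }
        out["final_pure_ids"] = list(self.final_pure_ids)
        return out


def _flag_group(ds: MicrosatDataset, group: str, flag: bool = True) -> MicrosatDataset:
    new = [
        replace(ind, known_origin_flag=flag) if ind.group_label == group else ind
        for ind in ds.individuals
    ]
    return MicrosatDataset(ds.loci, new, ds.missing_code)


def _focal_cluster(qmat: QMatrix, anchor_b_group: str) -> int:
    """The focal (species-A) cluster: the one the donor anchors do NOT own."""
    if qmat.k != 2:
        raise ValueError("threshold classification assumes K = 2")
    return 1 - qmat.cluster_of_group(anchor_b_group)


def stage1_stringent(
    ds: MicrosatDataset,
    razor_group: str = "razor",
    threshold: float = 0.99,
    admix_cfg: Optional[AdmixtureConfig] = None,
    class_cfg: Optional[ClassModelConfig] = None,
    mt_b_label: str = "hapB",
    seed: int = 0,
) -> Stage1Result:
    """Compose the pre-defined pure group by the most stringent screen.

    Morphological hybrids are left out of this stage (a large hybrid
    fraction weakens the clustering); the donor group anchors one cluster.
    An individual joins the pre-defined group only if BOTH models call it
    pure at the 99% rule AND its mtDNA is not the donor lineage.
    """
    candidates = [
        ind.id
        for ind in ds.individuals
        if ind.group_label != razor_group and not ind.morphology_hybrid
    ]
    if not candidates:
        raise ValueError("no morphologically pure candidates to screen")
    sub = ds.subset(candidates + [i.id for i in ds.individuals if i.group_label == razor_group])
    sub = _flag_group(sub, razor_group)

    admix_cfg = admix_cfg or AdmixtureConfig(
        k=2, iterations=20_000, burnin=5_000, replicates=20, use_popinfo=True, seed=seed
    )
    # only the donor side is anchored here, so cluster frequencies must be
    # estimated from everyone (the focal cluster has no flagged members yet)
    admix_cfg = replace_cfg(
        admix_cfg, use_popinfo=True, freqs_from_flagged_only=False,
        seed=admix_cfg.seed or seed,
    )
    runs = run_replicates(sub, admix_cfg)
    qmat = align_replicates(runs) if len(runs) > 1 else runs[0]
    focal = _focal_cluster(qmat, razor_group)
    q_focal = dict(zip(qmat.ids, qmat.q[:, focal]))
    admixture_pure = [i for i in candidates if q_focal[i] >= threshold]

    class_cfg = class_cfg or ClassModelConfig(
        iterations=20_000, burnin=5_000, prior_pi="uniform", prior_theta="jeffreys", seed=seed + 1
    )
    z_fixed = {
        ind.id: "pureB" for ind in sub.individuals if ind.group_label == razor_group
    }
    post = run_class_mcmc(sub, class_cfg, z_fixed=z_fixed)
    idx_pure_a = post.class_names.index("pureA")
    q_class = dict(zip(post.ids, post.q[:, idx_pure_a]))
    class_pure = [i for i in candidates if q_class[i] >= threshold]

    intersection = [i for i in candidates if i in set(admixture_pure) and i in set(class_pure)]
    hap = {ind.id: ind.mt_haplotype for ind in ds.individuals}
    mtdna_excluded = [i for i in intersection if hap.get(i) == mt_b_label]
    predefined = [i for i in intersection if i not in set(mtdna_excluded)]
    if not predefined:
        raise ValueError(
            "stringent screen produced an empty pre-defined group; review thresholds"
        )
    return Stage1Result(
        admixture_pure, class_pure, intersection, mtdna_excluded, predefined, qmat
    )


def replace_cfg(cfg, **kwargs):
    """dataclasses.replace for config objects (kept importable for reuse)."""
    return replace(cfg, **kwargs)


def stage2_calibrate(
    ds: MicrosatDataset,
    predefined_pure: Sequence[str],
    razor_group: str = "razor",
    n_per_class: int = 100,
    thresholds: Sequence[float] = (0.95, 0.98, 0.99),
    prior_combos=None,
    admix_cfg: Optional[AdmixtureConfig] = None,
    class_cfg: Optional[ClassModelConfig] = None,
    max_parental_error: float = 0.05,
    seed: int = 0,
) -> Stage2Result:
    """Power-calibrate the purity threshold from the pre-defined group."""
    if not predefined_pure:
        raise ValueError("pre-defined pure set is empty")
    if admix_cfg is not None:
        # honor the caller's chain sizes but force the scoring-run model
        # settings (see simulate_power_table defaults for the rationale)
        admix_cfg = replace_cfg(
            admix_cfg, use_popinfo=True, freqs_from_flagged_only=True,
            freq_model="independent", sample_alpha=False, alpha=0.2,
        )
    anchors_a = ds.subset(predefined_pure).relabel(
        {g: "anchorA" for g in ds.subset(predefined_pure).group_labels}
    )
    anchors_b = ds.group(razor_group)
    pt = simulate_power_table(
        anchors_a,
        anchors_b,
        n_per_class=n_per_class,
        thresholds=thresholds,
        prior_combos=prior_combos,
        admix_cfg=admix_cfg,
        class_cfg=class_cfg,
        seed=seed,
    )
    thr = choose_threshold(pt, max_parental_error=max_parental_error)
    rationale = (
        f"threshold {thr:.2f}: parental error <= {max_parental_error:.0%} with "
        f"maximal detection of the deepest simulated backcross"
    )
    return Stage2Result(pt, thr, rationale)


def stage3_final(
    ds: MicrosatDataset,
    predefined_pure: Sequence[str],
    threshold: float,
    razor_group: str = "razor",
    admix_cfg: Optional[AdmixtureConfig] = None,
    mt_b_label: str = "hapB",
    q_ranges: Optional[dict[str, np.ndarray]] = None,
    seed: int = 0,
) -> CensusReport:
    """Final classification of every individual and the census arithmetic.

    The pre-defined group and the donor group are flagged as known origin;
    everyone else (morphological hybrids included) is classified at the
    calibrated threshold, then filtered on mtDNA.  If per-class simulated
    q ranges are supplied, admixed individuals are attributed to hybrid
    classes by range membership, with overlaps reported rather than forced
    to a single label.
    """
    predefined = set(predefined_pure)
    flagged = [
        replace(
            ind,
            known_origin_flag=(ind.id in predefined or ind.group_label == razor_group),
            group_label=("predefA" if ind.id in predefined else ind.group_label),
        )
        for ind in ds.individuals
    ]
    run_ds = MicrosatDataset(ds.loci, flagged, ds.missing_code)
    # the final run must mirror the calibration runs' model settings, or the
    # calibrated threshold does not transfer: anchors pinned, cluster
    # frequencies from anchors only, independent-frequencies prior
    admix_cfg = admix_cfg or AdmixtureConfig(
        k=2, iterations=20_000, burnin=5_000, replicates=20, use_popinfo=True,
        freqs_from_flagged_only=True, freq_model="independent",
        sample_alpha=False, alpha=0.2, seed=seed,
    )
    admix_cfg = replace_cfg(
        admix_cfg, use_popinfo=True, freqs_from_flagged_only=True,
        freq_model="independent", sample_alpha=False, alpha=0.2,
    )
    runs = run_replicates(run_ds, admix_cfg)
    qmat = align_replicates(runs) if len(runs) > 1 else runs[0]
    focal = _focal_cluster(qmat, razor_group)
    q_focal = dict(zip(qmat.ids, qmat.q[:, focal]))

    non_razor = [ind for ind in ds.individuals if ind.group_label != razor_group]
    assigned_pure = [ind.id for ind in non_razor if q_focal[ind.id] >= threshold]
    hap = {ind.id: ind.mt_haplotype for ind in ds.individuals}
    final_excluded = [i for i in assigned_pure if hap.get(i) == mt_b_label]
    final_pure = [i for i in assigned_pure if i not in set(final_excluded)]
    reincorporated = [i for i in final_pure if i not in predefined]
    if not predefined.issubset(set(final_pure)):
        # flagged individuals are pinned to q = 1, so this cannot happen
        # unless their mtDNA labels changed between stages
        raise CensusIdentityError("pre-defined individuals lost at the final stage")

    sex = {ind.id: ind.sex for ind in ds.individuals}
    sex_counts = {"male": 0, "female": 0, "unknown": 0}
    for i in final_pure:
        sex_counts[sex.get(i) or "unknown"] += 1

    attribution = None
    if q_ranges:
        rows = []
        ranges = {
            cls: (float(v.min()), float(v.max()))
            for cls, v in q_ranges.items()
            if cls not in ("pureA", "pureB") and len(v)
        }
        for ind in non_razor:
            if ind.id in set(assigned_pure):
                continue
            q = q_focal[ind.id]
            compatible = [c for c, (lo, hi) in ranges.items() if lo <= q <= hi]
            if len(compatible) == 1:
                call, note = compatible[0], ""
            elif compatible:
                call, note = "unassigned", "overlapping class ranges: " + ",".join(compatible)
            else:
                call, note = "unassigned", "q outside all simulated class ranges"
            rows.append({"id": ind.id, "q": q, "class_call": call, "note": note})
        attribution = pd.DataFrame(rows)

    return _build_report(
        non_razor, predefined, threshold, len(assigned_pure), len(final_excluded),
        final_pure, len(reincorporated), sex_counts, attribution,
    )


def _build_report(
    non_razor, predefined, threshold, n_assigned_pure, n_final_excluded,
    final_pure_ids, n_reincorporated, sex_counts, attribution,
    stage1: Optional[Stage1Result] = None,
) -> CensusReport:
    n_morph_hybrid = sum(1 for ind in non_razor if ind.morphology_hybrid)
    return CensusReport(
        n_total=len(non_razor),
        n_morphology_hybrid=n_morph_hybrid,
        n_morphology_pure=len(non_razor) - n_morph_hybrid,
        stringent_admixture_pure=len(stage1.admixture_pure) if stage1 else len(predefined),
        stringent_class_pure=len(stage1.class_pure) if stage1 else len(predefined),
        stringent_intersection=len(stage1.intersection) if stage1 else len(predefined),
        stage1_mtdna_excluded=len(stage1.mtdna_excluded) if stage1 else 0,
        predefined_pure=len(predefined),
        threshold=threshold,
        assigned_pure_final=n_assigned_pure,
        final_mtdna_excluded=n_final_excluded,
        reincorporated=n_reincorporated,
        final_pure=len(final_pure_ids),
        final_pure_ids=list(final_pure_ids),
        sex_counts=sex_counts,
        hybrid_attribution=attribution,
    )


def parental_group_filter(
    ds: MicrosatDataset,
    final_pure_ids: Sequence[str],
    birth_window: tuple[int, int] = (1990, 1999),
    razor_group: str = "razor",
    mt_b_label: str = "hapB",
) -> tuple[list[str], dict[str, int], int]:
    """The 'parental group': final-pure, focal-phenotype individuals born in
    the window, with the focal mtDNA lineage.

    Returns (ids, sex counts, number excluded for missing birth year).
    """
    lo, hi = birth_window
    final = set(final_pure_ids)
    ids, n_missing_year = [], 0
    sex_counts = {"male": 0, "female": 0, "unknown": 0}
    for ind in ds.individuals:
        if ind.group_label == razor_group or ind.morphology_hybrid:
            continue
        if ind.id not in final or ind.mt_haplotype == mt_b_label:
            continue
        if ind.birth_year is None:
            n_missing_year += 1
            continue
        if lo <= ind.birth_year <= hi:
            ids.append(ind.id)
            sex_counts[ind.sex or "unknown"] += 1
    return ids, sex_counts, n_missing_year


def run_pipeline(
    ds: MicrosatDataset,
    razor_group: str = "razor",
    stringent_threshold: float = 0.99,
    n_per_class: int = 100,
    thresholds: Sequence[float] = (0.95, 0.98, 0.99),
    prior_combos=None,
    admix_cfg: Optional[AdmixtureConfig] = None,
    class_cfg: Optional[ClassModelConfig] = None,
    max_parental_error: float = 0.05,
    mt_b_label: str = "hapB",
    seed: int = 0,
) -> tuple[CensusReport, Stage1Result, Stage2Result, dict]:
    """Run stages 1-3 and return (census, stage1, stage2, provenance).

    The provenance dict records the input hash, seed and configuration so
    a run can be reproduced bit-identically.
    """
    s1 = stage1_stringent(
        ds, razor_group=razor_group, threshold=stringent_threshold,
        admix_cfg=admix_cfg, class_cfg=class_cfg, mt_b_label=mt_b_label, seed=seed,
    )
    s2 = stage2_calibrate(
        ds, s1.predefined_pure, razor_group=razor_group, n_per_class=n_per_class,
        thresholds=thresholds, prior_combos=prior_combos,
        admix_cfg=admix_cfg, class_cfg=class_cfg,
        max_parental_error=max_parental_error, seed=seed + 1,
    )
    report3 = stage3_final(
        ds, s1.predefined_pure, s2.threshold, razor_group=razor_group,
        admix_cfg=admix_cfg, mt_b_label=mt_b_label,
        q_ranges=s2.power_table.q_ranges, seed=seed + 2,
    )
    # rebuild the report with the stage-1 counts folded in
    non_razor = [ind for ind in ds.individuals if ind.group_label != razor_group]
    report = _build_report(
        non_razor,
        set(s1.predefined_pure),
        s2.threshold,
        n_assigned_pure=report3.assigned_pure_final,
        n_final_excluded=report3.final_mtdna_excluded,
        final_pure_ids=report3.final_pure_ids,
        n_reincorporated=report3.reincorporated,
        sex_counts=report3.sex_counts,
        attribution=report3.hybrid_attribution,
        stage1=s1,
    )
    provenance = {
        "input_sha256": hashlib.sha256(write_genepop(ds).encode()).hexdigest(),
        "seed": seed,
        "razor_group": razor_group,
        "stringent_threshold": stringent_threshold,
        "chosen_threshold": s2.threshold,
        "n_per_class": n_per_class,
        "thresholds": list(thresholds),
        "admixture_config": dict(admix_cfg.__dict__) if admix_cfg else "stage defaults",
        "class_config": dict(class_cfg.__dict__) if class_cfg else "stage defaults",
    }
    return report, s1, s2, provenance
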