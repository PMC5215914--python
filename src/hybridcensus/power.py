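"""Power analysis of hybrid detection and operating-threshold selection.

Given two anchor sets of known-origin parental genotypes, this module
simulates genotypes of each parental and hybrid class from the anchors'
allele frequencies, pushes them through the admixture model (at several
purity thresholds) and the genotype-class model (at several prior
combinations), and tabulates the percentage of each simulated class
correctly recognized as parental or hybrid — independently of which
hybrid class it gets attributed to.  The resulting table is the basis for
choosing the operating threshold by an explicit risk rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .admixture import AdmixtureConfig, align_replicates, run_replicates
from .core import MicrosatDataset, allele_frequencies
from .hybridclass import (
    ClassModelConfig,
    classify_single_class,
    run_class_mcmc,
)
from .simulate import HYBRID_CLASSES, simulate_hybrid_class_frequency

__all__ = ["PowerTable", "simulate_power_table", "choose_threshold"]

_PURE = ("pureA", "pureB")
DEFAULT_CLASS_ORDER = ("pureA", "pureB", "F1", "F2", "F3", "BxA1", "BxA2", "BxA3", "BxA4")
DEFAULT_PRIOR_COMBOS = (
    ("jeffreys", "jeffreys"),
    ("jeffreys", "uniform"),
    ("uniform", "uniform"),
    ("uniform", "jeffreys"),
)


@dataclass
class PowerTable:
    """Per-class, per-setting percentage of simulated genotypes scored correct.

    ``table`` rows are simulated classes, columns are settings
    (``admixture_95`` ... and/or ``class_<pi>x<theta>``); cells are
    percentages in [0, 100].  ``q_ranges`` keeps the admixture q values
    (toward the focal species) of each simulated class, used downstream
    for hybrid-class attribution by range overlap.
    """

    table: pd.DataFrame
    n_per_class: int
    q_ranges: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "n", self.n_per_class)
        out.to_csv(path, sep="\t")


def _admixture_correct(cls: str, q_focal: np.ndarray, q_all: np.ndarray, thr: float) -> np.ndarray:
    """Correctness mask for one simulated class at one threshold.

    A parental simulant is correct when called pure toward its own
    cluster; a hybrid simulant is correct when called pure toward neither
    cluster (max q below the threshold).
    """
    if cls == "pureA":
        return q_focal >= thr
    if cls == "pureB":
        return (1.0 - q_focal) >= thr
    return q_all.max(axis=1) < thr


def simulate_power_table(
    anchors_a: MicrosatDataset,
    anchors_b: MicrosatDataset,
    classes: Sequence[str] = DEFAULT_CLASS_ORDER,
    n_per_class: int = 100,
    thresholds: Sequence[float] = (0.95, 0.98, 0.99),
    prior_combos: Optional[Sequence[tuple[str, str]]] = DEFAULT_PRIOR_COMBOS,
    admix_cfg: Optional[AdmixtureConfig] = None,
    class_cfg: Optional[ClassModelConfig] = None,
    seed: int = 0,
    joint: bool = True,
) -> PowerTable:
    """Build the power table from two anchor datasets.

    The anchors' allele frequencies parameterize the gamete-pool
    simulation of ``n_per_class`` genotypes per class.  In the admixture
    run the anchors are flagged as known-origin while every simulant
    enters with unknown origin; by default all classes are scored in one
    joint run (``joint=False`` runs one class at a time).  Set
    ``prior_combos=None`` to skip the genotype-class model.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    for cls in classes:
        if cls not in HYBRID_CLASSES:
            raise KeyError(f"unknown class {cls!r}")
    rng = np.random.default_rng(seed)
    freq_a = allele_frequencies(anchors_a).single_group(anchors_a.group_labels[0])
    freq_b = allele_frequencies(anchors_b).single_group(anchors_b.group_labels[0])

    anchors = anchors_a.relabel({anchors_a.group_labels[0]: "anchorA"}).concat(
        anchors_b.relabel({anchors_b.group_labels[0]: "anchorB"})
    )
    from dataclasses import replace

    anchors = MicrosatDataset(
        anchors.loci,
        [replace(ind, known_origin_flag=True) for ind in anchors.individuals],
    )

    sims = {
        cls: simulate_hybrid_class_frequency(
            freq_a, freq_b, cls, n_per_class,
            seed=int(rng.integers(2**31 - 1)),
            group_label=f"sim_{cls}", id_prefix=f"sim_{cls}",
        )
        for cls in classes
    }

    # Scoring runs anchor the clusters on the flagged parentals and, as in
    # the emulated protocol, estimate cluster allele frequencies from the
    # flagged individuals only; the independent-frequencies prior keeps the
    # two clusters' frequency estimates uncoupled, which preserves their
    # separation when most of the batch is admixed.  Alpha is fixed at a
    # small, weakly informative value (prior weight 0.4 allele copies
    # against 28 observed): the batch's class composition is a design
    # artifact, so fitting the admixture hyperprior to it is meaningless
    # and drives a strong shrinkage of q toward 0.5.
    admix_cfg = admix_cfg or AdmixtureConfig(
        k=2, iterations=20_000, burnin=5_000, replicates=1, use_popinfo=True,
        freqs_from_flagged_only=True, freq_model="independent",
        sample_alpha=False, alpha=0.2,
    )
    results: dict[str, dict[str, float]] = {cls: {} for cls in classes}
    q_ranges: dict[str, np.ndarray] = {}

    def _score_run(ds_run: MicrosatDataset, member_classes: Sequence[str]) -> None:
        cfg = AdmixtureConfig(
            **{**admix_cfg.__dict__, "use_popinfo": True,
               "seed": int(rng.integers(2**31 - 1))}
        )
        runs = run_replicates(ds_run, cfg)
        qmat = align_replicates(runs) if len(runs) > 1 else runs[0]
        focal = 1 - qmat.cluster_of_group("anchorB") if qmat.k == 2 else qmat.cluster_of_group("anchorA")
        groups = np.array(qmat.groups)
        for cls in member_classes:
            mask = groups == f"sim_{cls}"
            q_focal = qmat.q[mask, focal]
            q_ranges[cls] = q_focal
            for thr in thresholds:
                ok = _admixture_correct(cls, q_focal, qmat.q[mask], thr)
                results[cls][f"admixture_{int(round(thr * 100))}"] = 100.0 * ok.mean()

    if joint:
        ds_run = anchors
        for cls in classes:
            ds_run = ds_run.concat(sims[cls])
        _score_run(ds_run, list(classes))
    else:
        for cls in classes:
            _score_run(anchors.concat(sims[cls]), [cls])

    if prior_combos:
        base_class_cfg = class_cfg or ClassModelConfig(iterations=15_000, burnin=3_000)
        z_fixed = {ind.id: "pureA" for ind in anchors.individuals if ind.group_label == "anchorA"}
        z_fixed.update(
            {ind.id: "pureB" for ind in anchors.individuals if ind.group_label == "anchorB"}
        )
        ds_run = anchors
        for cls in classes:
            ds_run = ds_run.concat(sims[cls])
        model_class_names = [c.name for c in base_class_cfg.classes]
        pure_names = {"pureA", "pureB"}
        for prior_pi, prior_theta in prior_combos:
            cfg = ClassModelConfig(
                **{**base_class_cfg.__dict__, "prior_pi": prior_pi,
                   "prior_theta": prior_theta,
                   "seed": int(rng.integers(2**31 - 1))}
            )
            post = run_class_mcmc(ds_run, cfg, z_fixed=z_fixed)
            calls = classify_single_class(post, cutoff=0.70)
            col = f"class_{prior_pi[:3]}x{prior_theta[:3]}"
            groups = np.array([ind.group_label for ind in ds_run.individuals])
            for cls in classes:
                sub = calls[groups == f"sim_{cls}"]
                if cls in _PURE:
                    # a parental simulant must be called its own pure class
                    ok = sub == cls
                else:
                    # any non-pure class counts; 'unassigned' does not
                    ok = sub.isin([n for n in model_class_names if n not in pure_names])
                results[cls][col] = 100.0 * ok.mean()

    table = pd.DataFrame(results).T.loc[list(classes)]
    return PowerTable(table, n_per_class, q_ranges)


def choose_threshold(
    pt: PowerTable,
    max_parental_error: float = 0.05,
    parental_row: str = "pureA",
) -> float:
    """Pick the operating admixture threshold by an explicit risk rule.

    Among thresholds whose focal-parental misassignment rate
    ``(100 - parental%) / 100`` does not exceed ``max_parental_error``,
    choose the one maximizing detection of the deepest backcross
    generation present in the table; ties break toward the lower
    threshold (fewer pure individuals sacrificed).
    """
    cols = [c for c in pt.table.columns if c.startswith("admixture_")]
    if not cols or pt.table.empty:
        raise ValueError("power table has no admixture columns")
    if parental_row not in pt.table.index:
        raise ValueError(f"power table has no parental row {parental_row!r}")
    backcrosses = [r for r in pt.table.index if r.startswith("BxA")]
    if not backcrosses:
        raise ValueError("power table has no backcross rows")
    deepest = backcrosses[-1]
    qualifying = []
    errors = {}
    for col in cols:
        thr = int(col.split("_")[1]) / 100.0
        err = (100.0 - float(pt.table.loc[parental_row, col])) / 100.0
        errors[col] = err
        if err <= max_parental_error + 1e-12:
            qualifying.append((float(pt.table.loc[deepest, col]), -thr, thr))
    if not qualifying:
        raise ValueError(
            f"no threshold satisfies parental error <= {max_parental_error}: {errors}"
        )
    qualifying.sort(reverse=True)
    return qualifying[0][2]
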