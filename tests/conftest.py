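"""Shared fixtures.

The heavyweight objects (calibrated parental frequencies, the joint
simulated-class admixture run, the end-to-end pipeline run on the synthetic
study fixture) are session-scoped so several tests can share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import hybridcensus as hc
from hybridcensus.core import IndividualRecord, LocusDef, MicrosatDataset

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study_conditions():
    """Calibrated parental frequency tables at the study's differentiation."""
    cfg = hc.SimulationConfig(seed=STUDY_SEED)
    freq_a, freq_b = hc.make_parental_frequencies(cfg)
    return cfg, freq_a, freq_b


@pytest.fixture(scope="session")
def anchor_sets(study_conditions):
    """Known-origin anchor datasets shaped like the study's (57 + 33)."""
    _, freq_a, freq_b = study_conditions
    anchors_a = hc.sample_population(
        freq_a, 57, seed=11, group_label="predefA", id_prefix="pA", known_origin=True
    )
    anchors_b = hc.sample_population(
        freq_b, 33, seed=12, group_label="razor", id_prefix="rz", known_origin=True
    )
    return anchors_a, anchors_b


SIM_CLASSES = ("pureA", "pureB", "F1", "F2", "F3", "BxA1", "BxA2", "BxA3", "BxA4")


@pytest.fixture(scope="session")
def joint_class_run(study_conditions, anchor_sets):
    """One joint admixture run over 100 simulants of every class plus anchors.

    Mirrors the study's power protocol: anchors flagged, cluster
    frequencies from the anchors only, independent-frequencies prior,
    fixed weakly-informative alpha, reduced chains.  Returns the per-class
    arrays of q toward the donor (B) cluster.
    """
    _, freq_a, freq_b = study_conditions
    anchors_a, anchors_b = anchor_sets
    ds = anchors_a.concat(anchors_b)
    for i, cls in enumerate(SIM_CLASSES):
        sim = hc.simulate_hybrid_class_frequency(
            freq_a, freq_b, cls, 100, seed=100 + i, group_label=f"sim_{cls}"
        )
        ds = ds.concat(sim)
    cfg = hc.AdmixtureConfig(
        k=2, iterations=50_000, burnin=10_000, use_popinfo=True,
        freqs_from_flagged_only=True, freq_model="independent",
        sample_alpha=False, alpha=0.2, seed=5,
    )
    qmat = hc.run_admixture(ds, cfg)
    focal = 1 - qmat.cluster_of_group("razor")
    groups = np.array(qmat.groups)
    q_b = {
        cls: 1.0 - qmat.q[groups == f"sim_{cls}", focal] for cls in SIM_CLASSES
    }
    q_max = {
        cls: qmat.q[groups == f"sim_{cls}"].max(axis=1) for cls in SIM_CLASSES
    }
    return q_b, q_max


@pytest.fixture(scope="session")
def pipeline_run():
    """End-to-end pipeline on the synthetic study fixture (reduced chains)."""
    cfg = hc.SimulationConfig(seed=STUDY_SEED)
    fixture = hc.make_study_fixture(cfg)
    admix_cfg = hc.AdmixtureConfig(
        k=2, iterations=8_000, burnin=2_000, replicates=3, use_popinfo=True, seed=5
    )
    class_cfg = hc.ClassModelConfig(
        iterations=8_000, burnin=2_000, prior_pi="uniform", prior_theta="jeffreys", seed=6
    )
    report, s1, s2, provenance = hc.run_pipeline(
        fixture.dataset, n_per_class=25, admix_cfg=admix_cfg, class_cfg=class_cfg, seed=5
    )
    return fixture, report, s1, s2, provenance


# ---------------------------------------------------------------------------
# small deterministic fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def two_by_two_dataset():
    """Two individuals, two loci; hand-parseable."""
    loci = [LocusDef("L1", ()), LocusDef("L2", ())]
    inds = [
        IndividualRecord("a1", "grp1", ((101, 103), (101, 101))),
        IndividualRecord("a2", "grp1", ((101, 101), None)),
    ]
    return MicrosatDataset(loci, inds)


def make_diagnostic_freqs(n_loci: int = 14, allele_a: int = 101, allele_b: int = 105):
    """Fully diagnostic frequency tables: A fixed for one allele, B for another."""
    loci = [f"L{j + 1}" for j in range(n_loci)]
    freqs_a = {("A", l): {allele_a: 1.0} for l in loci}
    freqs_b = {("B", l): {allele_b: 1.0} for l in loci}
    sizes = {k: 100 for k in list(freqs_a) + list(freqs_b)}
    fa = hc.FreqTable(("A",), loci, freqs_a, {k: 100 for k in freqs_a})
    fb = hc.FreqTable(("B",), loci, freqs_b, {k: 100 for k in freqs_b})
    return fa, fb


@pytest.fixture
def diagnostic_freqs():
    return make_diagnostic_freqs()
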