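"""Canned study conditions for validation experiments.

These builders pin down the synthetic cohorts used to validate state recovery:
three strongly separated block-covariance states (one intra-network, two
inter-network archetypes with both positive and negative between-network
coupling), Markov switching with a configurable mean dwell time, 30 subjects
of T = 400 timepoints at C = 53 components by default.  Both the test suite
and the reproduction script draw their cohorts from here so the conditions
stay identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import select_k_elbow
from .synthetic import (
    CohortDesign,
    Cohort,
    MarkovDesign,
    NetworkPartition,
    StateArchetype,
    gen_network_partition,
)
from .synthetic import gen_cohort
from .windows import DfncWindows, TaperSpec, compute_dfnc, make_taper


def three_state_archetypes(noise_sd: float = 0.05) -> list[StateArchetype]:
    """Strongly separated three-state design.

    State 1 is purely intra-network (strong within-block coupling only);
    state 2 couples the sensory networks positively; state 3 mixes positive
    sensory and cerebellar-subcortical coupling with negative default-mode to
    sensory coupling.  Low observation noise keeps windowed correlation
    estimates close to the planted values.
    """
    sensory = [("ADN", "SMN"), ("ADN", "VSN"), ("SMN", "VSN")]
    inter2: dict = {frozenset(p): 0.6 for p in sensory}
    inter3: dict = {frozenset(p): 0.35 for p in sensory}
    for net in ("ADN", "SMN", "VSN"):
        inter3[frozenset((net, "DMN"))] = -0.35
    inter3[frozenset(("CBN", "SCN"))] = 0.5
    return [
        StateArchetype("intra", intra_block_strength=0.8,
                       inter_block_strength=0.0, noise_sd=noise_sd),
        StateArchetype("inter-sensory", intra_block_strength=0.25,
                       inter_block_strength=inter2, noise_sd=noise_sd),
        StateArchetype("inter-mixed", intra_block_strength=0.45,
                       inter_block_strength=inter3, noise_sd=noise_sd),
    ]


def dwell_markov(mean_dwell: float = 50.0, K: int = 3,
                 subject_concentration: float = 200.0) -> MarkovDesign:
    """Symmetric K-state chain with the requested mean dwell time (in TRs)."""
    stay = 1.0 - 1.0 / mean_dwell
    P = np.full((K, K), (1.0 - stay) / (K - 1))
    np.fill_diagonal(P, stay)
    return MarkovDesign(K=K, transition=P,
                        subject_concentration=subject_concentration)


def three_state_cohort(
    seed: int,
    n_subjects: int = 30,
    T: int = 400,
    mean_dwell: float = 50.0,
    noise_sd: float = 0.05,
    partition: NetworkPartition | None = None,
) -> Cohort:
    """A planted three-state cohort at the standard validation scale."""
    if partition is None:
        partition = gen_network_partition(53, 7, seed=0)
    design = CohortDesign(n_subjects=n_subjects, T=T)
    return gen_cohort(design, partition, three_state_archetypes(noise_sd),
                      dwell_markov(mean_dwell), seed=seed)


def cohort_windows(cohort: Cohort, spec: TaperSpec | None = None) -> list[DfncWindows]:
    """Tapered sliding-window connectivity for every subject in a cohort."""
    spec = spec or TaperSpec()
    return [compute_dfnc(tc, spec) for tc in cohort.timecourses]


def true_window_labels(cohort: Cohort, windows: list[DfncWindows]) -> list[np.ndarray]:
    """Ground-truth state per window: the taper-weighted modal planted state.

    Windows straddling a state switch are labeled with whichever state
    carries more taper mass inside the window.
    """
    out = []
    K = int(cohort.truth["ocr"].shape[1])
    for seq, w in zip(cohort.truth["state_sequences"], windows):
        taper = make_taper(w.taper)
        L = len(taper)
        labels = np.empty(w.n_windows, dtype=int)
        for i, s in enumerate(w.window_starts):
            seg = seq[s: s + L]
            mass = np.bincount(seg, weights=taper, minlength=K + 1)[1:]
            labels[i] = int(np.argmax(mass)) + 1
        out.append(labels)
    return out


@dataclass
class ElbowExperiment:
    """Result of the repeated elbow-selection experiment."""

    selected: list[int]
    modal_k: int
    curves: list[dict[int, float]]


def run_elbow_experiment(
    seed: int,
    n_seeds: int = 10,
    n_subjects: int = 30,
    T: int = 400,
    mean_dwell: float = 50.0,
    k_range: range = range(2, 10),
    n_init: int = 10,
) -> ElbowExperiment:
    """Repeat cohort generation + elbow selection over ``n_seeds`` replicates.

    Each replicate generates a fresh three-state cohort, computes tapered
    sliding-window connectivity (width 20, sigma 3, step 1) and selects k by
    the elbow criterion over ``k_range``.
    """
    root = np.random.SeedSequence(seed)
    selected, curves = [], []
    for ss in root.spawn(n_seeds):
        child = np.random.default_rng(ss)
        rep_seed = int(child.integers(2**31))
        cohort = three_state_cohort(rep_seed, n_subjects=n_subjects, T=T,
                                    mean_dwell=mean_dwell)
        wins = cohort_windows(cohort)
        pooled = np.vstack([w.matrix for w in wins])
        k_best, curve = select_k_elbow(pooled, k_range, n_init=n_init,
                                       seed=rep_seed)
        selected.append(k_best)
        curves.append(curve)
    counts = np.bincount(selected)
    return ElbowExperiment(selected=selected, modal_k=int(np.argmax(counts)),
                           curves=curves)
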